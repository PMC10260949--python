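"""Levy pooling and the SSB cost / consumer-price arithmetic.

The UK soft-drinks industry levy is a two-rate volumetric levy on the
producer: 0.18 GBP/l for drinks with 5-8 g sugar/100 ml and 0.24 GBP/l
above 8 g/100 ml. For the market as a whole it is summarised by a single
pooled rate, the sales-volume-weighted mean of the band rates. A change
in the wholesale sugar price feeds into production cost through the sugar
content of the drink (g/l x GBP/t = 1e-6 GBP/l), and the producer cost
change reaches the consumer scaled by a pass-through rate.

All downstream computation uses unrounded GBP/l values; rounding to whole
pence is applied only in display tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: statutory band rates, GBP per litre
DEFAULT_BAND_RATES = {"mid": 0.18, "high": 0.24}
#: default sales-volume split over the levied bands; reproduces the
#: 0.23 GBP/l pooled rate
DEFAULT_BAND_SHARES = {"mid": 1.0 / 6.0, "high": 5.0 / 6.0}

DEFAULT_SUGAR_CONTENT = 93.0  # g sugar per litre of SSB (UK market mean)
DEFAULT_BASELINE_PRICE = 0.61  # GBP per litre, mean SSB consumer price
PASS_THROUGH_RATES = (0.8, 1.0, 1.2)


class LevySpecError(ValueError):
    pass


class PriceAssumptionError(ValueError):
    pass


@dataclass(frozen=True)
class LevySpec:
    """Band rates (GBP/l) and the sales-volume share of each band.

    A zero-rated band (<5 g/100 ml) can be represented with rate 0, but the
    default shares cover only the two levied bands.
    """

    band_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_RATES))
    band_sales_shares: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_SHARES)
    )

    def __post_init__(self):
        if set(self.band_sales_shares) - set(self.band_rates):
            raise LevySpecError(
                "sales shares refer to bands without rates: "
                f"{sorted(set(self.band_sales_shares) - set(self.band_rates))}"
            )
        if any(r < 0 for r in self.band_rates.values()):
            raise LevySpecError("band rates must be non-negative")
        if any(s < 0 for s in self.band_sales_shares.values()):
            raise LevySpecError("band sales shares must be non-negative")
        total = sum(self.band_sales_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise LevySpecError(f"band sales shares must sum to 1; got {total!r}")


@dataclass(frozen=True)
class PriceAssumptions:
    """Market-level price assumptions.

    sugar_content : g sugar per litre of SSB (default 93).
    baseline_price : mean SSB consumer price, GBP/l (default 0.61).
    pass_through : fraction of a producer cost change reaching the consumer
        price (0.8 / 1.0 / 1.2 modelled; values above 1 mean
        over-shifting).
    """

    sugar_content: float = DEFAULT_SUGAR_CONTENT
    baseline_price: float = DEFAULT_BASELINE_PRICE
    pass_through: float = 1.0

    def __post_init__(self):
        if self.sugar_content <= 0:
            raise PriceAssumptionError("sugar_content must be positive")
        if self.baseline_price <= 0:
            raise PriceAssumptionError("baseline_price must be positive")
        if not 0 < self.pass_through < 10:
            raise PriceAssumptionError(
                f"pass_through must lie in (0, 10); got {self.pass_through}"
            )


def pooled_levy_rate(levy: LevySpec) -> float:
    """Sales-volume-weighted single-rate equivalent of the levy, GBP/l."""
    return sum(
        levy.band_rates[band] * share
        for band, share in levy.band_sales_shares.items()
    )


def production_cost_change(
    sugar_price_change: float,
    assumptions: PriceAssumptions,
    levy_rate: float = 0.0,
) -> float:
    """SSB production-cost change, GBP per litre.

    levy_rate (GBP/l) plus the sugar-price change (GBP/t) converted
    through sugar content (g/l); 1 g/l x 1 GBP/t = 1e-6 GBP/l.
    """
    return levy_rate + sugar_price_change * assumptions.sugar_content * 1e-6


def consumer_price_change(cost_change: float, assumptions: PriceAssumptions) -> float:
    """Relative change in the SSB consumer price (fraction of baseline)."""
    return assumptions.pass_through * cost_change / assumptions.baseline_price


def pence_per_litre(cost_change: float) -> int:
    """Display helper: GBP/l rounded half-up to whole pence."""
    import math

    return int(math.floor(cost_change * 100 + 0.5))
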