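"""Post-Brexit trade regimes and their effect on the wholesale sugar price.

A trade regime is summarised by the import share of the UK sugar supply,
the split of those imports over three segments (EU, third-country
preferential, third-country non-preferential), and per-segment changes in
applied tariffs and trade-facilitation (border friction) costs relative to
the pre-Brexit baseline. The induced change in the sugar price is the
import-share-weighted mean per-tonne cost change:

    dP = import_share * sum_s share_s * (dtariff_s + dfacilitation_s)

converted to GBP when the per-tonne figures are EUR-denominated. Domestic
production is assumed to keep its market share and its price response is
not modelled, so only the imported share contributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

SEGMENTS = ("eu", "third_preferential", "third_non_preferential")

#: printed UK sugar-supply structure (2015): imports are 64% of supply, the
#: EU supplies 53% of imports, and 94% of third-country imports arrive under
#: preferential agreements.
IMPORT_SHARE_OF_SUPPLY = 0.64
EU_SHARE_OF_IMPORTS = 0.53
PREFERENTIAL_SHARE_OF_THIRD = 0.94

DEFAULT_EXCHANGE_RATE = 0.885  # GBP per EUR

_SEGMENT_SHARES = {
    "eu": EU_SHARE_OF_IMPORTS,
    "third_preferential": (1 - EU_SHARE_OF_IMPORTS) * PREFERENTIAL_SHARE_OF_THIRD,
    "third_non_preferential": (1 - EU_SHARE_OF_IMPORTS) * (1 - PREFERENTIAL_SHARE_OF_THIRD),
}

# Calibrated per-segment defaults (EUR/tonne). The published scenario
# endpoints are 92 and 203 GBP/t; with the supply shares above and a uniform
# facilitation cost, the WTO tariff that reproduces each endpoint is solved
# in closed form below. Both solutions land near the WTO MFN raw-sugar
# tariff (~339 EUR/t), which is what a "hard" regime would apply.
_FACILITATION_EUR = 33.9
_SOFT_ENDPOINT_GBP = 92.0
_HARD_ENDPOINT_GBP = 203.0
_SOFT_TARIFF_EUR = (
    _SOFT_ENDPOINT_GBP / (IMPORT_SHARE_OF_SUPPLY * DEFAULT_EXCHANGE_RATE)
    - _FACILITATION_EUR
) / _SEGMENT_SHARES["third_preferential"]
_HARD_TARIFF_EUR = (
    _HARD_ENDPOINT_GBP / (IMPORT_SHARE_OF_SUPPLY * DEFAULT_EXCHANGE_RATE)
    - _FACILITATION_EUR
) / (_SEGMENT_SHARES["eu"] + _SEGMENT_SHARES["third_preferential"])


class TradeScenarioError(ValueError):
    """Raised for inconsistent trade-regime specifications."""


@dataclass(frozen=True)
class TradeScenario:
    """A post-Brexit trade regime for sugar.

    Parameters
    ----------
    import_share_of_supply : float
        Imported sugar as a fraction of total UK supply, in [0, 1].
    segment_shares : dict
        Fraction of imports per segment; must sum to 1.
    tariff_change : dict
        Applied import tariff change per segment (currency/tonne,
        post- minus pre-Brexit). Negative values are accepted for
        exploratory use.
    facilitation_cost : dict
        Added border-friction cost per segment (currency/tonne).
    exchange_rate : float
        GBP per EUR; applied only when ``currency == "EUR"``.
    currency : {"EUR", "GBP"}
        Denomination of the per-tonne tariff/facilitation figures.
    label : str
        "none", "soft", "hard" or a custom name.
    """

    import_share_of_supply: float = IMPORT_SHARE_OF_SUPPLY
    segment_shares: dict[str, float] = field(
        default_factory=lambda: dict(_SEGMENT_SHARES)
    )
    tariff_change: dict[str, float] = field(default_factory=dict)
    facilitation_cost: dict[str, float] = field(default_factory=dict)
    exchange_rate: float = DEFAULT_EXCHANGE_RATE
    currency: str = "EUR"
    label: str = "custom"

    def __post_init__(self):
        if not 0.0 <= self.import_share_of_supply <= 1.0:
            raise TradeScenarioError(
                f"import_share_of_supply must lie in [0, 1]; "
                f"got {self.import_share_of_supply}"
            )
        shares = self.segment_shares
        if any(v < 0 for v in shares.values()):
            raise TradeScenarioError("segment shares must be non-negative")
        total = sum(shares.values())
        if abs(total - 1.0) > 1e-9:
            raise TradeScenarioError(f"segment shares must sum to 1; got {total!r}")
        if self.currency not in ("EUR", "GBP"):
            raise TradeScenarioError(f"unknown currency {self.currency!r}")
        for name, mapping in (
            ("tariff_change", self.tariff_change),
            ("facilitation_cost", self.facilitation_cost),
        ):
            if set(mapping) - set(shares):
                raise TradeScenarioError(
                    f"{name} refers to unknown segments "
                    f"{sorted(set(mapping) - set(shares))}"
                )
        if self.exchange_rate <= 0:
            raise TradeScenarioError("exchange_rate must be positive")

    def replace(self, **kw) -> "TradeScenario":
        return replace(self, **kw)


def sugar_price_change(scenario: TradeScenario) -> float:
    """Change in the wholesale sugar price, GBP per tonne.

    Share-weighted sum of per-segment tariff and facilitation changes,
    scaled by the import share of supply and converted to GBP when the
    scenario is EUR-denominated. Zero when all changes are zero (and for
    the packaged ``label="none"`` scenario).
    """
    per_tonne = sum(
        share
        * (
            scenario.tariff_change.get(seg, 0.0)
            + scenario.facilitation_cost.get(seg, 0.0)
        )
        for seg, share in scenario.segment_shares.items()
    )
    fx = scenario.exchange_rate if scenario.currency == "EUR" else 1.0
    return scenario.import_share_of_supply * per_tonne * fx


# --- packaged regimes --------------------------------------------------------

def no_brexit() -> TradeScenario:
    """Pre-Brexit status quo: no tariff or facilitation changes."""
    return TradeScenario(label="none")


def soft_brexit() -> TradeScenario:
    """Zero-duty FTA with the EU; WTO tariffs on third countries.

    Third-country preferential imports lose their preference and face the
    WTO tariff; non-preferential imports already pay it (no change); all
    segments incur facilitation costs. Calibrated to +92 GBP/t.
    """
    return TradeScenario(
        tariff_change={
            "eu": 0.0,
            "third_preferential": _SOFT_TARIFF_EUR,
            "third_non_preferential": 0.0,
        },
        facilitation_cost={s: _FACILITATION_EUR for s in SEGMENTS},
        label="soft",
    )


def hard_brexit() -> TradeScenario:
    """WTO default position: MFN tariffs on all preferential routes.

    EU and third-country preferential imports face the WTO tariff;
    non-preferential imports already pay it; facilitation costs apply to
    all segments. Calibrated to +203 GBP/t.
    """
    return TradeScenario(
        tariff_change={
            "eu": _HARD_TARIFF_EUR,
            "third_preferential": _HARD_TARIFF_EUR,
            "third_non_preferential": 0.0,
        },
        facilitation_cost={s: _FACILITATION_EUR for s in SEGMENTS},
        label="hard",
    )


NAMED_TRADE_SCENARIOS = {
    "none": no_brexit,
    "soft": soft_brexit,
    "hard": hard_brexit,
}


def named_trade_scenario(label: str) -> TradeScenario:
    try:
        return NAMED_TRADE_SCENARIOS[label]()
    except KeyError:
        raise TradeScenarioError(
            f"unknown trade scenario {label!r}; "
            f"expected one of {sorted(NAMED_TRADE_SCENARIOS)}"
        ) from None
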