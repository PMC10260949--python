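"""Price-to-intake translation with SEC-differentiated responsiveness.

The demand response is a meta-analytic "price effect": a 10% increase in
the SSB price reduces consumption by 6.7% (base effect). Because drawing
on longitudinal intake data, the estimate already nets out substitution
with other beverages. More deprived groups respond more strongly: the
most deprived SEC group is 65% more responsive than the most affluent.
The response is applied linearly in the relative price change (the
modelled levy implies a ~38% price rise, an extrapolation beyond the 10%
the estimate was reported for) and capped so intake cannot fall below
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .strata import DEFAULT_SEC_GROUPING, BaselineTable, BaselineError

DEFAULT_BASE_EFFECT = 6.7  # % intake decrease per 10% price increase
DEFAULT_RESPONSIVENESS_RATIO = 1.65  # most- vs least-deprived responsiveness
DEFAULT_SERVING_SIZE = 250.0  # g (~250 ml) per serving


class PriceEffectError(ValueError):
    pass


@dataclass(frozen=True)
class PriceEffect:
    """SEC-differentiated intake response to an SSB price change.

    Parameters
    ----------
    base_effect : float
        Percent intake decrease per 10% price increase (default 6.7).
    sec_multipliers : mapping or None
        Multiplier on the base effect per SEC group. ``None`` means
        "calibrate against the baseline when applied": the raw shape
        (1, (1+r)/2, r) with r = ``responsiveness_ratio`` is rescaled so
        the population-intake-weighted mean multiplier equals 1, i.e. the
        population-average response stays at the base effect.
    sec_grouping : mapping
        IMD quintile -> SEC group (default pools quintiles 1+2 and 4+5).
    responsiveness_ratio : float
        Ratio of the most- to least-deprived multiplier (default 1.65).
    """

    base_effect: float = DEFAULT_BASE_EFFECT
    sec_multipliers: Mapping[str, float] | None = None
    sec_grouping: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_SEC_GROUPING)
    )
    responsiveness_ratio: float = DEFAULT_RESPONSIVENESS_RATIO

    def __post_init__(self):
        if self.base_effect <= 0:
            raise PriceEffectError("base_effect must be positive")
        if self.sec_multipliers is not None:
            m = self.sec_multipliers
            if any(v <= 0 for v in m.values()):
                raise PriceEffectError("SEC multipliers must be positive")
            missing = set(self.sec_grouping.values()) - set(m)
            if missing:
                raise PriceEffectError(
                    f"SEC groups without a multiplier: {sorted(missing)}"
                )

    def multiplier_for(self, quintile: int) -> float:
        if self.sec_multipliers is None:
            raise PriceEffectError(
                "SEC multipliers are uncalibrated; call "
                "calibrate_sec_multipliers(...) or apply_to_baseline(...)"
            )
        try:
            group = self.sec_grouping[int(quintile)]
        except KeyError:
            raise PriceEffectError(
                f"IMD quintile {quintile!r} has no SEC group"
            ) from None
        return self.sec_multipliers[group]

    def calibrated(self, baseline: BaselineTable) -> "PriceEffect":
        """Return a copy with multipliers calibrated against `baseline`."""
        mult = calibrate_sec_multipliers(
            baseline, ratio=self.responsiveness_ratio, grouping=self.sec_grouping
        )
        return PriceEffect(
            base_effect=self.base_effect,
            sec_multipliers=mult,
            sec_grouping=dict(self.sec_grouping),
            responsiveness_ratio=self.responsiveness_ratio,
        )


def calibrate_sec_multipliers(
    baseline: BaselineTable,
    ratio: float = DEFAULT_RESPONSIVENESS_RATIO,
    grouping: Mapping[int, str] | None = None,
) -> dict[str, float]:
    """SEC multipliers with high/low ratio `ratio` and weighted mean 1.

    The raw gradient (low, mid, high) = (1, (1+ratio)/2, ratio) is rescaled
    by a single constant so that the population x intake weighted mean
    multiplier over the baseline equals 1. Two anchors are thus honoured
    simultaneously: the most-deprived group is `ratio` times as responsive
    as the least deprived, and the population-average response equals the
    base effect.
    """
    grouping = DEFAULT_SEC_GROUPING if grouping is None else dict(grouping)
    raw = {"low": 1.0, "mid": (1.0 + ratio) / 2.0, "high": ratio}
    groups = baseline.sec_group(grouping)
    w = baseline.data["population"].to_numpy() * baseline.data["intake"].to_numpy()
    w_total = w.sum()
    if w_total <= 0:
        raise PriceEffectError("baseline has zero total intake; cannot calibrate")
    weighted = sum(
        w[(groups == g).to_numpy()].sum() * raw[g] for g in ("low", "mid", "high")
    )
    c = w_total / weighted
    return {g: c * raw[g] for g in raw}


def relative_intake_change(
    price_change: float, effect: PriceEffect, quintile: int
) -> float:
    """Relative intake change (negative = reduction) for one IMD quintile.

    Linear in the relative price change: a price change of +0.10 with
    multiplier 1 gives -base_effect/100. Capped at -1 (intake cannot fall
    below zero).
    """
    if price_change < -1:
        raise PriceEffectError("price_change below -100% is not meaningful")
    slope = effect.base_effect / 10.0 * effect.multiplier_for(quintile)
    return max(-slope * price_change, -1.0)


@dataclass(frozen=True)
class IntakeChange:
    """Per-stratum intake change implied by a price change."""

    age_group: str
    sex: str
    imd_quintile: int
    relative_change: float  # fraction; negative = reduction
    absolute_change: float  # g/day
    servings_change: float  # servings/day (same sign as absolute_change)


def apply_to_baseline(
    price_change: float,
    effect: PriceEffect,
    baseline: BaselineTable,
    serving_size: float = DEFAULT_SERVING_SIZE,
) -> pd.DataFrame:
    """Intake change per stratum for a relative SSB price change.

    Returns a DataFrame keyed like the baseline with columns
    ``relative_change`` (fraction), ``absolute_change`` (g/day) and
    ``servings_change`` (servings/day). Uncalibrated price effects
    (``sec_multipliers=None``) are calibrated against `baseline` first.

    The population-intake-weighted mean of ``relative_change`` is the
    "overall population" intake reduction reported alongside the table.
    """
    if serving_size <= 0:
        raise PriceEffectError("serving_size must be positive")
    if effect.sec_multipliers is None:
        effect = effect.calibrated(baseline)
    df = baseline.data
    if df["intake"].isna().any():
        raise BaselineError("baseline intake is incomplete")
    rel = np.array(
        [
            relative_intake_change(price_change, effect, q)
            for q in df["imd_quintile"]
        ]
    )
    out = df[["age_group", "sex", "imd_quintile"]].copy()
    out["relative_change"] = rel
    out["absolute_change"] = rel * df["intake"].to_numpy()
    out["servings_change"] = out["absolute_change"] / serving_size
    return out


def overall_relative_change(
    intake_changes: pd.DataFrame, baseline: BaselineTable
) -> float:
    """Population x intake weighted mean relative intake change."""
    w = baseline.data["population"].to_numpy() * baseline.data["intake"].to_numpy()
    if w.sum() == 0:
        return 0.0
    return float(np.average(intake_changes["relative_change"].to_numpy(), weights=w))
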