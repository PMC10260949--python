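"""The CHD mortality engine: intake changes -> DPP and LYG.

The attribution step is a potential impact fraction (PIF) with log-linear
relative risk per daily serving of SSB. The CHD effect of SSB has two
additive components: a direct (BMI-adjusted) effect, applied to everyone,
and a BMI-mediated effect, applied in proportion to the stratum's
overweight prevalence:

    PIF = (1 - RR_adj^(-ds)) + p_ow * (1 - RR_med^(-ds)),   ds = servings/day reduction

clamped to [0, 1). SSB intake is assumed not to alter the case-fatality
of CHD, so the incidence PIF applies directly to mortality: deaths
prevented or postponed (DPP) in a stratum are baseline deaths x PIF.
Life-years gained (LYG) weight DPP by the median survival the decedents
would otherwise have had, mixed over CHD vital status (diagnosed CHD,
undiagnosed CHD, no CHD). The policy effect is a single-year snapshot
(2021); no lag or time-to-benefit structure is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import demand, pricing, trade
from .scenario import Scenario
from .strata import AGE_GROUPS, BaselineTable, BaselineError

__all__ = [
    "RelativeRiskSet",
    "ImpactResult",
    "mortality_reduction_fraction",
    "deaths_prevented",
    "life_years_gained",
    "run_scenario",
]


class RiskLookupError(KeyError):
    pass


# Default age-specific relative risks per daily serving, calibrated (the
# source pooled-analysis values are not published at this granularity) so
# that the levy-only scenario at 100% pass-through on the default synthetic
# baseline yields ~1% of baseline CHD deaths prevented overall, with a
# strong age gradient (~7% at 25-44 falling to ~1% over 65). RRs attenuate
# with age, as in the cohort pooling literature.
DEFAULT_RELATIVE_RISKS: dict[str, tuple[float, float]] = {
    "25-34": (1.40, 1.25),
    "35-44": (1.44, 1.27),
    "45-54": (1.26, 1.17),
    "55-64": (1.17, 1.11),
    "65-74": (1.11, 1.065),
    "75-84": (1.105, 1.07),
    "85+": (1.09, 1.06),
}


@dataclass(frozen=True)
class RelativeRiskSet:
    """BMI-adjusted and BMI-mediated CHD relative risks per serving/day.

    ``classes`` maps an RR age class to ``(rr_adjusted, rr_mediated)``;
    ``age_map`` maps each 10-year mortality age band to its RR class, so
    coarser RR age structures (as in pooled cohort analyses) can be
    attached to the finer mortality bands. The default uses one class per
    band.
    """

    classes: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RELATIVE_RISKS)
    )
    age_map: Mapping[str, str] = field(
        default_factory=lambda: {a: a for a in AGE_GROUPS}
    )

    def __post_init__(self):
        for cls, (ra, rm) in self.classes.items():
            if ra <= 0 or rm <= 0:
                raise ValueError(f"relative risks must be positive (class {cls!r})")
        missing = set(self.age_map.values()) - set(self.classes)
        if missing:
            raise ValueError(f"age classes without RRs: {sorted(missing)}")

    def lookup(self, age_group: str) -> tuple[float, float]:
        try:
            return self.classes[self.age_map[age_group]]
        except KeyError:
            raise RiskLookupError(
                f"no relative risks for age group {age_group!r}"
            ) from None

    def arrays(self, age_groups) -> tuple[np.ndarray, np.ndarray]:
        pairs = [self.lookup(a) for a in age_groups]
        arr = np.asarray(pairs, dtype=float)
        return arr[:, 0], arr[:, 1]


def _pif(servings_change, rr_adj, rr_med, overweight):
    """Vectorised PIF; clamped to [0, 1)."""
    pif = (1.0 - rr_adj ** (-servings_change)) + overweight * (
        1.0 - rr_med ** (-servings_change)
    )
    return np.clip(pif, 0.0, np.nextafter(1.0, 0.0))


def mortality_reduction_fraction(
    servings_change: float,
    rr: RelativeRiskSet,
    age_group: str,
    overweight_prevalence: float,
) -> float:
    """Fraction of CHD deaths averted for a daily-servings reduction.

    `servings_change` is the reduction in servings/day (positive =
    less SSB). The BMI-mediated component is weighted by the overweight
    prevalence of the stratum.
    """
    rr_adj, rr_med = rr.lookup(age_group)
    return float(_pif(servings_change, rr_adj, rr_med, overweight_prevalence))


def deaths_prevented(stratum_deaths: float, reduction_fraction: float) -> float:
    """DPP in one stratum; fractional deaths are retained internally."""
    return stratum_deaths * reduction_fraction


def life_years_gained(dpp, chd_status_proportions, median_survival) -> float:
    """LYG = DPP x mixture of median survivals over CHD vital status."""
    p = np.asarray(chd_status_proportions, dtype=float)
    s = np.asarray(median_survival, dtype=float)
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-9):
        raise BaselineError("CHD-status proportions must sum to 1")
    return dpp * (p * s).sum(axis=-1)


# --- full scenario run -------------------------------------------------------


@dataclass
class ImpactResult:
    """Per-stratum and aggregated results of one scenario run."""

    label: str
    pass_through: float
    sugar_price_change: float  # GBP/tonne
    levy_rate: float  # GBP/litre
    cost_change: float  # GBP/litre
    consumer_price_change: float  # fraction of baseline price
    overall_intake_change: float  # population x intake weighted fraction
    per_stratum: pd.DataFrame  # stratum keys + intake changes, pif, dpp, lyg

    @property
    def dpp(self) -> float:
        return float(self.per_stratum["dpp"].sum())

    @property
    def lyg(self) -> float:
        return float(self.per_stratum["lyg"].sum())

    def by_age_group(self) -> pd.DataFrame:
        """DPP/LYG per age group, with DPP as % of baseline deaths."""
        g = self.per_stratum.groupby("age_group", sort=False).agg(
            deaths=("deaths", "sum"), dpp=("dpp", "sum"), lyg=("lyg", "sum")
        )
        g = g.reindex(AGE_GROUPS)
        with np.errstate(invalid="ignore", divide="ignore"):
            g["dpp_pct_of_deaths"] = np.where(
                g["deaths"] > 0, 100.0 * g["dpp"] / g["deaths"], 0.0
            )
        return g.reset_index()

    def by_quintile(self) -> pd.DataFrame:
        g = self.per_stratum.groupby("imd_quintile").agg(
            deaths=("deaths", "sum"), dpp=("dpp", "sum"), lyg=("lyg", "sum")
        )
        return g.reset_index()


def _core(
    deaths: np.ndarray,
    overweight: np.ndarray,
    props: np.ndarray,  # (n, 3)
    survivals: np.ndarray,  # (n, 3)
    rr_adj: np.ndarray,
    rr_med: np.ndarray,
    servings_reduction: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised stratum arrays -> (pif, dpp, lyg). Shared by the point
    run and the probabilistic sensitivity analysis."""
    pif = _pif(servings_reduction, rr_adj, rr_med, overweight)
    dpp = deaths * pif
    lyg = dpp * (props * survivals).sum(axis=-1)
    return pif, dpp, lyg


def run_scenario(
    baseline: BaselineTable,
    scenario: Scenario,
    rr: RelativeRiskSet | None = None,
) -> ImpactResult:
    """Chain trade -> pricing -> demand -> mortality for one scenario.

    Totals are exact sums of the per-stratum values; fractional deaths are
    retained (reports round at display time).
    """
    rr = RelativeRiskSet() if rr is None else rr
    pa = scenario.price_assumptions

    sugar_dp = trade.sugar_price_change(scenario.trade) if scenario.trade else 0.0
    levy_rate = pricing.pooled_levy_rate(scenario.levy) if scenario.levy else 0.0
    cost = pricing.production_cost_change(sugar_dp, pa, levy_rate)
    price_rel = pricing.consumer_price_change(cost, pa)

    changes = demand.apply_to_baseline(
        price_rel, scenario.price_effect, baseline, scenario.serving_size
    )
    overall = demand.overall_relative_change(changes, baseline)

    df = baseline.data
    rr_adj, rr_med = rr.arrays(df["age_group"])
    servings_reduction = -changes["servings_change"].to_numpy()
    props = df[["p_diagnosed_chd", "p_undiagnosed_chd", "p_no_chd"]].to_numpy()
    survs = df[
        ["survival_diagnosed_chd", "survival_undiagnosed_chd", "survival_no_chd"]
    ].to_numpy()

    pif, dpp, lyg = _core(
        df["deaths"].to_numpy(),
        df["overweight_prevalence"].to_numpy(),
        props,
        survs,
        rr_adj,
        rr_med,
        servings_reduction,
    )

    per_stratum = changes.copy()
    per_stratum["deaths"] = df["deaths"].to_numpy()
    per_stratum["pif"] = pif
    per_stratum["dpp"] = dpp
    per_stratum["lyg"] = lyg

    return ImpactResult(
        label=scenario.label,
        pass_through=pa.pass_through,
        sugar_price_change=sugar_dp,
        levy_rate=levy_rate,
        cost_change=cost,
        consumer_price_change=price_rel,
        overall_intake_change=overall,
        per_stratum=per_stratum,
    )
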