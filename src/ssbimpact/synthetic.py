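"""Synthetic baseline tables with the structure the model assumes.

No input dataset of this model is redistributable (intake comes from a
national diet survey, mortality from national statistics projections), so
the generator emulates their joint structure on the 70-stratum grid:

* SSB intake follows a log-linear model in age band, sex and IMD
  quintile — declining with age, higher in men, higher with deprivation —
  with bounded multiplicative noise, rescaled so the population-weighted
  mean hits the target (99.5 g/day by default) exactly.
* Projected CHD deaths (38 000 by default) are disaggregated over age,
  sex and deprivation with a configurable deprivation gradient
  (most-deprived ≈ 2x most-affluent by default).
* Overweight prevalence rises with age and deprivation inside a plausible
  band; median survivals decline with age and are lower once CHD is
  diagnosed.

The noise amplitude is capped at 45% of the smallest log-gradient step,
so the ordering properties (age, sex, deprivation gradients) hold for
every seed; setting every gradient to zero silences the noise and yields
a fully uniform table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strata import (
    AGE_GROUPS,
    IMD_QUINTILES,
    SEXES,
    BaselineTable,
    stratum_grid,
)

TOTAL_POPULATION = 40_000_000  # England, adults 25+

#: population share per age band (25-34 ... 85+)
POPULATION_AGE_SHARES = (0.19, 0.17, 0.18, 0.16, 0.14, 0.10, 0.06)
#: male fraction of the population per age band
POPULATION_MALE_FRACTION = (0.50, 0.50, 0.49, 0.49, 0.48, 0.45, 0.38)

#: CHD death share per age band (deaths concentrate at old ages)
DEATH_AGE_SHARES = (0.002, 0.008, 0.03, 0.08, 0.17, 0.33, 0.38)
#: male fraction of CHD deaths per age band
DEATH_MALE_FRACTION = (0.72, 0.72, 0.72, 0.68, 0.60, 0.52, 0.42)

#: median survival (years) that a decedent without prior CHD would
#: otherwise have had, per age band; below general life expectancy, as
#: people dying of CHD carry worse-than-average risk profiles
SURVIVAL_NO_CHD = (46.0, 37.0, 29.0, 21.0, 14.0, 8.0, 3.6)


class SynthesisError(ValueError):
    pass


@dataclass(frozen=True)
class SynthesisParams:
    """Tunable structure of the synthetic baseline.

    Gradient parameters are log-scale steps: ``intake_age_step`` is the
    drop in log-intake per 10-year age band, ``intake_sex_gap`` the male
    premium, ``intake_quintile_step`` the rise per IMD quintile.
    ``mortality_gradient`` is the most-deprived : most-affluent death
    ratio at fixed age and sex.
    """

    target_total_deaths: float = 38_000.0
    target_mean_intake: float = 99.5
    intake_age_step: float = float(np.log(4.0) / 6.0)  # ~4x decline 25-34 -> 85+
    intake_sex_gap: float = float(np.log(1.30))
    intake_quintile_step: float = float(np.log(1.06))
    intake_noise_sd: float = 0.02
    mortality_gradient: float = 2.0
    overweight_base: float = 0.38
    overweight_age_slope: float = 0.05  # per age band
    overweight_deprivation_slope: float = 0.02  # per quintile
    overweight_range: tuple[float, float] = (0.30, 0.80)
    survival_no_chd: tuple[float, ...] = SURVIVAL_NO_CHD
    survival_ratio_undiagnosed: float = 0.85
    survival_ratio_diagnosed: float = 0.70
    survival_female_factor: float = 1.05
    seed: int = 0

    def __post_init__(self):
        if self.target_total_deaths <= 0 or self.target_mean_intake <= 0:
            raise SynthesisError("targets must be positive")
        for name in ("intake_age_step", "intake_sex_gap", "intake_quintile_step"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise SynthesisError(f"{name} must be finite and non-negative")
        if self.mortality_gradient <= 0:
            raise SynthesisError("mortality_gradient must be positive")
        lo, hi = self.overweight_range
        if not 0 <= lo < hi <= 1:
            raise SynthesisError("overweight_range must be an interval in [0, 1]")


def disaggregate_mortality(
    projected_total: float,
    sex_age_distribution,
    sec_distribution,
) -> pd.Series:
    """Split a projected death total over the stratum grid.

    ``sex_age_distribution`` maps (age_group, sex) -> share of all deaths
    (summing to 1); ``sec_distribution`` maps IMD quintile -> share of the
    deaths within each age-sex cell (summing to 1). The per-stratum deaths
    are the products, so they sum back to the total exactly.
    """
    sa = {k: float(v) for k, v in dict(sex_age_distribution).items()}
    sec = {int(k): float(v) for k, v in dict(sec_distribution).items()}
    if any(v < 0 for v in sa.values()) or any(v < 0 for v in sec.values()):
        raise SynthesisError("distribution shares must be non-negative")
    if abs(sum(sa.values()) - 1.0) > 1e-9:
        raise SynthesisError("sex-age distribution must sum to 1")
    if abs(sum(sec.values()) - 1.0) > 1e-9:
        raise SynthesisError("SEC distribution must sum to 1")
    grid = stratum_grid()
    try:
        deaths = [
            projected_total * sa[(a, s)] * sec[q]
            for a, s, q in grid.itertuples(index=False)
        ]
    except KeyError as e:
        raise SynthesisError(f"distribution missing stratum key {e}") from None
    out = pd.Series(deaths, index=pd.MultiIndex.from_frame(grid), name="deaths")
    # exact conservation up to float rounding
    np.testing.assert_allclose(out.sum(), projected_total, rtol=1e-12)
    return out


def _deprivation_death_shares(gradient: float) -> dict[int, float]:
    """Within-cell death share per quintile, linear in q with the given
    most-deprived : most-affluent ratio."""
    w = np.array([1.0 + (gradient - 1.0) * (q - 1) / 4.0 for q in IMD_QUINTILES])
    w /= w.sum()
    return dict(zip(IMD_QUINTILES, w))


def synthesize_baseline(params: SynthesisParams | None = None) -> BaselineTable:
    """Generate a full 70-stratum baseline table.

    Deterministic given ``params.seed``. The population-weighted mean
    intake and the total deaths hit their targets exactly (up to float
    rounding); gradient orderings hold for every seed by construction.
    """
    p = SynthesisParams() if params is None else params
    rng = np.random.default_rng(p.seed)
    grid = stratum_grid()
    a_idx = grid["age_group"].map({a: i for i, a in enumerate(AGE_GROUPS)}).to_numpy()
    male = (grid["sex"] == "male").to_numpy()
    q = grid["imd_quintile"].to_numpy()

    # population
    pop = (
        TOTAL_POPULATION
        * np.asarray(POPULATION_AGE_SHARES)[a_idx]
        * np.where(
            male,
            np.asarray(POPULATION_MALE_FRACTION)[a_idx],
            1.0 - np.asarray(POPULATION_MALE_FRACTION)[a_idx],
        )
        / len(IMD_QUINTILES)
    )

    # intake: log-linear structure + bounded noise, rescaled to the target
    steps = (p.intake_age_step, p.intake_sex_gap, p.intake_quintile_step)
    sigma = min(p.intake_noise_sd, 0.45 * min(steps))
    noise = sigma * rng.uniform(-1.0, 1.0, size=len(grid))
    log_intake = (
        -p.intake_age_step * a_idx
        + p.intake_sex_gap * male
        + p.intake_quintile_step * (q - 1)
        + noise
    )
    intake = np.exp(log_intake)
    intake *= p.target_mean_intake / np.average(intake, weights=pop)

    # deaths
    sa = {
        (a, s): DEATH_AGE_SHARES[i]
        * (DEATH_MALE_FRACTION[i] if s == "male" else 1.0 - DEATH_MALE_FRACTION[i])
        for i, a in enumerate(AGE_GROUPS)
        for s in SEXES
    }
    deaths = disaggregate_mortality(
        p.target_total_deaths, sa, _deprivation_death_shares(p.mortality_gradient)
    ).to_numpy()

    # overweight prevalence: rises with age and deprivation, clipped
    ow = np.clip(
        p.overweight_base
        + p.overweight_age_slope * a_idx
        + p.overweight_deprivation_slope * (q - 1),
        *p.overweight_range,
    )

    # CHD-status proportions of deaths: diagnosis more likely at older ages
    p_diag = 0.45 + 0.03 * a_idx
    p_undiag = 0.25 - 0.01 * a_idx
    p_none = 1.0 - p_diag - p_undiag

    surv_none = np.asarray(p.survival_no_chd)[a_idx] * np.where(
        male, 1.0, p.survival_female_factor
    )
    surv_undiag = surv_none * p.survival_ratio_undiagnosed
    surv_diag = surv_none * p.survival_ratio_diagnosed

    df = grid.copy()
    df["deaths"] = deaths
    df["population"] = pop
    df["intake"] = intake
    df["overweight_prevalence"] = ow
    df["p_diagnosed_chd"] = p_diag
    df["p_undiagnosed_chd"] = p_undiag
    df["p_no_chd"] = p_none
    df["survival_diagnosed_chd"] = surv_diag
    df["survival_undiagnosed_chd"] = surv_undiag
    df["survival_no_chd"] = surv_none
    return BaselineTable(df)


# --- fixture registry --------------------------------------------------------

FIXTURES: dict[str, SynthesisParams] = {
    # default study conditions, calibrated to the printed aggregates
    "paper-calibrated": SynthesisParams(seed=2021),
    # no gradients: identical intake everywhere (noise silenced by the cap)
    "uniform": SynthesisParams(
        intake_age_step=0.0,
        intake_sex_gap=0.0,
        intake_quintile_step=0.0,
        mortality_gradient=1.0,
        overweight_age_slope=0.0,
        overweight_deprivation_slope=0.0,
        seed=7,
    ),
    # round numbers for hand calculations
    "degenerate": SynthesisParams(
        target_total_deaths=70_000.0,
        target_mean_intake=100.0,
        intake_age_step=0.0,
        intake_sex_gap=0.0,
        intake_quintile_step=0.0,
        intake_noise_sd=0.0,
        mortality_gradient=1.0,
        overweight_base=0.5,
        overweight_age_slope=0.0,
        overweight_deprivation_slope=0.0,
        survival_no_chd=(10.0,) * 7,
        survival_ratio_undiagnosed=1.0,
        survival_ratio_diagnosed=1.0,
        survival_female_factor=1.0,
        seed=0,
    ),
}


def load_fixture(name: str) -> BaselineTable:
    """Generate one of the named baseline fixtures."""
    try:
        params = FIXTURES[name]
    except KeyError:
        raise SynthesisError(
            f"unknown fixture {name!r}; expected one of {sorted(FIXTURES)}"
        ) from None
    base = synthesize_baseline(params)
    if name == "degenerate":
        # uniform deaths across strata for easy arithmetic
        df = base.data.copy()
        df["deaths"] = params.target_total_deaths / len(df)
        df["population"] = TOTAL_POPULATION / len(df)
        df["intake"] = params.target_mean_intake
        return BaselineTable(df)
    return base
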