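"""The mortality engine: PIF, DPP, LYG, full scenario runs."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssbimpact import (
    Scenario,
    deaths_prevented,
    life_years_gained,
    mortality_reduction_fraction,
    run_scenario,
)
from ssbimpact.impact import RelativeRiskSet, RiskLookupError
from ssbimpact.strata import BaselineError, BaselineTable

from conftest import random_baseline

RR_FLAT = RelativeRiskSet(
    classes={"all": (1.1, 1.1)},
    age_map={a: "all" for a in
             ("25-34", "35-44", "45-54", "55-64", "65-74", "75-84", "85+")},
)


class TestMortalityReductionFraction:
    def test_no_intake_change_gives_zero(self):
        assert mortality_reduction_fraction(0.0, RR_FLAT, "45-54", 0.5) == 0.0

    def test_null_risks_give_zero(self):
        rr1 = RelativeRiskSet(
            classes={"all": (1.0, 1.0)}, age_map=dict(RR_FLAT.age_map)
        )
        assert mortality_reduction_fraction(0.8, rr1, "25-34", 0.9) == 0.0

    def test_closed_form_hand_calculation(self):
        # 1 - 1.1^(-0.5) = 0.046537...; mediated part scaled by 0.6
        got = mortality_reduction_fraction(0.5, RR_FLAT, "65-74", 0.6)
        direct = 1 - 1.1 ** -0.5
        assert direct == pytest.approx(0.04654, abs=5e-6)
        assert got == pytest.approx(direct + 0.6 * direct)
        assert got == pytest.approx(0.07446, abs=5e-6)

    def test_missing_age_group_raises(self):
        rr = RelativeRiskSet(classes={"young": (1.2, 1.1)}, age_map={"25-34": "young"})
        with pytest.raises(RiskLookupError):
            mortality_reduction_fraction(0.5, rr, "85+", 0.5)

    @given(eps=st.floats(1e-9, 1e-5))
    def test_small_effect_closed_form_limit(self, eps):
        # PIF / ds -> ln(rr_adj) + overweight * ln(rr_med) as ds -> 0
        rr = RelativeRiskSet(
            classes={"all": (1.3, 1.15)}, age_map=dict(RR_FLAT.age_map)
        )
        ow = 0.55
        got = mortality_reduction_fraction(eps, rr, "45-54", ow) / eps
        want = math.log(1.3) + ow * math.log(1.15)
        assert got == pytest.approx(want, rel=1e-4)

    def test_clamped_to_unit_interval(self):
        rr = RelativeRiskSet(classes={"all": (50.0, 50.0)}, age_map=dict(RR_FLAT.age_map))
        val = mortality_reduction_fraction(10.0, rr, "25-34", 1.0)
        assert 0.0 <= val < 1.0
        # negative servings change (intake rise) cannot produce negative PIF
        assert mortality_reduction_fraction(-0.5, RR_FLAT, "25-34", 0.5) == 0.0


class TestAttribution:
    def test_deaths_prevented_arithmetic(self):
        assert deaths_prevented(1000.0, 0.0745) == pytest.approx(74.5)
        assert deaths_prevented(1000.0, 0.0) == 0.0
        assert deaths_prevented(1000.0, 1.0) == 1000.0

    def test_life_years_gained_mixture(self):
        got = life_years_gained(10.0, (0.5, 0.2, 0.3), (8.0, 6.0, 15.0))
        assert got == pytest.approx(97.0)

    def test_life_years_gained_degenerate_mixture(self):
        assert life_years_gained(7.0, (1.0, 0.0, 0.0), (12.0, 99.0, 99.0)) == pytest.approx(84.0)
        assert life_years_gained(0.0, (0.5, 0.2, 0.3), (8.0, 6.0, 15.0)) == 0.0

    def test_bad_proportions_rejected(self):
        with pytest.raises(BaselineError):
            life_years_gained(10.0, (0.5, 0.2, 0.2), (8.0, 6.0, 15.0))


def _oracle_run(baseline: BaselineTable, scenario: Scenario, rr: RelativeRiskSet):
    """Naive pure-Python per-stratum loop, independent of the engine."""
    from ssbimpact import (
        apply_to_baseline,
        consumer_price_change,
        pooled_levy_rate,
        production_cost_change,
        sugar_price_change,
    )

    dp = sugar_price_change(scenario.trade) if scenario.trade else 0.0
    levy = pooled_levy_rate(scenario.levy) if scenario.levy else 0.0
    pa = scenario.price_assumptions
    cost = levy + dp * pa.sugar_content * 1e-6
    price = pa.pass_through * cost / pa.baseline_price

    effect = scenario.price_effect
    if effect.sec_multipliers is None:
        effect = effect.calibrated(baseline)

    total_dpp = total_lyg = 0.0
    for row in baseline.data.itertuples(index=False):
        mult = effect.multiplier_for(row.imd_quintile)
        rel = max(-(effect.base_effect / 10.0) * mult * price, -1.0)
        ds = -rel * row.intake / scenario.serving_size
        ra, rm = rr.lookup(row.age_group)
        pif = (1 - ra**-ds) + row.overweight_prevalence * (1 - rm**-ds)
        pif = min(max(pif, 0.0), 1.0 - 1e-16)
        dpp = row.deaths * pif
        surv = (
            row.p_diagnosed_chd * row.survival_diagnosed_chd
            + row.p_undiagnosed_chd * row.survival_undiagnosed_chd
            + row.p_no_chd * row.survival_no_chd
        )
        total_dpp += dpp
        total_lyg += dpp * surv
    return total_dpp, total_lyg


class TestRunScenario:
    def test_null_scenario_gives_zero(self, paper_baseline):
        res = run_scenario(paper_baseline, Scenario.null())
        assert res.dpp == 0.0
        assert res.lyg == 0.0
        assert res.consumer_price_change == 0.0

    def test_doubling_deaths_doubles_dpp(self, paper_baseline):
        res1 = run_scenario(paper_baseline, Scenario.levy_only())
        doubled = paper_baseline.data.copy()
        doubled["deaths"] *= 2
        res2 = run_scenario(BaselineTable(doubled), Scenario.levy_only())
        assert res2.dpp == pytest.approx(2 * res1.dpp, rel=1e-12)

    def test_stratum_additivity(self, paper_baseline):
        res = run_scenario(paper_baseline, Scenario.levy_hard_brexit())
        assert res.dpp == pytest.approx(res.per_stratum["dpp"].sum(), rel=0, abs=0)
        assert res.by_quintile()["dpp"].sum() == pytest.approx(res.dpp, rel=1e-12)
        assert res.by_age_group()["dpp"].sum() == pytest.approx(res.dpp, rel=1e-12)

    def test_dpp_bounded_by_stratum_deaths(self, any_baseline):
        res = run_scenario(any_baseline, Scenario.levy_hard_brexit(1.2))
        assert (res.per_stratum["dpp"] <= res.per_stratum["deaths"]).all()
        assert (res.per_stratum["lyg"] >= 0).all()

    @pytest.mark.parametrize("pass_through", [0.8, 1.0, 1.2])
    def test_scenario_ordering(self, paper_baseline, pass_through):
        levy = run_scenario(paper_baseline, Scenario.levy_only(pass_through))
        soft = run_scenario(paper_baseline, Scenario.levy_soft_brexit(pass_through))
        hard = run_scenario(paper_baseline, Scenario.levy_hard_brexit(pass_through))
        assert levy.dpp <= soft.dpp <= hard.dpp
        assert levy.lyg <= soft.lyg <= hard.lyg

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize(
        "scenario",
        [Scenario.levy_only(), Scenario.levy_hard_brexit(1.2), Scenario.null()],
        ids=["levy", "hard@120", "null"],
    )
    def test_oracle_equivalence_on_random_baselines(self, seed, scenario):
        baseline = random_baseline(seed + 10)
        rr = RelativeRiskSet()
        res = run_scenario(baseline, scenario, rr)
        dpp, lyg = _oracle_run(baseline, scenario, rr)
        assert res.dpp == pytest.approx(dpp, abs=1e-9)
        assert res.lyg == pytest.approx(lyg, abs=1e-9)

    def test_relative_brexit_increment_tracks_price_ratio(self, any_baseline):
        # hard-Brexit DPP exceeds levy-only by ~ the cost-increment ratio
        levy = run_scenario(any_baseline, Scenario.levy_only())
        hard = run_scenario(any_baseline, Scenario.levy_hard_brexit())
        price_ratio = hard.cost_change / levy.cost_change  # ~1.0821
        got = 100 * (hard.dpp / levy.dpp - 1)
        want = 100 * (price_ratio - 1)
        assert got == pytest.approx(want, abs=1.0)
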