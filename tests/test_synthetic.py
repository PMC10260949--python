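"""The synthetic baseline generator and mortality disaggregation."""

import numpy as np
import pandas as pd
import pytest

from ssbimpact.strata import AGE_GROUPS, IMD_QUINTILES, SEXES
from ssbimpact.synthetic import (
    FIXTURES,
    SynthesisError,
    SynthesisParams,
    disaggregate_mortality,
    load_fixture,
    synthesize_baseline,
)


class TestSynthesizeBaseline:
    def test_mean_intake_hits_target(self, paper_baseline):
        assert paper_baseline.mean_intake == pytest.approx(99.5, abs=0.5)

    def test_total_deaths_hit_target(self, paper_baseline):
        assert paper_baseline.total_deaths == pytest.approx(38_000, rel=0.005)

    @pytest.mark.parametrize("seed", [0, 1, 17, 2021])
    def test_gradients_hold_for_every_seed(self, seed):
        table = synthesize_baseline(SynthesisParams(seed=seed)).data
        for sex in SEXES:
            for q in IMD_QUINTILES:
                sub = table[(table.sex == sex) & (table.imd_quintile == q)]
                intake = sub.set_index("age_group")["intake"].reindex(AGE_GROUPS)
                assert (intake.diff().dropna() < 0).all(), "intake must fall with age"
        wide = table.pivot_table(
            index=["age_group", "imd_quintile"], columns="sex", values="intake"
        )
        assert (wide["male"] > wide["female"]).all(), "men drink more SSB"
        for (a, s), sub in table.groupby(["age_group", "sex"]):
            by_q = sub.set_index("imd_quintile")
            assert (
                by_q["intake"].reindex(IMD_QUINTILES).diff().dropna() > 0
            ).all(), "intake rises with deprivation"
            assert (
                by_q["deaths"].reindex(IMD_QUINTILES).diff().dropna() > 0
            ).all(), "mortality rises with deprivation"

    def test_mortality_deprivation_ratio(self, paper_baseline):
        by_q = paper_baseline.data.groupby("imd_quintile")["deaths"].sum()
        assert by_q[5] / by_q[1] == pytest.approx(2.0, rel=1e-9)

    def test_zero_gradients_give_identical_intake(self):
        params = SynthesisParams(
            intake_age_step=0.0, intake_sex_gap=0.0, intake_quintile_step=0.0
        )
        table = synthesize_baseline(params)
        assert np.allclose(table.data["intake"], table.data["intake"].iloc[0])

    def test_reproducible_under_seed(self):
        a = synthesize_baseline(SynthesisParams(seed=5))
        b = synthesize_baseline(SynthesisParams(seed=5))
        c = synthesize_baseline(SynthesisParams(seed=6))
        assert a.data.equals(b.data)
        assert not a.data["intake"].equals(c.data["intake"])

    def test_overweight_and_survival_plausible(self, paper_baseline):
        df = paper_baseline.data
        assert df["overweight_prevalence"].between(0.3, 0.8).all()
        surv = df.groupby("age_group")["survival_no_chd"].mean().reindex(AGE_GROUPS)
        assert (surv.diff().dropna() < 0).all(), "survival declines with age"
        assert (
            df["survival_diagnosed_chd"] < df["survival_no_chd"]
        ).all(), "diagnosed CHD shortens survival"

    def test_infeasible_params_rejected(self):
        with pytest.raises(SynthesisError):
            SynthesisParams(target_mean_intake=-1.0)
        with pytest.raises(SynthesisError):
            SynthesisParams(intake_age_step=float("nan"))


class TestDisaggregateMortality:
    def _uniform_sa(self):
        return {(a, s): 1.0 / 14 for a in AGE_GROUPS for s in SEXES}

    def test_uniform_shares(self):
        sec = {q: 0.2 for q in IMD_QUINTILES}
        out = disaggregate_mortality(7000.0, self._uniform_sa(), sec)
        assert np.allclose(out.to_numpy(), 100.0)

    def test_conservation(self):
        rng = np.random.default_rng(3)
        sa = rng.dirichlet(np.ones(14))
        sa = dict(zip(self._uniform_sa().keys(), sa))
        sec = dict(zip(IMD_QUINTILES, rng.dirichlet(np.ones(5))))
        out = disaggregate_mortality(38_000.0, sa, sec)
        assert out.sum() == pytest.approx(38_000.0, rel=1e-12)

    def test_degenerate_cell(self):
        sa = {k: 0.0 for k in self._uniform_sa()}
        sa[("85+", "female")] = 1.0
        sec = {q: 0.0 for q in IMD_QUINTILES}
        sec[5] = 1.0
        out = disaggregate_mortality(500.0, sa, sec)
        assert out[("85+", "female", 5)] == pytest.approx(500.0)
        assert out.drop(("85+", "female", 5)).sum() == 0.0

    def test_invalid_distribution_rejected(self):
        sec = {q: 0.25 for q in IMD_QUINTILES}  # sums to 1.25
        with pytest.raises(SynthesisError, match="sum to 1"):
            disaggregate_mortality(100.0, self._uniform_sa(), sec)


class TestFixtures:
    def test_registry_names(self):
        assert {"paper-calibrated", "uniform", "degenerate"} <= set(FIXTURES)

    def test_unknown_fixture(self):
        with pytest.raises(SynthesisError, match="unknown fixture"):
            load_fixture("nope")

    def test_degenerate_fixture_round_numbers(self, degenerate_baseline):
        df = degenerate_baseline.data
        assert np.allclose(df["deaths"], 1000.0)
        assert np.allclose(df["intake"], 100.0)
        assert np.allclose(df["overweight_prevalence"], 0.5)

    def test_uniform_fixture_flat_intake(self):
        table = load_fixture("uniform")
        assert np.allclose(table.data["intake"], table.data["intake"].iloc[0])

    def test_csv_round_trip(self, tmp_path, paper_baseline):
        path = tmp_path / "baseline.csv"
        paper_baseline.to_csv(path)
        from ssbimpact.strata import BaselineTable

        back = BaselineTable.read_csv(path)
        pd.testing.assert_frame_equal(back.data, paper_baseline.data, rtol=1e-9)
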