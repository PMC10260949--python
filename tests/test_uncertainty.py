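"""Probabilistic sensitivity analysis: draws, reproducibility, coverage."""

import numpy as np
import pytest

from ssbimpact import Scenario, run_psa, run_scenario
from ssbimpact.uncertainty import (
    DistributionError,
    ParameterDistribution,
    PSAConfig,
    _param_rng,
    _point_values,
    default_distributions,
    draw_parameters,
    fixed_distributions,
)
from ssbimpact.impact import RelativeRiskSet


class TestParameterDistribution:
    def test_fixed_returns_point(self):
        d = ParameterDistribution("x", "fixed")
        out = d.sample(np.random.default_rng(0), 3.5, 10)
        assert np.all(out == 3.5)

    def test_degenerate_normal_returns_mean(self):
        d = ParameterDistribution("x", "normal", sd=0.0)
        out = d.sample(np.random.default_rng(0), 2.0, 100)
        assert np.all(out == 2.0)

    def test_beta_draws_in_unit_interval(self):
        d = ParameterDistribution("x", "beta", kappa=10.0)
        out = d.sample(np.random.default_rng(0), np.array([0.1, 0.5, 0.9]), 500)
        assert np.all((out >= 0) & (out <= 1))
        assert out.mean(axis=0) == pytest.approx([0.1, 0.5, 0.9], abs=0.05)

    def test_truncated_normal_respects_bounds(self):
        d = ParameterDistribution("x", "normal", cv=2.0, lower=0.0)
        out = d.sample(np.random.default_rng(0), 1.0, 2000)
        assert np.all(out >= 0)

    def test_lognormal_positive_with_median_at_point(self):
        d = ParameterDistribution("x", "lognormal", sigma=0.3)
        out = d.sample(np.random.default_rng(0), 1.2, 20_000)
        assert np.all(out > 0)
        assert np.median(out) == pytest.approx(1.2, rel=0.02)

    def test_gamma_mean_at_point(self):
        d = ParameterDistribution("x", "gamma", cv=0.2)
        out = d.sample(np.random.default_rng(0), 10.0, 20_000)
        assert out.mean() == pytest.approx(10.0, rel=0.02)

    def test_unsupported_family_rejected(self):
        with pytest.raises(DistributionError, match="unsupported family"):
            ParameterDistribution("x", "cauchy")
        with pytest.raises(DistributionError, match="needs sd or cv"):
            ParameterDistribution("x", "normal")

    def test_unknown_parameter_id_rejected(self):
        with pytest.raises(DistributionError, match="unknown PSA parameters"):
            PSAConfig(distributions={"bogus": ParameterDistribution("bogus")})


class TestDrawParameters:
    def test_all_fixed_equal_point_estimates(self, paper_baseline):
        sc = Scenario.levy_hard_brexit()
        points = _point_values(paper_baseline, sc, RelativeRiskSet())
        draws = draw_parameters(fixed_distributions(), seed=1, iteration=4, points=points)
        for name, val in draws.items():
            np.testing.assert_array_equal(val, np.asarray(points[name], dtype=float))

    def test_reproducible_given_seed_and_iteration(self, paper_baseline):
        sc = Scenario.levy_only()
        points = _point_values(paper_baseline, sc, RelativeRiskSet())
        a = draw_parameters(default_distributions(), 7, 3, points)
        b = draw_parameters(default_distributions(), 7, 3, points)
        c = draw_parameters(default_distributions(), 8, 3, points)
        for name in a:
            np.testing.assert_array_equal(a[name], b[name])
        assert not np.array_equal(a["intake"], c["intake"])

    def test_parameter_substreams_are_order_independent(self):
        # the sub-stream depends only on (seed, name), not on draw order
        r1 = _param_rng(5, "intake").standard_normal(4)
        _ = _param_rng(5, "mortality").standard_normal(100)
        r2 = _param_rng(5, "intake").standard_normal(4)
        np.testing.assert_array_equal(r1, r2)


class TestRunPSA:
    def test_degenerate_distributions_reproduce_point_estimate(self, paper_baseline):
        sc = Scenario.levy_hard_brexit()
        point = run_scenario(paper_baseline, sc)
        psa = run_psa(paper_baseline, sc, fixed_distributions(), n_iterations=20, seed=0)
        mean, lo, hi = psa.dpp
        assert mean == pytest.approx(point.dpp, rel=1e-12)
        assert lo == pytest.approx(hi) == pytest.approx(mean)
        lmean, llo, lhi = psa.lyg
        assert lmean == pytest.approx(point.lyg, rel=1e-12)

    def test_same_seed_identical_summaries(self, paper_baseline):
        sc = Scenario.levy_only()
        a = run_psa(paper_baseline, sc, n_iterations=200, seed=11)
        b = run_psa(paper_baseline, sc, n_iterations=200, seed=11)
        assert a.iterations.equals(b.iterations)

    def test_interval_orders_and_stratum_frame(self, paper_baseline):
        psa = run_psa(paper_baseline, Scenario.levy_only(), n_iterations=300, seed=2)
        mean, lo, hi = psa.dpp
        assert lo <= mean <= hi
        sf = psa.stratum_frame()
        assert len(sf) == 70
        assert (sf["dpp_lower95"] <= sf["dpp_upper95"]).all()

    def test_fixing_a_parameter_never_widens_the_interval(self, paper_baseline):
        sc = Scenario.levy_only()
        full = default_distributions()
        narrowed = dict(full)
        narrowed["mortality"] = ParameterDistribution("mortality", "fixed")
        a = run_psa(paper_baseline, sc, full, n_iterations=2000, seed=3)
        b = run_psa(paper_baseline, sc, narrowed, n_iterations=2000, seed=3)
        wa = a.dpp[2] - a.dpp[1]
        wb = b.dpp[2] - b.dpp[1]
        assert wb <= wa

    def test_percentile_halfwidth_converges_to_196_sigma(self, paper_baseline):
        # all inputs fixed except per-stratum mortality ~ normal: total DPP
        # is then a linear combination of normals, so the empirical 95% UI
        # half-width must approach 1.96 x the output SD
        dists = fixed_distributions()
        dists["mortality"] = ParameterDistribution("mortality", "normal", cv=0.05)
        psa = run_psa(
            paper_baseline, Scenario.levy_only(), dists, n_iterations=10_000, seed=4
        )
        out = psa.iterations["dpp_total"].to_numpy()
        half_width = (np.percentile(out, 97.5) - np.percentile(out, 2.5)) / 2
        assert half_width == pytest.approx(1.96 * out.std(), rel=0.05)

    def test_mean_tracks_point_estimate(self, paper_baseline):
        sc = Scenario.levy_only()
        point = run_scenario(paper_baseline, sc)
        psa = run_psa(paper_baseline, sc, n_iterations=4000, seed=9)
        assert psa.dpp[0] == pytest.approx(point.dpp, rel=0.1)
        # UI roughly 0.6x-1.5x the mean under the default spreads
        mean, lo, hi = psa.dpp
        assert 0.3 * mean < lo < mean < hi < 2.5 * mean
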