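"""Model/Results interface over the scenario engine.

:class:`SSBLevyImpact` is constructed from a baseline table and a
scenario; :meth:`SSBLevyImpact.fit` returns an :class:`ImpactResults`
object carrying the point estimates, optional probabilistic-sensitivity
uncertainty intervals, per-stratum diagnostics and a ``summary()`` table.

Example
-------
>>> from ssbimpact import SSBLevyImpact, Scenario, load_fixture
>>> baseline = load_fixture("paper-calibrated")
>>> res = SSBLevyImpact(baseline, Scenario.levy_only()).fit()
>>> round(res.dpp / 10) * 10  # doctest: +SKIP
370.0
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import impact as _impact
from . import uncertainty as _uncertainty
from .scenario import Scenario
from .strata import BaselineTable


class SSBLevyImpact:
    """The levy/trade -> price -> intake -> CHD mortality model.

    Parameters
    ----------
    baseline : BaselineTable or pandas.DataFrame
        Per-stratum baseline (deaths, population, intake, overweight
        prevalence, CHD-status proportions, median survivals).
    scenario : Scenario
        Levy, trade regime, price and demand assumptions.
    relative_risks : RelativeRiskSet, optional
        CHD relative risks per daily serving; package defaults if omitted.
    """

    def __init__(
        self,
        baseline: BaselineTable | pd.DataFrame,
        scenario: Scenario,
        relative_risks: _impact.RelativeRiskSet | None = None,
    ):
        if isinstance(baseline, pd.DataFrame):
            baseline = BaselineTable(baseline)
        self.baseline = baseline
        self.scenario = scenario
        self.relative_risks = (
            _impact.RelativeRiskSet() if relative_risks is None else relative_risks
        )

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, scenario: Scenario, **kw
    ) -> "SSBLevyImpact":
        return cls(BaselineTable(data), scenario, **kw)

    def fit(
        self,
        n_psa: int | None = None,
        seed: int = 0,
        distributions=None,
    ) -> "ImpactResults":
        """Run the scenario; optionally add Monte Carlo uncertainty.

        ``n_psa`` iterations of the probabilistic sensitivity analysis are
        run when requested (the study design uses 10 000); ``None`` or 0
        yields point estimates only.
        """
        point = _impact.run_scenario(self.baseline, self.scenario, self.relative_risks)
        psa = None
        if n_psa:
            psa = _uncertainty.run_psa(
                self.baseline,
                self.scenario,
                distributions=distributions,
                n_iterations=n_psa,
                seed=seed,
                rr=self.relative_risks,
            )
        return ImpactResults(self, point, psa)

    def simulate(
        self, n_iterations: int = 10_000, seed: int = 0, distributions=None
    ) -> _uncertainty.UncertaintySummary:
        """Raw PSA draws (per-iteration outputs), without the point fit."""
        return _uncertainty.run_psa(
            self.baseline,
            self.scenario,
            distributions=distributions,
            n_iterations=n_iterations,
            seed=seed,
            rr=self.relative_risks,
        )


@dataclass
class ImpactResults:
    """Fit results: point estimates, diagnostics, optional 95% UIs."""

    model: SSBLevyImpact
    point: _impact.ImpactResult
    psa: _uncertainty.UncertaintySummary | None = None

    # --- point estimates -----------------------------------------------------

    @property
    def dpp(self) -> float:
        """Total CHD deaths prevented or postponed."""
        return self.point.dpp

    @property
    def lyg(self) -> float:
        """Total life-years gained."""
        return self.point.lyg

    @property
    def per_stratum(self) -> pd.DataFrame:
        return self.point.per_stratum

    def by_age_group(self) -> pd.DataFrame:
        return self.point.by_age_group()

    def by_quintile(self) -> pd.DataFrame:
        return self.point.by_quintile()

    @property
    def prices(self) -> dict[str, float]:
        p = self.point
        return {
            "sugar_price_change_gbp_per_t": p.sugar_price_change,
            "pooled_levy_rate_gbp_per_l": p.levy_rate,
            "cost_change_gbp_per_l": p.cost_change,
            "consumer_price_change": p.consumer_price_change,
        }

    @property
    def overall_intake_change(self) -> float:
        return self.point.overall_intake_change

    # --- uncertainty ---------------------------------------------------------

    def conf_int(self) -> pd.DataFrame:
        """95% uncertainty intervals for total DPP and LYG (requires PSA)."""
        if self.psa is None:
            raise ValueError("no PSA was run; call fit(n_psa=...) for intervals")
        return self.psa.summary_frame().set_index("output")

    def summary(self) -> str:
        """Human-readable results table."""
        p = self.point
        lines = [
            "SSB levy impact model results",
            "=" * 46,
            f"scenario:               {p.label}",
            f"pass-through:           {p.pass_through:.0%}",
            f"sugar price change:     {p.sugar_price_change:.0f} GBP/t",
            f"pooled levy rate:       {p.levy_rate:.2f} GBP/l",
            f"SSB cost change:        {p.cost_change:.4f} GBP/l",
            f"consumer price change:  {p.consumer_price_change:+.1%}",
            f"overall intake change:  {p.overall_intake_change:+.1%}",
            "-" * 46,
            f"CHD deaths prevented or postponed: {p.dpp:8.0f}",
            f"life-years gained:                 {p.lyg:8.0f}",
        ]
        if self.psa is not None:
            dm, dl, du = self.psa.dpp
            lm, ll, lu = self.psa.lyg
            lines += [
                "-" * 46,
                f"PSA ({self.psa.n_iterations} iterations, seed {self.psa.seed}):",
                f"  DPP mean {dm:6.0f}  (95% UI {dl:.0f}, {du:.0f})",
                f"  LYG mean {lm:6.0f}  (95% UI {ll:.0f}, {lu:.0f})",
            ]
        lines += [
            "-" * 46,
            "DPP as % of baseline CHD deaths by age group:",
        ]
        byage = self.by_age_group()
        for _, row in byage.iterrows():
            lines.append(
                f"  {row['age_group']:>6}: {row['dpp_pct_of_deaths']:5.1f} %"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<ImpactResults {self.point.label!r}: DPP={self.dpp:.0f}, "
            f"LYG={self.lyg:.0f}"
            + (", with PSA" if self.psa is not None else "")
            + ">"
        )
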