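# Methods

## Scope and structure

`ssbimpact` is a comparative risk assessment of SSB price policy on CHD
mortality in a single target year, on a fixed grid of 70 strata (7
ten-year age bands × 2 sexes × 5 IMD quintiles). The policy effect is
assumed constant over time and immediate (no lag between intake change
and risk change); only CHD is modelled — stroke, diabetes and obesity
endpoints are deliberately out of scope, which makes the health estimates
conservative. The public surface is a model object
(`SSBLevyImpact(baseline, scenario)`) whose `fit()` returns a results
object with point estimates, per-stratum diagnostics and (optionally)
percentile uncertainty intervals.

## Trade model

The wholesale sugar-price change of a trade regime is

    ΔP = m · Σ_s w_s (Δtariff_s + Δfacilitation_s) · e,

with `m` the import share of supply, `w_s` the segment shares of imports,
and `e` the £/€ rate applied only to €-denominated figures. Multiplying
by the *import share of supply* embeds the assumption that domestically
produced sugar keeps its market share and its price is not modelled —
the conservative reading when no domestic supply response is specified.

Packaged regimes fix the supply structure at its observed values (imports
64% of supply; EU 53% of imports; 94% of third-country imports
preferential) and use a uniform facilitation cost of 33.9 €/t. The WTO
tariff applied to the routes that lose preferential status is solved in
closed form so the packaged endpoints are +92 £/t ("soft": tariff on
third-country preferential imports only, ≈291 €/t) and +203 £/t
("hard": tariff on EU and third-country preferential imports, ≈334 €/t)
at the default exchange rate of 0.885 £/€. Both solved tariffs land near
the actual WTO MFN raw-sugar tariff (≈339 €/t), which is a useful
plausibility check on the decomposition; the per-segment schedule is
ordinary config and can be replaced wholesale.

## Pricing

The two-rate levy (0.18 £/l for 5–8 g sugar/100 ml; 0.24 £/l above) is
pooled to a single sales-volume-weighted rate. The packaged band shares
(1/6 mid, 5/6 high) reproduce the 0.23 £/l market-average rate;
band-level sales data are a config input. Production cost change is
`levy + ΔP × sugar_content × 10⁻⁶` £/l with sugar content 93 g/l;
consumer price change is `pass_through × Δcost / 0.61`. All downstream
arithmetic uses unrounded £/l values — rounding the Brexit increments to
whole pence (1p, 2p) before the demand step would distort the scenario
comparisons by up to a percentage point; pence are display-only.

## Demand

The price effect is linear: −6.7% intake per +10% price, extrapolated
linearly to the ~38–41% price changes the levy implies, and capped at
−100%. Responsiveness differs by socio-economic circumstance (SEC;
quintiles 1+2 / 3 / 4+5): the multipliers take the shape
(1, (1+r)/2, r) with r = 1.65 and are rescaled by one constant so the
population×intake-weighted mean multiplier is exactly 1 on the baseline
in use. This honours two anchors simultaneously — the most-deprived
group is 65% more responsive than the least deprived, and the
population-average response equals the base effect. A `PriceEffect`
constructed without explicit multipliers self-calibrates against the
baseline at apply time. Servings convert at 250 g (≈250 ml) per serving,
a common serving definition in the cohort literature the relative risks
come from; it is configurable and DPP/LYG are invariant to it only
jointly with the RR scale, so RRs edited by hand must match the serving
definition used.

## Mortality engine

The potential impact fraction uses log-linear relative risk per daily
serving, with additive direct and BMI-mediated components:

    PIF = (1 − RR_adj^(−Δs)) + p_ow · (1 − RR_med^(−Δs)),  clamped to [0, 1).

The BMI-mediated term is weighted by the stratum's overweight prevalence
(the mediated pathway only operates where excess weight exists). SSB
intake is assumed not to change CHD case-fatality, so the incidence PIF
applies directly to deaths: `DPP = deaths × PIF`, kept fractional
internally. `LYG = DPP × Σ p_status · survival_status` over diagnosed /
undiagnosed / no-CHD decedent subgroups. Totals are exact sums over
strata.

The default RR ladder declines with age (1.40/1.25 at 25–34 down to
1.09/1.06 at 85+, direct/mediated). The source pooled analyses do not
publish age-specific values at this granularity, so the ladder is a
package calibration, fixed once: against the default synthetic baseline
it yields a levy-only effect of ≈1% of baseline CHD deaths overall
(DPP ≈ 370, LYG ≈ 4 470 at 100% pass-through) with the expected age
gradient (≈7–8% of deaths averted at 25–44, ≈1% over 65). An `age_map`
lets coarser RR age classes attach to the finer mortality bands.

## Probabilistic sensitivity analysis

Each iteration draws nine inputs independently: import share (beta,
κ=200), exchange rate (normal, CV 5%, >0), SSB price (normal, sd 0.05,
>0), price effect (normal, sd 0.85, >0), per-stratum intake (normal,
CV 15%, ≥0), relative risks (lognormal, log-sd 0.05 — the width of a
typical pooled-cohort CI for an RR near 1.2/serving), overweight
prevalence (beta, κ=60), CHD mortality (normal, CV 10.68% — derived
from the projection's 95% CI of 30 600–46 500 around 38 000 — applied as
a *shared* factor across strata because that CI refers to the total),
and median survival (gamma, CV 10%). Families and spreads are config.

Independence across parameters is conservative (correlated inputs would
partly cancel); it may overstate uncertainty. Each parameter owns a
sub-stream seeded by (master seed, parameter id), so draws are
reproducible, independent, and invariant to the order in which
parameters are processed; adding a parameter never perturbs the others'
draws. UIs are linear-interpolation empirical percentiles over
iterations (10 000 by default), not normal approximations. Levy rates,
sugar content, pass-through, SEC multipliers and CHD-status proportions
stay at point values — they are policy settings or structural shares,
not sampled estimates.

## Synthetic baseline generator

The generator emulates the joint structure of the unavailable survey and
projection inputs. Intake is log-linear in age band, sex and quintile
(defaults: ≈4× decline from 25–34 to 85+, +30% for men, +6% per
quintile) with per-stratum multiplicative noise whose amplitude is
capped at 45% of the smallest log-gradient step — so every seed
produces a table in which the orderings (intake falls with age, men >
women, deprived > affluent) hold exactly, while the level is rescaled to
hit the population-weighted mean (99.5 g/d) exactly. Setting all
gradients to zero silences the noise and yields a uniform table. Deaths
(38 000) are split by fixed age/sex shares concentrated at old ages and
a linear deprivation gradient with a 2:1 most-:least-deprived ratio;
the split conserves the total exactly. Overweight prevalence rises with
age and deprivation within [0.3, 0.8]; median survivals decline with age
(3.6–46 years without CHD) and are shorter once CHD is diagnosed
(×0.70) or present undiagnosed (×0.85) — below general life
expectancy, since decedents-averted carry worse-than-average risk
profiles, and sized so that LYG/DPP ≈ 12 years on the default baseline.

What the generator does *not* emulate: survey weights and diary
measurement error, cohort effects, within-stratum heterogeneity, and
any correlation between intake and overweight at the individual level.
Tests passing on synthetic baselines therefore validate the *engine*
(arithmetic, orderings, invariances, uncertainty propagation), not the
empirical stratum-level values, which would require the original
microdata.

## Numerical choices and edge cases

- Fractional deaths are carried everywhere; reports round only at
  display time (percentages to integers, £/l to 2 decimals, pence
  half-up).
- PIF is clamped to [0, 1): an intake *increase* cannot yield negative
  DPP through this interface (exploratory price cuts should be modelled
  by negating the scenario, not relying on the clamp).
- Intake reductions are capped at −100%.
- Degenerate distributions (sd = 0, fixed family) reproduce point
  estimates bit-for-bit; PSA with all-fixed inputs equals the
  deterministic run.
- Validation is strict: segment/band/status shares must sum to 1 within
  1e-9; baselines must cover all 70 strata exactly.

## Known limitations

- Scenario endpoints (92/203 £/t), the pooled-rate shares, the SEC
  multipliers and the RR ladder are calibrations to published aggregate
  anchors, not re-derivations from primary schedules; each is an
  editable config surface.
- The deprivation gradient in DPP compounds three gradients (mortality
  2×, intake ≈1.26×, responsiveness 1.65×) and is therefore steeper
  (≈4×) than gradients reported from stratum-level national data
  (≈2×); quintile-level outputs should be read as illustrating the
  mechanism, not as calibrated estimates.
- Single-year snapshot: no cumulative multi-year benefit, no lag
  structure, no industry reformulation response, no substitution
  modelling beyond what the longitudinal price-effect estimate already
  embeds.
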