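# Full study configuration: the three policy scenarios at all three
# pass-through rates, probabilistic sensitivity analysis included.
# Every value shown here is also the packaged default, so `ssbimpact run`
# with no config produces the same point estimates (without PSA).

baseline:
  fixture: paper-calibrated        # synthetic; calibrated to 38k CHD deaths, 99.5 g/d intake

scenarios: [levy, levy+soft, levy+hard]
pass_through: [0.8, 1.0, 1.2]

levy:
  band_rates: {mid: 0.18, high: 0.24}          # GBP per litre
  band_sales_shares: {mid: 0.16666666666666666, high: 0.8333333333333334}

price_assumptions:
  sugar_content: 93.0              # g sugar per litre of SSB
  baseline_price: 0.61             # GBP per litre

price_effect:
  base_effect: 6.7                 # % intake decrease per 10% price increase
  responsiveness_ratio: 1.65       # most- vs least-deprived responsiveness
  sec_multipliers: null            # calibrate against the baseline

serving_size: 250.0                # g per serving

psa:
  iterations: 10000
  seed: 0
  distributions:
    import_share:  {family: beta, kappa: 200.0}
    exchange_rate: {family: normal, cv: 0.05, lower: 0.0}
    ssb_price:     {family: normal, sd: 0.05, lower: 0.0}
    price_effect:  {family: normal, sd: 0.85, lower: 0.0}
    intake:        {family: normal, cv: 0.15, lower: 0.0}
    relative_risk: {family: lognormal, sigma: 0.05}
    overweight:    {family: beta, kappa: 60.0}
    mortality:     {family: normal, cv: 0.1068, lower: 0.0, shared: true}  # CI is on the projected total
    survival:      {family: gamma, cv: 0.10}
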