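"""Scenario configuration files (YAML).

One config file describes a full run: which baseline to use (a named
fixture, a CSV path, or synthesis parameters), which policy scenarios to
evaluate, the pass-through rates, the levy / price / demand assumptions
and an optional PSA block. Every default is a packaged study value; an
empty mapping is a valid config that reproduces the headline analysis.

Schema (all keys optional):

.. code-block:: yaml

    baseline:
      fixture: paper-calibrated      # or path: my_baseline.csv
      # or synthesize: {seed: 3, target_mean_intake: 99.5, ...}
    scenarios: [levy, levy+soft, levy+hard]   # or custom: {label:, trade:, levy:}
    pass_through: [0.8, 1.0, 1.2]
    levy:
      band_rates: {mid: 0.18, high: 0.24}
      band_sales_shares: {mid: 0.1666667, high: 0.8333333}
    price_assumptions: {sugar_content: 93.0, baseline_price: 0.61}
    price_effect:
      base_effect: 6.7
      responsiveness_ratio: 1.65
    serving_size: 250.0
    psa:
      iterations: 10000
      seed: 0
      distributions:
        mortality: {family: normal, cv: 0.1068, lower: 0.0}
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .demand import PriceEffect
from .pricing import LevySpec, PriceAssumptions
from .scenario import Scenario
from .strata import BaselineTable
from .synthetic import FIXTURES, SynthesisParams, load_fixture, synthesize_baseline
from .trade import NAMED_TRADE_SCENARIOS, TradeScenario, named_trade_scenario
from .uncertainty import ParameterDistribution, PSAConfig

NAMED_SCENARIOS = ("levy", "levy+soft", "levy+hard", "null")


class ConfigError(ValueError):
    """A schema violation, reported with the offending field path."""


def _expect_mapping(value, path: str) -> dict:
    if value is None:
        return {}
    if not isinstance(value, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(value).__name__}")
    return value


def _known_keys(mapping: dict, allowed: set[str], path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")


@dataclass
class RunConfig:
    """Parsed, validated run configuration."""

    baseline_spec: dict = field(default_factory=lambda: {"fixture": "paper-calibrated"})
    scenario_specs: list = field(default_factory=lambda: list(NAMED_SCENARIOS[:3]))
    pass_through: list[float] = field(default_factory=lambda: [0.8, 1.0, 1.2])
    levy: LevySpec | None = field(default_factory=LevySpec)
    price_assumptions: PriceAssumptions = field(default_factory=PriceAssumptions)
    price_effect: PriceEffect = field(default_factory=PriceEffect)
    serving_size: float = 250.0
    psa: PSAConfig | None = None

    def load_baseline(self) -> BaselineTable:
        spec = self.baseline_spec
        if "path" in spec:
            return BaselineTable.read_csv(spec["path"])
        if "synthesize" in spec:
            return synthesize_baseline(SynthesisParams(**spec["synthesize"]))
        return load_fixture(spec.get("fixture", "paper-calibrated"))

    def scenarios(self, pass_through: float) -> list[Scenario]:
        out = []
        for spec in self.scenario_specs:
            out.append(self._build_scenario(spec, pass_through))
        return out

    def _build_scenario(self, spec, pass_through: float) -> Scenario:
        common = dict(
            levy=self.levy,
            price_assumptions=self.price_assumptions,
            price_effect=self.price_effect,
            serving_size=self.serving_size,
        )
        if isinstance(spec, str):
            if spec == "levy":
                trade, label, levy = None, "levy", self.levy
            elif spec == "levy+soft":
                trade, label, levy = named_trade_scenario("soft"), "levy+soft", self.levy
            elif spec == "levy+hard":
                trade, label, levy = named_trade_scenario("hard"), "levy+hard", self.levy
            elif spec == "null":
                trade, label, levy = None, "null", None
            else:  # pragma: no cover - validated at parse time
                raise ConfigError(f"scenarios: unknown scenario {spec!r}")
        else:
            label = spec.get("label", "custom")
            levy = self.levy if spec.get("levy", True) else None
            trade_spec = spec.get("trade")
            if trade_spec is None or trade_spec == "none":
                trade = None
            elif isinstance(trade_spec, str):
                trade = named_trade_scenario(trade_spec)
            else:
                trade = TradeScenario(**trade_spec)
        common["levy"] = levy
        sc = Scenario(label=label, trade=trade, **common)
        return sc.with_pass_through(pass_through)


def parse_config(raw: dict | None) -> RunConfig:
    """Validate a raw mapping (from YAML) into a :class:`RunConfig`."""
    raw = _expect_mapping(raw, "<root>")
    _known_keys(
        raw,
        {
            "baseline",
            "scenarios",
            "pass_through",
            "levy",
            "price_assumptions",
            "price_effect",
            "serving_size",
            "psa",
        },
        "<root>",
    )
    cfg = RunConfig()

    b = _expect_mapping(raw.get("baseline"), "baseline")
    _known_keys(b, {"fixture", "path", "synthesize"}, "baseline")
    if len([k for k in ("fixture", "path", "synthesize") if k in b]) > 1:
        raise ConfigError("baseline: give only one of fixture / path / synthesize")
    if "fixture" in b and b["fixture"] not in FIXTURES:
        raise ConfigError(
            f"baseline.fixture: unknown fixture {b['fixture']!r}; "
            f"expected one of {sorted(FIXTURES)}"
        )
    if "synthesize" in b:
        syn = _expect_mapping(b["synthesize"], "baseline.synthesize")
        valid = {f.name for f in dc_fields(SynthesisParams)}
        _known_keys(syn, valid, "baseline.synthesize")
        try:
            SynthesisParams(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in syn.items()})
        except Exception as e:
            raise ConfigError(f"baseline.synthesize: {e}") from None
        b = {"synthesize": {k: (tuple(v) if isinstance(v, list) else v) for k, v in syn.items()}}
    if b:
        cfg.baseline_spec = b

    if "scenarios" in raw:
        specs = raw["scenarios"]
        if not isinstance(specs, list) or not specs:
            raise ConfigError("scenarios: expected a non-empty list")
        for i, s in enumerate(specs):
            if isinstance(s, str):
                if s not in NAMED_SCENARIOS:
                    raise ConfigError(
                        f"scenarios[{i}]: unknown scenario {s!r}; "
                        f"named scenarios are {NAMED_SCENARIOS}"
                    )
            else:
                s = _expect_mapping(s, f"scenarios[{i}]")
                _known_keys(s, {"label", "trade", "levy"}, f"scenarios[{i}]")
                t = s.get("trade")
                if isinstance(t, str) and t not in set(NAMED_TRADE_SCENARIOS):
                    raise ConfigError(
                        f"scenarios[{i}].trade: unknown trade regime {t!r}"
                    )
        cfg.scenario_specs = specs

    if "pass_through" in raw:
        pt = raw["pass_through"]
        if isinstance(pt, (int, float)):
            pt = [float(pt)]
        if not isinstance(pt, list) or not pt:
            raise ConfigError("pass_through: expected a number or non-empty list")
        for i, v in enumerate(pt):
            if not isinstance(v, (int, float)) or not 0 < v < 10:
                raise ConfigError(f"pass_through[{i}]: must be a number in (0, 10)")
        cfg.pass_through = [float(v) for v in pt]

    if "levy" in raw:
        if raw["levy"] is None:
            cfg.levy = None
        else:
            lv = _expect_mapping(raw["levy"], "levy")
            _known_keys(lv, {"band_rates", "band_sales_shares"}, "levy")
            try:
                cfg.levy = LevySpec(**lv)
            except Exception as e:
                raise ConfigError(f"levy: {e}") from None

    if "price_assumptions" in raw:
        pa = _expect_mapping(raw["price_assumptions"], "price_assumptions")
        _known_keys(pa, {"sugar_content", "baseline_price", "pass_through"}, "price_assumptions")
        pa = {k: v for k, v in pa.items() if k != "pass_through"}
        try:
            cfg.price_assumptions = PriceAssumptions(**pa)
        except Exception as e:
            raise ConfigError(f"price_assumptions: {e}") from None

    if "price_effect" in raw:
        pe = _expect_mapping(raw["price_effect"], "price_effect")
        _known_keys(
            pe,
            {"base_effect", "sec_multipliers", "sec_grouping", "responsiveness_ratio"},
            "price_effect",
        )
        if "sec_grouping" in pe and pe["sec_grouping"] is not None:
            pe["sec_grouping"] = {int(k): v for k, v in pe["sec_grouping"].items()}
        try:
            cfg.price_effect = PriceEffect(**pe)
        except Exception as e:
            raise ConfigError(f"price_effect: {e}") from None

    if "serving_size" in raw:
        ss = raw["serving_size"]
        if not isinstance(ss, (int, float)) or ss <= 0:
            raise ConfigError("serving_size: must be a positive number")
        cfg.serving_size = float(ss)

    if "psa" in raw and raw["psa"] is not None:
        ps = _expect_mapping(raw["psa"], "psa")
        _known_keys(ps, {"iterations", "seed", "distributions"}, "psa")
        n = ps.get("iterations", 10_000)
        if not isinstance(n, int) or n < 0:
            raise ConfigError("psa.iterations: must be a non-negative integer")
        if n > 0:
            dists = None
            if "distributions" in ps and ps["distributions"] is not None:
                dists = {}
                dmap = _expect_mapping(ps["distributions"], "psa.distributions")
                for name, d in dmap.items():
                    d = _expect_mapping(d, f"psa.distributions.{name}")
                    try:
                        dists[name] = ParameterDistribution(name=name, **d)
                    except Exception as e:
                        raise ConfigError(f"psa.distributions.{name}: {e}") from None
            try:
                from .uncertainty import default_distributions

                cfg.psa = PSAConfig(
                    distributions=dists if dists is not None else default_distributions(),
                    n_iterations=n,
                    seed=int(ps.get("seed", 0)),
                )
            except Exception as e:
                raise ConfigError(f"psa: {e}") from None

    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return parse_config(raw)
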