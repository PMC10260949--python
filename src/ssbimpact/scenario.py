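"""Scenario objects: levy + trade regime + price and demand assumptions.

A :class:`Scenario` fully describes one model run. The three headline
policy scenarios are the levy alone, the levy under a "soft" Brexit
(zero-duty EU FTA, WTO tariffs on third countries) and the levy under a
"hard" Brexit (WTO default position), each at a chosen pass-through rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .demand import DEFAULT_SERVING_SIZE, PriceEffect
from .pricing import LevySpec, PriceAssumptions
from .trade import TradeScenario, named_trade_scenario, no_brexit


@dataclass(frozen=True)
class Scenario:
    """One policy scenario.

    ``levy=None`` means no levy (useful for trade-only counterfactuals);
    ``trade=None`` means no trade-regime change. Brexit sugar-cost deltas
    are modelled on top of the levy, not in a levy-free counterfactual.
    """

    label: str = "levy"
    levy: LevySpec | None = field(default_factory=LevySpec)
    trade: TradeScenario | None = None
    price_assumptions: PriceAssumptions = field(default_factory=PriceAssumptions)
    price_effect: PriceEffect = field(default_factory=PriceEffect)
    serving_size: float = DEFAULT_SERVING_SIZE

    @property
    def pass_through(self) -> float:
        return self.price_assumptions.pass_through

    def with_pass_through(self, pass_through: float) -> "Scenario":
        pa = replace(self.price_assumptions, pass_through=pass_through)
        return replace(self, price_assumptions=pa)

    def replace(self, **kw) -> "Scenario":
        return replace(self, **kw)

    # --- the three headline scenarios ---------------------------------------

    @classmethod
    def levy_only(cls, pass_through: float = 1.0, **kw) -> "Scenario":
        return cls(label="levy", trade=None, **kw).with_pass_through(pass_through)

    @classmethod
    def levy_soft_brexit(cls, pass_through: float = 1.0, **kw) -> "Scenario":
        return cls(
            label="levy+soft", trade=named_trade_scenario("soft"), **kw
        ).with_pass_through(pass_through)

    @classmethod
    def levy_hard_brexit(cls, pass_through: float = 1.0, **kw) -> "Scenario":
        return cls(
            label="levy+hard", trade=named_trade_scenario("hard"), **kw
        ).with_pass_through(pass_through)

    @classmethod
    def null(cls) -> "Scenario":
        """No levy, no trade change: the do-nothing counterfactual."""
        return cls(label="null", levy=None, trade=no_brexit())


def headline_scenarios(pass_through: float = 1.0) -> list[Scenario]:
    return [
        Scenario.levy_only(pass_through),
        Scenario.levy_soft_brexit(pass_through),
        Scenario.levy_hard_brexit(pass_through),
    ]
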