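"""Strategy interface and registry plumbing.

A strategy is a stateful object: ``reset()`` returns it to its initial state
and ``next_action(own, opp, ctx, rng)`` produces the intended action for the
upcoming round given the realized histories visible to the player.  Static
classifier metadata (stochastic, makes-use-of-game, makes-use-of-length,
memory size) lives on the instance and is exported through
:class:`StrategySpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

from ..game import Action, C, D, MatchContext

__all__ = ["Strategy", "StrategySpec", "spec_of", "build_catalog"]


class Strategy:
    """Base class for all strategies.

    Subclasses set the classifier attributes and implement
    :meth:`next_action`.  ``memory_size`` is the number of past rounds the
    rule conditions on (``math.inf`` for full-history rules).
    """

    name: str = "Strategy"
    stochastic: bool = False
    makes_use_of_game: bool = False
    makes_use_of_length: bool = False
    memory_size: float = math.inf

    def reset(self) -> None:
        """Return the strategy to its exact initial state."""

    def next_action(self, own: list, opp: list, ctx: MatchContext, rng) -> Action:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{type(self).__name__} {self.name!r}>"


@dataclass(frozen=True)
class StrategySpec:
    """Registered strategy: classifier metadata plus a fresh-instance factory."""

    name: str
    stochastic: bool
    makes_use_of_game: bool
    makes_use_of_length: bool
    memory_size: float
    factory: Callable[[], Strategy]

    def classifiers(self) -> dict:
        return {
            "stochastic": self.stochastic,
            "makes_use_of_game": self.makes_use_of_game,
            "makes_use_of_length": self.makes_use_of_length,
            "memory_size": self.memory_size,
        }


def spec_of(factory: Callable[[], Strategy]) -> StrategySpec:
    """Build a :class:`StrategySpec` by instantiating the factory once."""
    proto = factory()
    return StrategySpec(
        name=proto.name,
        stochastic=bool(proto.stochastic),
        makes_use_of_game=bool(proto.makes_use_of_game),
        makes_use_of_length=bool(proto.makes_use_of_length),
        memory_size=proto.memory_size,
        factory=factory,
    )


def build_catalog(factories: Sequence[Callable[[], Strategy]]) -> Dict[str, StrategySpec]:
    """Registry mapping name -> spec; duplicate names are an error."""
    registry: Dict[str, StrategySpec] = {}
    for factory in factories:
        spec = spec_of(factory)
        if spec.name in registry:
            raise ValueError(f"duplicate strategy name: {spec.name!r}")
        registry[spec.name] = spec
    return registry
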