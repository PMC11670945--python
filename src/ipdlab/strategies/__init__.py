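"""Strategy catalog and registry.

:func:`catalog` returns the default registry of fully specified canonical
strategies.  Every entry carries the classifier metadata used by the feature
stage (stochastic, makes-use-of-game, makes-use-of-length, memory size) plus
a factory producing a fresh instance for each match.
"""

from __future__ import annotations

from typing import Dict

from .base import Strategy, StrategySpec, build_catalog, spec_of
from .catalog import (
    AdaptiveTitForTat,
    Alternator,
    BackStabber,
    Cooperator,
    Defector,
    FoolMeOnce,
    GenerousTitForTat,
    Gradual,
    Grudger,
    OmegaTFT,
    Pavlov,
    Prober,
    Random,
    SpitefulTitForTat,
    SuspiciousTitForTat,
    TitFor2Tats,
    TitForTat,
    TwoTitsForTat,
    generous_probability,
)
from .generic import (
    FSM,
    Lookup,
    MemoryOne,
    MetaMajority,
    MetaWinner,
    zd_extort_2,
    zd_gtft_2,
)
from .loader import load_strategies

__all__ = [
    "Strategy",
    "StrategySpec",
    "build_catalog",
    "spec_of",
    "catalog",
    "classify",
    "load_strategies",
    "generous_probability",
    # families
    "MemoryOne",
    "FSM",
    "Lookup",
    "MetaMajority",
    "MetaWinner",
    # named strategies
    "Cooperator",
    "Defector",
    "Alternator",
    "Random",
    "TitForTat",
    "SuspiciousTitForTat",
    "TitFor2Tats",
    "TwoTitsForTat",
    "GenerousTitForTat",
    "Grudger",
    "SpitefulTitForTat",
    "FoolMeOnce",
    "Pavlov",
    "Gradual",
    "AdaptiveTitForTat",
    "OmegaTFT",
    "Prober",
    "BackStabber",
    "zd_extort_2",
    "zd_gtft_2",
]


def _default_meta_team():
    return [TitForTat, TitFor2Tats, Grudger, Pavlov, Cooperator, Defector]


DEFAULT_FACTORIES = [
    Cooperator,
    Defector,
    Alternator,
    Random,
    TitForTat,
    SuspiciousTitForTat,
    TitFor2Tats,
    TwoTitsForTat,
    GenerousTitForTat,
    Grudger,
    SpitefulTitForTat,
    FoolMeOnce,
    Pavlov,
    Gradual,
    AdaptiveTitForTat,
    OmegaTFT,
    Prober,
    BackStabber,
    zd_extort_2,
    zd_gtft_2,
    lambda: MetaMajority(_default_meta_team()),
    lambda: MetaWinner(_default_meta_team()),
]


def catalog() -> Dict[str, StrategySpec]:
    """The default registry of canonical strategies (name -> spec)."""
    return build_catalog(DEFAULT_FACTORIES)


def classify(spec_or_name, registry=None) -> dict:
    """Classifier record (stochastic, uses game, uses length, memory size).

    Accepts a :class:`StrategySpec` or a registered name (looked up in
    ``registry``, defaulting to the standard catalog).
    """
    if isinstance(spec_or_name, StrategySpec):
        return spec_or_name.classifiers()
    registry = registry if registry is not None else catalog()
    try:
        return registry[spec_or_name].classifiers()
    except KeyError:
        raise KeyError(f"unknown strategy: {spec_or_name!r}") from None
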