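"""Validating loader for user-supplied strategy definitions.

Schema (YAML or an equivalent mapping)::

    strategies:
      - type: memory_one
        name: MyRule            # optional
        vector: [1, 0, 1, 0]    # (p_CC, p_CD, p_DC, p_DD)
        initial: C              # optional, default C
      - type: fsm
        name: MyFSM
        initial_state: 0
        initial_action: D
        transitions:            # [state, opp_action, next_state, action]
          - [0, C, 0, C]
          - [0, D, 1, D]
          - [1, C, 1, D]
          - [1, D, 1, D]
      - type: lookup
        name: MyLookup
        memory: 1
        openings: [C]
        table:                  # "own|opp" windows, most recent last
          "C|C": C
          "C|D": D
          "D|C": C
          "D|D": D

The loader returns :class:`StrategySpec` objects ready for tournaments.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Union

import yaml

from ..game import Action, C, D
from .base import StrategySpec, spec_of
from .generic import FSM, Lookup, MemoryOne

__all__ = ["load_strategies"]


def _parse_action(token) -> Action:
    if isinstance(token, Action):
        return token
    if isinstance(token, str) and token.upper() in ("C", "D"):
        return C if token.upper() == "C" else D
    raise ValueError(f"invalid action {token!r}; expected 'C' or 'D'")


def _memory_one(entry: Mapping) -> MemoryOne:
    if "vector" not in entry:
        raise ValueError("memory_one entry needs a 'vector'")
    return MemoryOne(
        entry["vector"],
        initial=_parse_action(entry.get("initial", "C")),
        name=entry.get("name"),
    )


def _fsm(entry: Mapping) -> FSM:
    try:
        rows = entry["transitions"]
        initial_state = entry["initial_state"]
    except KeyError as exc:
        raise ValueError(f"fsm entry missing {exc}") from exc
    transitions = {}
    for row in rows:
        if len(row) != 4:
            raise ValueError(f"fsm transition row must have 4 fields, got {row!r}")
        state, opp_action, next_state, action = row
        transitions[(state, _parse_action(opp_action))] = (
            next_state,
            _parse_action(action),
        )
    return FSM(
        transitions,
        initial_state=initial_state,
        initial_action=_parse_action(entry.get("initial_action", "C")),
        name=entry.get("name"),
    )


def _lookup(entry: Mapping) -> Lookup:
    try:
        memory = int(entry["memory"])
        openings = entry["openings"]
        raw = entry["table"]
    except KeyError as exc:
        raise ValueError(f"lookup entry missing {exc}") from exc
    table = {}
    for key, value in raw.items():
        parts = key.split("|")
        if len(parts) != 2 or any(len(p) != memory for p in parts):
            raise ValueError(
                f"lookup key {key!r} must be 'own|opp' windows of length {memory}"
            )
        own = tuple(_parse_action(ch) for ch in parts[0])
        opp = tuple(_parse_action(ch) for ch in parts[1])
        table[(own, opp)] = _parse_action(value)
    return Lookup(
        table,
        memory=memory,
        openings=[_parse_action(a) for a in openings],
        name=entry.get("name"),
    )


_BUILDERS = {"memory_one": _memory_one, "fsm": _fsm, "lookup": _lookup}


def load_strategies(source: Union[str, Mapping]) -> List[StrategySpec]:
    """Load strategy definitions from a YAML file path or a parsed mapping."""
    if isinstance(source, Mapping):
        doc = source
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "strategies" not in doc:
        raise ValueError("strategy config must be a mapping with a 'strategies' list")
    specs: List[StrategySpec] = []
    seen: Dict[str, bool] = {}
    for entry in doc["strategies"]:
        kind = entry.get("type")
        if kind not in _BUILDERS:
            raise ValueError(
                f"unknown strategy type {kind!r}; expected one of {sorted(_BUILDERS)}"
            )
        builder = _BUILDERS[kind]
        # Build once to validate, then register a factory that rebuilds fresh.
        proto = builder(entry)
        if proto.name in seen:
            raise ValueError(f"duplicate strategy name: {proto.name!r}")
        seen[proto.name] = True
        specs.append(spec_of(lambda entry=entry, builder=builder: builder(entry)))
    return specs
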