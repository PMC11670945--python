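"""Generic strategy families: memory-one, finite-state machines, lookup
tables, and meta ensembles.

These provide the machinery to express strategies from published rule tables
(memory-one vectors, FSM transition tables, lookup tables) without shipping
any trained parameter sets.
"""

from __future__ import annotations

import math
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple

from ..game import Action, C, D, stage_payoff
from .base import Strategy

__all__ = [
    "MemoryOne",
    "FSM",
    "Lookup",
    "MetaMajority",
    "MetaWinner",
    "zd_extort_2",
    "zd_gtft_2",
]

# Joint-state order used throughout: (CC, CD, DC, DD), focal action first.
STATE_ORDER = ((C, C), (C, D), (D, C), (D, D))


def _state_index(own_last: Action, opp_last: Action) -> int:
    return 2 * int(own_last) + int(opp_last)


class MemoryOne(Strategy):
    """Plays according to four conditional cooperation probabilities
    (p_CC, p_CD, p_DC, p_DD) keyed on the previous round's realized joint
    state, with a fixed opening action.

    Degenerate probabilities (0 or 1) are resolved without consuming the RNG
    stream, so a 0/1 vector such as TFT's (1, 0, 1, 0) is fully
    deterministic.
    """

    memory_size = 1

    def __init__(
        self,
        vector: Sequence[float],
        initial: Action = C,
        name: Optional[str] = None,
    ):
        vec = tuple(float(p) for p in vector)
        if len(vec) != 4:
            raise ValueError("memory-one vector must have 4 entries (CC, CD, DC, DD)")
        if any(not (0.0 <= p <= 1.0) for p in vec):
            raise ValueError(f"memory-one probabilities must be in [0, 1], got {vec}")
        self.vector = vec
        self.initial = Action(initial)
        self.name = name or f"MemoryOne{vec}"
        self.stochastic = any(0.0 < p < 1.0 for p in vec)

    def next_action(self, own, opp, ctx, rng):
        if not own:
            return self.initial
        p = self.vector[_state_index(own[-1], opp[-1])]
        if p >= 1.0:
            return C
        if p <= 0.0:
            return D
        return C if rng.random() < p else D


def zd_extort_2() -> MemoryOne:
    """Extortionate zero-determinant strategy with chi = 2 (vector
    (8/9, 1/2, 1/3, 0))."""
    return MemoryOne((8 / 9, 1 / 2, 1 / 3, 0.0), initial=C, name="ZD-Extort-2")


def zd_gtft_2() -> MemoryOne:
    """Generous zero-determinant strategy (vector (1, 1/8, 1, 1/4))."""
    return MemoryOne((1.0, 1 / 8, 1.0, 1 / 4), initial=C, name="ZD-GTFT-2")


class FSM(Strategy):
    """Moore-style finite-state machine.

    ``transitions`` maps (state, opponent's last action) to
    (next state, action to play).  The machine plays ``initial_action`` on
    the first turn and thereafter advances one transition per observed
    opponent action.
    """

    memory_size = math.inf

    def __init__(
        self,
        transitions: Mapping[Tuple[object, Action], Tuple[object, Action]],
        initial_state,
        initial_action: Action = C,
        name: Optional[str] = None,
    ):
        self.transitions = {
            (s, Action(a)): (s2, Action(a2)) for (s, a), (s2, a2) in transitions.items()
        }
        states = {s for s, _ in self.transitions}
        for s in states:
            for a in (C, D):
                if (s, a) not in self.transitions:
                    raise ValueError(f"FSM transition table missing ({s!r}, {a})")
        if initial_state not in states:
            raise ValueError(f"unknown initial state {initial_state!r}")
        self.initial_state = initial_state
        self.initial_action = Action(initial_action)
        self.name = name or f"FSM({len(states)} states)"
        self.reset()

    def reset(self):
        self._state = self.initial_state
        self._last_action = self.initial_action
        self._seen = 0

    def next_action(self, own, opp, ctx, rng):
        while self._seen < len(opp):
            self._state, self._last_action = self.transitions[
                (self._state, opp[self._seen])
            ]
            self._seen += 1
        return self._last_action


class Lookup(Strategy):
    """Looks up the action from the last ``memory`` rounds of joint history.

    ``table`` maps (own last m actions, opponent last m actions) — most
    recent last — to an action.  The first m turns follow the fixed
    ``openings`` sequence.
    """

    def __init__(
        self,
        table: Mapping[Tuple[Tuple[Action, ...], Tuple[Action, ...]], Action],
        memory: int,
        openings: Sequence[Action],
        name: Optional[str] = None,
    ):
        if memory < 1:
            raise ValueError("memory must be >= 1")
        if len(openings) != memory:
            raise ValueError("openings must supply exactly `memory` opening actions")
        self.table = {
            (tuple(Action(a) for a in ok), tuple(Action(a) for a in pk)): Action(v)
            for (ok, pk), v in table.items()
        }
        expected = 4 ** memory
        if len(self.table) != expected:
            raise ValueError(
                f"lookup table must cover all {expected} joint histories, "
                f"got {len(self.table)}"
            )
        self.memory = memory
        self.memory_size = memory
        self.openings = [Action(a) for a in openings]
        self.name = name or f"Lookup(m={memory})"

    def next_action(self, own, opp, ctx, rng):
        t = len(own)
        if t < self.memory:
            return self.openings[t]
        key = (tuple(own[-self.memory:]), tuple(opp[-self.memory:]))
        return self.table[key]


class _Meta(Strategy):
    """Shared plumbing for ensemble strategies.

    Team members observe the ensemble's realized history as their own; each
    round every member proposes an action and the ensemble aggregates the
    proposals.
    """

    def __init__(self, team_factories: Sequence[Callable[[], Strategy]], name: str):
        if not team_factories:
            raise ValueError("meta strategy needs a non-empty team")
        self._factories = list(team_factories)
        self.team = [f() for f in self._factories]
        self.name = name
        self.stochastic = any(m.stochastic for m in self.team)
        self.makes_use_of_length = any(m.makes_use_of_length for m in self.team)
        self.memory_size = math.inf
        self.reset()

    def reset(self):
        self.team = [f() for f in self._factories]
        for m in self.team:
            m.reset()

    def _proposals(self, own, opp, ctx, rng):
        return [m.next_action(own, opp, ctx, rng) for m in self.team]


class MetaMajority(_Meta):
    """Plays the majority vote of its team's proposed actions (ties -> C)."""

    def __init__(self, team_factories, name: str = "Meta Majority"):
        super().__init__(team_factories, name)
        self.makes_use_of_game = any(m.makes_use_of_game for m in self.team)

    def next_action(self, own, opp, ctx, rng):
        proposals = self._proposals(own, opp, ctx, rng)
        defects = sum(1 for a in proposals if a == D)
        return D if defects > len(proposals) / 2 else C


class MetaWinner(_Meta):
    """Plays the proposal of the team member with the best hypothetical
    running score (each member's proposals scored against the opponent's
    realized actions; ties go to the earliest member)."""

    makes_use_of_game = True

    def __init__(self, team_factories, name: str = "Meta Winner"):
        super().__init__(team_factories, name)

    def reset(self):
        super().reset()
        self._scores = [0.0] * len(self.team)
        self._last_proposals = None

    def next_action(self, own, opp, ctx, rng):
        if self._last_proposals is not None and opp:
            for i, a in enumerate(self._last_proposals):
                self._scores[i] += stage_payoff(a, opp[-1], ctx.payoffs)[0]
        proposals = self._proposals(own, opp, ctx, rng)
        best = max(range(len(self.team)), key=lambda i: (self._scores[i], -i))
        self._last_proposals = proposals
        return proposals[best]
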