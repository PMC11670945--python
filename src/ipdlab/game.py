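"""Stage game and single-match engine for the Iterated Prisoner's Dilemma.

The stage game is the standard symmetric two-action game with payoffs
``T > R > P > S`` and ``2R > T + S`` (defaults R=3, S=0, T=5, P=1).  A match
iterates the stage game either for a fixed number of turns ``n`` or until a
geometric stopping event with per-turn ending probability ``p_e``.  Each
player's intended action may independently be flipped with probability
``p_n`` ("noise") before it is played; the flipped, *realized* action is what
both players observe and what is scored.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np

__all__ = [
    "Action",
    "C",
    "D",
    "PayoffMatrix",
    "DEFAULT_PAYOFFS",
    "MatchConfig",
    "MatchContext",
    "RoundRecord",
    "MatchResult",
    "stage_payoff",
    "sample_match_length",
    "apply_noise",
    "play_match",
]


class Action(enum.IntEnum):
    """Cooperate or defect."""

    C = 0
    D = 1

    def flip(self) -> "Action":
        return Action(1 - self.value)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


C = Action.C
D = Action.D


@dataclass(frozen=True)
class PayoffMatrix:
    """The four stage-game payoffs.

    ``R`` is the reward for mutual cooperation, ``S`` the sucker's payoff,
    ``T`` the temptation to defect and ``P`` the punishment for mutual
    defection.  The orderings ``T > R > P > S`` and ``2R > T + S`` are
    enforced; they make defection dominant in one shot while keeping
    alternating exploitation worse than mutual cooperation.
    """

    R: float = 3.0
    S: float = 0.0
    T: float = 5.0
    P: float = 1.0

    def __post_init__(self) -> None:
        if not (self.T > self.R > self.P > self.S):
            raise ValueError(
                f"payoffs must satisfy T > R > P > S, got "
                f"T={self.T}, R={self.R}, P={self.P}, S={self.S}"
            )
        if not (2 * self.R > self.T + self.S):
            raise ValueError(
                f"payoffs must satisfy 2R > T + S, got R={self.R}, "
                f"T={self.T}, S={self.S}"
            )

    def table(self) -> dict:
        """Mapping (focal, opponent) -> (focal payoff, opponent payoff)."""
        return {
            (C, C): (self.R, self.R),
            (C, D): (self.S, self.T),
            (D, C): (self.T, self.S),
            (D, D): (self.P, self.P),
        }


DEFAULT_PAYOFFS = PayoffMatrix()


def stage_payoff(
    focal: Action, opponent: Action, payoffs: PayoffMatrix = DEFAULT_PAYOFFS
) -> tuple:
    """Payoff pair (focal, opponent) for one joint action."""
    return payoffs.table()[(Action(focal), Action(opponent))]


class RoundRecord(NamedTuple):
    """Realized (post-noise) actions of one round, focal player first."""

    focal_action: Action
    opponent_action: Action


@dataclass
class MatchResult:
    """One player's view of a completed match."""

    rounds: list
    total_focal: float
    total_opponent: float

    @property
    def length(self) -> int:
        return len(self.rounds)

    @property
    def per_turn_focal(self) -> float:
        return self.total_focal / self.length

    @property
    def per_turn_opponent(self) -> float:
        return self.total_opponent / self.length

    def focal_actions(self) -> list:
        return [r.focal_action for r in self.rounds]


@dataclass(frozen=True)
class MatchConfig:
    """Match-level parameters.

    Exactly one of ``turns`` (fixed length n) and ``ending`` (per-turn ending
    probability p_e) must be set.  ``noise`` is the per-player per-turn action
    flip probability p_n.  ``length_cap`` bounds geometric match lengths so a
    tiny p_e cannot produce an effectively infinite match.
    """

    turns: Optional[int] = None
    ending: Optional[float] = None
    noise: float = 0.0
    length_cap: int = 10_000
    seed: Union[int, np.random.SeedSequence] = 0

    def __post_init__(self) -> None:
        if (self.turns is None) == (self.ending is None):
            raise ValueError("exactly one of turns / ending must be set")
        if self.turns is not None and self.turns < 1:
            raise ValueError(f"turns must be >= 1, got {self.turns}")
        if self.ending is not None and not (0.0 < self.ending <= 1.0):
            raise ValueError(f"ending probability must be in (0, 1], got {self.ending}")
        if not (0.0 <= self.noise <= 1.0):
            raise ValueError(f"noise must be in [0, 1], got {self.noise}")
        if self.length_cap < 1:
            raise ValueError("length_cap must be >= 1")


@dataclass
class MatchContext:
    """Information a strategy may consult besides the action histories.

    ``turns`` is the total match length when it is known in advance (fixed-n
    matches) and ``None`` under probabilistic ending; ``turn`` is the 0-based
    index of the round about to be played.
    """

    payoffs: PayoffMatrix
    turns: Optional[int]
    turn: int = 0


def sample_match_length(
    ending: float, cap: int, rng: np.random.Generator
) -> int:
    """Draw a geometric match length: P(L = l) = (1 - p_e)^(l-1) p_e, capped.

    Raises on p_e outside (0, 1].
    """
    if not (0.0 < ending <= 1.0):
        raise ValueError(f"ending probability must be in (0, 1], got {ending}")
    if ending == 1.0:
        return 1
    return min(int(rng.geometric(ending)), int(cap))


def apply_noise(intended: Action, noise: float, rng: np.random.Generator) -> Action:
    """Flip ``intended`` with probability ``noise``."""
    if noise <= 0.0:
        return intended
    if noise >= 1.0:
        return intended.flip()
    if rng.random() < noise:
        return intended.flip()
    return intended


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def play_match(
    strategy_a,
    strategy_b,
    config: MatchConfig,
    payoffs: PayoffMatrix = DEFAULT_PAYOFFS,
) -> tuple:
    """Play one match and return (result for a, result for b).

    Three independent RNG streams are derived from ``config.seed``: one for
    the match-length draw and one per player (noise + the player's own
    stochastic decisions).  Both strategies observe the realized, post-noise
    history — their own realized actions included — which is the standard
    noisy-IPD convention.
    """
    ss = _as_seedseq(config.seed)
    ss_len, ss_a, ss_b = ss.spawn(3)
    rng_a = np.random.default_rng(ss_a)
    rng_b = np.random.default_rng(ss_b)

    if config.turns is not None:
        length = config.turns
        known = config.turns
    else:
        length = sample_match_length(
            config.ending, config.length_cap, np.random.default_rng(ss_len)
        )
        known = None

    strategy_a.reset()
    strategy_b.reset()
    ctx_a = MatchContext(payoffs=payoffs, turns=known)
    ctx_b = MatchContext(payoffs=payoffs, turns=known)

    table = payoffs.table()
    hist_a: list = []
    hist_b: list = []
    total_a = 0.0
    total_b = 0.0
    noise = config.noise
    for t in range(length):
        ctx_a.turn = t
        ctx_b.turn = t
        ia = strategy_a.next_action(hist_a, hist_b, ctx_a, rng_a)
        ib = strategy_b.next_action(hist_b, hist_a, ctx_b, rng_b)
        ra = apply_noise(ia, noise, rng_a)
        rb = apply_noise(ib, noise, rng_b)
        hist_a.append(ra)
        hist_b.append(rb)
        pa, pb = table[(ra, rb)]
        total_a += pa
        total_b += pb

    rounds_a = [RoundRecord(a, b) for a, b in zip(hist_a, hist_b)]
    rounds_b = [RoundRecord(b, a) for a, b in zip(hist_a, hist_b)]
    return (
        MatchResult(rounds=rounds_a, total_focal=total_a, total_opponent=total_b),
        MatchResult(rounds=rounds_b, total_focal=total_b, total_opponent=total_a),
    )
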