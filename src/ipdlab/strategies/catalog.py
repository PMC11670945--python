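"""Canonical named strategies.

Each class documents its exact decision rule; the golden-trace tests assert
these rules against hand-derived action sequences.  Strategies observe the
realized (post-noise) history, so rules that react to "the opponent defected"
react to what was actually played, not to intent.
"""

from __future__ import annotations

import math

from ..game import Action, C, D
from .base import Strategy

__all__ = [
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
    "generous_probability",
]


class Cooperator(Strategy):
    """Always cooperates."""

    name = "Cooperator"
    memory_size = 0

    def next_action(self, own, opp, ctx, rng):
        return C


class Defector(Strategy):
    """Always defects."""

    name = "Defector"
    memory_size = 0

    def next_action(self, own, opp, ctx, rng):
        return D


class Alternator(Strategy):
    """Cooperates first, then plays the opposite of its own previous action."""

    name = "Alternator"
    memory_size = 1

    def next_action(self, own, opp, ctx, rng):
        if not own:
            return C
        return own[-1].flip()


class Random(Strategy):
    """Cooperates with fixed probability p each turn (default 0.5)."""

    name = "Random"
    stochastic = True
    memory_size = 0

    def __init__(self, p: float = 0.5):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p must be in [0, 1], got {p}")
        self.p = p

    def next_action(self, own, opp, ctx, rng):
        return C if rng.random() < self.p else D


class TitForTat(Strategy):
    """Cooperates first; thereafter copies the opponent's previous action."""

    name = "Tit For Tat"
    memory_size = 1

    def next_action(self, own, opp, ctx, rng):
        if not opp:
            return C
        return opp[-1]


class SuspiciousTitForTat(Strategy):
    """Defects first; thereafter copies the opponent's previous action."""

    name = "Suspicious Tit For Tat"
    memory_size = 1

    def next_action(self, own, opp, ctx, rng):
        if not opp:
            return D
        return opp[-1]


class TitFor2Tats(Strategy):
    """Defects only after two consecutive opponent defections."""

    name = "Tit For 2 Tats"
    memory_size = 2

    def next_action(self, own, opp, ctx, rng):
        if len(opp) >= 2 and opp[-1] == D and opp[-2] == D:
            return D
        return C


class TwoTitsForTat(Strategy):
    """Defects if the opponent defected in either of the last two rounds."""

    name = "Two Tits For Tat"
    memory_size = 2

    def next_action(self, own, opp, ctx, rng):
        if D in opp[-2:]:
            return D
        return C


def generous_probability(payoffs) -> float:
    """Generosity g = min(1 - (T-R)/(R-S), (R-P)/(T-P)); 1/3 at defaults."""
    R, S, T, P = payoffs.R, payoffs.S, payoffs.T, payoffs.P
    return min(1.0 - (T - R) / (R - S), (R - P) / (T - P))


class GenerousTitForTat(Strategy):
    """TFT that forgives a defection with probability g.

    g is the standard generosity level min(1-(T-R)/(R-S), (R-P)/(T-P)),
    evaluated from the match's payoff matrix (1/3 at the default payoffs).
    Behaviorally memory-one with cooperation vector (1, g, 1, g).
    """

    name = "Generous Tit For Tat"
    stochastic = True
    makes_use_of_game = True
    memory_size = 1

    def next_action(self, own, opp, ctx, rng):
        if not opp:
            return C
        if opp[-1] == C:
            return C
        return C if rng.random() < generous_probability(ctx.payoffs) else D


class Grudger(Strategy):
    """Cooperates until the opponent's first defection, then defects forever."""

    name = "Grudger"
    memory_size = math.inf

    def __init__(self):
        self.reset()

    def reset(self):
        self._triggered = False
        self._seen = 0

    def _observe(self, opp):
        while self._seen < len(opp):
            if opp[self._seen] == D:
                self._triggered = True
            self._seen += 1

    def next_action(self, own, opp, ctx, rng):
        self._observe(opp)
        return D if self._triggered else C


class SpitefulTitForTat(Strategy):
    """TFT until the opponent defects twice consecutively, then defects forever."""

    name = "Spiteful Tit For Tat"
    memory_size = math.inf

    def __init__(self):
        self.reset()

    def reset(self):
        self._triggered = False
        self._seen = 0

    def next_action(self, own, opp, ctx, rng):
        while self._seen < len(opp):
            if self._seen >= 1 and opp[self._seen] == D and opp[self._seen - 1] == D:
                self._triggered = True
            self._seen += 1
        if self._triggered:
            return D
        return opp[-1] if opp else C


class FoolMeOnce(Strategy):
    """Forgives one defection; defects forever after the opponent's second."""

    name = "Fool Me Once"
    memory_size = math.inf

    def __init__(self):
        self.reset()

    def reset(self):
        self._defections = 0
        self._seen = 0

    def next_action(self, own, opp, ctx, rng):
        while self._seen < len(opp):
            if opp[self._seen] == D:
                self._defections += 1
            self._seen += 1
        return D if self._defections >= 2 else C


class Pavlov(Strategy):
    """Win-Stay-Lose-Shift: cooperates first and whenever the previous round's
    actions matched; defects after a mismatched round."""

    name = "Pavlov"
    memory_size = 1

    def next_action(self, own, opp, ctx, rng):
        if not own:
            return C
        return C if own[-1] == opp[-1] else D


class Gradual(Strategy):
    """Punishes the opponent's k-th defection with k consecutive defections,
    then cooperates twice (a "calming" phase) before returning to cooperation.

    The punishment length equals the opponent's total defection count at the
    moment the punishment is triggered.  Defections committed while the
    strategy is punishing or calming are counted but do not trigger a new
    punishment until the strategy is idle again.
    """

    name = "Gradual"
    memory_size = math.inf

    def __init__(self):
        self.reset()

    def reset(self):
        self._defections = 0
        self._punishing = 0
        self._calming = 0
        self._seen = 0

    def next_action(self, own, opp, ctx, rng):
        while self._seen < len(opp):
            if opp[self._seen] == D:
                self._defections += 1
            self._seen += 1
        if self._punishing > 0:
            self._punishing -= 1
            if self._punishing == 0:
                self._calming = 2
            return D
        if self._calming > 0:
            self._calming -= 1
            return C
        if opp and opp[-1] == D:
            self._punishing = self._defections - 1
            if self._punishing == 0:
                self._calming = 2
            return D
        return C


class AdaptiveTitForTat(Strategy):
    """Keeps an exponentially smoothed estimate w of the opponent's
    cooperativeness (w <- (1-theta) w + theta [opponent played C], w0 = 0.5)
    and cooperates iff w >= 0.5."""

    name = "Adaptive Tit For Tat"
    memory_size = math.inf

    def __init__(self, theta: float = 0.5):
        if not (0.0 < theta <= 1.0):
            raise ValueError(f"theta must be in (0, 1], got {theta}")
        self.theta = theta
        self.reset()

    def reset(self):
        self._w = 0.5
        self._seen = 0

    def next_action(self, own, opp, ctx, rng):
        while self._seen < len(opp):
            obs = 1.0 if opp[self._seen] == C else 0.0
            self._w = (1.0 - self.theta) * self._w + self.theta * obs
            self._seen += 1
        return C if self._w >= 0.5 else D


class OmegaTFT(Strategy):
    """TFT with deadlock-breaking and a randomness trigger.

    Plays C on turn 1 and TFT on turn 2.  From turn 3 on it keeps two
    counters.  The deadlock counter increments whenever the previous round's
    actions differed (the CD/DC alternation TFT can fall into under noise)
    and resets on agreement; once it reaches ``deadlock_threshold`` the
    strategy cooperates to break the cycle and resets the counter.  The
    randomness counter increases when the opponent's last two moves differ
    and when the previous round's actions differed, and decreases after two
    consecutive opponent cooperations; once it reaches
    ``randomness_threshold`` the opponent is deemed random and the strategy
    defects for the remainder of the match.
    """

    name = "Omega TFT"
    memory_size = math.inf

    def __init__(self, deadlock_threshold: int = 3, randomness_threshold: int = 8):
        self.deadlock_threshold = deadlock_threshold
        self.randomness_threshold = randomness_threshold
        self.reset()

    def reset(self):
        self._deadlock = 0
        self._randomness = 0
        self._defect_forever = False

    def next_action(self, own, opp, ctx, rng):
        if self._defect_forever:
            return D
        t = len(own)
        if t == 0:
            return C
        if t == 1:
            return opp[-1]
        if self._deadlock >= self.deadlock_threshold:
            self._deadlock = 0
            return C
        if opp[-1] != opp[-2]:
            self._randomness += 1
        if own[-1] != opp[-1]:
            self._randomness += 1
        if opp[-1] == C and opp[-2] == C:
            self._randomness -= 1
        if self._randomness >= self.randomness_threshold:
            self._defect_forever = True
            return D
        move = opp[-1]
        if own[-1] != opp[-1]:
            self._deadlock += 1
        else:
            self._deadlock = 0
        return move


class Prober(Strategy):
    """Opens D, C, C; if the opponent cooperated on turns 2 and 3 it defects
    forever (the opponent looks exploitable), otherwise plays TFT."""

    name = "Prober"
    memory_size = math.inf

    def next_action(self, own, opp, ctx, rng):
        t = len(own)
        if t == 0:
            return D
        if t in (1, 2):
            return C
        if opp[1] == C and opp[2] == C:
            return D
        return opp[-1]


class BackStabber(Strategy):
    """Forgives the first three opponent defections and defects forever on the
    fourth; when the match length is known, unconditionally defects on the
    last two rounds."""

    name = "BackStabber"
    makes_use_of_length = True
    memory_size = math.inf

    def __init__(self):
        self.reset()

    def reset(self):
        self._defections = 0
        self._seen = 0

    def next_action(self, own, opp, ctx, rng):
        while self._seen < len(opp):
            if opp[self._seen] == D:
                self._defections += 1
            self._seen += 1
        if ctx.turns is not None and ctx.turn >= ctx.turns - 2:
            return D
        return D if self._defections >= 4 else C
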