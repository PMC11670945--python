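"""Round-robin tournament runner and per-strategy result summaries.

A tournament plays every unordered pair of players once per repetition
(self-pairs included by default, but excluded from scoring and ranking).
A player's score in one repetition is its mean per-turn payoff over its
matches against the other N-1 players; the ranking statistic is the median
of these per-repetition means over the k repetitions.  Behavioral statistics
(cooperation rating, initial cooperation, joint-state occupancy, conditional
cooperation rates, match wins) are pooled raw counts over all rounds, matches
and repetitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .game import (
    Action,
    C,
    D,
    DEFAULT_PAYOFFS,
    MatchConfig,
    MatchResult,
    PayoffMatrix,
    play_match,
)
from .strategies import StrategySpec

__all__ = [
    "TournamentConfig",
    "SummaryRow",
    "ResultSummary",
    "BehaviorCounter",
    "run_tournament",
    "summarize_behavior",
    "rank_rows",
    "SUMMARY_COLUMNS",
]

STATES = ("CC", "CD", "DC", "DD")

SUMMARY_COLUMNS = [
    "rank",
    "name",
    "median_score",
    "cooperation_rating",
    "wins",
    "initial_C",
    "CC_rate",
    "CD_rate",
    "DC_rate",
    "DD_rate",
    "CC_to_C",
    "CD_to_C",
    "DC_to_C",
    "DD_to_C",
]


@dataclass(frozen=True)
class TournamentConfig:
    """Tournament parameters.

    Exactly one of ``turns`` / ``ending`` governs match length.  Flags:
    ``self_play`` plays self-pairs; ``self_play_scores`` includes them in
    scoring (off by default); ``self_play_behavior`` includes their rounds in
    the behavioral statistics.  ``rank_statistic`` is "median" (default) or
    "mean" over the per-repetition scores.
    """

    players: Sequence[StrategySpec]
    repetitions: int = 1
    turns: Optional[int] = None
    ending: Optional[float] = None
    noise: float = 0.0
    seed: int = 0
    length_cap: int = 10_000
    self_play: bool = True
    self_play_scores: bool = False
    self_play_behavior: bool = True
    rank_statistic: str = "median"

    def __post_init__(self) -> None:
        if len(self.players) < 2:
            raise ValueError("a tournament needs at least 2 players")
        names = [p.name for p in self.players]
        if len(set(names)) != len(names):
            raise ValueError(f"player names must be unique, got {names}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.rank_statistic not in ("median", "mean"):
            raise ValueError("rank_statistic must be 'median' or 'mean'")
        # Delegate length/noise validation.
        MatchConfig(
            turns=self.turns,
            ending=self.ending,
            noise=self.noise,
            length_cap=self.length_cap,
        )


class BehaviorCounter:
    """Pooled behavioral counts for one player."""

    def __init__(self) -> None:
        self.plays = 0
        self.coop = 0
        self.matches = 0
        self.initial_coop = 0
        self.state_counts = np.zeros(4, dtype=np.int64)
        self.cond_counts = np.zeros(4, dtype=np.int64)  # focal C after state
        self.cond_totals = np.zeros(4, dtype=np.int64)  # state had a successor
        self.wins = 0

    def add_match(self, result: MatchResult) -> None:
        rounds = result.rounds
        self.matches += 1
        self.plays += len(rounds)
        self.coop += sum(1 for r in rounds if r.focal_action == C)
        if rounds[0].focal_action == C:
            self.initial_coop += 1
        prev = None
        for r in rounds:
            s = 2 * int(r.focal_action) + int(r.opponent_action)
            self.state_counts[s] += 1
            if prev is not None:
                self.cond_totals[prev] += 1
                if r.focal_action == C:
                    self.cond_counts[prev] += 1
            prev = s

    def summary(self) -> dict:
        out = {
            "cooperation_rating": self.coop / self.plays if self.plays else math.nan,
            "initial_C": self.initial_coop / self.matches if self.matches else math.nan,
            "wins": self.wins,
        }
        total = self.state_counts.sum()
        for i, s in enumerate(STATES):
            out[f"{s}_rate"] = self.state_counts[i] / total if total else math.nan
            # A conditional rate with no visits to its state is missing, not 0.
            out[f"{s}_to_C"] = (
                self.cond_counts[i] / self.cond_totals[i]
                if self.cond_totals[i]
                else math.nan
            )
        return out


@dataclass
class SummaryRow:
    rank: int
    name: str
    median_score: float
    cooperation_rating: float
    wins: int
    initial_C: float
    CC_rate: float
    CD_rate: float
    DC_rate: float
    DD_rate: float
    CC_to_C: float
    CD_to_C: float
    DC_to_C: float
    DD_to_C: float

    def cond_coop(self) -> dict:
        return {s: getattr(self, f"{s}_to_C") for s in STATES}

    def state_rates(self) -> dict:
        return {s: getattr(self, f"{s}_rate") for s in STATES}


@dataclass
class ResultSummary:
    """Per-strategy tournament statistics, ordered by rank."""

    rows: List[SummaryRow]
    repetitions: int = 1
    turns: Optional[int] = None
    ending: Optional[float] = None
    noise: float = 0.0
    seed: Optional[int] = None

    @property
    def n_players(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> SummaryRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(f"no row for {name!r}")

    def names(self) -> List[str]:
        return [r.name for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{c: getattr(r, c) for c in SUMMARY_COLUMNS} for r in self.rows],
            columns=SUMMARY_COLUMNS,
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **meta) -> "ResultSummary":
        rows = [
            SummaryRow(**{c: row[c] for c in SUMMARY_COLUMNS})
            for _, row in df.iterrows()
        ]
        rows = [
            SummaryRow(
                **{
                    c: (int(getattr(r, c)) if c in ("rank", "wins") else getattr(r, c))
                    for c in SUMMARY_COLUMNS
                }
            )
            for r in rows
        ]
        return cls(rows=rows, **meta)

    @classmethod
    def read_csv(cls, path, **meta) -> "ResultSummary":
        return cls.from_frame(pd.read_csv(path), **meta)


def rank_rows(scores: Sequence[float], names: Sequence[str]) -> np.ndarray:
    """Ranks 0..N-1 by descending score; ties broken by lexicographic name."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], names[i]))
    ranks = np.empty(len(scores), dtype=int)
    for position, idx in enumerate(order):
        ranks[idx] = position
    return ranks


def summarize_behavior(match_results: Dict[str, Sequence[MatchResult]]) -> dict:
    """Pool behavioral statistics from per-player match result lists.

    ``match_results`` maps player name to the player's focal
    :class:`MatchResult` views.  Wins count matches with a strictly greater
    total; equal totals count for neither player.
    """
    out = {}
    for name, results in match_results.items():
        counter = BehaviorCounter()
        for res in results:
            counter.add_match(res)
            if res.total_focal > res.total_opponent:
                counter.wins += 1
        out[name] = counter.summary()
    return out


def run_tournament(
    config: TournamentConfig, payoffs: PayoffMatrix = DEFAULT_PAYOFFS
) -> ResultSummary:
    """Run a round-robin tournament and produce its result summary.

    Match seeds derive deterministically from the tournament seed and the
    (repetition, pair) indices, so the result is reproducible and independent
    of iteration order.
    """
    players = list(config.players)
    n = len(players)
    names = [p.name for p in players]
    k = config.repetitions

    counters = [BehaviorCounter() for _ in range(n)]
    rep_scores = np.full((n, k), np.nan)

    for rep in range(k):
        per_turn: List[List[float]] = [[] for _ in range(n)]
        for i in range(n):
            for j in range(i, n):
                if i == j and not config.self_play:
                    continue
                mc = MatchConfig(
                    turns=config.turns,
                    ending=config.ending,
                    noise=config.noise,
                    length_cap=config.length_cap,
                    seed=np.random.SeedSequence(
                        config.seed, spawn_key=(rep, i, j)
                    ),
                )
                res_i, res_j = play_match(
                    players[i].factory(), players[j].factory(), mc, payoffs
                )
                if i != j:
                    per_turn[i].append(res_i.per_turn_focal)
                    per_turn[j].append(res_j.per_turn_focal)
                    counters[i].add_match(res_i)
                    counters[j].add_match(res_j)
                    if res_i.total_focal > res_j.total_focal:
                        counters[i].wins += 1
                    elif res_j.total_focal > res_i.total_focal:
                        counters[j].wins += 1
                else:
                    if config.self_play_scores:
                        per_turn[i].append(
                            (res_i.per_turn_focal + res_j.per_turn_focal) / 2.0
                        )
                    if config.self_play_behavior:
                        counters[i].add_match(res_i)
                        counters[i].add_match(res_j)
        for i in range(n):
            rep_scores[i, rep] = float(np.mean(per_turn[i]))

    if config.rank_statistic == "median":
        scores = np.median(rep_scores, axis=1)
    else:
        scores = np.mean(rep_scores, axis=1)
    ranks = rank_rows(scores, names)

    rows = []
    for i in range(n):
        beh = counters[i].summary()
        rows.append(
            SummaryRow(
                rank=int(ranks[i]),
                name=names[i],
                median_score=float(scores[i]),
                **beh,
            )
        )
    rows.sort(key=lambda r: r.rank)
    return ResultSummary(
        rows=rows,
        repetitions=k,
        turns=config.turns,
        ending=config.ending,
        noise=config.noise,
        seed=config.seed,
    )
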