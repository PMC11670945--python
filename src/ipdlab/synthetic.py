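"""Synthetic feature tables with planted feature-rank relationships.

The generator emulates the schema and internal consistency of real feature
tables — tournament blocks with shared cooperation aggregates, ratios that
recompute from their parts, ranks consistent with the normalized-rank
ordering — while the relationship between features and the normalized rank
is a known linear model.  This lets every analysis-stage operation be tested
for parameter recovery without running tournaments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .features import (
    FEATURE_COLUMNS,
    cooperation_aggregates,
    cooperation_ratios,
)
from .experiment import TOURNAMENT_TYPES
from .tournament import ResultSummary, SummaryRow

__all__ = ["SyntheticSpec", "generate_feature_table", "generate_summary_fixture",
           "DEFAULT_COEFFICIENTS"]

# Planted model: moderate, sign-matched effects that keep the linear
# predictor inside [0, 1] for almost all draws (clipping < 1% of rows).
DEFAULT_COEFFICIENTS: Dict[str, float] = {
    "CC_to_C": -0.04,
    "CD_to_C": 0.12,
    "DC_to_C": 0.08,
    "SSE": 0.10,
    "Cr_over_Cmean": -0.08,
    "C_mean": -0.06,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic feature-table generator.

    Behavioral rates are drawn from Beta(beta_a, beta_b) (interior
    concentrated by default, avoiding degenerate 0/1 denominators); trial
    parameters come from the sampler's ranges.  ``coefficients`` and
    ``intercept`` define the planted linear map from features to the
    normalized rank, perturbed by Normal(0, sigma) noise and clipped to
    [0, 1].
    """

    tournaments_per_type: int = 50
    n_players: Tuple[int, int] = (3, 12)
    repetitions: Tuple[int, int] = (10, 100)
    turns: Tuple[int, int] = (1, 200)
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    intercept: float = 0.55
    sigma: float = 0.05
    beta_a: float = 2.0
    beta_b: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.tournaments_per_type < 1:
            raise ValueError("tournaments_per_type must be >= 1")


def generate_feature_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Generate a feature table with the planted feature-rank relationship.

    Within each synthetic tournament the cooperation aggregates are computed
    from the generated per-strategy cooperation ratings, so the ratio
    features are internally consistent, and integer ranks are assigned by
    ordering the planted normalized rank.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    trial = 0
    for ttype in TOURNAMENT_TYPES:
        fixed_length = "ending" not in ttype
        for _ in range(spec.tournaments_per_type):
            n_players = int(rng.integers(spec.n_players[0], spec.n_players[1] + 1))
            k = int(rng.integers(spec.repetitions[0], spec.repetitions[1] + 1))
            n = int(rng.integers(spec.turns[0], spec.turns[1] + 1))
            p_n = float(rng.uniform()) if "noisy" in ttype else 0.0
            p_e = 1.0 - float(rng.uniform(0.0, 1.0)) if not fixed_length else math.nan
            beta = (spec.beta_a, spec.beta_b)
            c_r = rng.beta(*beta, size=n_players)
            cond = rng.beta(*beta, size=(n_players, 4))
            sse = rng.beta(*beta, size=n_players)
            mem = rng.beta(*beta, size=n_players)
            aggregates = cooperation_aggregates(c_r)
            block = []
            for i in range(n_players):
                row = {
                    "trial": trial,
                    "tournament_type": ttype,
                    "strategy": f"synthetic-{i}",
                    "median_score": math.nan,
                    "cooperation_rating": float(c_r[i]),
                    "CC_to_C": float(cond[i, 0]),
                    "CD_to_C": float(cond[i, 1]),
                    "DC_to_C": float(cond[i, 2]),
                    "DD_to_C": float(cond[i, 3]),
                    **aggregates,
                    **cooperation_ratios(float(c_r[i]), aggregates),
                    "SSE": float(sse[i]),
                    "sse_imputed": False,
                    "memory_usage": float(mem[i]) if fixed_length else math.nan,
                    "stochastic": bool(rng.integers(0, 2)),
                    "makes_use_of_game": bool(rng.integers(0, 2)),
                    "makes_use_of_length": bool(rng.integers(0, 2)),
                    "N": n_players,
                    "k": k,
                    "n": n if fixed_length else math.nan,
                    "p_n": p_n,
                    "p_e": p_e,
                }
                predictor = spec.intercept
                for feature, coef in spec.coefficients.items():
                    predictor += coef * row[feature]
                noise = float(rng.normal(0.0, spec.sigma)) if spec.sigma > 0 else 0.0
                row["normalized_rank"] = float(np.clip(predictor + noise, 0.0, 1.0))
                block.append(row)
            order = np.argsort([r["normalized_rank"] for r in block], kind="stable")
            for rank, idx in enumerate(order):
                block[idx]["rank"] = int(rank)
            # Median score: monotone decreasing in rank, for target plumbing.
            for r in block:
                r["median_score"] = float(3.0 - 2.0 * r["normalized_rank"])
            rows.extend(block)
            trial += 1
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def generate_summary_fixture(n_players: int, seed: int = 0) -> ResultSummary:
    """A schema-valid, internally consistent synthetic result summary.

    State rates are Dirichlet draws (summing to one); the cooperation rating
    equals the focal-C state mass CC + CD; ranks follow descending median
    score.  Intended for reader/writer round-trip tests.
    """
    if n_players < 2:
        raise ValueError("need at least 2 players")
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.uniform(1.0, 3.0, size=n_players))[::-1]
    rows = []
    for rank in range(n_players):
        states = rng.dirichlet(np.ones(4))
        cond = rng.beta(2.0, 2.0, size=4)
        rows.append(
            SummaryRow(
                rank=rank,
                name=f"synthetic-{rank}",
                median_score=float(scores[rank]),
                cooperation_rating=float(states[0] + states[1]),
                wins=int(rng.integers(0, n_players)),
                initial_C=float(rng.beta(2.0, 2.0)),
                CC_rate=float(states[0]),
                CD_rate=float(states[1]),
                DC_rate=float(states[2]),
                DD_rate=float(states[3]),
                CC_to_C=float(cond[0]),
                CD_to_C=float(cond[1]),
                DC_to_C=float(cond[2]),
                DD_to_C=float(cond[3]),
            )
        )
    return ResultSummary(rows=rows, repetitions=1, turns=10, noise=0.0, seed=seed)
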