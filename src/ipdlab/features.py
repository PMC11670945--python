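"""Derived per-(trial, tournament, strategy) features.

Covers the normalized rank r = R/(N-1), tournament-level cooperation
aggregates and ratios, memory usage, and the least-squares distance (SSE)
between a strategy's observed memory-one behavior and the extortionate
zero-determinant family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .game import DEFAULT_PAYOFFS, PayoffMatrix
from .tournament import ResultSummary

__all__ = [
    "ZDFit",
    "normalized_rank",
    "median_normalized_rank",
    "cooperation_aggregates",
    "cooperation_ratios",
    "memory_usage",
    "zd_vector",
    "sse_to_zd",
    "feature_rows_for_summary",
    "build_feature_table",
    "FEATURE_COLUMNS",
    "write_feature_csv",
    "read_feature_csv",
]

FEATURE_COLUMNS = [
    "trial",
    "tournament_type",
    "strategy",
    "rank",
    "normalized_rank",
    "median_score",
    "cooperation_rating",
    "CC_to_C",
    "CD_to_C",
    "DC_to_C",
    "DD_to_C",
    "C_max",
    "C_min",
    "C_mean",
    "C_median",
    "Cr_over_Cmax",
    "Cmin_over_Cr",
    "Cr_over_Cmedian",
    "Cr_over_Cmean",
    "SSE",
    "sse_imputed",
    "memory_usage",
    "stochastic",
    "makes_use_of_game",
    "makes_use_of_length",
    "N",
    "k",
    "n",
    "p_n",
    "p_e",
]


def normalized_rank(rank: int, n_players: int) -> float:
    """r = R/(N-1): 0 for the winner, 1 for last place."""
    if n_players < 2:
        raise ValueError(f"need at least 2 players, got {n_players}")
    if not (0 <= rank <= n_players - 1):
        raise ValueError(f"rank {rank} out of range for N={n_players}")
    return rank / (n_players - 1)


def median_normalized_rank(values: Sequence[float]) -> float:
    """The median of a strategy's normalized ranks across tournaments."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median of an empty set of normalized ranks")
    return float(np.median(arr))


def cooperation_aggregates(coop_ratings: Sequence[float]) -> dict:
    """Tournament-level cooperation aggregates C_max, C_min, C_mean, C_median."""
    arr = np.asarray(list(coop_ratings), dtype=float)
    if arr.size == 0:
        raise ValueError("no cooperation ratings supplied")
    lo, hi = float(np.min(arr)), float(np.max(arr))
    return {
        "C_max": hi,
        "C_min": lo,
        # clip guards against 1-ulp summation error breaking min<=mean<=max
        "C_mean": float(min(max(np.mean(arr), lo), hi)),
        "C_median": float(np.median(arr)),
    }


def _safe_ratio(num: float, den: float) -> float:
    if den == 0 or math.isnan(den) or math.isnan(num):
        return math.nan
    return num / den


def cooperation_ratios(coop_rating: float, aggregates: Mapping[str, float]) -> dict:
    """Per-strategy ratios against the tournament aggregates.

    Ratios with a zero denominator are reported missing (NaN).
    """
    return {
        "Cr_over_Cmax": _safe_ratio(coop_rating, aggregates["C_max"]),
        "Cmin_over_Cr": _safe_ratio(aggregates["C_min"], coop_rating),
        "Cr_over_Cmedian": _safe_ratio(coop_rating, aggregates["C_median"]),
        "Cr_over_Cmean": _safe_ratio(coop_rating, aggregates["C_mean"]),
    }


def memory_usage(memory_size: float, turns: Optional[int]) -> float:
    """min(memory size / n, 1); 1 for infinite memory; undefined without n."""
    if turns is None:
        return math.nan
    if turns < 1:
        raise ValueError(f"turns must be >= 1, got {turns}")
    if math.isinf(memory_size):
        return 1.0
    return min(memory_size / turns, 1.0)


@dataclass(frozen=True)
class ZDFit:
    """Result of projecting a memory-one vector onto the ZD family.

    ``p`` is the cooperation vector (p_CC, p_CD, p_DC, p_DD); ``p_tilde`` its
    tilde transform (p_CC-1, p_CD-1, p_DC, p_DD).  The fitted model is
    a*(S_x - P) - b*(S_y - P) with a = phi and b = phi*chi; ``sse`` is the
    residual sum of squares and ``sse_clipped`` = min(sse, 1).
    """

    p: tuple
    p_tilde: tuple
    a: float
    b: float
    phi: float
    chi: float
    sse: float

    @property
    def sse_clipped(self) -> float:
        return min(self.sse, 1.0)


def _zd_design(payoffs: PayoffMatrix):
    s_x = np.array([payoffs.R, payoffs.S, payoffs.T, payoffs.P])
    s_y = np.array([payoffs.R, payoffs.T, payoffs.S, payoffs.P])
    u = s_x - payoffs.P
    v = s_y - payoffs.P
    return u, v


def zd_vector(phi: float, chi: float, payoffs: PayoffMatrix = DEFAULT_PAYOFFS) -> np.ndarray:
    """Memory-one cooperation vector of the extortionate ZD with (phi, chi).

    p_tilde = phi * ((S_x - P) - chi * (S_y - P)); the cooperation vector is
    p_tilde + (1, 1, 0, 0).  Raises if the parameters do not give valid
    probabilities.
    """
    u, v = _zd_design(payoffs)
    p_tilde = phi * (u - chi * v)
    p = p_tilde + np.array([1.0, 1.0, 0.0, 0.0])
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise ValueError(
            f"(phi={phi}, chi={chi}) does not define a valid probability vector: {p}"
        )
    return np.clip(p, 0.0, 1.0)


def sse_to_zd(
    p: Sequence[float],
    payoffs: PayoffMatrix = DEFAULT_PAYOFFS,
    constrained: bool = True,
) -> ZDFit:
    """Least-squares distance of a memory-one vector from the ZD family.

    Solves min ||a*u - b*v - p_tilde||^2 with u = S_x - P, v = S_y - P.
    With ``constrained=True`` (default) the coefficients are restricted to
    a, b >= 0, which confines the fit to the extortionate branch of the
    family; the unconstrained ordinary least squares fit is also available.
    An SSE of 0 means the strategy's memory-one shadow is exactly ZD.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (4,):
        raise ValueError("p must be a 4-vector (p_CC, p_CD, p_DC, p_DD)")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"p components must be in [0, 1], got {p}")
    p_tilde = np.array([p[0] - 1.0, p[1] - 1.0, p[2], p[3]])
    u, v = _zd_design(payoffs)
    A = np.column_stack([u, -v])
    if constrained:
        x, rnorm = nnls(A, p_tilde)
        sse = float(rnorm**2)
    else:
        x, _, _, _ = np.linalg.lstsq(A, p_tilde, rcond=None)
        sse = float(np.sum((A @ x - p_tilde) ** 2))
    a, b = float(x[0]), float(x[1])
    chi = b / a if a > 0 else math.nan
    return ZDFit(
        p=tuple(p),
        p_tilde=tuple(p_tilde),
        a=a,
        b=b,
        phi=a,
        chi=chi,
        sse=sse,
    )


def _row_sse(row, payoffs: PayoffMatrix, impute: float = 0.5):
    """SSE from a summary row's conditional cooperation rates.

    Unvisited states have missing conditional rates; they are imputed with a
    neutral 0.5 and the row is flagged.
    """
    rates = [row.CC_to_C, row.CD_to_C, row.DC_to_C, row.DD_to_C]
    imputed = any(math.isnan(r) for r in rates)
    p = [impute if math.isnan(r) else r for r in rates]
    fit = sse_to_zd(p, payoffs)
    return fit.sse, imputed


def feature_rows_for_summary(
    summary: ResultSummary,
    tournament_type: str,
    trial_meta: Mapping,
    classifiers: Mapping[str, Mapping],
    payoffs: PayoffMatrix = DEFAULT_PAYOFFS,
) -> list:
    """Feature rows (dicts) for one tournament's result summary.

    ``trial_meta`` supplies trial, N, k, n, p_n, p_e; ``classifiers`` maps
    strategy name to its classifier record.  Match length n (and hence
    memory usage) is undefined for probabilistic-ending tournaments.
    """
    aggregates = cooperation_aggregates([r.cooperation_rating for r in summary.rows])
    n_players = summary.n_players
    turns = trial_meta.get("n") if "ending" not in tournament_type else None
    if summary.turns is not None:
        turns = summary.turns
    rows = []
    for r in summary.rows:
        cls = classifiers[r.name]
        sse, imputed = _row_sse(r, payoffs)
        rows.append(
            {
                "trial": trial_meta.get("trial"),
                "tournament_type": tournament_type,
                "strategy": r.name,
                "rank": r.rank,
                "normalized_rank": normalized_rank(r.rank, n_players),
                "median_score": r.median_score,
                "cooperation_rating": r.cooperation_rating,
                "CC_to_C": r.CC_to_C,
                "CD_to_C": r.CD_to_C,
                "DC_to_C": r.DC_to_C,
                "DD_to_C": r.DD_to_C,
                **aggregates,
                **cooperation_ratios(r.cooperation_rating, aggregates),
                "SSE": sse,
                "sse_imputed": imputed,
                "memory_usage": memory_usage(cls["memory_size"], turns),
                "stochastic": cls["stochastic"],
                "makes_use_of_game": cls["makes_use_of_game"],
                "makes_use_of_length": cls["makes_use_of_length"],
                "N": n_players,
                "k": summary.repetitions,
                "n": turns if turns is not None else math.nan,
                "p_n": summary.noise,
                "p_e": summary.ending if summary.ending is not None else math.nan,
            }
        )
    return rows


def build_feature_table(
    trials: Iterable,
    classifiers: Mapping[str, Mapping],
    payoffs: PayoffMatrix = DEFAULT_PAYOFFS,
) -> pd.DataFrame:
    """Feature table over an iterable of trial records.

    Each trial record must expose ``config`` (with seed/trial metadata) and
    ``summaries`` (mapping tournament type -> :class:`ResultSummary`).
    """
    rows = []
    for record in trials:
        cfg = record.config
        meta = {
            "trial": cfg.trial,
            "n": cfg.turns,
            "k": cfg.repetitions,
            "p_n": cfg.noise,
            "p_e": cfg.ending,
        }
        for ttype, summary in record.summaries.items():
            rows.extend(
                feature_rows_for_summary(summary, ttype, meta, classifiers, payoffs)
            )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def write_feature_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=FEATURE_COLUMNS)


def read_feature_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
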