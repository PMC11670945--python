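"""Statistical layer: feature correlations, rank regressions, winner profiles.

Given a feature table (one row per trial x tournament type x strategy) this
module computes, per tournament type: Spearman rank correlations of each
feature with the normalized rank and the median score; a multivariate
ordinary-least-squares regression of the normalized rank on a per-type
feature list; and the distributions of the winners' (rank-0) features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .experiment import TOURNAMENT_TYPES

__all__ = [
    "CORRELATION_FEATURES",
    "FEATURE_AVAILABILITY",
    "REGRESSION_FEATURES",
    "WINNER_FEATURES",
    "RegressionResult",
    "correlate_features",
    "fit_rank_regression",
    "winner_profiles",
    "write_analysis",
]

TARGETS = ("normalized_rank", "median_score")

CORRELATION_FEATURES = [
    "CC_to_C",
    "CD_to_C",
    "DC_to_C",
    "DD_to_C",
    "cooperation_rating",
    "C_max",
    "C_min",
    "C_median",
    "C_mean",
    "Cr_over_Cmax",
    "Cmin_over_Cr",
    "Cr_over_Cmedian",
    "Cr_over_Cmean",
    "N",
    "k",
    "n",
    "p_n",
    "p_e",
    "makes_use_of_game",
    "makes_use_of_length",
    "SSE",
    "stochastic",
    "memory_usage",
]

# Features that are undefined (or structurally constant) for some tournament
# types: n and memory usage require a known match length; p_n varies only in
# noisy types; p_e only in probabilistic-ending types.
FEATURE_AVAILABILITY = {
    "n": {"standard", "noisy"},
    "memory_usage": {"standard", "noisy"},
    "p_n": {"noisy", "noisy_probabilistic_ending"},
    "p_e": {"probabilistic_ending", "noisy_probabilistic_ending"},
}

_COMMON_REGRESSORS = [
    "CC_to_C",
    "CD_to_C",
    "DC_to_C",
    "SSE",
    "C_max",
    "C_min",
    "C_mean",
    "Cmin_over_Cr",
    "Cr_over_Cmean",
    "k",
]

# Per-type regressor lists for the rank regression (collinearity-pruned).
REGRESSION_FEATURES: Dict[str, List[str]] = {
    "standard": _COMMON_REGRESSORS + ["n", "memory_usage"],
    "noisy": _COMMON_REGRESSORS + ["memory_usage", "Cr_over_Cmedian", "p_n"],
    "probabilistic_ending": _COMMON_REGRESSORS + ["Cr_over_Cmedian", "p_e"],
    "noisy_probabilistic_ending": _COMMON_REGRESSORS + ["p_n", "p_e"],
}

WINNER_FEATURES = [
    "cooperation_rating",
    "Cr_over_Cmean",
    "SSE",
    "CC_to_C",
    "CD_to_C",
    "DC_to_C",
    "DD_to_C",
]


def _available(feature: str, ttype: str) -> bool:
    allowed = FEATURE_AVAILABILITY.get(feature)
    return allowed is None or ttype in allowed


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation with pairwise deletion; NaN if degenerate."""
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 3:
        return math.nan
    xv, yv = x[mask], y[mask]
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        return math.nan
    rho, _ = stats.spearmanr(xv, yv)
    return float(rho)


def correlate_features(
    table: pd.DataFrame,
    features: Optional[Sequence[str]] = None,
    targets: Sequence[str] = TARGETS,
) -> pd.DataFrame:
    """Spearman correlation of each feature with each target, per type.

    Returns a tidy frame (tournament_type, feature, target, spearman); pairs
    unavailable for a type are omitted, mirroring the study's dashes.
    Constant features yield a missing coefficient.
    """
    features = list(features) if features is not None else CORRELATION_FEATURES
    out = []
    for ttype, group in table.groupby("tournament_type", sort=False):
        if len(group) < 3:
            raise ValueError(f"need at least 3 rows per type, got {len(group)} for {ttype}")
        for feature in features:
            if not _available(feature, ttype):
                continue
            x = group[feature].to_numpy(dtype=float)
            for target in targets:
                y = group[target].to_numpy(dtype=float)
                out.append(
                    {
                        "tournament_type": ttype,
                        "feature": feature,
                        "target": target,
                        "spearman": _spearman(x, y),
                    }
                )
    return pd.DataFrame(out, columns=["tournament_type", "feature", "target", "spearman"])


@dataclass
class RegressionResult:
    """OLS fit of a target on a feature list, for one tournament type."""

    tournament_type: str
    target: str
    features: List[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    rsquared_adj: float
    nobs: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"coefficient": self.params, "p_value": self.pvalues}
        )
        df.insert(0, "tournament_type", self.tournament_type)
        df["rsquared_adj"] = self.rsquared_adj
        df["nobs"] = self.nobs
        return df.reset_index(names="feature")


def _collinear_columns(X: pd.DataFrame) -> List[str]:
    _, r = np.linalg.qr(X.to_numpy(dtype=float))
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.max() > 0 else 1.0
    return [c for c, d in zip(X.columns, diag) if d < 1e-10 * scale]


def fit_rank_regression(
    table: pd.DataFrame,
    target: str = "normalized_rank",
    feature_lists: Optional[Mapping[str, Sequence[str]]] = None,
) -> Dict[str, RegressionResult]:
    """Multivariate OLS of ``target`` on the per-type feature lists.

    Rows with any missing regressor are dropped.  A rank-deficient design
    raises, naming the collinear columns.
    """
    feature_lists = feature_lists if feature_lists is not None else REGRESSION_FEATURES
    results = {}
    for ttype, group in table.groupby("tournament_type", sort=False):
        if ttype not in feature_lists:
            continue
        features = list(feature_lists[ttype])
        cols = group[features + [target]].astype(float).dropna()
        if len(cols) < len(features) + 2:
            raise ValueError(
                f"{ttype}: need at least {len(features) + 2} complete rows, "
                f"got {len(cols)}"
            )
        X = sm.add_constant(cols[features], has_constant="add")
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            bad = _collinear_columns(X)
            raise ValueError(
                f"{ttype}: design matrix is rank deficient; collinear columns: {bad}"
            )
        fit = sm.OLS(cols[target], X).fit()
        rename = {"const": "constant"}
        results[ttype] = RegressionResult(
            tournament_type=ttype,
            target=target,
            features=features,
            params=fit.params.rename(index=rename),
            bse=fit.bse.rename(index=rename),
            pvalues=fit.pvalues.rename(index=rename),
            conf_int=fit.conf_int(alpha=0.05).rename(index=rename),
            rsquared_adj=float(fit.rsquared_adj),
            nobs=int(fit.nobs),
        )
    return results


def winner_profiles(
    table: pd.DataFrame, features: Sequence[str] = WINNER_FEATURES
) -> pd.DataFrame:
    """Distribution summaries of the winners' features, per tournament type.

    Winners are the rank-0 rows.  Returns one row per (type, feature) with
    count, mean, median and quartiles over the winners that have the feature.
    """
    winners = table[table["rank"] == 0]
    out = []
    for ttype, group in winners.groupby("tournament_type", sort=False):
        for feature in features:
            values = group[feature].to_numpy(dtype=float)
            values = values[~np.isnan(values)]
            row = {
                "tournament_type": ttype,
                "feature": feature,
                "count": int(values.size),
            }
            if values.size:
                row.update(
                    mean=float(np.mean(values)),
                    median=float(np.median(values)),
                    q25=float(np.percentile(values, 25)),
                    q75=float(np.percentile(values, 75)),
                    min=float(np.min(values)),
                    max=float(np.max(values)),
                )
            else:
                row.update(mean=math.nan, median=math.nan, q25=math.nan,
                           q75=math.nan, min=math.nan, max=math.nan)
            out.append(row)
    return pd.DataFrame(out)


def write_analysis(
    table: pd.DataFrame,
    out_dir,
    target: str = "normalized_rank",
) -> Dict[str, Path]:
    """Run the full analysis stage and write its three CSV outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    corr = correlate_features(table)
    paths["correlations"] = out / "correlations.csv"
    corr.to_csv(paths["correlations"], index=False)
    reg = fit_rank_regression(table, target=target)
    reg_frame = pd.concat([r.to_frame() for r in reg.values()], ignore_index=True)
    paths["regression"] = out / "regression.csv"
    reg_frame.to_csv(paths["regression"], index=False)
    winners = winner_profiles(table)
    paths["winners"] = out / "winners.csv"
    winners.to_csv(paths["winners"], index=False)
    return paths
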