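"""Correlation, regression and winner-profile analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ipdlab.analysis import (
    FEATURE_AVAILABILITY,
    REGRESSION_FEATURES,
    correlate_features,
    fit_rank_regression,
    winner_profiles,
    write_analysis,
)
from ipdlab.synthetic import SyntheticSpec, generate_feature_table


def brute_force_spearman(x, y):
    """Rank-transform (average ranks for ties) then Pearson."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _minimal_table(feature_values, r_values, ttype="standard"):
    return pd.DataFrame(
        {
            "tournament_type": ttype,
            "f": feature_values,
            "normalized_rank": r_values,
            "median_score": [3 - 2 * r for r in r_values],
        }
    )


def test_identity_and_negation_correlations():
    r = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
    table = _minimal_table(r, r)
    out = correlate_features(table, features=["f"])
    rho = out[out["target"] == "normalized_rank"]["spearman"].iloc[0]
    assert rho == pytest.approx(1.0)

    table_neg = _minimal_table([-v for v in r], r)
    out_neg = correlate_features(table_neg, features=["f"])
    rho_neg = out_neg[out_neg["target"] == "normalized_rank"]["spearman"].iloc[0]
    assert rho_neg == pytest.approx(-1.0)


def test_constant_feature_reports_missing():
    table = _minimal_table([0.5] * 6, [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    out = correlate_features(table, features=["f"])
    assert out["spearman"].isna().all()


def test_spearman_equals_brute_force_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(10, 60))
        x = rng.integers(0, 8, size=n).astype(float)  # ties on purpose
        y = rng.normal(size=n)
        table = _minimal_table(x, y)
        out = correlate_features(table, features=["f"])
        rho = out[out["target"] == "normalized_rank"]["spearman"].iloc[0]
        assert rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)


def test_unavailable_features_are_omitted_per_type():
    spec = SyntheticSpec(tournaments_per_type=4, seed=0)
    table = generate_feature_table(spec)
    out = correlate_features(table)
    for feature, allowed in FEATURE_AVAILABILITY.items():
        present = set(out[out["feature"] == feature]["tournament_type"])
        assert present == allowed


def test_planted_monotone_feature_recovered():
    spec = SyntheticSpec(
        tournaments_per_type=120,
        coefficients={"SSE": 0.25},
        sigma=0.02,
        seed=1,
    )
    table = generate_feature_table(spec)
    out = correlate_features(table, features=["SSE", "DD_to_C"])
    sse_rho = out[
        (out["feature"] == "SSE") & (out["target"] == "normalized_rank")
    ]["spearman"]
    assert (sse_rho > 0.5).all()  # planted positive link, clear signal
    null_rho = out[
        (out["feature"] == "DD_to_C") & (out["target"] == "normalized_rank")
    ]["spearman"]
    assert (null_rho.abs() < 0.15).all()  # no planted link


def test_noiseless_regression_recovers_coefficients_exactly():
    spec = SyntheticSpec(tournaments_per_type=30, sigma=0.0, seed=2)
    table = generate_feature_table(spec)
    lists = {t: list(spec.coefficients) for t in table["tournament_type"].unique()}
    results = fit_rank_regression(table, feature_lists=lists)
    for res in results.values():
        assert res.params["constant"] == pytest.approx(spec.intercept, abs=1e-8)
        for feature, beta in spec.coefficients.items():
            assert res.params[feature] == pytest.approx(beta, abs=1e-8)
        assert res.rsquared_adj == pytest.approx(1.0, abs=1e-8)


def test_regression_residuals_orthogonal_to_design():
    spec = SyntheticSpec(tournaments_per_type=40, sigma=0.05, seed=3)
    table = generate_feature_table(spec)
    results = fit_rank_regression(table)
    for ttype, res in results.items():
        group = table[table["tournament_type"] == ttype]
        cols = group[res.features + ["normalized_rank"]].astype(float).dropna()
        X = np.column_stack([np.ones(len(cols)), cols[res.features].to_numpy()])
        beta = np.concatenate(
            [[res.params["constant"]], [res.params[f] for f in res.features]]
        )
        resid = cols["normalized_rank"].to_numpy() - X @ beta
        assert np.max(np.abs(X.T @ resid)) < 1e-8 * len(cols)


def test_duplicated_feature_raises_naming_collinear_column():
    spec = SyntheticSpec(tournaments_per_type=10, seed=4)
    table = generate_feature_table(spec)
    table["SSE_copy"] = table["SSE"]
    lists = {"standard": ["SSE", "SSE_copy"]}
    with pytest.raises(ValueError, match="rank deficient"):
        fit_rank_regression(table, feature_lists=lists)


def test_default_feature_lists_follow_type_availability():
    for ttype, features in REGRESSION_FEATURES.items():
        for feature, allowed in FEATURE_AVAILABILITY.items():
            if feature in features:
                assert ttype in allowed


def test_winner_profiles_counts_and_medians():
    spec = SyntheticSpec(tournaments_per_type=25, seed=5)
    table = generate_feature_table(spec)
    profiles = winner_profiles(table)
    for ttype, group in profiles.groupby("tournament_type"):
        # one winner per synthetic tournament
        assert (group["count"] == 25).all()

    # A table whose winners all sit exactly at the mean cooperation level.
    tiny = pd.DataFrame(
        {
            "tournament_type": ["standard"] * 4,
            "rank": [0, 1, 0, 1],
            "Cr_over_Cmean": [1.0, 0.4, 1.0, 1.7],
        }
    )
    out = winner_profiles(tiny, features=["Cr_over_Cmean"])
    assert out["median"].iloc[0] == pytest.approx(1.0)
    assert out["count"].iloc[0] == 2


def test_write_analysis_outputs(tmp_path):
    spec = SyntheticSpec(tournaments_per_type=25, seed=6)
    table = generate_feature_table(spec)
    paths = write_analysis(table, tmp_path)
    for key in ("correlations", "regression", "winners"):
        assert paths[key].exists()
    reg = pd.read_csv(paths["regression"])
    assert set(reg["tournament_type"]) == set(REGRESSION_FEATURES)
    assert "constant" in set(reg["feature"])
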