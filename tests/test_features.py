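"""Derived features: normalized rank, aggregates, memory usage, SSE-to-ZD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipdlab.features import (
    cooperation_aggregates,
    cooperation_ratios,
    feature_rows_for_summary,
    median_normalized_rank,
    memory_usage,
    normalized_rank,
    sse_to_zd,
    zd_vector,
)
from ipdlab.game import DEFAULT_PAYOFFS
from ipdlab.synthetic import generate_summary_fixture


def grid_search_sse(p, payoffs=DEFAULT_PAYOFFS):
    """Independent SSE oracle: exhaustive grid over (a, b) with refinement.

    Coarse grid at step 0.01 over [0, 5]^2, then a fine grid at step 1e-4 in
    a window around the coarse optimum (valid because the objective is a
    convex quadratic in (a, b)).
    """
    p = np.asarray(p, dtype=float)
    p_tilde = np.array([p[0] - 1.0, p[1] - 1.0, p[2], p[3]])
    u = np.array([payoffs.R, payoffs.S, payoffs.T, payoffs.P]) - payoffs.P
    v = np.array([payoffs.R, payoffs.T, payoffs.S, payoffs.P]) - payoffs.P

    def objective(a, b):
        resid = (
            a[..., None] * u - b[..., None] * v - p_tilde
        )
        return np.sum(resid**2, axis=-1)

    def best_on(avals, bvals):
        A, B = np.meshgrid(avals, bvals, indexing="ij")
        vals = objective(A, B)
        idx = np.unravel_index(np.argmin(vals), vals.shape)
        return avals[idx[0]], bvals[idx[1]], vals[idx]

    a0, b0, _ = best_on(np.arange(0, 5.0001, 0.01), np.arange(0, 5.0001, 0.01))
    fine_a = np.arange(max(a0 - 0.02, 0.0), a0 + 0.02, 1e-4)
    fine_b = np.arange(max(b0 - 0.02, 0.0), b0 + 0.02, 1e-4)
    _, _, best = best_on(fine_a, fine_b)
    return float(best)


@pytest.mark.parametrize(
    "rank,n,expected", [(0, 5, 0.0), (4, 5, 1.0), (1, 3, 0.5), (0, 2, 0.0)]
)
def test_normalized_rank_values(rank, n, expected):
    assert normalized_rank(rank, n) == expected


def test_normalized_rank_errors():
    with pytest.raises(ValueError):
        normalized_rank(0, 1)
    with pytest.raises(ValueError):
        normalized_rank(5, 5)


def test_median_normalized_rank():
    assert median_normalized_rank([0, 0, 0]) == 0.0
    assert median_normalized_rank([0, 0.5, 1]) == 0.5
    with pytest.raises(ValueError):
        median_normalized_rank([])


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_aggregate_ordering_invariant(values):
    agg = cooperation_aggregates(values)
    assert agg["C_min"] <= agg["C_mean"] <= agg["C_max"]
    assert agg["C_min"] <= agg["C_median"] <= agg["C_max"]


def test_ratios_unit_when_all_equal_and_missing_on_zero():
    agg = cooperation_aggregates([0.6, 0.6, 0.6])
    ratios = cooperation_ratios(0.6, agg)
    assert all(v == pytest.approx(1.0) for v in ratios.values())

    agg0 = cooperation_aggregates([0.0, 0.5])
    ratios0 = cooperation_ratios(0.0, agg0)
    assert math.isnan(ratios0["Cmin_over_Cr"])  # zero denominator -> missing


@pytest.mark.parametrize(
    "memory,n,expected",
    [(2, 100, 0.02), (math.inf, 7, 1.0), (5, 2, 1.0), (0, 10, 0.0)],
)
def test_memory_usage(memory, n, expected):
    assert memory_usage(memory, n) == expected


def test_memory_usage_undefined_without_length():
    assert math.isnan(memory_usage(2, None))
    with pytest.raises(ValueError):
        memory_usage(2, 0)


def test_tft_vector_lies_exactly_in_zd_family():
    fit = sse_to_zd([1, 0, 1, 0])
    assert fit.sse == pytest.approx(0.0, abs=1e-12)
    assert fit.a == pytest.approx(0.2) and fit.b == pytest.approx(0.2)


def test_constructed_extortionate_vector_has_zero_sse():
    p = zd_vector(0.1, 2.0)
    fit = sse_to_zd(p)
    assert fit.sse == pytest.approx(0.0, abs=1e-12)
    assert fit.phi == pytest.approx(0.1, abs=1e-6)
    assert fit.chi == pytest.approx(2.0, abs=1e-6)


def test_unconditional_cooperator_is_far_from_zd():
    # p_tilde's fourth component is 1 while both design vectors vanish there.
    assert sse_to_zd([1, 1, 1, 1]).sse >= 1.0


def test_zd_parameter_recovery():
    """Any valid (phi, chi) member is recovered with SSE ~ 0."""
    rng = np.random.default_rng(0)
    found = 0
    while found < 20:
        phi = rng.uniform(0.01, 0.25)
        chi = rng.uniform(1.0, 4.0)
        try:
            p = zd_vector(phi, chi)
        except ValueError:
            continue
        found += 1
        fit = sse_to_zd(p)
        assert fit.sse < 1e-12
        assert fit.phi == pytest.approx(phi, abs=1e-6)
        assert fit.chi == pytest.approx(chi, abs=1e-6)


def test_sse_matches_grid_search_oracle():
    rng = np.random.default_rng(7)
    for _ in range(25):
        p = rng.uniform(0, 1, size=4)
        fit = sse_to_zd(p)
        oracle = grid_search_sse(p)
        assert fit.sse <= oracle + 1e-12  # exact solver can only do better
        assert abs(fit.sse - oracle) < 1e-4


def test_unconstrained_fit_never_worse():
    rng = np.random.default_rng(3)
    for _ in range(20):
        p = rng.uniform(0, 1, size=4)
        assert (
            sse_to_zd(p, constrained=False).sse
            <= sse_to_zd(p, constrained=True).sse + 1e-12
        )


def test_sse_input_validation():
    with pytest.raises(ValueError):
        sse_to_zd([1.5, 0, 0, 0])
    with pytest.raises(ValueError):
        sse_to_zd([0.5, 0.5])


def test_feature_rows_from_summary():
    summary = generate_summary_fixture(4, seed=1)
    classifiers = {
        f"synthetic-{i}": {
            "stochastic": False,
            "makes_use_of_game": False,
            "makes_use_of_length": False,
            "memory_size": 2,
        }
        for i in range(4)
    }
    meta = {"trial": 0, "n": 10, "k": 1, "p_n": 0.0, "p_e": 0.1}
    rows = feature_rows_for_summary(summary, "standard", meta, classifiers)
    assert len(rows) == 4
    ranks = sorted(r["rank"] for r in rows)
    assert ranks == [0, 1, 2, 3]
    for r in rows:
        assert r["normalized_rank"] == pytest.approx(r["rank"] / 3)
        assert r["memory_usage"] == pytest.approx(0.2)
        assert r["SSE"] >= 0
        assert not r["sse_imputed"]

    # Probabilistic ending: the match length is unknown, memory usage missing.
    summary_pe = generate_summary_fixture(4, seed=2)
    summary_pe.turns = None
    summary_pe.ending = 0.1
    rows_pe = feature_rows_for_summary(
        summary_pe, "probabilistic_ending", meta, classifiers
    )
    assert all(math.isnan(r["memory_usage"]) for r in rows_pe)
    assert all(math.isnan(r["n"]) for r in rows_pe)
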