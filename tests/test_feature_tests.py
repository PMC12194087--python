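"""DFT/RFT partition losses, rankings and top-K intersections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_dft, brute_rft
from greenrad.feature_tests import (
    PartitionGrid,
    dft_loss,
    intersect_top_k,
    rank_features,
    rft_loss,
)

EXH = PartitionGrid(mode="exhaustive")


def test_rft_zero_loss_for_piecewise_constant_target():
    res = rft_loss([1, 2, 3, 10, 11, 12], [0.1, 0.1, 0.1, 0.5, 0.5, 0.5], EXH)
    assert res.loss == pytest.approx(0.0, abs=1e-15)
    assert 3 < res.threshold < 10


def test_rft_constant_target_gives_zero_loss():
    res = rft_loss([1.0, 2, 3, 4], [0.2, 0.2, 0.2, 0.2], EXH)
    assert res.loss == pytest.approx(0.0, abs=1e-15)


def test_rft_constant_feature_falls_back_to_population_std():
    y = np.array([0.1, 0.4, 0.2, 0.9])
    res = rft_loss([1.0, 1, 1, 1], y, EXH)
    assert res.degenerate
    assert res.loss == pytest.approx(float(np.std(y)))
    assert np.isnan(res.threshold)


def test_rft_matches_brute_force_on_alternating_target():
    grid = PartitionGrid(min_segment=1, mode="exhaustive")
    res = rft_loss([1.0, 2, 3, 4], [0.0, 1, 0, 1], grid)
    assert res.loss == pytest.approx(brute_rft([1, 2, 3, 4], [0, 1, 0, 1], 1), abs=1e-12)


def test_dft_zero_loss_for_pure_segments():
    grid = PartitionGrid(min_segment=2, mode="exhaustive")
    res = dft_loss([0.0, 1, 2, 3], [0, 0, 1, 1], grid)
    assert res.loss == pytest.approx(0.0, abs=1e-15)
    assert 1 < res.threshold < 2


def test_dft_single_class_degenerate_zero_loss():
    res = dft_loss([1.0, 2, 3, 4], [0, 0, 0, 0], EXH)
    assert res.loss == 0.0 and res.degenerate


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.integers(0, 10_000), st.integers(8, 50))
def test_exhaustive_losses_equal_brute_force(seed, n):
    """Exhaustive-mode DFT/RFT equals independent split enumeration."""
    rng = np.random.default_rng(seed)
    x = np.round(rng.normal(size=n), 2)  # rounding forces ties
    y = rng.uniform(size=n)
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    assert rft_loss(x, y, EXH).loss == pytest.approx(brute_rft(x, y), abs=1e-12)
    assert dft_loss(x, labels, EXH).loss == pytest.approx(brute_dft(x, labels), abs=1e-12)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_two_segment_fit_never_worse_than_single_segment(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=40)
    y = rng.uniform(size=40)
    labels = rng.integers(0, 2, size=40)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    assert rft_loss(x, y, EXH).loss <= float(np.std(y)) + 1e-12
    p = labels.mean()
    full_entropy = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
    assert dft_loss(x, labels, EXH).loss <= full_entropy + 1e-12


def test_refining_the_grid_never_increases_loss():
    rng = np.random.default_rng(11)
    x = rng.normal(size=60)
    y = rng.uniform(size=60)
    coarse = rft_loss(x, y, PartitionGrid(n_candidates=7)).loss
    fine = rft_loss(x, y, PartitionGrid(n_candidates=31)).loss  # superset grid? no --
    exhaustive = rft_loss(x, y, EXH).loss
    # exhaustive search dominates any candidate grid
    assert exhaustive <= coarse + 1e-12
    assert exhaustive <= fine + 1e-12
    # a uniform grid that is an exact superset cannot be worse
    nested = rft_loss(x, y, PartitionGrid(n_candidates=15)).loss  # 15+2 pts include 7+2 pts
    assert nested <= coarse + 1e-12


def test_length_mismatch_and_bad_labels_error():
    with pytest.raises(ValueError):
        rft_loss([1.0, 2], [1.0, 2, 3], EXH)
    with pytest.raises(ValueError):
        dft_loss([1.0, 2, 3], [0, 1, 2], EXH)


def test_ranking_puts_perfect_separator_first():
    rng = np.random.default_rng(0)
    n = 40
    labels = np.array([0] * 20 + [1] * 20)
    table = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"n{i}" for i in range(10)])
    table["sep"] = labels * 10.0 + rng.normal(scale=0.01, size=n)
    r = rank_features(table, labels, "dft", EXH)
    assert r.order[0] == "sep"


def test_duplicated_column_gets_adjacent_ranks_in_column_order(tiny_table):
    t = tiny_table.copy()
    t["f0_dup"] = t["f0"]
    y = np.random.default_rng(1).uniform(size=len(t))
    r = rank_features(t, y, "rft", EXH)
    order = r.order
    assert order.index("f0_dup") == order.index("f0") + 1


def test_per_feature_losses_are_columnwise_local(tiny_table):
    y = np.random.default_rng(2).uniform(size=len(tiny_table))
    full = rank_features(tiny_table, y, "rft", EXH)
    solo = rank_features(tiny_table[["f3"]], y, "rft", EXH)
    assert full.loss_of()["f3"] == pytest.approx(solo.loss_of()["f3"], abs=1e-15)


def test_planted_informative_features_rank_highly():
    from greenrad.cohort import planted_spec, simulate_cohort

    spec = planted_spec("regression", seed=4, n_samples=150, n_features=200,
                        n_blocks=20, informative_indices=tuple(range(20)))
    table, y = simulate_cohort(spec)
    r = rank_features(table, y, "rft", PartitionGrid())
    top = set(r.top_k(50))
    info = {table.columns[i] for i in spec.informative()}
    assert len(info & top) >= 18


def test_intersection_identity_reversed_and_oracle():
    names = [f"f{i}" for i in range(10)]
    rng = np.random.default_rng(9)
    t = pd.DataFrame(rng.normal(size=(25, 10)), columns=names)
    y = rng.uniform(size=25)
    r1 = rank_features(t, y, "rft", EXH)
    # identical rankings, K=3 -> the top-3 set itself
    ident = intersect_top_k(r1, r1, 3)
    assert set(ident.features) == set(r1.top_k(3)) and len(ident) == 3
    # a second independent ranking: intersection equals the set oracle
    y2 = rng.uniform(size=25)
    r2 = rank_features(t, y2, "rft", EXH)
    for K in (1, 4, 7, 10):
        inter = intersect_top_k(r1, r2, K)
        assert set(inter.features) == set(r1.top_k(K)) & set(r2.top_k(K))
        assert list(inter.ordered) == [f for f in r1.order[:K] if f in inter.features]
    with pytest.raises(ValueError):
        intersect_top_k(r1, r2, 11)


def test_exactly_reversed_rankings_have_empty_intersection():
    from greenrad.feature_tests import LossRanking

    names = tuple(f"f{i}" for i in range(10))
    loss = np.arange(10, dtype=float)
    fwd = LossRanking(names, loss, np.zeros(10), "rft")
    rev = LossRanking(names, loss[::-1].copy(), np.zeros(10), "rft")
    assert len(intersect_top_k(fwd, rev, 5)) == 0
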