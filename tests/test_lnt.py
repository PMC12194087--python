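"""Least-squares normal transform: grouping, fitting, application."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from greenrad.feature_tests import PartitionGrid, rank_features
from greenrad.lnt import (
    apply_complementary,
    apply_lnt,
    assign_subgroups,
    fit_lnt,
    generate_complementary,
)


def test_strided_grouping_examples():
    assert [list(g) for g in assign_subgroups("123456", stride_s=2).groups] == [
        ["1", "3", "5"], ["2", "4", "6"],
    ]
    assert [list(g) for g in assign_subgroups("12345", stride_s=1).groups] == [
        ["1", "2", "3", "4", "5"],
    ]
    groups = assign_subgroups("1234567", stride_s=3).groups
    assert [list(g) for g in groups] == [["1", "4", "7"], ["2", "5"], ["3", "6"]]
    sizes = [len(g) for g in groups]
    assert max(sizes) - min(sizes) <= 1


def test_grouping_partitions_and_respects_n_groups():
    feats = [f"f{i}" for i in range(17)]
    a = assign_subgroups(feats, stride_s=5, n_groups=4)
    assert a.n_groups == 4 and len(a.groups) == 4
    flat = [f for g in a.groups for f in g]
    assert sorted(flat) == sorted(feats)
    # group i holds ranks i, i+g, i+2g, ...
    assert list(a.groups[1]) == feats[1::4]
    with pytest.raises(ValueError):
        assign_subgroups(["a", "b"], n_groups=3)
    with pytest.raises(ValueError):
        assign_subgroups(["a", "b"])


def test_exact_solve_on_identity_design():
    m = fit_lnt(np.eye(2), [3.0, 5.0], standardize=False)
    assert m.weights == pytest.approx([3.0, 5.0])


def test_target_in_row_space_gives_zero_residual():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(3, 8))
    m = fit_lnt(x, x[0], standardize=False)
    resid = x[0] - m.weights @ x
    assert np.abs(resid).max() < 1e-10


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(0, 10_000), st.integers(2, 6), st.integers(7, 15))
def test_weights_match_generic_least_squares_solver(seed, d, n):
    """Normal-equation solve agrees with numpy's lstsq to 1e-8."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(d, n))
    t = rng.normal(size=n)
    m = fit_lnt(x, t)
    xc = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    tc = t - t.mean()
    oracle, *_ = np.linalg.lstsq(xc.T, tc, rcond=None)
    assert m.weights == pytest.approx(oracle, abs=1e-8)


def test_underdetermined_solve_is_minimum_norm_with_orthogonal_residual():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(12, 6))  # more features than samples
    t = rng.normal(size=6)
    m = fit_lnt(x, t)
    xc = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    tc = t - t.mean()
    oracle, *_ = np.linalg.lstsq(xc.T, tc, rcond=None)
    assert m.weights == pytest.approx(oracle, abs=1e-8)
    assert m.residual_orthogonality < 1e-8 * np.linalg.norm(t)


def test_pseudoinverse_and_exact_inverse_agree_when_well_conditioned():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(4, 40))
    t = rng.normal(size=40)
    m = fit_lnt(x, t)
    xc = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    tc = t - t.mean()
    gram = xc @ xc.T
    assert np.linalg.cond(gram) < 1e8
    exact = tc @ xc.T @ np.linalg.inv(gram)
    assert m.weights == pytest.approx(exact, abs=1e-8)


def test_apply_reproduces_fitted_values_and_is_leakage_frozen():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(5, 30))
    t = rng.normal(size=30)
    m = fit_lnt(x, t)
    xc = (x - m.mu[:, None]) / m.sd[:, None]
    assert apply_lnt(m, x) == pytest.approx(m.weights @ xc)
    # all-zero standardized input -> p = 0 (bias fixed at zero)
    at_mean = np.repeat(m.mu[:, None], 4, axis=1)
    assert apply_lnt(m, at_mean) == pytest.approx(np.zeros(4), abs=1e-12)
    # held-out samples: plain dot-product oracle with *training* stats
    x_new = rng.normal(size=(5, 7))
    manual = m.weights @ ((x_new - m.mu[:, None]) / m.sd[:, None])
    assert apply_lnt(m, x_new) == pytest.approx(manual)
    with pytest.raises(ValueError):
        apply_lnt(m, rng.normal(size=(4, 7)))


def test_errors():
    with pytest.raises(ValueError):
        fit_lnt(np.empty((0, 4)), [1.0, 2, 3, 4])
    with pytest.raises(ValueError):
        fit_lnt(np.eye(2), [1.0, 2, 3])


def test_single_perfect_predictor_yields_unit_correlation(tiny_table):
    rng = np.random.default_rng(4)
    y = 2.0 * tiny_table["f2"].to_numpy() + 1.0
    ranking = rank_features(tiny_table[["f2"]], y, "rft",
                            PartitionGrid(mode="exhaustive"))
    comp = generate_complementary(tiny_table[["f2"]], ranking, y, n_groups=1)
    p = comp.values["lnt_001"].to_numpy()
    assert abs(np.corrcoef(p, y)[0, 1]) == pytest.approx(1.0, abs=1e-10)


def test_generate_complementary_shapes_names_and_out_of_fold_application(small_cohort):
    _, table, target = small_cohort
    y = target.to_numpy(dtype=float)
    train, test = table.iloc[:90], table.iloc[90:]
    ranking = rank_features(train, y[:90], "dft", PartitionGrid())
    comp = generate_complementary(train, ranking, y[:90], n_groups=5, fold_id=0)
    assert comp.values.shape == (90, 5)
    assert comp.names == [f"lnt_{i:03d}" for i in range(1, 6)]
    flat = sorted(f for g in comp.assignment.groups for f in g)
    assert flat == sorted(table.columns)
    out = apply_complementary(comp, test)
    assert out.shape == (30, 5) and list(out.columns) == comp.names
    # frozen weights: recompute one group by hand
    g0, m0 = comp.assignment.groups[0], comp.models[0]
    manual = m0.weights @ ((test[list(g0)].to_numpy().T - m0.mu[:, None]) / m0.sd[:, None])
    assert out["lnt_001"].to_numpy() == pytest.approx(manual)


def test_complementary_features_beat_best_raw_feature_in_sample():
    """LNT features reach lower partition loss than any raw feature
    (the combined re-ranking places them first)."""
    from greenrad.cohort import planted_spec, simulate_cohort

    wins = 0
    for seed in range(5):
        spec = planted_spec("regression", seed=seed, n_samples=150,
                            n_features=100, n_blocks=10,
                            informative_indices=tuple(range(20)))
        table, target = simulate_cohort(spec)
        y = target.to_numpy()
        grid = PartitionGrid()
        ranking = rank_features(table, y, "rft", grid)
        comp = generate_complementary(table, ranking, y, n_groups=10)
        combined = pd.concat([table, comp.values], axis=1)
        rank2 = rank_features(combined, y, "rft", grid)
        best_raw = min(rank2.loss_of()[f] for f in table.columns)
        best_lnt = min(rank2.loss_of()[f] for f in comp.names)
        wins += best_lnt < best_raw
    assert wins >= 4
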