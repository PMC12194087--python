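"""Correlation redundancy filter: pair identification and greedy resolution."""

import math

import numpy as np
import pandas as pd
import pytest

from greenrad.redundancy import (
    correlation_matrix,
    identify_redundant_pairs,
    resolve_redundancy,
    retained_dimension_curve,
)


def _table(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols)


def test_affine_and_sign_invariance_give_unit_correlation():
    f = np.array([1.0, 2.0, 5.0, 7.0])
    rep = correlation_matrix(_table({"a": f, "b": 2 * f + 3, "c": -f}))
    assert rep.lookup("a", "b") == pytest.approx(1.0)
    assert rep.lookup("a", "c") == pytest.approx(1.0)


def test_pearson_matches_textbook_formula():
    # x=[1,2,3], y=[1,2,4]: r = 3 / sqrt(2 * 14/3)
    rep = correlation_matrix(_table({"x": [1.0, 2, 3], "y": [1.0, 2, 4]}))
    assert rep.lookup("x", "y") == pytest.approx(3 / math.sqrt(2 * 14 / 3), abs=1e-12)


def test_threshold_one_excludes_nothing_threshold_zero_lists_all(tiny_table):
    rep = correlation_matrix(tiny_table)
    assert identify_redundant_pairs(rep, 1.0) == []
    d = tiny_table.shape[1]
    assert len(identify_redundant_pairs(rep, 0.0)) == d * (d - 1) // 2


def test_duplicated_column_is_the_single_pair_at_09(tiny_table):
    t = tiny_table.copy()
    t["dup"] = t["f0"]
    rep = correlation_matrix(t)
    pairs = identify_redundant_pairs(rep, 0.9)
    assert ("f0", "dup") in pairs


def test_resolution_keeps_lower_loss_of_identical_columns():
    f = np.arange(10.0)
    t = _table({"a": f + 0.0, "b": f})
    rep = correlation_matrix(t)
    pairs = identify_redundant_pairs(rep, 0.9)
    kept = resolve_redundancy(pairs, {"a": 0.3, "b": 0.2}, ["a", "b"])
    assert kept == ["b"]


def test_chain_resolution_matches_brute_force_unique_answer():
    # A~B~C all pairwise redundant, losses 0.1 < 0.2 < 0.3.  The only
    # retained set that is pairwise non-redundant AND gives every
    # dropped feature a retained partner with <= loss is {A}.
    rng = np.random.default_rng(0)
    base = rng.normal(size=50)
    t = _table({
        "A": base + 0.01 * rng.normal(size=50),
        "B": base + 0.01 * rng.normal(size=50),
        "C": base + 0.01 * rng.normal(size=50),
    })
    rep = correlation_matrix(t)
    pairs = identify_redundant_pairs(rep, 0.9)
    assert len(pairs) == 3
    kept = resolve_redundancy(pairs, {"A": 0.1, "B": 0.2, "C": 0.3}, ["A", "B", "C"])
    assert kept == ["A"]


def test_no_pairs_above_threshold_retains_everything(tiny_table):
    rep = correlation_matrix(tiny_table)
    losses = {c: i * 0.1 for i, c in enumerate(tiny_table.columns)}
    kept = resolve_redundancy([], losses, tiny_table.columns)
    assert kept == list(tiny_table.columns)


def test_retained_set_contract_on_planted_blocks():
    # planted |r|>0.9 blocks: retained pairwise non-redundant and every
    # dropped feature has a retained partner with <= loss
    rng = np.random.default_rng(3)
    n, n_blocks, per = 300, 12, 4
    factors = rng.normal(size=(n, n_blocks))
    cols = {}
    for j in range(n_blocks * per):
        b = j // per
        cols[f"f{j}"] = np.sqrt(0.97) * factors[:, b] + np.sqrt(0.03) * rng.normal(size=n)
    t = pd.DataFrame(cols)
    rep = correlation_matrix(t)
    pairs = identify_redundant_pairs(rep, 0.9)
    losses = {c: float(l) for c, l in zip(t.columns, rng.uniform(0, 1, t.shape[1]))}
    kept = resolve_redundancy(pairs, losses, t.columns)
    kept_idx = [list(t.columns).index(c) for c in kept]
    sub = rep.abs_corr[np.ix_(kept_idx, kept_idx)]
    assert (sub[np.triu_indices_from(sub, k=1)] <= 0.9).all()
    adj = {c: set() for c in t.columns}
    for a, b in pairs:
        adj[a].add(b)
        adj[b].add(a)
    for c in set(t.columns) - set(kept):
        partners = adj[c] & set(kept)
        assert partners and min(losses[p] for p in partners) <= losses[c]


def test_constant_features_flagged_and_uncorrelated():
    t = _table({"a": [1.0, 2, 3, 4], "const": [5.0, 5, 5, 5]})
    rep = correlation_matrix(t)
    assert rep.constant_features == {"const"}
    assert rep.lookup("a", "const") == 0.0
    assert rep.lookup("const", "const") == 1.0


def test_correlation_is_local_to_column_pairs(tiny_table):
    full = correlation_matrix(tiny_table)
    sub = correlation_matrix(tiny_table[["f1", "f4"]])
    assert sub.lookup("f1", "f4") == pytest.approx(full.lookup("f1", "f4"), abs=1e-12)


def test_errors():
    with pytest.raises(ValueError):
        correlation_matrix(_table({"a": [1.0], "b": [2.0]}))  # <2 samples
    with pytest.raises(ValueError):
        correlation_matrix(_table({"a": [1.0, 1], "b": [3.0, 3]}))  # all constant
    with pytest.raises(ValueError):
        resolve_redundancy([("a", "b")], {"a": 0.1}, ["a", "b"])  # missing loss


def test_retained_dimension_curve_is_monotone(tiny_table):
    t = tiny_table.copy()
    t["dup1"] = t["f0"]
    t["dup2"] = t["f2"]
    rep = correlation_matrix(t)
    losses = {c: i * 0.1 for i, c in enumerate(t.columns)}
    curve = retained_dimension_curve(rep, losses, thresholds=[0.0, 0.5, 0.9, 1.0])
    dims = curve["retained_dimension"].tolist()
    assert dims == sorted(dims)
    assert dims[-1] == t.shape[1]  # threshold 1.0 drops nothing
    assert dims[0] == 1  # threshold 0.0: one survivor per component
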