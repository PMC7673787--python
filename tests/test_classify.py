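"""Normalization, k-selection, labeling and composition statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from itertools import combinations
from scipy.stats import fisher_exact as scipy_fisher

from pvint.classify import (
    SubtypeModel,
    cluster,
    composition,
    fisher_exact_rc,
    label_subtypes,
    normalize,
    select_k,
    ward_check,
)


# -- normalization ----------------------------------------------------------

def test_normalize_log_then_zscore():
    df = pd.DataFrame({"rin": [10.0, 100.0], "ff_2x": [50.0, 50.0]},
                      index=["a", "b"])
    logged = np.log10(df)
    assert logged["rin"].diff().iloc[-1] == pytest.approx(1.0)
    z = normalize(df)
    assert np.allclose(z["ff_2x"], 0.0)        # constant column -> zeros
    assert np.allclose(z["rin"], [-1.0, 1.0])  # population z-score


def test_normalize_rejects_nonpositive():
    df = pd.DataFrame({"rin": [10.0, -1.0]}, index=["a", "bad_cell"])
    with pytest.raises(ValueError, match="bad_cell"):
        normalize(df)
    # a second pass re-logs: z-scores are signed, so it must raise
    z = normalize(pd.DataFrame({"rin": [10.0, 100.0]}))
    with pytest.raises(ValueError):
        normalize(z)


# -- K-means ----------------------------------------------------------------

def test_kmeans_unit_square_matches_enumeration():
    """k = 2 on the four unit-square corners: K-means must find the
    bipartition with the lowest within-cluster sum of squares, verified by
    enumerating all 2+2 splits."""
    pts = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])

    def wcss(groups):
        return sum(((pts[list(g)] - pts[list(g)].mean(0)) ** 2).sum()
                   for g in groups)

    best = min(((set(c), set(range(4)) - set(c))
                for c in combinations(range(4), 2)), key=wcss)
    labels = cluster(pts, 2, seed=0)
    found = ({i for i in range(4) if labels[i] == labels[0]},
             {i for i in range(4) if labels[i] != labels[0]})
    assert {frozenset(g) for g in found} == {frozenset(g) for g in best}


def test_kmeans_k_equals_n_and_duplicates():
    pts = np.array([[0.0], [1.0], [5.0], [9.0]])
    labels = cluster(pts, 4, seed=0)
    assert len(set(labels)) == 4
    dup = np.array([[0.0, 1.0], [0.0, 1.0], [7.0, 3.0], [7.0, 3.0]])
    labels = cluster(dup, 2, seed=0)
    assert labels[0] == labels[1] and labels[2] == labels[3]


def test_kmeans_row_order_invariant():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(8, 1, (20, 3))])
    perm = rng.permutation(len(X))
    l1 = cluster(X, 2, seed=1)
    l2 = cluster(X[perm], 2, seed=1)
    # same partition as a set structure
    a = l1[perm] == l1[perm][0]
    b = l2 == l2[0]
    assert np.array_equal(a, b) or np.array_equal(a, ~b)


# -- k selection ------------------------------------------------------------

def _blobs(centers, n=40, seed=0):
    rng = np.random.default_rng(seed)
    return np.vstack([rng.normal(0, 1, (n, 7)) + c for c in centers])


def test_select_k_two_well_separated_blobs_unanimous():
    X = _blobs([np.zeros(7), np.full(7, 10.0)])
    k, votes, _ = select_k(X, seed=0)
    assert k == 2
    assert all(v == 2 for v in votes.values())


def test_select_k_three_blobs():
    X = _blobs([np.zeros(7), np.full(7, 10.0),
                np.r_[np.full(3, 20.0), np.full(4, -10.0)]])
    k, votes, _ = select_k(X, seed=0)
    assert k == 3


def test_select_k_single_blob_rarely_splits():
    """Degenerate-input guard: one Gaussian blob should almost never be
    reported as two clusters once the gap statistic can vote k = 1."""
    chosen = []
    for seed in range(10):
        X = np.random.default_rng(1000 + seed).normal(0, 1, (60, 7))
        k, _, _ = select_k(X, seed=seed)
        chosen.append(k)
    assert sum(k == 2 for k in chosen) <= 2


def test_select_k_needs_enough_cells():
    with pytest.raises(ValueError, match="cells"):
        select_k(np.zeros((5, 7)), k_range=(2, 8))


# -- semantic labels --------------------------------------------------------

def test_label_subtypes_by_firing_frequency():
    df = pd.DataFrame({"ff_2x": [137.0, 140.0, 66.0, 60.0]})
    labels = label_subtypes([0, 0, 1, 1], df)
    assert list(labels) == ["FS", "FS", "NFS", "NFS"]
    df3 = pd.DataFrame({"ff_2x": [168.0, 106.0, 57.0]})
    labels = label_subtypes([2, 0, 1], df3)
    assert list(labels) == ["FS", "IS", "NFS"]
    with pytest.warns(UserWarning, match="single cluster"):
        labels = label_subtypes([0, 0], pd.DataFrame({"ff_2x": [1.0, 2.0]}))
    assert set(labels) == {"FS"}


# -- Ward cross-validation --------------------------------------------------

def test_ward_agrees_on_separable_data():
    X = _blobs([np.zeros(7), np.full(7, 10.0)], seed=3)
    km = cluster(X, 2, seed=0)
    _, ari = ward_check(X, 2, km)
    assert ari == pytest.approx(1.0)


def test_ward_ari_near_zero_for_random_labels():
    rng = np.random.default_rng(0)
    aris = []
    for seed in range(20):
        X = _blobs([np.zeros(7), np.full(7, 10.0)], seed=seed)
        random_labels = rng.integers(0, 2, len(X))
        _, ari = ward_check(X, 2, random_labels)
        aris.append(ari)
    assert abs(np.mean(aris)) < 0.1


# -- composition ------------------------------------------------------------

def test_composition_percentages():
    labels = ["FS"] * 67 + ["NFS"] * 16
    tab = composition(labels, ["WT"] * 83)
    assert tab.counts.tolist() == [[67, 16]]
    assert tab.percentages().tolist() == [[81, 19]]  # 80.7 rounds to 81
    labels = ["FS"] * 20 + ["IS"] * 21 + ["NFS"] * 4
    tab = composition(labels, ["GlobalLis"] * 45)
    pct = dict(zip(tab.subtypes, tab.percentages()[0]))
    assert pct == {"FS": 44, "IS": 47, "NFS": 9}


def test_composition_empty_genotype_zero_row():
    tab = composition(["FS", "FS"], ["WT", "WT"])
    assert "IS" not in tab.subtypes or tab.counts.sum() == 2


# -- Fisher exact test ------------------------------------------------------

@given(st.tuples(st.integers(0, 8), st.integers(0, 8),
                 st.integers(0, 8), st.integers(0, 6)))
@settings(max_examples=150, deadline=None, derandomize=True)
def test_fisher_2x2_matches_independent_oracle(cells):
    """Full-enumeration p equals the classical hypergeometric two-sided p
    for every small 2 x 2 table (n <= 30)."""
    a, b, c, d = cells
    if a + b + c + d == 0:
        return
    p_mine, method = fisher_exact_rc([[a, b], [c, d]])
    assert method == "enumeration"
    p_ref = scipy_fisher([[a, b], [c, d]]).pvalue
    assert p_mine == pytest.approx(p_ref, abs=1e-12)


def test_fisher_worked_examples():
    p, _ = fisher_exact_rc([[5, 0], [0, 5]])
    assert p == pytest.approx(2 / 252, rel=1e-9)
    p, _ = fisher_exact_rc([[1, 1], [1, 1]])
    assert p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        fisher_exact_rc([[-1, 2], [3, 4]])


def test_fisher_2x3_composition_difference():
    p, method = fisher_exact_rc([[67, 0, 16], [20, 21, 4]])
    assert method == "enumeration"
    assert p < 1e-4


# -- model / results --------------------------------------------------------

def test_subtype_model_excludes_incomplete_cells_and_summarizes():
    rng = np.random.default_rng(0)
    n = 30
    df = pd.DataFrame({
        "ap_halfwidth": np.r_[rng.normal(0.42, 0.02, n), rng.normal(0.59, 0.02, n)],
        "ff_2x": np.r_[rng.normal(137, 5, n), rng.normal(66, 4, n)],
        "ff_3x": np.r_[rng.normal(171, 5, n), rng.normal(96, 4, n)],
        "ar_2x": np.r_[rng.normal(0.79, 0.02, n), rng.normal(0.67, 0.02, n)],
        "rin": np.r_[rng.normal(82, 4, n), rng.normal(143, 8, n)],
        "rheobase": np.r_[rng.normal(364, 20, n), rng.normal(153, 10, n)],
        "sag_index": np.r_[rng.normal(0.90, 0.01, n), rng.normal(0.80, 0.02, n)],
        "genotype": "WT",
    })
    df.loc[3, "ff_2x"] = np.nan
    model = SubtypeModel(df)
    res = model.fit(seed=0)
    assert model.excluded == [3]
    assert res.chosen_k == 2
    assert set(res.labels.unique()) == {"FS", "NFS"}
    assert res.ward_agreement >= 0.9
    text = res.summary()
    assert "chosen k: 2" in text and "FS" in text
    assert (res.labels.index == df.drop(index=3).index).all()
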