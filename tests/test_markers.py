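import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scimmune.io import CountMatrix, lognormalize
from scimmune.markers import MarkerCriteria, find_markers, rank_sum_p
from tests.conftest import nb_counts


def test_rank_sum_exact_enumeration():
    # U = 0; of the 20 equally likely rank assignments, 2 are as extreme
    assert rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_rank_sum_identical_multisets_p_one():
    assert rank_sum_p([1, 2, 2, 5], [1, 2, 2, 5]) == pytest.approx(1.0)


def test_rank_sum_empty_group_errors():
    with pytest.raises(ValueError):
        rank_sum_p([], [1.0])


def test_rank_sum_approximation_close_to_permutation_oracle():
    rng = np.random.default_rng(42)
    x = rng.normal(0.0, 1.0, size=30)
    y = rng.normal(0.5, 1.0, size=30)
    p = rank_sum_p(x, y)
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    w_obs = ranks[:30].sum()
    mu = ranks.sum() / 2
    n_resample = 100_000
    sel = rng.random((n_resample, 60)).argsort(axis=1)[:, :30]
    w_perm = ranks[sel].sum(axis=1)
    p_oracle = float((np.abs(w_perm - mu) >= abs(w_obs - mu) - 1e-9).mean())
    assert p == pytest.approx(p_oracle, abs=0.01)


def _norm_two_groups(rng, n_genes, n_a, n_b, fold_rows=(), fold=2.0):
    mu = np.tile(rng.lognormal(0.3, 0.5, size=(n_genes, 1)), (1, n_a + n_b))
    for r in fold_rows:
        mu[r, :n_a] *= fold
    cm = CountMatrix(
        genes=pd.Index([f"G{i:04d}" for i in range(n_genes)]),
        cells=pd.Index([f"c{i:04d}" for i in range(n_a + n_b)]),
        counts=sp.csr_matrix(nb_counts(rng, mu)),
    )
    totals = np.asarray(cm.counts.sum(axis=0)).ravel()
    cm = cm.subset_cells(totals > 0)
    labels = pd.Series(
        ["A"] * n_a + ["B"] * n_b, index=[f"c{i:04d}" for i in range(n_a + n_b)]
    ).reindex(cm.cells)
    return lognormalize(cm), labels


def test_planted_fold_detected_with_correct_sign():
    rng = np.random.default_rng(0)
    norm, labels = _norm_two_groups(rng, 60, 100, 100, fold_rows=range(10), fold=3.0)
    res = find_markers(norm, labels, "A", "B")
    top = res[res["passing"] & (res["lnfc"] > 0)]["gene"]
    planted = {f"G{i:04d}" for i in range(10)}
    assert planted <= set(top)


def test_lnfc_antisymmetric_under_group_swap():
    rng = np.random.default_rng(1)
    norm, labels = _norm_two_groups(rng, 40, 50, 60, fold_rows=range(5))
    ab = find_markers(norm, labels, "A", "B").set_index("gene")
    ba = find_markers(norm, labels, "B", "A").set_index("gene")
    common = ab.index.intersection(ba.index)
    np.testing.assert_allclose(ab.loc[common, "lnfc"], -ba.loc[common, "lnfc"], atol=1e-12)
    np.testing.assert_allclose(ab.loc[common, "p"], ba.loc[common, "p"], atol=1e-12)


def test_lnfc_matches_delogged_means_oracle():
    rng = np.random.default_rng(4)
    norm, labels = _norm_two_groups(rng, 30, 40, 40, fold_rows=range(3))
    res = find_markers(norm, labels, "A", "B", MarkerCriteria(min_pct=0.0)).set_index("gene")
    dense = norm.dense()
    a = dense[:, (labels == "A").to_numpy()]
    b = dense[:, (labels == "B").to_numpy()]
    expect = np.log(np.expm1(a).mean(axis=1) + 1) - np.log(np.expm1(b).mean(axis=1) + 1)
    got = res["lnfc"].reindex(norm.genes)
    np.testing.assert_allclose(got.to_numpy(), expect, atol=1e-10)


def test_min_pct_prefilter():
    rng = np.random.default_rng(6)
    norm, labels = _norm_two_groups(rng, 30, 40, 40)
    # a gene expressed nowhere can never be tested
    res = find_markers(norm, labels, "A", "B", MarkerCriteria(min_pct=0.99))
    dense = norm.dense()
    a = (dense[:, (labels == "A").to_numpy()] > 0).mean(axis=1)
    b = (dense[:, (labels == "B").to_numpy()] > 0).mean(axis=1)
    tested = set(norm.genes[np.maximum(a, b) > 0.99])
    assert set(res["gene"]) == tested


def test_unknown_group_errors():
    rng = np.random.default_rng(8)
    norm, labels = _norm_two_groups(rng, 10, 20, 20)
    with pytest.raises(ValueError):
        find_markers(norm, labels, "Z")


def test_null_raw_p_calibration():
    """Exchangeable groups: ~5% of tested genes reach raw p < 0.05."""
    rng = np.random.default_rng(10)
    norm, labels = _norm_two_groups(rng, 800, 60, 60)
    res = find_markers(norm, labels, "A", "B", MarkerCriteria(use_adjusted=False))
    frac = (res["p"] < 0.05).mean()
    assert frac == pytest.approx(0.05, abs=0.025)
    # adjusted p keeps its ordering guarantee
    assert (res["p_adj"] >= res["p"] - 1e-12).all()
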