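import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scimmune.interactions import (
    BUILTIN_PAIRS,
    LRPair,
    dotplot_matrices,
    entity_mean,
    expressed_fraction,
    read_pairs,
    score_interactions,
)
from scimmune.io import NormalizedMatrix


def _norm_from_dense(dense, genes=None):
    n_genes, n_cells = dense.shape
    return NormalizedMatrix(
        genes=pd.Index(genes or [f"G{i}" for i in range(n_genes)]),
        cells=pd.Index([f"c{i}" for i in range(n_cells)]),
        values=sp.csr_matrix(dense),
    )


def test_expressed_fraction_arithmetic():
    dense = np.zeros((2, 20))
    dense[0, :3] = 1.0  # 3 of 20 cells
    norm = _norm_from_dense(dense)
    labels = pd.Series(["K"] * 20, index=norm.cells)
    assert expressed_fraction(norm, labels, "G0", "K") == pytest.approx(0.15)
    assert expressed_fraction(norm, labels, "G1", "K") == 0.0
    with pytest.raises(KeyError):
        expressed_fraction(norm, labels, "NOPE", "K")


def test_entity_mean_min_rule_and_subunit_expression():
    dense = np.zeros((3, 10))
    dense[0, :] = 2.0  # A: mean 2, expressed everywhere
    dense[1, :] = 0.5  # B: mean 0.5, expressed everywhere
    norm = _norm_from_dense(dense, ["A", "B", "C"])
    labels = pd.Series(["K"] * 10, index=norm.cells)
    mean, ok = entity_mean(norm, labels, ("A", "B"), "K")
    assert mean == pytest.approx(0.5) and ok
    # one subunit expressed in 0% of cells -> complex unexpressed
    mean2, ok2 = entity_mean(norm, labels, ("A", "C"), "K")
    assert not ok2 and mean2 == 0.0
    # single-gene mean equals the brute-force average
    m, _ = entity_mean(norm, labels, "A", "K")
    assert m == pytest.approx(dense[0].mean())


def _two_cluster_norm(rng, n_cells=60, lig_fold=1.0, rec_fold=1.0):
    genes = ["LIG", "REC", "X1", "X2"]
    dense = rng.gamma(2.0, 1.0, size=(4, n_cells))
    half = n_cells // 2
    dense[0, :half] *= lig_fold  # ligand up in cluster A
    dense[1, half:] *= rec_fold  # receptor up in cluster B
    norm = _norm_from_dense(dense, genes)
    labels = pd.Series(["A"] * half + ["B"] * (n_cells - half), index=norm.cells)
    return norm, labels


PAIR = (LRPair("LIG_REC", ("LIG",), ("REC",)),)


def test_planted_axis_reaches_p_zero():
    rng = np.random.default_rng(0)
    norm, labels = _two_cluster_norm(rng, lig_fold=8.0, rec_fold=8.0)
    res = score_interactions(norm, labels, PAIR, n_perm=1000, seed=1)
    row = res[(res.cluster_a == "A") & (res.cluster_b == "B")].iloc[0]
    assert row["tested"]
    assert row["p"] == 0.0


def test_untested_when_ligand_below_ten_percent():
    rng = np.random.default_rng(1)
    norm, labels = _two_cluster_norm(rng)
    dense = np.asarray(norm.values.todense())
    dense[0, :] = 0.0  # ligand silent everywhere
    norm = _norm_from_dense(dense, list(norm.genes))
    res = score_interactions(norm, labels, PAIR, n_perm=50, seed=0)
    assert not res[res.pair == "LIG_REC"]["tested"].any()
    assert res[res.pair == "LIG_REC"]["p"].isna().all()


def test_mean_score_is_mean_of_cluster_means():
    rng = np.random.default_rng(2)
    norm, labels = _two_cluster_norm(rng)
    res = score_interactions(norm, labels, PAIR, n_perm=10, seed=0)
    dense = np.asarray(norm.values.todense())
    a = (labels == "A").to_numpy()
    expect = 0.5 * (dense[0, a].mean() + dense[1, ~a].mean())
    row = res[(res.cluster_a == "A") & (res.cluster_b == "B")].iloc[0]
    assert row["mean_score"] == pytest.approx(expect, abs=1e-12)


def test_reproducible_and_direction_asymmetric():
    rng = np.random.default_rng(3)
    norm, labels = _two_cluster_norm(rng, lig_fold=3.0)
    r1 = score_interactions(norm, labels, PAIR, n_perm=200, seed=42)
    r2 = score_interactions(norm, labels, PAIR, n_perm=200, seed=42)
    pd.testing.assert_frame_equal(r1, r2)
    ab = r1[(r1.cluster_a == "A") & (r1.cluster_b == "B")].iloc[0]["mean_score"]
    ba = r1[(r1.cluster_a == "B") & (r1.cluster_b == "A")].iloc[0]["mean_score"]
    assert ab != pytest.approx(ba)


def test_pseudocount_estimator_bounds_p_away_from_zero():
    rng = np.random.default_rng(4)
    norm, labels = _two_cluster_norm(rng, lig_fold=8.0, rec_fold=8.0)
    res = score_interactions(norm, labels, PAIR, n_perm=100, seed=1, pseudocount=True)
    assert (res.loc[res["tested"], "p"] >= 1 / 101).all()


def test_builtin_pairs_and_table_io(tmp_path):
    assert len(BUILTIN_PAIRS) == 9
    p = tmp_path / "pairs.tsv"
    p.write_text(
        "pair\tligand_subunits\treceptor_subunits\n"
        "IL15_IL15R\tIL15\tIL2RB;IL2RG\n"
    )
    pairs = read_pairs(p)
    assert pairs[0].receptor == ("IL2RB", "IL2RG")


def test_dotplot_matrices_shape():
    rng = np.random.default_rng(5)
    norm, labels = _two_cluster_norm(rng)
    res = score_interactions(norm, labels, PAIR, n_perm=20, seed=0)
    pmat, smat = dotplot_matrices(res)
    assert pmat.shape == (1, 4) and smat.shape == (1, 4)
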