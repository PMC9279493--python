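import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scimmune.tcr import (
    clonality,
    clone_sizes,
    define_clonotypes,
    match_longitudinal,
    partition_tumor_clones,
    shannon_index,
    shared_clonotypes,
    startrac_expa,
    startrac_tran,
)


def _cells(barcodes, **cols):
    df = pd.DataFrame({"barcode": barcodes, **cols}).set_index("barcode")
    if "lineage" not in df.columns:
        df["lineage"] = "CD8"
    return df


def _contig(barcode, chain, cdr3, productive=True, umis=5):
    return {"barcode": barcode, "chain": chain, "cdr3_nt": cdr3,
            "productive": productive, "umis": umis}


def test_identical_cdr3_pairs_share_clonotype():
    contigs = pd.DataFrame(
        [
            _contig("c1", "TRA", "AAAA"), _contig("c1", "TRB", "CCCC"),
            _contig("c2", "TRB", "CCCC"), _contig("c2", "TRA", "AAAA"),
            _contig("c3", "TRA", "AAAA"), _contig("c3", "TRB", "GGGG"),
        ]
    )
    ct = define_clonotypes(contigs, _cells(["c1", "c2", "c3"]))
    assert ct.assignments["c1"] == ct.assignments["c2"]
    assert ct.assignments["c1"] != ct.assignments["c3"]
    assert ct.keys[ct.assignments["c1"]] == "TRA:AAAA;TRB:CCCC"


def test_single_chain_cell_included_and_nonproductive_ignored():
    contigs = pd.DataFrame(
        [
            _contig("c1", "TRA", "AAAA"),
            _contig("c2", "TRB", "TTTT", productive=False),
        ]
    )
    ct = define_clonotypes(contigs, _cells(["c1", "c2"]))
    assert list(ct.barcodes()) == ["c1"]
    assert ct.keys[ct.assignments["c1"]] == "TRA:AAAA"


def test_multi_contig_resolution_by_umi_then_lexicographic():
    contigs = pd.DataFrame(
        [
            _contig("c1", "TRB", "GGGG", umis=9),
            _contig("c1", "TRB", "AAAA", umis=2),
            _contig("c2", "TRB", "CCCC", umis=5),
            _contig("c2", "TRB", "AAAA", umis=5),  # tie -> lexicographically smaller
        ]
    )
    ct = define_clonotypes(contigs, _cells(["c1", "c2"]))
    assert ct.keys[ct.assignments["c1"]] == "TRB:GGGG"
    assert ct.keys[ct.assignments["c2"]] == "TRB:AAAA"


def test_unknown_barcode_skipped():
    contigs = pd.DataFrame([_contig("c1", "TRB", "AAAA"), _contig("zz", "TRB", "CCCC")])
    ct = define_clonotypes(contigs, _cells(["c1"]))
    assert list(ct.barcodes()) == ["c1"]


def _toy_clonotypes(clone_map):
    """ClonotypeTable from {barcode: clone_label} via one TRB CDR3 per clone."""
    alphabet = {}
    rows = []
    for bc, clone in clone_map.items():
        if clone not in alphabet:
            alphabet[clone] = "".join("ACGT"[(len(alphabet) >> (2 * k)) % 4] for k in range(8))
        rows.append(_contig(bc, "TRB", alphabet[clone]))
    cells = _cells(list(clone_map))
    return define_clonotypes(pd.DataFrame(rows), cells)


def test_clone_sizes_matches_groupby_oracle():
    rng = np.random.default_rng(0)
    clone_map = {f"c{i}": f"K{rng.integers(0, 60)}" for i in range(500)}
    ct = _toy_clonotypes(clone_map)
    sizes = clone_sizes(ct)
    oracle = pd.Series(clone_map).value_counts()
    assert sorted(sizes.tolist()) == sorted(oracle.tolist())
    assert sizes.sum() == 500


def test_clone_sizes_empty_subset_errors():
    ct = _toy_clonotypes({"c1": "K1"})
    with pytest.raises(ValueError):
        clone_sizes(ct, ["not_there"])


def test_shannon_closed_forms():
    assert shannon_index([4]) == pytest.approx(0.0)
    assert shannon_index([1] * 10) == pytest.approx(1.0)  # log10(10)
    assert shannon_index([2, 1, 1]) == pytest.approx(0.4515, abs=1e-4)
    # natural-base option
    assert shannon_index([1] * 8, base=2) == pytest.approx(3.0)


def test_clonality_closed_forms():
    assert clonality([5]) == pytest.approx(1.0)  # monoclonal, N >= 2
    assert clonality([1] * 16) == pytest.approx(0.0)  # all singletons: H = log2 N
    assert clonality([2, 1, 1]) == pytest.approx(0.25)  # H = 1.5 bits over log2(4)
    assert math.isnan(clonality([1]))  # N < 2 undefined


def test_diversity_matches_direct_formula_on_random_repertoires():
    rng = np.random.default_rng(1)
    for _ in range(25):
        sizes = rng.integers(1, 20, size=rng.integers(2, 40))
        p = sizes / sizes.sum()
        h10 = -(p * np.log10(p)).sum()
        assert shannon_index(sizes) == pytest.approx(h10, abs=1e-12)
        h2 = -(p * np.log2(p)).sum()
        expect = 1 - h2 / np.log2(sizes.sum())
        assert clonality(sizes) == pytest.approx(expect, abs=1e-12)


def test_shared_clonotypes_partition_and_pairwise():
    clone_map = {}
    comp = {}
    # T: clones a,b,c ; P1: clones b,c,d ; N: clone e only
    for i, cl in enumerate(["a", "b", "c"]):
        clone_map[f"t{i}"] = cl
        comp[f"t{i}"] = "T"
    for i, cl in enumerate(["b", "c", "d"]):
        clone_map[f"p{i}"] = cl
        comp[f"p{i}"] = "P1"
    clone_map["n0"] = "e"
    comp["n0"] = "N"
    ct = _toy_clonotypes(clone_map)
    ov = shared_clonotypes(ct, pd.Series(comp))
    assert sum(ov.region_counts.values()) == ov.union_size == 5
    pw = ov.pairwise.set_index(["group_a", "group_b"])
    assert pw.loc[("P1", "T"), "shared"] == 2 or pw.loc[("T", "P1"), "shared"] == 2
    assert ov.region_counts[frozenset({"T", "P1"})] == 2
    assert ov.region_counts[frozenset({"N"})] == 1


def test_disjoint_repertoires_share_nothing():
    clone_map = {"a1": "x", "a2": "y", "b1": "z"}
    comp = {"a1": "T", "a2": "T", "b1": "P1"}
    ov = shared_clonotypes(_toy_clonotypes(clone_map), pd.Series(comp))
    assert (ov.pairwise["shared"] == 0).all()


def test_match_longitudinal_inner_join_and_ratio():
    clone_map = {}
    comp = {}
    for i in range(3):
        clone_map[f"x{i}"] = "common"
        comp[f"x{i}"] = "P0"
    for i in range(12):
        clone_map[f"y{i}"] = "common"
        comp[f"y{i}"] = "P1"
    clone_map["only0"] = "p0only"
    comp["only0"] = "P0"
    ct = _toy_clonotypes(clone_map)
    m = match_longitudinal(ct, pd.Series(comp))
    assert len(m) == 1
    assert m.iloc[0]["size_P0"] == 3 and m.iloc[0]["size_P1"] == 12
    assert m.iloc[0]["expansion_ratio"] == pytest.approx(4.0)


def test_partition_labels_clonotype_constant():
    clone_map = {"t1": "s", "t2": "s", "t3": "r", "p1": "s"}
    comp = {"t1": "T", "t2": "T", "t3": "T", "p1": "P1"}
    ct = _toy_clonotypes(clone_map)
    part = partition_tumor_clones(ct, pd.Series(comp))
    assert part["t1"] == part["t2"] == "shared_with_P1"
    assert part["t3"] == "tumor_resident_only"
    # empty blood repertoire -> everything tumor-resident
    comp2 = {k: "T" for k in clone_map}
    part2 = partition_tumor_clones(ct, pd.Series(comp2))
    assert (part2 == "tumor_resident_only").all()


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.integers(min_value=1, max_value=100), min_size=2, max_size=60))
def test_diversity_bounds_property(sizes):
    """Shannon index is in [0, lg K] with the extremes exactly at monoclonal
    and uniform repertoires; clonality stays within [0, 1]."""
    h = shannon_index(sizes)
    k = len(sizes)
    assert -1e-12 <= h <= np.log10(k) + 1e-12
    c = clonality(sizes)
    assert -1e-12 <= c <= 1 + 1e-12
    if len(set(sizes)) == 1:
        assert h == pytest.approx(np.log10(k), abs=1e-12)
    assert shannon_index([sum(sizes)]) == 0.0


def test_cd8_clonality_higher_post_therapy_across_replicates():
    """The planted peripheral CD8 expansion makes pooled P1 CD8 clonality
    exceed P0 CD8 clonality in (at least) 19 of 20 seeded cohorts."""
    from scimmune.qc import compute_qc_metrics, filter_cells
    from scimmune.simulate import CohortConfig, generate_cohort

    wins = 0
    for seed in range(20):
        c = generate_cohort(
            CohortConfig(cells_per_sample=40, n_genes=350, seed=300 + seed)
        )
        mask = filter_cells(compute_qc_metrics(c.counts))
        cells = c.cells.loc[mask[mask].index]
        ct = define_clonotypes(c.contigs, cells)
        vals = {}
        for comp in ("P0", "P1"):
            bc = cells.index[(cells["compartment"] == comp) & (cells["lineage"] == "CD8")]
            vals[comp] = clonality(clone_sizes(ct, bc).to_numpy())
        wins += vals["P1"] > vals["P0"]
    assert wins >= 19


def brute_expa(clones, clusters, base=2.0):
    out = {}
    for cl in sorted(set(clusters.values)):
        members = clones[clusters == cl]
        if len(members) < 2:
            out[cl] = np.nan
            continue
        counts = members.value_counts().to_numpy(dtype=float)
        if len(counts) == 1:
            out[cl] = 1.0
        else:
            p = counts / counts.sum()
            h = -(p * np.log(p) / np.log(base)).sum()
            out[cl] = 1 - h / (np.log(len(counts)) / np.log(base))
    return pd.Series(out)


def brute_tran(clones, clusters):
    names = sorted(set(clusters.values))
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for i, k in enumerate(names):
        for l in names[i + 1:]:
            sel = clusters.isin([k, l])
            total = int(sel.sum())
            val = 0.0
            if total:
                for _, grp in clones[sel].groupby(clones[sel]):
                    nk = int((clusters[grp.index] == k).sum())
                    nl = len(grp) - nk
                    f = nk / (nk + nl)
                    h2 = 0.0 if f in (0.0, 1.0) else -(
                        f * np.log2(f) + (1 - f) * np.log2(1 - f)
                    )
                    val += (nk + nl) / total * h2
            mat.loc[k, l] = mat.loc[l, k] = val
    return mat


def test_expa_closed_forms():
    clones = pd.Series(["a", "a", "a", "b"], index=list("wxyz"))
    clusters = pd.Series(["K"] * 4, index=list("wxyz"))
    expa = startrac_expa(clones, clusters)
    assert expa["K"] == pytest.approx(1 - 0.8112781245 / 1.0, abs=1e-9)
    # all distinct clonotypes -> 0 ; single clonotype -> 1
    expa0 = startrac_expa(pd.Series(list("abcd"), index=list("wxyz")), clusters)
    assert expa0["K"] == pytest.approx(0.0)
    expa1 = startrac_expa(pd.Series(["a"] * 4, index=list("wxyz")), clusters)
    assert expa1["K"] == pytest.approx(1.0)


def test_tran_closed_forms():
    idx = ["c1", "c2", "c3", "c4"]
    clusters = pd.Series(["K", "K", "L", "L"], index=idx)
    # one clone split 50/50 across the pair -> tran = 1
    split = pd.Series(["a", "b", "a", "c"], index=idx)
    tran = startrac_tran(split, clusters)
    assert tran.loc["K", "L"] == pytest.approx(0.5)  # clone a: w=1/2, H2=1
    confined = pd.Series(["a", "a", "b", "b"], index=idx)
    assert startrac_tran(confined, clusters).loc["K", "L"] == 0.0
    one_clone = pd.Series(["a", "a", "a", "a"], index=idx)
    assert startrac_tran(one_clone, clusters).loc["K", "L"] == pytest.approx(1.0)


def test_expa_tran_match_brute_force_and_are_order_invariant():
    rng = np.random.default_rng(3)
    for _ in range(10):
        n = 200
        idx = [f"c{i}" for i in range(n)]
        clones = pd.Series(rng.integers(0, 50, size=n).astype(str), index=idx)
        clusters = pd.Series(
            rng.choice([f"K{j}" for j in range(rng.integers(4, 7))], size=n), index=idx
        )
        expa = startrac_expa(clones, clusters)
        pd.testing.assert_series_equal(
            expa, brute_expa(clones, clusters).rename("expa"),
            atol=1e-12, check_exact=False,
        )
        tran = startrac_tran(clones, clusters)
        pd.testing.assert_frame_equal(tran, brute_tran(clones, clusters), atol=1e-12)
        assert np.allclose(tran.to_numpy(), tran.to_numpy().T, equal_nan=True)
        # permutation of the cell order changes nothing
        perm = rng.permutation(n)
        expa_p = startrac_expa(clones.iloc[perm], clusters)
        pd.testing.assert_series_equal(expa, expa_p, atol=1e-12, check_exact=False)
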