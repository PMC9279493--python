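"""TCR repertoire analysis.

A clonotype is the set of T cells sharing identical productive CDR3 nucleotide
sequences (both chains when available, single chain otherwise). On top of the
clonotype assignment this module computes cross-compartment clone sharing
(Venn partitions and pairwise overlap), Shannon diversity and clonality of
repertoires, longitudinal clone matching between pre/post-therapy blood (P0 vs
P1), the shared-vs-tumor-resident partition of intratumoral clones, and the
STARTRAC clonal-expansion (expa) and state-transition (tran) indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_CHAINS = ("TRA", "TRB")


@dataclass
class ClonotypeTable:
    """Cell -> clonotype assignment with canonical clonotype keys.

    ``assignments`` maps barcode to clonotype_id; ``keys`` maps clonotype_id to
    its canonical key (chain-tagged productive CDR3 nt strings, sorted and
    joined). Cells without a productive TRA/TRB chain are absent.
    """

    assignments: pd.Series
    keys: pd.Series
    lineage: pd.Series

    def barcodes(self) -> pd.Index:
        return self.assignments.index

    def subset(self, barcodes) -> "ClonotypeTable":
        sub = self.assignments.loc[self.assignments.index.intersection(barcodes)]
        return ClonotypeTable(sub, self.keys, self.lineage.reindex(sub.index))

    def clone_set(self, barcodes=None) -> set:
        a = self.assignments if barcodes is None else self.subset(barcodes).assignments
        return set(a.unique())


def define_clonotypes(contigs: pd.DataFrame, cells: pd.DataFrame) -> ClonotypeTable:
    """Assign clonotypes from productive TRA/TRB contigs.

    Per cell and chain, the highest-UMI productive contig wins (ties broken by
    lexicographically smallest CDR3). Contigs whose barcode is not in the cell
    table are logged and skipped; cells with no productive chain are excluded.
    """
    known = contigs["barcode"].isin(cells.index)
    n_skip = int((~known).sum())
    if n_skip:
        logger.warning("skipping %d contig(s) with barcodes absent from the cell table", n_skip)
    use = contigs.loc[
        known & contigs["productive"] & contigs["chain"].isin(_CHAINS)
    ].copy()
    if use.empty:
        return ClonotypeTable(
            pd.Series(dtype=object, name="clonotype_id"),
            pd.Series(dtype=object, name="key"),
            pd.Series(dtype=object, name="lineage"),
        )
    use = use.sort_values(
        ["barcode", "chain", "umis", "cdr3_nt"], ascending=[True, True, False, True]
    ).drop_duplicates(["barcode", "chain"], keep="first")
    use["tagged"] = use["chain"] + ":" + use["cdr3_nt"]
    keys = (
        use.sort_values(["barcode", "tagged"])
        .groupby("barcode", sort=True)["tagged"]
        .agg(";".join)
    )
    uniq = pd.Index(sorted(keys.unique()))
    width = max(6, len(str(len(uniq))))
    id_of_key = pd.Series(
        [f"CT{i + 1:0{width}d}" for i in range(len(uniq))], index=uniq
    )
    assignments = keys.map(id_of_key).rename("clonotype_id")
    key_table = pd.Series(id_of_key.index, index=id_of_key.values, name="key")
    lineage = (
        cells["lineage"].reindex(assignments.index)
        if "lineage" in cells.columns
        else pd.Series("unknown", index=assignments.index)
    ).rename("lineage")
    return ClonotypeTable(assignments, key_table, lineage)


def clone_sizes(clonotypes: ClonotypeTable, barcodes=None) -> pd.Series:
    """Clonotype sizes among a cell subset; N = number of TCR-bearing cells."""
    a = clonotypes.assignments if barcodes is None else clonotypes.subset(barcodes).assignments
    if a.empty:
        raise ValueError("subset contains no TCR-bearing cells")
    return a.value_counts().rename("n_i")


def shannon_index(sizes, base: float = 10.0) -> float:
    """Shannon-Wiener diversity of clone abundances, -sum p_i log(p_i).

    ``base`` defaults to 10 ('lg'); a uniform repertoire of K singletons scores
    log10(K), a monoclonal one scores 0.
    """
    n = np.asarray(sizes, dtype=float)
    if n.size == 0 or n.sum() < 1:
        raise ValueError("need at least one sequence")
    p = n / n.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def clonality(sizes, denominator: str = "total", base: float = 2.0) -> float:
    """1 - normalized Shannon entropy (base 2) of clone abundances.

    The normalizer is log2 of the total sequence count N by default
    (``denominator='total'``); ``denominator='unique'`` switches to the
    conventional log2(number of clonotypes). Undefined (NaN) for N < 2.
    """
    n = np.asarray(sizes, dtype=float)
    total = n.sum()
    if total < 2:
        logger.warning("clonality undefined for N < 2 (log2(1) = 0); returning NaN")
        return float("nan")
    p = n / total
    h = float(-(p * (np.log(p) / np.log(base))).sum())
    if denominator == "total":
        denom = np.log(total) / np.log(base)
    elif denominator == "unique":
        if n.size < 2:
            return 1.0
        denom = np.log(n.size) / np.log(base)
    else:
        raise ValueError("denominator must be 'total' or 'unique'")
    return float(1.0 - h / denom)


@dataclass
class OverlapResult:
    """Venn partition and pairwise sharing of clonotypes across groups."""

    groups: tuple
    clone_sets: dict
    region_counts: dict  # frozenset of group names -> exclusive region count
    pairwise: pd.DataFrame  # columns group_a, group_b, shared, frac_of_a, frac_of_b

    @property
    def union_size(self) -> int:
        return len(set().union(*self.clone_sets.values())) if self.clone_sets else 0


def shared_clonotypes(clonotypes: ClonotypeTable, grouping: pd.Series) -> OverlapResult:
    """Clonotype overlap between cell groups (typically tissue compartments).

    Emits all 2^k - 1 exclusive Venn region counts plus pairwise shared counts
    and shared fractions relative to each group's clonotype count. Groups with
    no TCR-bearing cells are dropped with a warning.
    """
    grouping = pd.Series(grouping)
    a = clonotypes.assignments
    g = grouping.reindex(a.index).dropna()
    sets = {name: set(a.loc[g.index[g == name]].unique()) for name in sorted(g.unique())}
    empty = [k for k, v in sets.items() if not v]
    for k in empty:
        logger.warning("group %r has no TCR-bearing cells; dropped from overlap", k)
        del sets[k]
    if len(sets) < 2:
        raise ValueError("need at least two groups with TCR-bearing cells")
    names = tuple(sets)
    membership = {}
    for name, s in sets.items():
        for c in s:
            membership.setdefault(c, set()).add(name)
    region_counts: dict = {}
    for c, present in membership.items():
        key = frozenset(present)
        region_counts[key] = region_counts.get(key, 0) + 1
    rows = []
    for ga, gb in combinations(names, 2):
        shared = len(sets[ga] & sets[gb])
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "shared": shared,
                "frac_of_a": shared / len(sets[ga]),
                "frac_of_b": shared / len(sets[gb]),
            }
        )
    return OverlapResult(names, sets, region_counts, pd.DataFrame(rows))


def match_longitudinal(
    clonotypes: ClonotypeTable,
    compartment_of: pd.Series,
    patient_of: pd.Series | None = None,
    before: str = "P0",
    after: str = "P1",
) -> pd.DataFrame:
    """Clones present in both pre- and post-therapy blood, with expansion ratios.

    Inner join on the clonotype key; when ``patient_of`` is given the match is
    per patient and patients lacking either compartment are skipped with a
    warning. ``expansion_ratio`` is size_after / size_before.
    """
    comp = pd.Series(compartment_of).reindex(clonotypes.barcodes())
    pat = (
        pd.Series(patient_of).reindex(clonotypes.barcodes())
        if patient_of is not None
        else pd.Series("all", index=clonotypes.barcodes())
    )
    out = []
    for patient in sorted(pat.dropna().unique()):
        sel = pat == patient
        b0 = clonotypes.barcodes()[sel & (comp == before)]
        b1 = clonotypes.barcodes()[sel & (comp == after)]
        if len(b0) == 0 or len(b1) == 0:
            logger.warning(
                "patient %s lacks TCR cells in %s or %s; skipped from longitudinal match",
                patient, before, after,
            )
            continue
        s0 = clone_sizes(clonotypes, b0)
        s1 = clone_sizes(clonotypes, b1)
        common = s0.index.intersection(s1.index)
        lin = clonotypes.lineage.loc[b0].groupby(clonotypes.assignments.loc[b0]).first()
        for c in common:
            out.append(
                {
                    "patient": patient,
                    "clonotype_id": c,
                    "key": clonotypes.keys.get(c),
                    "lineage": lin.get(c, "unknown"),
                    f"size_{before}": int(s0[c]),
                    f"size_{after}": int(s1[c]),
                    "expansion_ratio": float(s1[c]) / float(s0[c]),
                }
            )
    cols = [
        "patient", "clonotype_id", "key", "lineage",
        f"size_{before}", f"size_{after}", "expansion_ratio",
    ]
    return pd.DataFrame(out, columns=cols)


def partition_tumor_clones(
    clonotypes: ClonotypeTable,
    compartment_of: pd.Series,
    tumor: str = "T",
    blood: str = "P1",
) -> pd.Series:
    """Label tumor TCR-bearing cells by whether their clone also occurs in blood.

    Labels are 'shared_with_P1' / 'tumor_resident_only' (for the default
    compartments) and are constant within a clonotype by construction.
    """
    comp = pd.Series(compartment_of).reindex(clonotypes.barcodes())
    tumor_cells = clonotypes.barcodes()[comp == tumor]
    if len(tumor_cells) == 0:
        raise ValueError(f"no TCR-bearing cells in compartment {tumor!r}")
    blood_cells = clonotypes.barcodes()[comp == blood]
    blood_clones = clonotypes.clone_set(blood_cells) if len(blood_cells) else set()
    assign = clonotypes.assignments.loc[tumor_cells]
    labels = np.where(
        assign.isin(blood_clones), f"shared_with_{blood}", "tumor_resident_only"
    )
    return pd.Series(labels, index=tumor_cells, name="clone_partition")


def _entropy(counts: np.ndarray, base: float) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * (np.log(p) / np.log(base))).sum())


def startrac_expa(
    clone_of: pd.Series, cluster_of: pd.Series, min_cells: int = 2, base: float = 2.0
) -> pd.Series:
    """Per-cluster clonal expansion index: 1 - H(clone sizes)/log(U).

    U is the number of unique clonotypes in the cluster; single-clonotype
    clusters score 1 by convention; clusters with fewer than ``min_cells``
    TCR-bearing cells are NA. The index is base-invariant (entropy and its
    normalizer share a base).
    """
    clone_of = pd.Series(clone_of)
    cluster_of = pd.Series(cluster_of).reindex(clone_of.index)
    out = {}
    for cl in sorted(cluster_of.dropna().unique()):
        members = clone_of[cluster_of == cl]
        if len(members) < min_cells:
            out[cl] = np.nan
            continue
        sizes = members.value_counts().to_numpy(dtype=float)
        u = len(sizes)
        if u == 1:
            out[cl] = 1.0
        else:
            out[cl] = 1.0 - _entropy(sizes, base) / (np.log(u) / np.log(base))
    return pd.Series(out, name="expa")


def startrac_tran(clone_of: pd.Series, cluster_of: pd.Series) -> pd.DataFrame:
    """Pairwise state-transition index between clusters.

    For clusters (k, l), each clone's cells restricted to k union l contribute
    its binary entropy H2 of the within-pair split, weighted by the clone's
    share of cells in the pair; clones confined to one cluster contribute 0.
    Symmetric with an NA diagonal; 0 when a pair has no TCR cells.
    """
    clone_of = pd.Series(clone_of)
    cluster_of = pd.Series(cluster_of).reindex(clone_of.index)
    clusters = sorted(cluster_of.dropna().unique())
    if len(clusters) < 2:
        raise ValueError("need at least two clusters with TCR-bearing cells")
    # clone x cluster contingency table
    tab = pd.crosstab(clone_of, cluster_of)
    tab = tab.reindex(columns=clusters, fill_value=0)
    mat = pd.DataFrame(np.nan, index=clusters, columns=clusters, dtype=float)
    arr = tab.to_numpy(dtype=float)
    for i, j in combinations(range(len(clusters)), 2):
        nk, nl = arr[:, i], arr[:, j]
        tot = nk + nl
        n_pair = tot.sum()
        if n_pair == 0:
            val = 0.0
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.where(tot > 0, nk / np.where(tot > 0, tot, 1), 0.0)
                h2 = np.zeros_like(f)
                inner = (f > 0) & (f < 1)
                fi = f[inner]
                h2[inner] = -(fi * np.log2(fi) + (1 - fi) * np.log2(1 - fi))
            val = float(((tot / n_pair) * h2).sum())
        mat.iloc[i, j] = mat.iloc[j, i] = val
    return mat


def diversity_table(
    clonotypes: ClonotypeTable,
    cells: pd.DataFrame,
    by=("patient", "compartment", "lineage"),
    lineages=("CD4", "CD8"),
    shannon_base: float = 10.0,
    clonality_denominator: str = "total",
) -> pd.DataFrame:
    """Shannon diversity and clonality per stratum (default: patient x compartment x lineage)."""
    meta = cells.reindex(clonotypes.barcodes())
    meta = meta[meta["lineage"].isin(lineages)] if "lineage" in meta.columns else meta
    rows = []
    for key, sub in meta.groupby(list(by), observed=True, sort=True):
        if len(sub) == 0:
            continue
        sizes = clone_sizes(clonotypes, sub.index).to_numpy()
        rec = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        rec.update(
            n_cells=int(sizes.sum()),
            n_clonotypes=int(len(sizes)),
            shannon=shannon_index(sizes, base=shannon_base),
            clonality=clonality(sizes, denominator=clonality_denominator),
        )
        rows.append(rec)
    return pd.DataFrame(rows)
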