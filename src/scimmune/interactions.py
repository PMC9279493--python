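"""Ligand-receptor interaction scoring between cell clusters.

CellPhoneDB-style statistical test: an interaction between the ligand in
cluster a and the receptor in cluster b is considered only when both entities
are expressed in more than 10% of that cluster's cells; its score is the mean
of the two cluster means (a multimeric complex contributes the minimum of its
subunit means and requires every subunit to pass the 10% rule); significance
is the proportion of globally label-permuted datasets whose score is equal to
or above the observed one. Both directions of each cluster pair are scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scimmune.io import NormalizedMatrix


@dataclass(frozen=True)
class LRPair:
    name: str
    ligand: tuple  # subunit gene symbols
    receptor: tuple

    def __post_init__(self):
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and receptor must be non-empty gene sets")


#: Interaction axes relevant to chemoimmunotherapy response: DC/Treg chemokine
#: recruitment (CCL22/CCL17-CCR4), lymphoid homing (CCL19-CCR7), NK/T-cell
#: support (IL15 trans-presentation), and checkpoint/costimulation
#: (PD-1, TIGIT/CD226-NECTIN2, CD80-PD-L1).
BUILTIN_PAIRS = (
    LRPair("CCL22_CCR4", ("CCL22",), ("CCR4",)),
    LRPair("CCL17_CCR4", ("CCL17",), ("CCR4",)),
    LRPair("CCL19_CCR7", ("CCL19",), ("CCR7",)),
    LRPair("IL15_IL15R", ("IL15",), ("IL2RB", "IL2RG")),
    LRPair("PDCD1_CD274", ("PDCD1",), ("CD274",)),
    LRPair("PDCD1_PDCD1LG2", ("PDCD1",), ("PDCD1LG2",)),
    LRPair("CD226_NECTIN2", ("CD226",), ("NECTIN2",)),
    LRPair("TIGIT_NECTIN2", ("TIGIT",), ("NECTIN2",)),
    LRPair("CD80_CD274", ("CD80",), ("CD274",)),
)


def read_pairs(path) -> tuple:
    """Read pairs from a delimited table: pair, ligand_subunits, receptor_subunits
    (';'-separated subunits)."""
    df = pd.read_csv(path, sep=None, engine="python")
    needed = {"pair", "ligand_subunits", "receptor_subunits"}
    if not needed.issubset(df.columns):
        raise ValueError(f"pair table must have columns {sorted(needed)}")
    return tuple(
        LRPair(
            r["pair"],
            tuple(str(r["ligand_subunits"]).split(";")),
            tuple(str(r["receptor_subunits"]).split(";")),
        )
        for _, r in df.iterrows()
    )


def expressed_fraction(norm: NormalizedMatrix, labels: pd.Series, gene: str, cluster) -> float:
    """Fraction of the cluster's cells with normalized expression > 0."""
    labels = pd.Series(labels).reindex(norm.cells)
    mask = (labels == cluster).to_numpy()
    if not mask.any():
        raise ValueError(f"cluster {cluster!r} is empty or unknown")
    gi = norm.genes.get_indexer([gene])
    if gi[0] < 0:
        raise KeyError(f"unknown gene {gene!r}")
    row = norm.values[gi[0], :].toarray().ravel()
    return float((row[mask] > 0).mean())


def entity_mean(
    norm: NormalizedMatrix,
    labels: pd.Series,
    entity,
    cluster,
    min_frac: float = 0.1,
) -> tuple[float, bool]:
    """(mean expression, expressed?) of a gene or complex within a cluster.

    A complex takes the minimum of its subunit cluster means and counts as
    expressed only when every subunit individually passes the ``min_frac``
    rule; a single gene needs only itself to pass.
    """
    subunits = (entity,) if isinstance(entity, str) else tuple(entity)
    means, fracs = [], []
    for g in subunits:
        means.append(_cluster_mean(norm, labels, g, cluster))
        fracs.append(expressed_fraction(norm, labels, g, cluster))
    return float(min(means)), bool(all(f > min_frac for f in fracs))


def _cluster_mean(norm, labels, gene, cluster) -> float:
    labels = pd.Series(labels).reindex(norm.cells)
    mask = (labels == cluster).to_numpy()
    gi = norm.genes.get_indexer([gene])
    if gi[0] < 0:
        raise KeyError(f"unknown gene {gene!r}")
    row = norm.values[gi[0], :].toarray().ravel()
    return float(row[mask].mean())


def score_interactions(
    norm: NormalizedMatrix,
    labels: pd.Series,
    pairs=BUILTIN_PAIRS,
    n_perm: int = 1000,
    seed=None,
    min_frac: float = 0.1,
    min_cells: int = 5,
    pseudocount: bool = False,
) -> pd.DataFrame:
    """Score every ordered cluster pair x L-R pair.

    ``tested`` is False when the 10% rule excludes the combination (no p is
    reported there). ``mean_score`` is (ligand mean in a + receptor mean in
    b)/2 with the min-subunit rule for complexes. The null permutes cluster
    labels globally across all cells ``n_perm`` times; p is the proportion of
    permuted scores >= observed (optionally the (k+1)/(n+1) estimator with
    ``pseudocount=True``). Deterministic given ``seed``.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    labels = pd.Series(labels).reindex(norm.cells).dropna()
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    sizes = labels.value_counts()
    if (sizes < min_cells).any():
        small = sizes[sizes < min_cells]
        raise ValueError(f"every cluster needs >= {min_cells} cells; too small: {dict(small)}")

    genes_needed = sorted({g for p in pairs for g in (*p.ligand, *p.receptor)})
    missing = [g for g in genes_needed if g not in norm.genes]
    if missing:
        raise KeyError(f"gene(s) absent from the data: {missing[:5]}")
    cell_idx = norm.cells.get_indexer(labels.index)
    expr = norm.dense(genes=genes_needed, cells_idx=cell_idx)  # genes x cells
    gpos = {g: i for i, g in enumerate(genes_needed)}
    codes = pd.Categorical(labels, categories=clusters).codes
    k = len(clusters)
    n_cells = expr.shape[1]
    onehot = np.zeros((k, n_cells))
    onehot[codes, np.arange(n_cells)] = 1.0
    csize = onehot.sum(axis=1)[:, None]

    def cluster_means(oh):
        return (oh @ expr.T) / csize  # k x genes

    means = cluster_means(onehot)
    fracs = (onehot @ (expr.T > 0)) / csize

    def entity_stats(subunits):
        idx = [gpos[g] for g in subunits]
        m = means[:, idx].min(axis=1)
        ok = (fracs[:, idx] > min_frac).all(axis=1)
        return m, ok, idx

    lig_stats = [entity_stats(p.ligand) for p in pairs]
    rec_stats = [entity_stats(p.receptor) for p in pairs]

    # observed scores and tested mask: (k clusters a) x (k clusters b) x pairs
    lig_m = np.stack([s[0] for s in lig_stats], axis=1)  # k x P
    rec_m = np.stack([s[0] for s in rec_stats], axis=1)
    lig_ok = np.stack([s[1] for s in lig_stats], axis=1)
    rec_ok = np.stack([s[1] for s in rec_stats], axis=1)
    obs = 0.5 * (lig_m[:, None, :] + rec_m[None, :, :])
    tested = lig_ok[:, None, :] & rec_ok[None, :, :]

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    lig_idx = [s[2] for s in lig_stats]
    rec_idx = [s[2] for s in rec_stats]
    for _ in range(n_perm):
        perm = rng.permutation(n_cells)
        pm = (onehot[:, perm] @ expr.T) / csize
        plig = np.stack([pm[:, ix].min(axis=1) for ix in lig_idx], axis=1)
        prec = np.stack([pm[:, ix].min(axis=1) for ix in rec_idx], axis=1)
        score = 0.5 * (plig[:, None, :] + prec[None, :, :])
        exceed += score >= obs
    if pseudocount:
        pvals = (exceed + 1.0) / (n_perm + 1.0)
    else:
        pvals = exceed / n_perm

    rows = []
    for ai, a in enumerate(clusters):
        for bi, b in enumerate(clusters):  # self-pairs kept (autocrine signalling)
            for pi, p in enumerate(pairs):
                t = bool(tested[ai, bi, pi])
                rows.append(
                    {
                        "cluster_a": a,
                        "cluster_b": b,
                        "pair": p.name,
                        "mean_score": float(obs[ai, bi, pi]),
                        "p": float(pvals[ai, bi, pi]) if t else np.nan,
                        "tested": t,
                    }
                )
    return pd.DataFrame(rows)


def dotplot_matrices(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dot-plot-ready (pair x directed-cluster-pair) matrices of p and mean score."""
    res = results.copy()
    res["direction"] = res["cluster_a"].astype(str) + ">" + res["cluster_b"].astype(str)
    pmat = res.pivot(index="pair", columns="direction", values="p")
    smat = res.pivot(index="pair", columns="direction", values="mean_score")
    return pmat, smat
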