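"""Immune gene-signature enrichment by a weighted Kolmogorov-Smirnov running sum.

Three built-in signatures: the T follicular helper (Tfh) program, the
12-chemokine tertiary-lymphoid-structure signature, and CXCL13 alone. Genes
are ranked by the difference of group means of normalized expression; the
enrichment score is the signed maximum deviation of the running sum (hit
increments weighted by |score|, miss decrements uniform). Significance comes
from cell-label permutations; after BH adjustment, scores with adjusted
p > 0.05 are displayed as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from scimmune.io import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple

    def __post_init__(self):
        if not self.genes:
            raise ValueError("signature gene list must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")


BUILTIN_SIGNATURES = {
    "Tfh": GeneSignature(
        "Tfh",
        ("CXCL13", "CD200", "FBLN7", "ICOS", "SGPP2", "SH2D1A", "TIGIT", "PDCD1"),
    ),
    "chemokine12": GeneSignature(
        "chemokine12",
        (
            "CCL2", "CCL3", "CCL4", "CCL5", "CCL8", "CCL18",
            "CCL19", "CCL21", "CXCL9", "CXCL10", "CXCL11", "CXCL13",
        ),
    ),
    "CXCL13": GeneSignature("CXCL13", ("CXCL13",)),
}


def read_gmt(path) -> dict[str, GeneSignature]:
    """Read named gene lists from GMT (name <tab> description <tab> genes...)."""
    sigs = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sigs[parts[0]] = GeneSignature(parts[0], tuple(parts[2:]))
    return sigs


def write_gmt(signatures: dict[str, GeneSignature], path) -> Path:
    path = Path(path)
    lines = ["\t".join([s.name, "scimmune"] + list(s.genes)) for s in signatures.values()]
    path.write_text("\n".join(lines) + "\n")
    return path


def rank_genes(norm: NormalizedMatrix, cells_in, cells_out) -> pd.DataFrame:
    """Genes scored by difference of group means, sorted descending.

    Ties are broken by gene name so the ranking is deterministic.
    """
    in_idx = norm.cells.get_indexer(pd.Index(cells_in))
    out_idx = norm.cells.get_indexer(pd.Index(cells_out))
    if len(in_idx) == 0 or len(out_idx) == 0:
        raise ValueError("both cell sets must be non-empty")
    if np.any(in_idx < 0) or np.any(out_idx < 0):
        raise KeyError("unknown barcode in group definition")
    v = norm.values.tocsc()
    mean_in = np.asarray(v[:, in_idx].mean(axis=1)).ravel()
    mean_out = np.asarray(v[:, out_idx].mean(axis=1)).ravel()
    df = pd.DataFrame({"gene": norm.genes, "score": mean_in - mean_out})
    return df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )


def _es_from_sorted(hit_sorted: np.ndarray, absscore_sorted: np.ndarray, weight: float) -> np.ndarray:
    """Enrichment scores for rows of already rank-ordered hit masks/|scores|.

    Vectorized over the leading axis; used by both the public scalar API and
    the permutation machinery.
    """
    n = hit_sorted.shape[-1]
    nh = hit_sorted.sum(axis=-1, keepdims=True)
    if np.any(nh == 0):
        raise ValueError("signature has zero overlap with the ranked gene universe")
    w = np.where(hit_sorted, absscore_sorted**weight, 0.0)
    denom = w.sum(axis=-1, keepdims=True)
    # all hit scores zero: fall back to uniform hit increments
    w = np.where(denom > 0, w / np.where(denom > 0, denom, 1.0), hit_sorted / nh)
    n_miss = n - nh
    miss = np.where(
        ~hit_sorted.astype(bool), 1.0 / np.where(n_miss > 0, n_miss, 1), 0.0
    )
    running = np.cumsum(w - miss, axis=-1)
    idx = np.abs(running).argmax(axis=-1)
    return np.take_along_axis(running, idx[..., None], axis=-1)[..., 0]


def enrichment_score(ranked: pd.DataFrame, signature: GeneSignature, weight: float = 1.0) -> float:
    """Signed maximum deviation of the weighted running sum over ``ranked``.

    ``ranked`` must have 'gene' and 'score' columns ordered best-to-worst (as
    produced by :func:`rank_genes`).
    """
    genes = ranked["gene"].to_numpy()
    hit = np.isin(genes, list(signature.genes))
    absscore = np.abs(ranked["score"].to_numpy(dtype=float))
    es = float(_es_from_sorted(hit[None, :], absscore[None, :], weight)[0])
    return es


def _present_signature(sig: GeneSignature, universe: pd.Index) -> GeneSignature:
    present = tuple(g for g in sig.genes if g in universe)
    if not present:
        raise ValueError(f"signature {sig.name!r} has no genes in the data")
    if len(present) < len(sig.genes):
        dropped = sorted(set(sig.genes) - set(present))
        logger.warning("signature %s: dropping absent genes %s", sig.name, dropped)
    return GeneSignature(sig.name, present)


def gsea(
    norm: NormalizedMatrix,
    groups: pd.Series,
    signatures=None,
    n_perm: int = 1000,
    seed=None,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Enrichment of each signature in each group versus all other cells.

    Per (signature, group) cell: enrichment score, permutation p (proportion of
    label permutations whose \\|es\\| >= \\|observed\\|), BH-adjusted p over the
    whole table, and the masked display value (es where p_adj <= 0.05, else 0).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        logger.warning("n_perm=%d is low; permutation p-values will be coarse", n_perm)
    if signatures is None:
        signatures = list(BUILTIN_SIGNATURES.values())
    groups = pd.Series(groups).reindex(norm.cells)
    labels = groups.dropna()
    group_names = sorted(labels.unique())
    sizes = labels.value_counts()
    small = sizes[sizes < 10]
    if len(small):
        raise ValueError(f"each group needs >= 10 cells; too small: {dict(small)}")

    # order genes by name once so stable argsort breaks score ties by name
    gene_order = np.argsort(norm.genes.to_numpy())
    genes_sorted = norm.genes.to_numpy()[gene_order]
    cell_idx = norm.cells.get_indexer(labels.index)
    dense = np.asarray(norm.values.tocsc()[:, cell_idx].todense())[gene_order, :]
    n_cells = dense.shape[1]
    sigs = [_present_signature(s, pd.Index(genes_sorted)) for s in signatures]
    hit_vecs = {s.name: np.isin(genes_sorted, list(s.genes)) for s in sigs}

    rng = np.random.default_rng(seed)
    label_arr = labels.to_numpy()
    rows = []
    for gname in group_names:
        in_mask = label_arr == gname
        n_in = int(in_mask.sum())
        # observed + permuted membership matrices, scored in one pass
        memberships = np.empty((n_perm + 1, n_cells), dtype=bool)
        memberships[0] = in_mask
        for k in range(n_perm):
            perm = rng.permutation(n_cells)
            memberships[k + 1] = False
            memberships[k + 1, perm[:n_in]] = True
        m = memberships.astype(np.float64)
        mean_in = m @ dense.T / n_in
        mean_out = (1.0 - m) @ dense.T / (n_cells - n_in)
        scores = mean_in - mean_out  # (n_perm+1) x genes, gene axis name-sorted
        order = np.argsort(-scores, axis=1, kind="stable")
        abs_sorted = np.abs(np.take_along_axis(scores, order, axis=1))
        for s in sigs:
            hit_sorted = hit_vecs[s.name][order]
            es_all = _es_from_sorted(hit_sorted, abs_sorted, weight)
            es_obs = float(es_all[0])
            p = float(np.mean(np.abs(es_all[1:]) >= abs(es_obs) - 1e-12))
            rows.append({"signature": s.name, "group": gname, "es": es_obs, "p": p})
    res = pd.DataFrame(rows)
    res["p_adj"] = multipletests(res["p"], method="fdr_bh")[1]
    res["display_value"] = np.where(res["p_adj"] <= 0.05, res["es"], 0.0)
    return res


def display_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Heatmap-ready signature x group matrix of masked enrichment scores."""
    return results.pivot(index="signature", columns="group", values="display_value")
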