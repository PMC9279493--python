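"""Differential expression between cell groups by Wilcoxon rank-sum.

Marker criteria follow the common single-cell convention: a natural-log fold
change threshold on de-logged group means, a p-value threshold (BH-adjusted by
default, raw optionally), and a minimum expressed fraction in at least one of
the two groups. Used for cluster markers, treatment-group DEGs, shared-vs-
resident clone DEGs and subset comparisons alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from scimmune.io import NormalizedMatrix

EXACT_MAX_N = 8


@dataclass(frozen=True)
class MarkerCriteria:
    min_lnfc: float = 0.25
    max_p: float = 0.05
    min_pct: float = 0.1
    #: pass rule uses BH-adjusted p when True, raw p when False
    use_adjusted: bool = True

    def validate(self) -> "MarkerCriteria":
        if self.min_lnfc < 0:
            raise ValueError("min_lnfc must be >= 0")
        if not 0 < self.max_p <= 1:
            raise ValueError("max_p must be in (0, 1]")
        if not 0 <= self.min_pct <= 1:
            raise ValueError("min_pct must be in [0, 1]")
        return self


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p by full enumeration of rank assignments (handles ties via midranks)."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    mu = ranks.sum() * nx / len(pooled)
    dev = abs(w_obs - mu)
    hits = 0
    total = 0
    for idx in combinations(range(len(pooled)), nx):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def rank_sum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have <= 8 observations; otherwise the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N:
        return _exact_rank_sum_p(x, y)
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _rank_sum_p_rows(xin: np.ndarray, xout: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p for genes x cells blocks."""
    n_in, n_out = xin.shape[1], xout.shape[1]
    if n_in <= EXACT_MAX_N and n_out <= EXACT_MAX_N:
        return np.array([_exact_rank_sum_p(a, b) for a, b in zip(xin, xout)])
    res = scipy.stats.mannwhitneyu(
        xin, xout, alternative="two-sided", method="asymptotic", axis=1
    )
    return np.atleast_1d(res.pvalue)


def _log_mean_expm1(block: np.ndarray) -> np.ndarray:
    """ln(mean(expm1(values)) + 1) per gene row."""
    return np.log1p(np.expm1(block).mean(axis=1))


def find_markers(
    norm: NormalizedMatrix,
    labels: pd.Series,
    target_group,
    reference_group="rest",
    criteria: MarkerCriteria = MarkerCriteria(),
) -> pd.DataFrame:
    """Marker genes of ``target_group`` against ``reference_group``.

    Genes are pre-filtered to max(pct_in, pct_out) > min_pct; the log fold
    change is computed on de-logged means, ln(mean(expm1)+1) in minus out; the
    p-value is the two-sided rank-sum test with BH adjustment over tested
    genes. Results are sorted by p then decreasing \\|lnfc\\|.
    """
    criteria.validate()
    labels = pd.Series(labels)
    labels = labels.reindex(norm.cells)
    present = set(labels.dropna().unique())
    if target_group not in present:
        raise ValueError(f"unknown target group {target_group!r}")
    in_mask = (labels == target_group).to_numpy()
    if reference_group == "rest":
        out_mask = ~in_mask & labels.notna().to_numpy()
    else:
        if reference_group not in present:
            raise ValueError(f"unknown reference group {reference_group!r}")
        out_mask = (labels == reference_group).to_numpy()
    if in_mask.sum() < 3 or out_mask.sum() < 3:
        raise ValueError("each group needs at least 3 cells")

    v = norm.values.tocsc()
    xin = np.asarray(v[:, np.flatnonzero(in_mask)].todense())
    xout = np.asarray(v[:, np.flatnonzero(out_mask)].todense())
    pct_in = (xin > 0).mean(axis=1)
    pct_out = (xout > 0).mean(axis=1)
    tested = np.maximum(pct_in, pct_out) > criteria.min_pct
    if not tested.any():
        return pd.DataFrame(
            columns=["gene", "lnfc", "p", "p_adj", "pct_in", "pct_out", "passing"]
        )
    xin, xout = xin[tested], xout[tested]
    lnfc = _log_mean_expm1(xin) - _log_mean_expm1(xout)
    p = _rank_sum_p_rows(xin, xout)
    p_adj = multipletests(p, method="fdr_bh")[1]
    p_rule = p_adj if criteria.use_adjusted else p
    res = pd.DataFrame(
        {
            "gene": norm.genes[tested],
            "lnfc": lnfc,
            "p": p,
            "p_adj": p_adj,
            "pct_in": pct_in[tested],
            "pct_out": pct_out[tested],
            "passing": (np.abs(lnfc) > criteria.min_lnfc) & (p_rule < criteria.max_p),
        }
    )
    res = res.sort_values(
        ["p", "lnfc"], key=lambda c: c if c.name == "p" else -c.abs(), kind="mergesort"
    ).reset_index(drop=True)
    return res


def find_all_markers(
    norm: NormalizedMatrix,
    labels: pd.Series,
    criteria: MarkerCriteria = MarkerCriteria(),
) -> pd.DataFrame:
    """Markers of every label against the rest, concatenated with a 'cluster' column."""
    out = []
    for lab in sorted(pd.Series(labels).dropna().unique()):
        res = find_markers(norm, labels, lab, "rest", criteria)
        res.insert(0, "cluster", lab)
        out.append(res)
    return pd.concat(out, ignore_index=True)
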