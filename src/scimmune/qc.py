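"""Per-cell quality control.

Cells are removed when they detect too few or too many genes (likely debris or
doublets), too few UMIs, or carry a high mitochondrial read fraction (stressed
or dying cells). All four rules use strict inequalities, so cells sitting
exactly on a threshold are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scimmune.io import CountMatrix

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid threshold or pipeline configuration."""


@dataclass(frozen=True)
class QCThresholds:
    min_genes: int = 200
    max_genes: int = 6000
    min_umi: int = 1000
    max_pct_mito: float = 10.0

    def validate(self) -> "QCThresholds":
        if not self.min_genes < self.max_genes:
            raise ConfigError("min_genes must be < max_genes")
        if self.min_umi <= 0:
            raise ConfigError("min_umi must be positive")
        if not 0 < self.max_pct_mito <= 100:
            raise ConfigError("max_pct_mito must be in (0, 100]")
        return self


def compute_qc_metrics(counts: CountMatrix, mito_flags=None) -> pd.DataFrame:
    """n_genes, n_umi and pct_mito per cell.

    ``pct_mito`` of an all-zero cell is defined as 0 (such cells fail the UMI
    rule regardless, and 0/0 is avoided).
    """
    mito = counts.mito_flags if mito_flags is None else np.asarray(mito_flags, dtype=bool)
    if mito.shape != (len(counts.genes),):
        raise ValueError("mito_flags length must equal the gene count")
    x = counts.counts
    n_genes = np.asarray((x > 0).sum(axis=0)).ravel()
    n_umi = np.asarray(x.sum(axis=0)).ravel()
    mito_umi = np.asarray(x[mito, :].sum(axis=0)).ravel() if mito.any() else np.zeros_like(n_umi)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_umi > 0, 100.0 * mito_umi / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {"n_genes": n_genes.astype(int), "n_umi": n_umi.astype(int), "pct_mito": pct},
        index=counts.cells,
    )


def filter_cells(metrics: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> pd.Series:
    """Boolean retention mask.

    A cell is retained iff NOT(n_genes < min_genes or n_genes > max_genes or
    n_umi < min_umi or pct_mito > max_pct_mito); boundary values pass.
    """
    thresholds.validate()
    m = metrics
    removed = (
        (m["n_genes"] < thresholds.min_genes)
        | (m["n_genes"] > thresholds.max_genes)
        | (m["n_umi"] < thresholds.min_umi)
        | (m["pct_mito"] > thresholds.max_pct_mito)
    )
    return (~removed).rename("retained")


def qc_summary(metrics: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> pd.Series:
    """Counts of cells failing each rule (not mutually exclusive) and retained."""
    thresholds.validate()
    m = metrics
    mask = filter_cells(metrics, thresholds)
    return pd.Series(
        {
            "n_cells": len(m),
            "low_genes": int((m["n_genes"] < thresholds.min_genes).sum()),
            "high_genes": int((m["n_genes"] > thresholds.max_genes).sum()),
            "low_umi": int((m["n_umi"] < thresholds.min_umi).sum()),
            "high_mito": int((m["pct_mito"] > thresholds.max_pct_mito).sum()),
            "retained": int(mask.sum()),
            "removed": int((~mask).sum()),
        },
        name="qc_summary",
    )
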