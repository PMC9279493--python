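"""Core data containers and readers/writers for the standard formats.

Counts travel as Matrix Market sparse matrices with delimited feature and
barcode tables (the 10x triplet layout); cell metadata and TCR contigs are
plain delimited tables. Barcodes are composite ``<patient>_<compartment>_<n>``
keys so that 10x barcode reuse across samples can never collide.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Closed vocabulary of tissue compartments: tumor, nearest non-cancer tissue,
#: draining lymph node, distal normal tissue, peripheral blood pre/post therapy.
COMPARTMENTS = ("T", "N", "LN", "D", "P0", "P1")
#: Treatment/response groups: treatment-naive, non-major-pathological-response,
#: major pathological response.
GROUPS = ("naive", "nonMPR", "MPR")
LINEAGES = ("CD4", "CD8", "other", "unknown")

MITO_PREFIX = "MT-"

_CDR3_RE = re.compile(r"^[ACGT]+$")


class FormatError(Exception):
    """A file does not conform to the expected on-disk format."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique()[:5].tolist()
        raise ValueError(f"duplicate {what} identifiers, e.g. {dups}")


@dataclass
class CountMatrix:
    """Sparse non-negative integer UMI counts, genes x cells.

    ``mito_flags`` marks mitochondrially encoded genes; by default genes whose
    symbol starts with ``MT-``.
    """

    genes: pd.Index
    cells: pd.Index
    counts: sp.csr_matrix
    mito_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, dtype=object, name="gene")
        self.cells = pd.Index(self.cells, dtype=object, name="barcode")
        _check_unique(self.genes, "gene")
        _check_unique(self.cells, "barcode")
        counts = sp.csr_matrix(self.counts)
        if counts.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if counts.nnz:
            data = counts.data
            if np.any(data < 0):
                raise ValueError("counts must be non-negative")
            if not np.issubdtype(data.dtype, np.integer):
                if not np.all(data == np.floor(data)):
                    raise ValueError("counts must be integral")
                counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        counts.eliminate_zeros()
        self.counts = counts
        if self.mito_flags is None:
            self.mito_flags = np.asarray(self.genes.str.startswith(MITO_PREFIX), dtype=bool)
        self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        if self.mito_flags.shape != (len(self.genes),):
            raise ValueError("mito_flags length must equal the gene count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_cells(self, mask_or_barcodes) -> "CountMatrix":
        """Column subset by boolean mask (cell order) or barcode sequence."""
        if isinstance(mask_or_barcodes, (np.ndarray, pd.Series)) and getattr(
            mask_or_barcodes, "dtype", None
        ) == bool:
            idx = np.flatnonzero(np.asarray(mask_or_barcodes))
        else:
            idx = self.cells.get_indexer(pd.Index(mask_or_barcodes))
            if np.any(idx < 0):
                raise KeyError("unknown barcode(s) in subset request")
        return CountMatrix(
            genes=self.genes,
            cells=self.cells[idx],
            counts=self.counts[:, idx],
            mito_flags=self.mito_flags,
        )


@dataclass
class NormalizedMatrix:
    """Log-transformed library-size-normalized expression on CountMatrix axes.

    Zero counts map to exactly zero and every value is finite, so sparsity is
    preserved.
    """

    genes: pd.Index
    cells: pd.Index
    values: sp.csr_matrix

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, dtype=object, name="gene")
        self.cells = pd.Index(self.cells, dtype=object, name="barcode")
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        if self.values.nnz and not np.all(np.isfinite(self.values.data)):
            raise ValueError("normalized values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self, genes=None, cells_idx=None) -> np.ndarray:
        """Dense block; ``genes`` by label, ``cells_idx`` by position."""
        v = self.values
        if genes is not None:
            gi = self.genes.get_indexer(pd.Index(genes))
            if np.any(gi < 0):
                missing = [g for g, i in zip(genes, gi) if i < 0]
                raise KeyError(f"unknown gene(s): {missing[:5]}")
            v = v[gi, :]
        if cells_idx is not None:
            v = v[:, cells_idx]
        return np.asarray(v.todense())


def lognormalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """value(g, c) = ln(1 + scale_factor * count(g, c) / total_umi(c)).

    Every retained cell must have positive total UMI; run QC filtering first.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = np.asarray(counts.counts.sum(axis=0)).ravel().astype(np.float64)
    if np.any(totals == 0):
        n0 = int((totals == 0).sum())
        raise ValueError(
            f"{n0} cell(s) have zero total UMI; apply QC filtering before normalization"
        )
    x = counts.counts.tocsc().astype(np.float64)
    # scale each column by scale_factor / total, then log1p on stored entries
    per_cell = np.repeat(scale_factor / totals, np.diff(x.indptr))
    x.data = np.log1p(x.data * per_cell)
    return NormalizedMatrix(genes=counts.genes, cells=counts.cells, values=x.tocsr())


# ---------------------------------------------------------------------------
# counts IO (Matrix Market + features/barcodes tables)

def read_counts(matrix_path, features_path, barcodes_path) -> CountMatrix:
    """Read a Matrix Market genes x cells matrix with its two axis tables."""
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # malformed MTX
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}") from exc
    features = pd.read_csv(features_path, sep="\t")
    barcodes = pd.read_csv(barcodes_path, sep="\t")
    if "gene" not in features.columns:
        raise FormatError(f"{features_path} lacks a 'gene' column")
    if "barcode" not in barcodes.columns:
        raise FormatError(f"{barcodes_path} lacks a 'barcode' column")
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix is {mat.shape} but features/barcodes tables have "
            f"{len(features)}/{len(barcodes)} rows"
        )
    mito = (
        features["mito"].astype(bool).to_numpy()
        if "mito" in features.columns
        else None
    )
    return CountMatrix(
        genes=pd.Index(features["gene"].astype(str)),
        cells=pd.Index(barcodes["barcode"].astype(str)),
        counts=sp.csr_matrix(mat),
        mito_flags=mito,
    )


def write_counts(cm: CountMatrix, directory) -> dict[str, Path]:
    """Write matrix.mtx + features.tsv + barcodes.tsv under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": d / "matrix.mtx",
        "features": d / "features.tsv",
        "barcodes": d / "barcodes.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), cm.counts.tocoo())
    pd.DataFrame({"gene": cm.genes, "mito": cm.mito_flags.astype(int)}).to_csv(
        paths["features"], sep="\t", index=False
    )
    pd.DataFrame({"barcode": cm.cells}).to_csv(paths["barcodes"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# cell metadata table

CELL_COLUMNS = ("patient", "compartment", "group", "cluster", "lineage")


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Check the per-cell metadata contract (closed vocabularies, unique barcodes)."""
    if cells.index.name != "barcode":
        if "barcode" in cells.columns:
            cells = cells.set_index("barcode")
        else:
            raise FormatError("cell table needs a 'barcode' column or index")
    _check_unique(cells.index, "barcode")
    for col in ("patient", "compartment", "group"):
        if col not in cells.columns:
            raise FormatError(f"cell table lacks required column '{col}'")
    bad_comp = set(cells["compartment"].unique()) - set(COMPARTMENTS)
    if bad_comp:
        raise ValueError(f"unknown compartment value(s): {sorted(bad_comp)}")
    bad_grp = set(cells["group"].unique()) - set(GROUPS)
    if bad_grp:
        raise ValueError(f"unknown group value(s): {sorted(bad_grp)}")
    if "lineage" in cells.columns:
        bad_lin = set(cells["lineage"].unique()) - set(LINEAGES)
        if bad_lin:
            raise ValueError(f"unknown lineage value(s): {sorted(bad_lin)}")
    for col in ("n_genes", "n_umi", "pct_mito"):
        if col in cells.columns and (cells[col] < 0).any():
            raise ValueError(f"QC column '{col}' must be non-negative")
    return cells


def read_cells(path) -> pd.DataFrame:
    return validate_cells(pd.read_csv(path, sep="\t", dtype={"barcode": str}))


def write_cells(cells: pd.DataFrame, path) -> Path:
    path = Path(path)
    cells.to_csv(path, sep="\t", index=True, float_format="%.10g")
    return path


# ---------------------------------------------------------------------------
# TCR contig table (10x filtered-contig CSV dialect)

CONTIG_COLUMNS = ("barcode", "chain", "cdr3_nt", "productive", "umis")

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", "none"}


def read_contigs(path) -> pd.DataFrame:
    """Read a filtered-contig CSV; one row per assembled TCR contig."""
    df = pd.read_csv(path, dtype={"barcode": str, "chain": str, "cdr3_nt": str})
    missing = [c for c in CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"contig table {path} lacks column(s) {missing}")
    bad = ~df["cdr3_nt"].astype(str).str.match(_CDR3_RE)
    if bad.any():
        example = df.loc[bad, "cdr3_nt"].iloc[0]
        raise ValueError(f"cdr3_nt must be over ACGT; offending value {example!r}")

    def _parse_bool(v) -> bool:
        s = str(v).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE:
            return False
        raise ValueError(f"cannot parse productivity flag {v!r}")

    df["productive"] = df["productive"].map(_parse_bool)
    df["umis"] = pd.to_numeric(df["umis"])
    if (df["umis"] < 0).any():
        raise ValueError("umis must be non-negative")
    return df[list(CONTIG_COLUMNS)].copy()


def write_contigs(contigs: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = contigs[list(CONTIG_COLUMNS)].copy()
    out["productive"] = out["productive"].map({True: "True", False: "False"})
    out.to_csv(path, index=False)
    return path
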