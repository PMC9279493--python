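"""Seeded synthetic multi-compartment cohort generator with full ground truth.

Emulates a 12-patient neoadjuvant chemoimmunotherapy cohort (4 treatment-naive
/ 4 non-MPR / 4 MPR patients) profiled across up to six tissue compartments
(tumor T, nearest non-cancer N, draining lymph node LN, distal normal D,
peripheral blood P0/P1; naive patients lack the pre/post blood draws).

Counts are negative-binomial (gamma-Poisson) with lognormal gene weights and
per-cell lognormal depth; each cluster carries planted marker genes at a fixed
fold; one gene signature is shifted in a designated response group's tumor
cells; mitochondrial genes are generated to hit a per-cell Beta-drawn
mitochondrial fraction in expectation; a ligand-receptor axis is planted
between two clusters. T cells receive clonotypes per lineage with the study's
TCR coverage (75.09% of CD4, 68.64% of CD8 cells), geometric clone sizes per
compartment/lineage, explicit cross-compartment shared clones, and one
hyper-expanded clone per treated patient in the cytotoxic CD8 cluster. Every
planted signal is recorded in a GroundTruth mapping; regeneration from the
same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from scimmune.io import (
    COMPARTMENTS,
    CountMatrix,
    read_cells,
    read_contigs,
    read_counts,
    write_cells,
    write_contigs,
    write_counts,
)
from scimmune.qc import ConfigError
from scimmune.signatures import BUILTIN_SIGNATURES
from scimmune.interactions import BUILTIN_PAIRS

MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-ND4", "MT-ND5", "MT-CO1",
    "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB",
)

_NT = np.array(list("ACGT"))


def _default_cluster_props():
    # cluster mixture per response group; MPR enriched for the cytotoxic CD8
    # cluster C3 and B/myeloid (C6) reduced, echoing post-therapy remodelling
    return {
        "naive": (0.20, 0.10, 0.12, 0.13, 0.15, 0.30),
        "nonMPR": (0.22, 0.12, 0.16, 0.12, 0.13, 0.25),
        "MPR": (0.20, 0.12, 0.20, 0.12, 0.13, 0.23),
    }


def _default_clone_geom():
    # geometric clone-size parameter per (lineage, compartment); smaller p =>
    # larger clones. CD8 repertoires are expanded everywhere and most of all in
    # post-therapy blood (P1); CD4 repertoires stay near-diverse.
    geom = {}
    for comp in COMPARTMENTS:
        geom[("CD4", comp)] = 0.85
    geom.update(
        {
            ("CD8", "T"): 0.55,
            ("CD8", "N"): 0.60,
            ("CD8", "LN"): 0.70,
            ("CD8", "D"): 0.65,
            ("CD8", "P0"): 0.70,
            ("CD8", "P1"): 0.35,
        }
    )
    return geom


def _default_shared_clones():
    # planted shared clones per treated patient per compartment pair;
    # CD8 clones cross compartments more than CD4 (tumor<->blood, tumor<->N)
    return {
        ("T", "P1"): {"CD8": 2, "CD4": 0},
        ("T", "N"): {"CD8": 2, "CD4": 0},
        ("T", "LN"): {"CD8": 1, "CD4": 0},
        ("T", "D"): {"CD8": 1, "CD4": 1},
        ("P0", "P1"): {"CD8": 3, "CD4": 1},
    }


@dataclass
class CohortConfig:
    n_patients: int = 12
    group_sizes: dict = field(
        default_factory=lambda: {"naive": 4, "nonMPR": 4, "MPR": 4}
    )
    compartments: dict = field(
        default_factory=lambda: {
            "naive": ("T", "N", "LN", "D"),
            "nonMPR": COMPARTMENTS,
            "MPR": COMPARTMENTS,
        }
    )
    cells_per_sample: int = 75
    n_genes: int = 500
    cluster_names: tuple = ("C1", "C2", "C3", "C4", "C5", "C6")
    cluster_lineage: dict = field(
        default_factory=lambda: {
            "C1": "CD4", "C2": "CD4", "C3": "CD8", "C4": "CD8", "C5": "CD8", "C6": "other",
        }
    )
    cluster_props: dict = field(default_factory=_default_cluster_props)
    markers_per_cluster: int = 20
    marker_fold: float = 2.0
    #: (signature name, response group, fold); applied in tumor cells of the group
    signature_shift: tuple = ("Tfh", "MPR", 3.0)
    #: planted interaction axis: ligand genes up in one cluster, receptor in another
    lr_axis: dict = field(
        default_factory=lambda: {
            "pair": "CCL19_CCR7",
            "ligand_cluster": "C6",
            "receptor_cluster": "C1",
            "fold": 8.0,
        }
    )
    nb_dispersion: float = 0.3
    target_depth: float = 2500.0
    depth_sigma: float = 0.2
    mito_beta: tuple = (20.0, 480.0)  # mean 4% mitochondrial fraction, sd ~0.9pp
    frac_low_depth: float = 0.02  # planted QC violators: debris-like cells
    frac_high_mito: float = 0.02  # planted QC violators: dying cells
    tcr_coverage: dict = field(default_factory=lambda: {"CD4": 0.7509, "CD8": 0.6864})
    clone_geom: dict = field(default_factory=_default_clone_geom)
    shared_clones: dict = field(default_factory=_default_shared_clones)
    expanded_clone: dict = field(
        default_factory=lambda: {
            "cluster": "C3", "lineage": "CD8", "compartment": "P1", "size": 12,
        }
    )
    cdr3_len: tuple = (30, 45)
    chain_dropout: float = 0.1  # clone-level probability of a TRB-only clonotype
    decoy_duplicate_rate: float = 0.05
    decoy_nonproductive_rate: float = 0.05
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if sum(self.group_sizes.values()) != self.n_patients:
            raise ConfigError("group sizes must sum to n_patients")
        n_special = len(self._special_genes()) + len(MITO_GENES)
        n_markers = self.markers_per_cluster * len(self.cluster_names)
        if n_special + n_markers > self.n_genes:
            raise ConfigError(
                f"n_genes={self.n_genes} too small for {n_markers} marker genes "
                f"plus {n_special} signature/receptor/mitochondrial genes"
            )
        for grp, props in self.cluster_props.items():
            if len(props) != len(self.cluster_names):
                raise ConfigError(f"cluster_props[{grp}] length mismatch")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ConfigError(f"cluster_props[{grp}] must sum to 1")
        for v in (*self.tcr_coverage.values(), self.frac_low_depth, self.frac_high_mito,
                  self.chain_dropout):
            if not 0 <= v <= 1:
                raise ConfigError("probabilities must be in [0, 1]")
        if self.nb_dispersion <= 0 or self.target_depth <= 0:
            raise ConfigError("nb_dispersion and target_depth must be positive")
        return self

    def _special_genes(self) -> list:
        sig = sorted({g for s in BUILTIN_SIGNATURES.values() for g in s.genes})
        lr = sorted({g for p in BUILTIN_PAIRS for g in (*p.ligand, *p.receptor)})
        return sorted(set(sig) | set(lr))


@dataclass
class SyntheticCohort:
    counts: CountMatrix
    cells: pd.DataFrame
    contigs: pd.DataFrame
    truth: dict
    config: CohortConfig


def _canonical_key(chains: dict) -> str:
    return ";".join(sorted(f"{ch}:{nt}" for ch, nt in chains.items() if nt))


class _Cdr3Factory:
    """Unique random CDR3 nucleotide strings."""

    def __init__(self, rng, length_range):
        self.rng = rng
        self.lo, self.hi = length_range
        self.used: set = set()

    def new(self) -> str:
        while True:
            ln = int(self.rng.integers(self.lo, self.hi + 1))
            s = "".join(_NT[self.rng.integers(0, 4, size=ln)])
            if s not in self.used:
                self.used.add(s)
                return s


def generate_cohort(config: CohortConfig = CohortConfig()) -> SyntheticCohort:
    """Generate a full cohort (counts, cell metadata, contigs) plus ground truth."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    clusters = list(cfg.cluster_names)

    # --- gene universe -----------------------------------------------------
    special = cfg._special_genes()
    marker_genes = {
        cl: [f"MK-{cl}-{j + 1:02d}" for j in range(cfg.markers_per_cluster)]
        for cl in clusters
    }
    flat_markers = [g for cl in clusters for g in marker_genes[cl]]
    n_filler = cfg.n_genes - len(special) - len(MITO_GENES) - len(flat_markers)
    fillers = [f"FILLER{j + 1:04d}" for j in range(n_filler)]
    genes = pd.Index(special + flat_markers + fillers + list(MITO_GENES), name="gene")
    mito_flags = np.asarray(genes.str.startswith("MT-"), dtype=bool)

    base_w = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    # signature/receptor genes get reliably detectable baseline expression
    special_pos = genes.get_indexer(special)
    base_w[special_pos] = rng.lognormal(mean=0.7, sigma=0.3, size=len(special))

    # per-cluster multipliers: planted markers and the ligand-receptor axis
    mult = pd.DataFrame(1.0, index=genes, columns=clusters)
    for cl in clusters:
        mult.loc[marker_genes[cl], cl] = cfg.marker_fold
    if cfg.lr_axis:
        pair = {p.name: p for p in BUILTIN_PAIRS}[cfg.lr_axis["pair"]]
        mult.loc[list(pair.ligand), cfg.lr_axis["ligand_cluster"]] *= cfg.lr_axis["fold"]
        mult.loc[list(pair.receptor), cfg.lr_axis["receptor_cluster"]] *= cfg.lr_axis["fold"]
    sig_name, sig_group, sig_fold = cfg.signature_shift
    sig_genes = [g for g in BUILTIN_SIGNATURES[sig_name].genes if g in genes]

    # --- patients and cells ------------------------------------------------
    patients, groups_of = [], {}
    i = 1
    for grp, n in cfg.group_sizes.items():
        for _ in range(n):
            pid = f"PT{i:02d}"
            patients.append(pid)
            groups_of[pid] = grp
            i += 1

    cell_rows = []
    count_blocks = []
    qc_low, qc_high = [], []
    nonmito_w = np.where(mito_flags, 0.0, base_w)
    mito_w = np.where(mito_flags, base_w, 0.0)
    mito_w = mito_w / mito_w.sum()

    for pid in patients:
        grp = groups_of[pid]
        props = np.asarray(cfg.cluster_props[grp], dtype=float)
        for comp in cfg.compartments[grp]:
            n = cfg.cells_per_sample
            labels = rng.choice(clusters, size=n, p=props)
            barcodes = [f"{pid}_{comp}_{j + 1:04d}" for j in range(n)]
            n_low = int(round(cfg.frac_low_depth * n))
            n_high = int(round(cfg.frac_high_mito * n))
            bad = rng.choice(n, size=n_low + n_high, replace=False)
            low_idx, high_idx = bad[:n_low], bad[n_low:]
            depth = rng.lognormal(np.log(cfg.target_depth), cfg.depth_sigma, size=n)
            depth[low_idx] = rng.lognormal(np.log(300.0), 0.2, size=n_low)
            mfrac = rng.beta(*cfg.mito_beta, size=n)
            mfrac[high_idx] = rng.beta(20.0, 60.0, size=n_high)  # ~25% mito

            mu = np.empty((len(genes), n))
            for j in range(n):
                w = nonmito_w * mult[labels[j]].to_numpy()
                if grp == sig_group and comp == "T":
                    gi = genes.get_indexer(sig_genes)
                    w = w.copy()
                    w[gi] *= sig_fold
                w = w / w.sum() * (1.0 - mfrac[j])
                mu[:, j] = depth[j] * (w + mfrac[j] * mito_w)
            shape = 1.0 / cfg.nb_dispersion
            lam = rng.gamma(shape, mu * cfg.nb_dispersion)
            block = rng.poisson(lam)
            count_blocks.append(sp.csc_matrix(block))
            qc_low.extend(barcodes[k] for k in low_idx)
            qc_high.extend(barcodes[k] for k in high_idx)
            for j in range(n):
                cell_rows.append(
                    {
                        "barcode": barcodes[j],
                        "patient": pid,
                        "compartment": comp,
                        "group": grp,
                        "cluster": labels[j],
                        "lineage": cfg.cluster_lineage[labels[j]],
                    }
                )

    cells = pd.DataFrame(cell_rows).set_index("barcode")
    counts = CountMatrix(
        genes=genes,
        cells=pd.Index(cells.index),
        counts=sp.hstack(count_blocks).tocsr(),
        mito_flags=mito_flags,
    )

    # realized QC violations by an independent dense scan (thresholds are the
    # standard defaults); recorded so downstream filtering is checkable exactly
    dense = counts.counts.toarray()
    g_det = (dense > 0).sum(axis=0)
    umi = dense.sum(axis=0)
    with np.errstate(invalid="ignore"):
        pct = np.where(umi > 0, 100.0 * dense[mito_flags, :].sum(axis=0) / np.maximum(umi, 1), 0.0)
    violator_mask = (g_det < 200) | (g_det > 6000) | (umi < 1000) | (pct > 10.0)
    qc_violators = [b for b, v in zip(cells.index, violator_mask) if v]
    del dense

    # --- clonotypes ---------------------------------------------------------
    # QC-failing cells carry no TCR so the clonal ground truth survives filtering
    planted_violators = set(qc_low) | set(qc_high) | set(qc_violators)
    tcr_positive = pd.Series(False, index=cells.index)
    for lineage, cov in cfg.tcr_coverage.items():
        sel = (cells["lineage"] == lineage) & ~cells.index.isin(planted_violators)
        draws = rng.random(int(sel.sum())) < cov
        tcr_positive.loc[sel[sel].index] = draws

    clone_of_cell: dict[str, int] = {}
    clone_meta: list[dict] = []  # lineage per clone

    def new_clone(lineage: str) -> int:
        clone_meta.append({"lineage": lineage})
        return len(clone_meta) - 1

    shared_truth: dict[tuple, dict] = {}
    expanded_ids: list[int] = []
    for pid in patients:
        grp = groups_of[pid]
        comps = cfg.compartments[grp]
        pools = {
            (lin, comp): list(
                cells.index[
                    (cells["patient"] == pid)
                    & (cells["compartment"] == comp)
                    & (cells["lineage"] == lin)
                    & tcr_positive
                ]
            )
            for lin in ("CD4", "CD8")
            for comp in comps
        }
        for pool in pools.values():
            rng.shuffle(pool)

        # hyper-expanded clone in the designated cluster (treated patients only,
        # since its compartment is post-therapy blood by default)
        exp = cfg.expanded_clone
        if exp and exp["compartment"] in comps:
            pool = pools[(exp["lineage"], exp["compartment"])]
            eligible = [b for b in pool if cells.at[b, "cluster"] == exp["cluster"]]
            take = eligible[: exp["size"]]
            if len(take) >= 2:
                cid = new_clone(exp["lineage"])
                expanded_ids.append(cid)
                for b in take:
                    clone_of_cell[b] = cid
                    pool.remove(b)

        # planted cross-compartment shared clones
        for (ca, cb), per_lineage in cfg.shared_clones.items():
            if ca not in comps or cb not in comps:
                continue
            for lin, k in per_lineage.items():
                for _ in range(k):
                    pa, pb = pools[(lin, ca)], pools[(lin, cb)]
                    if not pa or not pb:
                        continue
                    cid = new_clone(lin)
                    for pool in (pa, pb):
                        size = 1 + int(rng.binomial(2, 0.3))
                        for _ in range(min(size, len(pool))):
                            clone_of_cell[pool.pop()] = cid
                    shared_truth.setdefault((ca, cb), {}).setdefault(lin, []).append(cid)

        # remaining cells: compartment-private clones with geometric sizes
        for (lin, comp), pool in pools.items():
            p_geom = cfg.clone_geom[(lin, comp)]
            while pool:
                size = min(int(rng.geometric(p_geom)), len(pool))
                cid = new_clone(lin)
                for _ in range(size):
                    clone_of_cell[pool.pop()] = cid

    # --- CDR3 sequences and contig table -------------------------------------
    factory = _Cdr3Factory(rng, cfg.cdr3_len)
    clone_chains: dict[int, dict] = {}
    for cid in range(len(clone_meta)):
        chains = {"TRB": factory.new()}
        if rng.random() >= cfg.chain_dropout:
            chains["TRA"] = factory.new()
        clone_chains[cid] = chains

    contig_rows = []
    for barcode in cells.index:  # cell order => deterministic contig order
        cid = clone_of_cell.get(barcode)
        if cid is None:
            continue
        for ch, nt in sorted(clone_chains[cid].items()):
            contig_rows.append(
                {
                    "barcode": barcode,
                    "chain": ch,
                    "cdr3_nt": nt,
                    "productive": True,
                    "umis": int(4 + rng.poisson(3.0)),
                }
            )
            if rng.random() < cfg.decoy_duplicate_rate:
                contig_rows.append(
                    {
                        "barcode": barcode,
                        "chain": ch,
                        "cdr3_nt": factory.new(),
                        "productive": True,
                        "umis": int(1 + rng.integers(0, 3)),
                    }
                )
        if rng.random() < cfg.decoy_nonproductive_rate:
            contig_rows.append(
                {
                    "barcode": barcode,
                    "chain": str(rng.choice(["TRA", "TRB"])),
                    "cdr3_nt": factory.new(),
                    "productive": False,
                    "umis": int(1 + rng.poisson(2.0)),
                }
            )
    contigs = pd.DataFrame(
        contig_rows, columns=["barcode", "chain", "cdr3_nt", "productive", "umis"]
    )

    # --- ground truth ---------------------------------------------------------
    key_of = {cid: _canonical_key(ch) for cid, ch in clone_chains.items()}
    comp_clones: dict[str, set] = {}
    comp_lin_clones: dict[str, dict[str, set]] = {}
    for barcode, cid in clone_of_cell.items():
        comp = cells.at[barcode, "compartment"]
        lin = clone_meta[cid]["lineage"]
        comp_clones.setdefault(comp, set()).add(key_of[cid])
        comp_lin_clones.setdefault(lin, {}).setdefault(comp, set()).add(key_of[cid])

    truth = {
        "markers": marker_genes,
        "marker_fold": cfg.marker_fold,
        "signature_shift": {
            "signature": sig_name, "group": sig_group, "fold": sig_fold, "compartment": "T",
        },
        "lr_axis": dict(cfg.lr_axis) if cfg.lr_axis else None,
        "qc_planted": {"low_depth": qc_low, "high_mito": qc_high},
        "qc_violators": qc_violators,
        "qc_thresholds": {"min_genes": 200, "max_genes": 6000, "min_umi": 1000,
                          "max_pct_mito": 10.0},
        "clone_key_of_cell": {b: key_of[c] for b, c in clone_of_cell.items()},
        "clone_lineage": {key_of[c]: m["lineage"] for c, m in zip(range(len(clone_meta)), clone_meta)},
        "compartment_clones": {c: sorted(s) for c, s in comp_clones.items()},
        "compartment_clones_by_lineage": {
            lin: {c: sorted(s) for c, s in d.items()} for lin, d in comp_lin_clones.items()
        },
        "planted_shared": {
            f"{ca}|{cb}": {lin: sorted(key_of[c] for c in ids) for lin, ids in d.items()}
            for (ca, cb), d in shared_truth.items()
        },
        "expanded_clones": sorted(key_of[c] for c in expanded_ids),
        "expanded_cluster": cfg.expanded_clone["cluster"] if cfg.expanded_clone else None,
    }
    return SyntheticCohort(counts=counts, cells=cells, contigs=contigs, truth=truth, config=cfg)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Emit MTX + axis tables, cell metadata TSV, contig CSV and ground-truth JSON."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = write_counts(cohort.counts, d)
    paths["cells"] = write_cells(cohort.cells, d / "cells.tsv")
    paths["contigs"] = write_contigs(cohort.contigs, d / "contigs.csv")
    paths["truth"] = d / "truth.json"
    paths["truth"].write_text(json.dumps(_jsonable(cohort.truth), indent=1, sort_keys=True))
    paths["config"] = d / "config.json"
    paths["config"].write_text(
        json.dumps(_jsonable(dataclasses.asdict(cohort.config)), indent=1, sort_keys=True)
    )
    return paths


def read_cohort(directory) -> SyntheticCohort:
    """Round-trip a written cohort (truth and config reloaded as plain JSON)."""
    d = Path(directory)
    counts = read_counts(d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv")
    cells = read_cells(d / "cells.tsv")
    contigs = read_contigs(d / "contigs.csv")
    truth = json.loads((d / "truth.json").read_text())
    return SyntheticCohort(counts=counts, cells=cells, contigs=contigs, truth=truth, config=None)
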