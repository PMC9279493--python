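"""End-to-end orchestration: QC -> composition -> markers -> signatures ->
TCR repertoire -> ligand-receptor interactions, with a run manifest.

Clustering is deliberately not performed here: cluster labels are consumed
from the input cell table (or produced by a user-supplied external hook
command), because every downstream analysis is label-conditional and the
labelling procedure is interchangeable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import scimmune
from scimmune import interactions as lr
from scimmune import markers as mk
from scimmune import qc as qcmod
from scimmune import signatures as sig
from scimmune import tcr as tcrmod
from scimmune.io import (
    FormatError,
    lognormalize,
    read_cells,
    read_contigs,
    read_counts,
    write_cells,
)
from scimmune.simulate import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

# stable per-stage substream codes: toggling one stage never shifts another's draws
_STAGE_STREAMS = {"simulate": 1, "signatures": 2, "lr": 3}


class PipelineError(RuntimeError):
    """A stage failed; partial outputs up to that stage are preserved."""


@dataclass
class PipelineConfig:
    #: directory with matrix.mtx/features.tsv/barcodes.tsv/cells.tsv/contigs.csv,
    #: or None to simulate a cohort
    input_dir: str | None = None
    simulate: CohortConfig | None = None
    out_dir: str = "scimmune_out"
    thresholds: qcmod.QCThresholds = field(default_factory=qcmod.QCThresholds)
    criteria: mk.MarkerCriteria = field(default_factory=mk.MarkerCriteria)
    signature_file: str | None = None  # GMT; None -> built-ins
    pair_file: str | None = None  # L-R table; None -> built-ins
    n_perm_gsea: int = 1000
    n_perm_lr: int = 1000
    seed: int = 0
    #: shell command receiving a cells TSV path and printing barcode<TAB>cluster
    #: lines; None keeps the input cluster labels
    cluster_hook: str | None = None

    def validate(self) -> "PipelineConfig":
        if (self.input_dir is None) == (self.simulate is None):
            raise qcmod.ConfigError("exactly one of input_dir or simulate must be set")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise qcmod.ConfigError(f"input_dir {self.input_dir} does not exist")
        return self


def composition_table(cells: pd.DataFrame, groupby=("compartment", "group"), level="cluster") -> pd.DataFrame:
    """Cell counts and within-stratum proportions of ``level`` labels.

    Proportions sum to 1 within each stratum defined by ``groupby``.
    """
    if level not in cells.columns:
        raise ValueError(f"cell table lacks the '{level}' column")
    groupby = [g for g in groupby if g is not None]
    for g in groupby:
        if g not in cells.columns:
            raise ValueError(f"cell table lacks the '{g}' column")
    counts = (
        cells.groupby(groupby + [level], observed=True).size().rename("n_cells").reset_index()
    )
    totals = counts.groupby(groupby, observed=True)["n_cells"].transform("sum")
    counts["proportion"] = counts["n_cells"] / totals
    return counts


def _stage_seed(master: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master, _STAGE_STREAMS[stage]]))


def _write(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _apply_cluster_hook(cmd: str, cells: pd.DataFrame) -> pd.Series:
    with tempfile.TemporaryDirectory() as tmp:
        p = Path(tmp) / "cells.tsv"
        write_cells(cells, p)
        out = subprocess.run(
            f"{cmd} {p}", shell=True, check=True, capture_output=True, text=True
        ).stdout
    pairs = [line.split("\t") for line in out.strip().splitlines() if line.strip()]
    labels = pd.Series({b: c for b, c in pairs}, name="cluster")
    missing = cells.index.difference(labels.index)
    if len(missing):
        raise PipelineError(f"cluster hook returned no label for {len(missing)} cell(s)")
    return labels.reindex(cells.index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write one TSV/JSON per result type plus a manifest.

    Returns a dict of result objects keyed by stage. Reruns with the same
    config and seed produce byte-identical outputs.
    """
    cfg = config.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "scimmune",
        "version": scimmune.__version__,
        "seed": cfg.seed,
        "parameters": {
            "thresholds": dataclasses.asdict(cfg.thresholds),
            "criteria": dataclasses.asdict(cfg.criteria),
            "n_perm_gsea": cfg.n_perm_gsea,
            "n_perm_lr": cfg.n_perm_lr,
        },
        "stages": {},
    }
    results: dict = {}

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage %s ...", name)
                fn()
            except Exception as exc:
                _dump_manifest(manifest, out)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return deco

    state: dict = {}

    @stage("load")
    def _load():
        if cfg.simulate is not None:
            sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.simulate.seed)
            cohort = generate_cohort(sim_cfg)
            state.update(counts=cohort.counts, cells=cohort.cells, contigs=cohort.contigs)
            results["truth"] = cohort.truth
        else:
            d = Path(cfg.input_dir)
            state["counts"] = read_counts(d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv")
            state["cells"] = read_cells(d / "cells.tsv")
            cpath = d / "contigs.csv"
            state["contigs"] = read_contigs(cpath) if cpath.exists() else None
        manifest["stages"]["load"] = {"n_cells": int(state["counts"].shape[1]),
                                      "n_genes": int(state["counts"].shape[0])}

    @stage("qc")
    def _qc():
        metrics = qcmod.compute_qc_metrics(state["counts"])
        mask = qcmod.filter_cells(metrics, cfg.thresholds)
        summary = qcmod.qc_summary(metrics, cfg.thresholds)
        cells = state["cells"].join(metrics)
        _write(cells.join(mask), out / "qc_metrics.tsv", index=True)
        summary.to_frame().T.to_csv(out / "qc_summary.tsv", sep="\t", index=False)
        retained = mask[mask].index
        state["counts"] = state["counts"].subset_cells(retained)
        state["cells"] = cells.loc[retained]
        results["qc_mask"] = mask
        results["qc_summary"] = summary
        manifest["stages"]["qc"] = {
            "input": int(len(mask)), "retained": int(mask.sum()),
            "removed": int((~mask).sum()),
        }

    @stage("normalize")
    def _norm():
        state["norm"] = lognormalize(state["counts"])
        manifest["stages"]["normalize"] = {"scale_factor": 1e4}

    @stage("labels")
    def _labels():
        if cfg.cluster_hook:
            state["cells"]["cluster"] = _apply_cluster_hook(cfg.cluster_hook, state["cells"])
        if "cluster" not in state["cells"].columns or state["cells"]["cluster"].isna().all():
            raise FormatError("no cluster labels: supply them in cells.tsv or via cluster_hook")
        manifest["stages"]["labels"] = {
            "n_clusters": int(state["cells"]["cluster"].nunique()),
            "source": "hook" if cfg.cluster_hook else "input",
        }

    @stage("composition")
    def _composition():
        comp = composition_table(state["cells"], ("compartment", "group"), "cluster")
        _write(comp, out / "composition.tsv")
        results["composition"] = comp
        manifest["stages"]["composition"] = {"n_strata": int(len(comp.groupby(["compartment", "group"])))}

    @stage("markers")
    def _markers():
        res = mk.find_all_markers(state["norm"], state["cells"]["cluster"], cfg.criteria)
        _write(res, out / "markers.tsv")
        results["markers"] = res
        manifest["stages"]["markers"] = {"n_passing": int(res["passing"].sum())}

    @stage("signatures")
    def _signatures():
        sigs = list(sig.read_gmt(cfg.signature_file).values()) if cfg.signature_file else None
        tumor = state["cells"][state["cells"]["compartment"] == "T"]
        norm_t = _subset_norm(state["norm"], tumor.index)
        res = sig.gsea(
            norm_t, tumor["group"], signatures=sigs,
            n_perm=cfg.n_perm_gsea, seed=_stage_seed(cfg.seed, "signatures").integers(2**31),
        )
        _write(res, out / "gsea.tsv")
        _write(sig.display_matrix(res), out / "gsea_heatmap.tsv", index=True)
        results["gsea"] = res
        manifest["stages"]["signatures"] = {"n_significant": int((res["p_adj"] <= 0.05).sum())}

    @stage("tcr")
    def _tcr():
        if state.get("contigs") is None:
            manifest["stages"]["tcr"] = {"skipped": "no contig table"}
            return
        cells = state["cells"]
        ct = tcrmod.define_clonotypes(state["contigs"], cells)
        results["clonotypes"] = ct
        pd.DataFrame(
            {"clonotype_id": ct.assignments, "key": ct.assignments.map(ct.keys)}
        ).to_csv(out / "clonotypes.tsv", sep="\t", index=True, index_label="barcode")

        div = tcrmod.diversity_table(ct, cells)
        _write(div, out / "diversity.tsv")
        results["diversity"] = div
        pooled = tcrmod.diversity_table(ct, cells, by=("compartment", "lineage"))
        _write(pooled, out / "diversity_pooled.tsv")
        results["diversity_pooled"] = pooled

        comp_of = cells["compartment"]
        venn: dict = {}
        sharing_frames = []
        for lin in ("CD4", "CD8"):
            sub = ct.subset(cells.index[cells["lineage"] == lin])
            if sub.assignments.empty or comp_of.reindex(sub.barcodes()).nunique() < 2:
                continue
            ov = tcrmod.shared_clonotypes(sub, comp_of)
            venn[lin] = {
                "&".join(sorted(k)): v for k, v in sorted(
                    ov.region_counts.items(), key=lambda kv: "&".join(sorted(kv[0]))
                )
            }
            pw = ov.pairwise.copy()
            pw.insert(0, "lineage", lin)
            sharing_frames.append(pw)
        (out / "venn_regions.json").write_text(json.dumps(venn, indent=1, sort_keys=True))
        sharing = pd.concat(sharing_frames, ignore_index=True) if sharing_frames else pd.DataFrame()
        _write(sharing, out / "clone_sharing.tsv")
        results["venn"] = venn
        results["sharing"] = sharing

        matched = tcrmod.match_longitudinal(ct, comp_of, cells["patient"])
        _write(matched, out / "matched_P0_P1.tsv")
        results["matched"] = matched

        tumor_tcr = ct.barcodes()[comp_of.reindex(ct.barcodes()) == "T"]
        if len(tumor_tcr):
            part = tcrmod.partition_tumor_clones(ct, comp_of)
            part.to_frame().to_csv(out / "tumor_clone_partition.tsv", sep="\t",
                                   index=True, index_label="barcode")
            results["partition"] = part
            if part.nunique() == 2 and part.value_counts().min() >= 3:
                deg = mk.find_markers(
                    _subset_norm(state["norm"], part.index), part,
                    "shared_with_P1", "tumor_resident_only", cfg.criteria,
                )
                _write(deg, out / "shared_vs_resident_markers.tsv")
                results["shared_vs_resident"] = deg

        cd8 = cells.index[cells["lineage"] == "CD8"]
        sub = ct.subset(cd8)
        expa = tcrmod.startrac_expa(sub.assignments, cells["cluster"].reindex(sub.barcodes()))
        tran = tcrmod.startrac_tran(sub.assignments, cells["cluster"].reindex(sub.barcodes()))
        expa.to_frame().to_csv(out / "startrac_expa.tsv", sep="\t", index=True,
                               index_label="cluster", float_format="%.10g")
        tran.to_csv(out / "startrac_tran.tsv", sep="\t", index=True, float_format="%.10g")
        results["expa"] = expa
        results["tran"] = tran
        manifest["stages"]["tcr"] = {
            "n_tcr_cells": int(len(ct.assignments)),
            "n_clonotypes": int(len(ct.keys)),
        }

    @stage("lr")
    def _lr():
        pairs = lr.read_pairs(cfg.pair_file) if cfg.pair_file else lr.BUILTIN_PAIRS
        res = lr.score_interactions(
            state["norm"], state["cells"]["cluster"], pairs,
            n_perm=cfg.n_perm_lr, seed=_stage_seed(cfg.seed, "lr").integers(2**31),
        )
        _write(res, out / "lr_interactions.tsv")
        pmat, smat = lr.dotplot_matrices(res)
        _write(pmat, out / "lr_p_matrix.tsv", index=True)
        _write(smat, out / "lr_score_matrix.tsv", index=True)
        results["lr"] = res
        manifest["stages"]["lr"] = {
            "n_tested": int(res["tested"].sum()),
            "n_p_lt_05": int((res.loc[res["tested"], "p"] < 0.05).sum()),
        }

    _dump_manifest(manifest, out)
    results["manifest"] = manifest
    return results


def _subset_norm(norm, barcodes):
    from scimmune.io import NormalizedMatrix

    idx = norm.cells.get_indexer(pd.Index(barcodes))
    if np.any(idx < 0):
        raise KeyError("unknown barcode(s) in subset")
    return NormalizedMatrix(genes=norm.genes, cells=norm.cells[idx], values=norm.values[:, idx])


def _dump_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
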