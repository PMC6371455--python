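"""End-to-end orchestration of the analysis stages from one configuration.

Stages run in order exons -> psi -> dispersion -> features -> associate ->
predict -> categories, each reading the previous stage's tab-separated
outputs, so any suffix of the pipeline can be resumed from disk.  A manifest
records the resolved configuration, package version, seed, per-stage
wall-clock and the SHA-256 of every input and output file.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import categories as cat
from . import dispersion as disp
from . import features as feat
from . import io as sio
from . import prediction as pred
from . import psi as psimod
from .exons import filter_cassette_exons, read_cassette_exon_annotation

STAGES = ("exons", "psi", "dispersion", "features", "associate", "predict",
          "categories")


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration; thresholds default to the standard
    printed values (5-read/10-cell floors, 0.3/0.7 binarization, 900 bp fill
    window, 300 bp intron ends, 0.2/0.8 category bounds, FDR 0.05)."""

    gtf: str = ""
    fasta: str = ""
    conservation: str = ""
    counts: Dict[str, str] = field(default_factory=dict)       # state -> tsv
    methylation: Dict[str, str] = field(default_factory=dict)  # state -> dir
    out_dir: str = "scsplice_out"
    chrom_whitelist: Optional[List[str]] = None
    min_reads: int = 5
    min_cells: int = 10
    min_intron: int = 100
    min_exon: int = 50
    max_exon: int = 450
    min_tss_dist: int = 500
    fdr: float = 0.05
    fdr_method: str = "storey"
    dispersion_sims: int = 400
    cv_folds: int = 10
    cv_repeats: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class DependencyError(RuntimeError):
    pass


def _require(path: str, stage: str) -> str:
    if not path or not os.path.exists(path):
        raise DependencyError(f"stage '{stage}' requires missing input: {path!r}")
    return path


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Run the requested stages (default: all) and return the run manifest."""
    cfg = config
    stages = list(stages) if stages is not None else list(STAGES)
    os.makedirs(cfg.out_dir, exist_ok=True)
    out = lambda name: os.path.join(cfg.out_dir, name)
    states = sorted(cfg.counts) or ["A"]
    manifest = {
        "config": asdict(cfg), "seed": cfg.seed, "stages": {}, "hashes": {},
    }
    for p in [cfg.gtf, cfg.fasta, cfg.conservation, *cfg.counts.values()]:
        if p and os.path.exists(p):
            manifest["hashes"][p] = _sha256(p)

    genome = conservation = None
    if "exons" in stages or "features" in stages or "associate" in stages:
        _require(cfg.fasta, "exons/features")
        genome = sio.open_genome(cfg.fasta)
    if cfg.conservation and os.path.exists(cfg.conservation):
        conservation = sio.read_conservation_bedgraph(cfg.conservation)

    for stage in stages:
        t0 = time.time()
        if stage == "exons":
            candidates = read_cassette_exon_annotation(
                _require(cfg.gtf, stage), genome)
            kept = filter_cassette_exons(
                candidates, genome, cfg.chrom_whitelist,
                min_intron=cfg.min_intron, min_exon=cfg.min_exon,
                max_exon=cfg.max_exon, min_tss_dist=cfg.min_tss_dist)
            sio.write_exon_table(kept, out("exons.tsv"))
            manifest["stages"][stage] = {
                "candidates": len(candidates), "retained": len(kept)}

        elif stage == "psi":
            for state in states:
                counts = sio.read_count_table(_require(cfg.counts[state], stage))
                psi = psimod.compute_psi_matrix(counts, cfg.min_reads, cfg.min_cells)
                psi.psi.to_csv(out(f"psi_{state}.tsv"), sep="\t")
                psi.total_reads.to_csv(out(f"reads_{state}.tsv"), sep="\t")
                psimod.exon_summary(psi).to_csv(out(f"summary_{state}.tsv"), sep="\t")
            manifest["stages"][stage] = {"states": states}

        elif stage == "dispersion":
            for state in states:
                psi = _load_psi(out, state, stage)
                table = disp.evaluate_models(psi, n_sims=cfg.dispersion_sims,
                                             seed=cfg.seed)
                table.to_csv(out(f"dispersion_{state}.tsv"), sep="\t")
            manifest["stages"][stage] = {"n_sims": cfg.dispersion_sims}

        elif stage == "features":
            exons = sio.read_exon_table(_require(out("exons.tsv"), stage))
            gtable = feat.genomic_feature_table(exons, genome, conservation)
            gtable.to_csv(out("features_genomic.tsv"), sep="\t")
            for state in states:
                if state not in cfg.methylation:
                    continue
                calls = sio.read_methylation_dir(
                    _require(cfg.methylation[state], stage))
                idx = feat.MethylationIndex(calls)
                mean_tab = feat.methylation_feature_table(
                    exons, genome, idx, mode="mean")
                mean_tab.to_csv(out(f"features_meth_mean_{state}.tsv"), sep="\t")
                ctx_meth = feat.context_methylation_matrix(exons, genome, idx)
                ctx_meth.to_csv(out(f"context_meth_{state}.tsv"), sep="\t")
            feat.feature_manifest().to_csv(out("feature_manifest.tsv"),
                                           sep="\t", index=False)
            manifest["stages"][stage] = {"genomic_features": gtable.shape[1]}

        elif stage == "associate":
            results = {}
            for state in states:
                psi = _load_psi(out, state, stage)
                ctx_meth = pd.read_csv(
                    _require(out(f"context_meth_{state}.tsv"), stage),
                    sep="\t", index_col=[0, 1])
                res = assoc.methylation_splicing_association(
                    psi, ctx_meth, method=cfg.fdr_method)
                res.table.to_csv(out(f"association_{state}.tsv"),
                                 sep="\t", index=False)
                results[state] = res
                manifest["stages"].setdefault(stage, {})[state] = {
                    "tested": len(res.table),
                    "significant": int((res.table["q"] < cfg.fdr).sum()),
                }
            if len(states) == 2:
                rep = assoc.replication_assessment(results[states[0]],
                                                   results[states[1]], cfg.fdr)
                manifest["stages"][stage]["replication"] = rep

        elif stage == "predict":
            gtable = pd.read_csv(_require(out("features_genomic.tsv"), stage),
                                 sep="\t", index_col=0)
            for state in states:
                psi = _load_psi(out, state, stage)
                feats, target = build_single_cell_design(gtable, psi)
                spec = pred.ModelSpec(feature_set="genomic",
                                      folds=cfg.cv_folds,
                                      repeats=cfg.cv_repeats, seed=cfg.seed)
                cv = pred.cross_validated_ridge(feats, target, spec)
                cv.summary().to_csv(out(f"cv_genomic_{state}.tsv"),
                                    sep="\t", index=False)
                manifest["stages"].setdefault(stage, {})[state] = {
                    "r2_mean": cv.r2_mean, "r2_sd": cv.r2_sd}

        elif stage == "categories":
            fits = {}
            for state in states:
                summary = pd.read_csv(
                    _require(out(f"summary_{state}.tsv"), stage),
                    sep="\t", index_col=0)
                fit = cat.fit_expected_dispersion(summary["bpsi"],
                                                  summary["psi_sd"])
                assignments = cat.assign_categories(summary, fit)
                assignments.to_csv(out(f"categories_{state}.tsv"), sep="\t")
                fits[state] = assignments
                manifest["stages"].setdefault(stage, {})[state] = \
                    assignments["category"].value_counts().to_dict()
            if len(states) == 2:
                switch = cat.category_switch_table(fits[states[0]],
                                                   fits[states[1]])
                if switch["table"] is not None:
                    switch["table"].to_csv(out("switch_table.tsv"), sep="\t")
                manifest["stages"][stage]["retained_fraction"] = \
                    switch["retained_fraction"]
        else:
            raise ValueError(f"unknown stage {stage!r}")
        manifest["stages"].setdefault(stage, {})
        if isinstance(manifest["stages"][stage], dict):
            manifest["stages"][stage]["wall_clock_s"] = round(time.time() - t0, 3)

    for name in sorted(os.listdir(cfg.out_dir)):
        path = os.path.join(cfg.out_dir, name)
        if os.path.isfile(path) and name != "manifest.json":
            manifest["hashes"][path] = _sha256(path)
    with open(out("resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _load_psi(out, state: str, stage: str) -> psimod.PsiMatrix:
    psi_df = pd.read_csv(_require(out(f"psi_{state}.tsv"), stage),
                         sep="\t", index_col=0)
    reads_df = pd.read_csv(_require(out(f"reads_{state}.tsv"), stage),
                           sep="\t", index_col=0)
    return psimod.PsiMatrix(psi=psi_df, total_reads=reads_df)


def build_single_cell_design(
    exon_features: pd.DataFrame,
    psi: psimod.PsiMatrix,
    meth_features: Optional[pd.DataFrame] = None,
):
    """Pool (exon, cell) rows: exon-level features replicated per quantified
    cell, optionally joined with per-(exon, cell) methylation features."""
    long = psi.psi.stack().rename("psi")
    long.index.names = ["exon_id", "cell_id"]
    common = long.index.get_level_values("exon_id").isin(exon_features.index)
    long = long[common]
    X = exon_features.loc[long.index.get_level_values("exon_id")].set_index(long.index)
    if meth_features is not None:
        X = X.join(meth_features, how="inner")
        long = long.loc[X.index]
    return X, long
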