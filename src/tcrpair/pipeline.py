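"""End-to-end orchestration: simulate → filter → dedup → analyses → report.

Each stage's randomness derives from a single global seed through a
splittable scheme (a seed sequence keyed by the stage name), so adding or
toggling a stage never perturbs another stage's stream, and a run record
with config, seeds and output checksums is written alongside the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import association, classify, information, overlap, simulate
from .core import (
    Lineage,
    Scope,
    cells_to_frame,
    deduplicate,
    filter_cells,
    read_clonotype_table,
    write_exclusion_report,
    write_repertoires,
)

log = logging.getLogger("tcrpair")

ALL_STAGES = ("simulate", "overlap", "associate", "info", "classify", "annotate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name;
    stable across runs and independent between stages."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    output_dir: str = "tcrpair_run"
    seed: int = 0
    stages: Sequence[str] = ALL_STAGES
    input_path: str | None = None  # read cells from TSV instead of simulating
    annotation_path: str | None = None
    sim: simulate.SimConfig | None = None
    association_features: Sequence[str] = ("v_gene", "v_pair")
    info_features: Sequence[str] = ("v", "j", "length", "charge")
    info_estimator: str = "corrected"
    info_n_boot: int = 30
    classify_modes: Sequence[str] = ("alpha", "beta", "additive", "paired")
    classify_repeats: int = 2
    classify_config: classify.ModelConfig = field(default_factory=classify.ModelConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "sim" in d and d["sim"] is not None:
            d["sim"] = simulate.SimConfig.from_dict(d["sim"])
        if "classify_config" in d and isinstance(d["classify_config"], Mapping):
            d["classify_config"] = classify.ModelConfig(**d["classify_config"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest
    (also written to ``manifest.json`` in the output directory)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    stage = "input"
    try:
        # --- acquire cells -------------------------------------------------
        truth = None
        if config.input_path:
            cells, errors = read_clonotype_table(config.input_path)
            manifest["stages"]["input"] = {"n_cells": len(cells),
                                           "n_malformed": len(errors)}
        else:
            stage = "simulate"
            sim_cfg = config.sim or simulate.default_effect_config(
                seed=stage_seed(config.seed, "simulate"))
            cells, truth = simulate.generate_repertoire(sim_cfg)
            emit("cells.tsv", cells_to_frame(cells))
            manifest["stages"]["simulate"] = {
                "n_cells": len(cells), "seed": sim_cfg.seed}
        kept, report = filter_cells(cells)
        write_exclusion_report(report, outdir / "exclusions.json")
        written.append(outdir / "exclusions.json")
        reps = {scope: deduplicate(kept, scope) for scope in Scope}
        write_repertoires(reps[Scope.PAIRED], outdir / "clonotypes.tsv")
        written.append(outdir / "clonotypes.tsv")
        manifest["stages"]["filter"] = {"kept": len(kept), **dict(report)}

        cd4p, cd8p = reps[Scope.PAIRED][Lineage.CD4], reps[Scope.PAIRED][Lineage.CD8]

        # --- overlap -------------------------------------------------------
        if "overlap" in config.stages:
            stage = "overlap"
            rows = []
            for scope in Scope:
                r = overlap.overlap_summary(reps[scope][Lineage.CD4],
                                            reps[scope][Lineage.CD8])
                rows.append({"scope": scope.value, "jaccard": r.jaccard,
                             "overlap_percent": r.overlap_percent,
                             "n_shared": r.n_shared,
                             "n_cd4_only": r.n_cd4_only,
                             "n_cd8_only": r.n_cd8_only})
            emit("overlap.tsv", pd.DataFrame(rows))
            manifest["stages"]["overlap"] = {
                r["scope"]: r["overlap_percent"] for r in rows}

        # --- association ---------------------------------------------------
        if "associate" in config.stages:
            stage = "associate"
            sig_counts = {}
            for ft in config.association_features:
                if ft in association.SINGLE_FEATURES:
                    res_a = association.association_scan(
                        reps[Scope.ALPHA][Lineage.CD4],
                        reps[Scope.ALPHA][Lineage.CD8], ft)
                    res_b = association.association_scan(
                        reps[Scope.BETA][Lineage.CD4],
                        reps[Scope.BETA][Lineage.CD8], ft)
                    emit(f"assoc_{ft}_alpha.tsv", association.scan_to_frame(res_a))
                    emit(f"assoc_{ft}_beta.tsv", association.scan_to_frame(res_b))
                    sig_counts[ft] = sum(r.significant for r in res_a + res_b)
                else:
                    res = association.association_scan(cd4p, cd8p, ft)
                    emit(f"assoc_{ft}.tsv", association.scan_to_frame(res))
                    sig_counts[ft] = sum(r.significant for r in res)
            manifest["stages"]["associate"] = {"n_significant": sig_counts}

        # --- information ---------------------------------------------------
        if "info" in config.stages:
            stage = "info"
            profile = information.feature_info_profile(
                kept, feature_types=config.info_features,
                estimator=config.info_estimator,
                n_boot=config.info_n_boot,
                seed=stage_seed(config.seed, "info"))
            emit("info_profile.tsv", profile)
            manifest["stages"]["info"] = {
                row["feature_type"]: {"paired_bits": row["mi_paired"],
                                      "synergy_bits": row["synergy"]}
                for _, row in profile.iterrows()}

        # --- classification ------------------------------------------------
        if "classify" in config.stages:
            stage = "classify"
            ds = classify.prepare_dataset(cd4p, cd8p)
            results = [classify.cross_validate(
                ds, mode, config.classify_config,
                seed=stage_seed(config.seed, "classify"),
                n_repeats=config.classify_repeats)
                for mode in config.classify_modes]
            emit("classify_folds.tsv", pd.DataFrame({
                r.mode: r.fold_auc for r in results}))
            comparison = classify.compare_modes(results)
            emit("classify_comparison.tsv", comparison)
            manifest["stages"]["classify"] = {
                r.mode: {"auc": r.mean_auc, "sd": r.sd_auc} for r in results}

        # --- annotation ----------------------------------------------------
        if "annotate" in config.stages:
            stage = "annotate"
            if config.annotation_path:
                db = annotate_mod.load_annotation_db(config.annotation_path)
            elif truth is not None:
                ann = simulate.generate_annotation_db(
                    cells, config.sim or sim_cfg, truth,
                    seed=stage_seed(config.seed, "annotate"))
                emit("annotation_db.tsv", ann)
                db = annotate_mod.load_annotation_db(ann)
            else:
                raise ValueError("annotation stage needs annotation_path")
            report_c = annotate_mod.paired_concordance(
                pd.concat([cd4p.table, cd8p.table]), db)
            manifest["stages"]["annotate"] = dict(report_c.counts)
            emit("concordance_matrix.tsv",
                 report_c.species_matrix.reset_index())
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest["outputs"] = {str(p.name): _sha256(p) for p in written}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["outputs"] = {str(p.name): _sha256(p) for p in written}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
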