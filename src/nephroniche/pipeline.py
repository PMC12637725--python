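"""One-command orchestration of the full niche analysis.

``run_pipeline`` executes the stages in order — generate (or read) the
cohort, type cells, tile niches, cluster/annotate niches, composition
statistics, niche expression analytics, spatial crosstalk — writing every
stage's tables under the output directory and a machine-readable
``report.json`` with stage checksums, seeds and headline statistics.
Re-running with the same config and seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import catalogs, io
from .abundance import celltype_fold_changes, composition_model
from .cell_typing import DEFAULT_MIN_TRANSCRIPTS, apply_typing, \
    normalize_expression
from .cohort import Cohort
from .crosstalk import (fibrosis_adjacency, lr_condition_totals,
                        lr_interaction_strength, score_correlation,
                        transcript_attribution)
from .errors import ConfigurationError
from .expression import (differential_expression, fibrosis_signature,
                         gsea_preranked, module_score,
                         pseudobulk_area_normalized, rank_statistic)
from .niche_typing import type_niches
from .synthetic import CohortConfig, default_config, generate_cohort
from .tiling import (DEFAULT_COHERENCE_THRESHOLD, DEFAULT_MAX_EDGE_UM,
                     DEFAULT_TARGET_SIZE, tile_cohort)

logger = logging.getLogger(__name__)

STAGES = ("cohort", "cell_typing", "tiling", "niche_typing", "abundance",
          "expression", "crosstalk")

_KNOWN_KEYS = {
    "input_dir", "synthetic", "seed", "outdir", "min_transcripts",
    "max_edge_um", "target_size", "coherence_threshold", "n_boot", "n_perm",
    "stages",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Either ``input_dir`` (an on-disk cohort) or ``synthetic`` (overrides for
    the default cohort generator, possibly empty) must be provided.
    """

    outdir: str
    input_dir: str | None = None
    synthetic: dict[str, Any] | None = None
    seed: int = 0
    min_transcripts: int = DEFAULT_MIN_TRANSCRIPTS
    max_edge_um: float = DEFAULT_MAX_EDGE_UM
    target_size: int = DEFAULT_TARGET_SIZE
    coherence_threshold: float = DEFAULT_COHERENCE_THRESHOLD
    n_boot: int = 200
    n_perm: int = 200
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigurationError(
                f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ConfigurationError("config requires 'outdir'")
        cfg = cls(**{**raw, "stages": tuple(raw.get("stages", STAGES))})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.input_dir is None and self.synthetic is None:
            raise ConfigurationError(
                "config needs either 'input_dir' or a 'synthetic' block")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ConfigurationError(f"unknown stages: {sorted(bad)}")

    def cohort_config(self) -> CohortConfig:
        assert self.synthetic is not None
        return default_config(seed=self.seed, **self.synthetic)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | dict[str, Any]) -> dict[str, Any]:
    """Run all configured stages; returns the report dictionary."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "seed": config.seed,
        "stages": {},
        "headline": {},
        "config": {k: v for k, v in asdict(config).items()},
    }
    written: dict[str, list[str]] = {}
    current = "cohort"
    try:
        cohort = _stage_cohort(config, outdir, written)
        ctx: dict[str, Any] = {"cohort": cohort}
        for stage in STAGES[1:]:
            if stage not in config.stages:
                continue
            current = stage
            t0 = time.time()
            logger.info("stage %s: start", stage)
            _STAGE_FUNCS[stage](config, outdir, ctx, report, written)
            logger.info("stage %s: done in %.1fs", stage, time.time() - t0)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {current}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {current!r}") from exc
    for stage, files in written.items():
        report["stages"][stage] = {
            f: _sha256(outdir / f) for f in files}
    try:
        from importlib.metadata import version
        report["version"] = version("nephroniche")
    except Exception:            # pragma: no cover - metadata missing
        report["version"] = "unknown"
    (outdir / "report.json").write_text(json.dumps(report, indent=1,
                                                   sort_keys=True))
    return report


def _stage_cohort(config: PipelineConfig, outdir: Path,
                  written: dict[str, list[str]]) -> Cohort:
    if config.input_dir is not None:
        return io.read_cohort(config.input_dir)
    cohort = generate_cohort(config.cohort_config())
    io.write_cohort(cohort, outdir / "cohort")
    written["cohort"] = [f"cohort/{io.CELLS_FILE}",
                         f"cohort/{io.SAMPLES_FILE}"]
    return cohort


def _stage_cell_typing(config, outdir, ctx, report, written):
    cohort = ctx["cohort"]
    apply_typing(cohort, catalogs.CELL_TYPE_MARKERS,
                 min_transcripts=config.min_transcripts)
    path = outdir / "cells_typed.csv"
    cohort.cells.to_csv(path, index=False)
    written["cell_typing"] = [path.name]
    labels = cohort.cells.loc[cohort.cells["qc_pass"], "type_label"]
    report["headline"]["n_cell_types"] = int(labels.nunique())


def _stage_tiling(config, outdir, ctx, report, written):
    cohort = ctx["cohort"]
    niches = tile_cohort(cohort, max_edge_um=config.max_edge_um,
                         target_size=config.target_size,
                         coherence_threshold=config.coherence_threshold,
                         seed=config.seed)
    ctx["niches"] = niches
    path = outdir / "niche_assignment.csv"
    niches.assignment.rename_axis("cell_key").to_frame().to_csv(path)
    written["tiling"] = [path.name]
    report["headline"]["n_niches"] = int(len(niches.table))
    report["headline"]["mean_cells_per_niche"] = float(
        niches.table["n_cells"].mean())


def _stage_niche_typing(config, outdir, ctx, report, written):
    niches = ctx["niches"]
    type_niches(niches, catalogs.NICHE_TYPE_MARKERS,
                catalogs.IMMUNE_SUBTYPE_MARKERS, seed=config.seed)
    path = outdir / "niches.csv"
    niches.table.to_csv(path, index=False)
    geo = outdir / "niche_polygons.geojson"
    io.write_niche_polygons(niches, geo)
    written["niche_typing"] = [path.name, geo.name]
    report["headline"]["n_niche_clusters"] = int(
        niches.table["cluster"].nunique())
    report["headline"]["niche_types"] = sorted(
        niches.table["major_type"].unique().tolist())


def _stage_abundance(config, outdir, ctx, report, written):
    cohort, niches = ctx["cohort"], ctx["niches"]
    qc = cohort.cells["qc_pass"]
    folds = celltype_fold_changes(
        cohort.cells.loc[qc, "type_label"], cohort.cells.loc[qc, "sample_id"],
        cohort.samples, n_boot=config.n_boot, seed=config.seed)
    path = outdir / "celltype_folds.csv"
    folds.to_csv(path, index=False)
    imm = niches.table[niches.table["subtype"] != ""]
    comp = pd.crosstab(imm["sample_id"], imm["subtype"])
    # denominators are all niches of the sample, so subtype shares are
    # compositions of the whole tissue, not of the immune subset
    totals = niches.table.groupby("sample_id").size()
    comp["other niches"] = totals - comp.sum(axis=1)
    model = composition_model(comp, cohort.samples)
    path2 = outdir / "niche_composition_model.csv"
    model.to_csv(path2, index=False)
    written["abundance"] = [path.name, path2.name]
    report["headline"]["fold_changes"] = dict(
        zip(folds["cell_type"],
            [None if not np.isfinite(f) else round(float(f), 3)
             for f in folds["fold"]]))
    ctx["folds"] = folds


def _stage_expression(config, outdir, ctx, report, written):
    cohort, niches = ctx["cohort"], ctx["niches"]
    norm = normalize_expression(niches.counts)
    cond = cohort.samples.set_index("sample_id")["condition"]
    niche_cond = niches.table["sample_id"].map(cond).to_numpy()
    files = []
    de = differential_expression(norm, niches.genes,
                                 niche_cond == "AIN", niche_cond == "ATN")
    p = outdir / "niche_de_ain_vs_atn.csv"
    de.to_csv(p, index=False)
    files.append(p.name)
    stat = rank_statistic(de)
    gsea_rows = []
    for name, gene_set in catalogs.GENE_SETS.items():
        res = gsea_preranked(stat, gene_set, n_perm=config.n_perm,
                             seed=config.seed)
        gsea_rows.append({"set": name, **res})
    gsea = pd.DataFrame(gsea_rows)
    p = outdir / "gsea.csv"
    gsea.to_csv(p, index=False)
    files.append(p.name)
    scores = pd.DataFrame({
        "niche_id": niches.table["niche_id"],
        "ifng_response": module_score(norm, niches.genes,
                                      catalogs.GENE_SETS["IFNg Response"]),
        "oxphos": module_score(
            norm, niches.genes,
            catalogs.GENE_SETS["Oxidative Phosphorylation"]),
    })
    p = outdir / "module_scores.csv"
    scores.to_csv(p, index=False)
    files.append(p.name)
    ctx["module_scores"] = scores

    fib_mask = (niches.table["major_type"] == "fibrotic").to_numpy()
    if fib_mask.any() and (~fib_mask).any():
        de_fib = differential_expression(norm, niches.genes, fib_mask,
                                         ~fib_mask)
        signature = fibrosis_signature(de_fib)
        (outdir / "fibrosis_signature.txt").write_text(
            "\n".join(signature) + "\n")
        files.append("fibrosis_signature.txt")
        sig_scores = module_score(norm, niches.genes, signature)
        niches.table["fibrosis_score"] = sig_scores
        imm = niches.table[niches.table["subtype"] != ""]
        report["headline"]["fibrosis_score_by_subtype"] = {
            k: round(float(v), 4) for k, v in
            imm.groupby("subtype")["fibrosis_score"].mean().items()}

    dens = pseudobulk_area_normalized(cohort.transcripts, cohort.samples,
                                      catalogs.PROTEOMICS_GENES)
    p = outdir / "pseudobulk_density.csv"
    dens.to_csv(p)
    files.append(p.name)
    written["expression"] = files

    gsea_idx = gsea.set_index("set")
    report["headline"]["gsea_nes"] = {
        k: round(float(v), 3) for k, v in gsea_idx["nes"].items()}


def _stage_crosstalk(config, outdir, ctx, report, written):
    cohort, niches = ctx["cohort"], ctx["niches"]
    files = []
    strengths = lr_interaction_strength(niches, catalogs.LR_PAIRS,
                                        cohort.samples,
                                        n_perm=config.n_perm,
                                        seed=config.seed)
    p = outdir / "lr_strength.csv"
    strengths.to_csv(p, index=False)
    files.append(p.name)
    totals = lr_condition_totals(strengths)
    report["headline"]["lr_condition_totals"] = {
        c: {a: round(float(v), 4) for a, v in row.items()}
        for c, row in totals.iterrows()}

    fib = fibrosis_adjacency(niches, cohort.samples)
    p = outdir / "fibrosis_adjacency.csv"
    fib.to_csv(p, index=False)
    files.append(p.name)

    attribution = transcript_attribution(
        cohort.transcripts, cohort.cells, "IFNG",
        type_subset=catalogs.IMMUNE_CELL_TYPES)
    p = outdir / "ifng_attribution.csv"
    attribution.rename_axis("cell_type").to_frame("fraction").to_csv(p)
    files.append(p.name)
    if len(attribution):
        report["headline"]["ifng_cd8_percent"] = round(
            100.0 * float(attribution.get("CD8 T", 0.0)), 2)

    scores = ctx.get("module_scores")
    if scores is not None:
        cond = cohort.samples.set_index("sample_id")["condition"]
        tab = niches.table
        mask = ((tab["major_type"] == "proximal tubule")
                & (tab["sample_id"].map(cond) == "AIN")).to_numpy()
        if mask.sum() >= 3:
            corr = score_correlation(scores["oxphos"].to_numpy(),
                                     scores["ifng_response"].to_numpy(),
                                     mask)
            report["headline"]["oxphos_ifng_r"] = round(corr.r, 4)
            report["headline"]["oxphos_ifng_p"] = corr.p_value
    written["crosstalk"] = files


_STAGE_FUNCS = {
    "cell_typing": _stage_cell_typing,
    "tiling": _stage_tiling,
    "niche_typing": _stage_niche_typing,
    "abundance": _stage_abundance,
    "expression": _stage_expression,
    "crosstalk": _stage_crosstalk,
}
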