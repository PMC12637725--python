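"""Readers and writers for every on-disk artifact.

Formats: UTF-8 comma-delimited text for tables (cells, transcripts, sample
metadata, results), MatrixMarket for the sparse counts matrix (with
``genes.txt`` and ``cell_index.csv`` side files), GeoJSON for niche polygons
(planar micrometre coordinates; not a geographic CRS) and JSON for marker
catalogs and ground truth. Readers validate strictly and reject malformed
input rather than coercing it.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from shapely.geometry import mapping

from .cohort import (CELLS_COLUMNS, SAMPLES_COLUMNS, TRANSCRIPTS_COLUMNS,
                     Cohort, GroundTruth)
from .errors import SchemaError

logger = logging.getLogger(__name__)

CELLS_FILE = "cells.csv"
TRANSCRIPTS_FILE = "transcripts.csv"
COUNTS_FILE = "counts.mtx"
GENES_FILE = "genes.txt"
CELL_INDEX_FILE = "cell_index.csv"
SAMPLES_FILE = "samples.csv"
TRUTH_FILE = "ground_truth.json"


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write all cohort artifacts into ``outdir``; returns the directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.cells.to_csv(outdir / CELLS_FILE, index=False)
    cohort.transcripts.to_csv(outdir / TRANSCRIPTS_FILE, index=False)
    scipy.io.mmwrite(outdir / COUNTS_FILE, cohort.counts.astype(int))
    (outdir / GENES_FILE).write_text("\n".join(cohort.genes) + "\n")
    cohort.cells[["sample_id", "cell_id"]].to_csv(
        outdir / CELL_INDEX_FILE, index=False)
    cohort.samples.to_csv(outdir / SAMPLES_FILE, index=False)
    if cohort.ground_truth is not None:
        (outdir / TRUTH_FILE).write_text(
            json.dumps(cohort.ground_truth.to_dict()))
    return outdir


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, keep_default_na=False, dtype={"cell_id": str})
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing column {col!r}")
    return df


def read_cohort(indir: str | Path) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`.

    Enforces cross-file consistency: every assigned transcript's cell must
    exist, and the counts matrix dimensions must match cells x panel.
    """
    indir = Path(indir)
    cells = _read_table(indir / CELLS_FILE, CELLS_COLUMNS)
    cells["qc_pass"] = cells["qc_pass"].astype(bool)
    transcripts = _read_table(indir / TRANSCRIPTS_FILE, TRANSCRIPTS_COLUMNS)
    samples = _read_table(indir / SAMPLES_FILE, SAMPLES_COLUMNS)
    genes = [g for g in (indir / GENES_FILE).read_text().splitlines() if g]
    counts = sp.csr_matrix(scipy.io.mmread(indir / COUNTS_FILE))
    if counts.shape != (len(cells), len(genes)):
        raise SchemaError(
            f"counts.mtx dimensions {counts.shape} do not match "
            f"{len(cells)} cells x {len(genes)} genes")
    index = _read_table(indir / CELL_INDEX_FILE, ["sample_id", "cell_id"])
    if not (index["sample_id"].tolist() == cells["sample_id"].tolist()
            and index["cell_id"].tolist() == cells["cell_id"].tolist()):
        raise SchemaError("cell_index.csv disagrees with cells.csv ordering")
    truth = None
    if (indir / TRUTH_FILE).exists():
        truth = GroundTruth.from_dict(
            json.loads((indir / TRUTH_FILE).read_text()))
    cohort = Cohort(cells=cells, transcripts=transcripts,
                    counts=counts.astype(int), genes=genes, samples=samples,
                    ground_truth=truth)
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# GeoJSON niche polygons

def polygon_feature(niche_id: str, geom, properties: dict) -> dict:
    gj = mapping(geom)
    if gj["type"] == "Polygon":
        gj = {"type": "MultiPolygon", "coordinates": [gj["coordinates"]]}
    return {"type": "Feature", "id": niche_id, "geometry": gj,
            "properties": properties}


def write_niche_polygons(niches, path: str | Path) -> Path:
    """Write one GeoJSON Feature (MultiPolygon) per niche.

    ``niches`` is a :class:`~nephroniche.tiling.NicheSet`. Degenerate niches
    (fewer than 3 distinct points) were already buffered to small disks at
    polygonisation time; a warning is logged for zero-area geometries.
    """
    path = Path(path)
    features = []
    table = niches.table.set_index("niche_id")
    for nid in table.index:
        geom = niches.polygons[nid]
        if geom.area <= 0:
            logger.warning("niche %s has degenerate geometry", nid)
        row = table.loc[nid]
        props = {"niche_id": nid, "sample_id": row["sample_id"],
                 "n_cells": int(row["n_cells"])}
        for key in ("major_type", "subtype"):
            if key in table.columns:
                props[key] = row[key]
        features.append(polygon_feature(nid, geom, props))
    doc = {
        "type": "FeatureCollection",
        "features": features,
        # planar tissue coordinates in micrometres, not a geographic CRS
        "crs_note": "planar micrometre coordinates (non-geographic)",
    }
    path.write_text(json.dumps(doc))
    return path


# ---------------------------------------------------------------------------
# catalogs, gene sets, LR pairs, protein tables

def write_marker_catalog(catalog: dict[str, list[str]], path: str | Path) -> None:
    Path(path).write_text(json.dumps(catalog, indent=1))


def read_marker_catalog(path: str | Path) -> dict[str, list[str]]:
    catalog = json.loads(Path(path).read_text())
    if not isinstance(catalog, dict) or not all(
            isinstance(v, list) for v in catalog.values()):
        raise SchemaError(f"{path}: marker catalog must map type -> gene list")
    return catalog


def write_gene_sets_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    """GMT format: name <tab> description <tab> genes..."""
    lines = [f"{name}\tna\t" + "\t".join(genes)
             for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_sets_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise SchemaError(f"{path}: malformed GMT line {line[:40]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_lr_pairs(path: str | Path) -> list[tuple[str, str, str]]:
    df = _read_table(Path(path), ["ligand", "receptor", "axis"])
    return list(df[["ligand", "receptor", "axis"]].itertuples(index=False,
                                                              name=None))


def write_lr_pairs(pairs: list[tuple[str, str, str]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["ligand", "receptor", "axis"]).to_csv(
        path, index=False)


def read_protein_table(path: str | Path) -> pd.DataFrame:
    """Sample x protein normalized abundances; first column is sample_id."""
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise SchemaError(f"{path}: first column must be 'sample_id'")
    return df.set_index("sample_id")
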