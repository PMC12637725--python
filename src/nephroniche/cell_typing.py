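"""Marker-based cell typing.

Cells are library-size normalised (counts-per-10k, log1p) and assigned to the
catalog type whose markers have the highest mean normalised expression; when
per-type centroid vectors are supplied the assignment is nearest-centroid by
cosine similarity instead. Cells below the transcript QC floor are labelled
``LowQ`` and excluded from all downstream composition statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError

LOWQ = "LowQ"
CP10K_TARGET = 10_000.0
DEFAULT_MIN_TRANSCRIPTS = 10


def normalize_expression(counts: sp.spmatrix | np.ndarray,
                         target: float = CP10K_TARGET) -> sp.csr_matrix:
    """Counts-per-``target`` library scaling followed by log1p.

    All-zero rows stay all-zero. Returns CSR float64.
    """
    x = sp.csr_matrix(counts, dtype=float)
    lib = np.asarray(x.sum(axis=1)).ravel()
    scale = np.divide(target, lib, out=np.zeros_like(lib), where=lib > 0)
    x = sp.diags(scale) @ x
    x.data = np.log1p(x.data)
    return x.tocsr()


def _check_catalog(catalog: dict[str, list[str]], genes: list[str]) -> None:
    gene_set = set(genes)
    if not catalog:
        raise ConfigurationError("marker catalog is empty")
    for t, markers in catalog.items():
        if not markers:
            raise ConfigurationError(f"type {t!r} has no markers")
        missing = set(markers) - gene_set
        if missing:
            raise ConfigurationError(
                f"catalog type {t!r} references genes absent from the "
                f"panel: {sorted(missing)}")


def marker_scores(normalized: sp.spmatrix | np.ndarray, genes: list[str],
                  catalog: dict[str, list[str]]) -> pd.DataFrame:
    """Mean normalised marker expression per cell per catalog type."""
    _check_catalog(catalog, genes)
    x = sp.csr_matrix(normalized)
    gene_idx = {g: i for i, g in enumerate(genes)}
    types = sorted(catalog)
    out = np.empty((x.shape[0], len(types)))
    for j, t in enumerate(types):
        cols = [gene_idx[g] for g in catalog[t]]
        out[:, j] = np.asarray(x[:, cols].mean(axis=1)).ravel()
    return pd.DataFrame(out, columns=types)


def assign_types(normalized: sp.spmatrix | np.ndarray, genes: list[str],
                 catalog: dict[str, list[str]],
                 n_transcripts: np.ndarray,
                 min_transcripts: int = DEFAULT_MIN_TRANSCRIPTS,
                 centroids: pd.DataFrame | None = None) -> pd.Series:
    """Assign one label per cell (catalog type or ``LowQ``).

    Ties break lexicographically by type name. When ``centroids`` (type x
    gene, normalised space) is given, assignment is nearest-centroid by
    cosine similarity on the centroid's genes.
    """
    n_transcripts = np.asarray(n_transcripts)
    if centroids is not None:
        x = sp.csr_matrix(normalized)
        gene_idx = {g: i for i, g in enumerate(genes)}
        missing = set(centroids.columns) - set(genes)
        if missing:
            raise ConfigurationError(
                f"centroid genes absent from panel: {sorted(missing)[:5]}")
        cols = [gene_idx[g] for g in centroids.columns]
        sub = np.asarray(x[:, cols].todense())
        c = centroids.to_numpy(float)
        c = c / np.maximum(np.linalg.norm(c, axis=1, keepdims=True), 1e-12)
        s = sub / np.maximum(np.linalg.norm(sub, axis=1, keepdims=True), 1e-12)
        sim = pd.DataFrame(s @ c.T, columns=centroids.index)
        sim = sim[sorted(sim.columns)]
        scores = sim
    else:
        scores = marker_scores(normalized, genes, catalog)
    # idxmax returns the first (lexicographically smallest) column on ties
    labels = scores.idxmax(axis=1).to_numpy(object)
    labels[n_transcripts < min_transcripts] = LOWQ
    return pd.Series(labels, name="type_label")


def apply_typing(cohort, catalog: dict[str, list[str]],
                 min_transcripts: int = DEFAULT_MIN_TRANSCRIPTS,
                 overrides: pd.DataFrame | None = None) -> pd.Series:
    """Type all cells of a cohort in place (fills ``type_label``/``qc_pass``).

    ``overrides`` optionally supplies manual label curation as a table with
    columns ``sample_id, cell_id, type_label``.
    """
    norm = normalize_expression(cohort.counts)
    labels = assign_types(norm, cohort.genes, catalog,
                          cohort.cells["n_transcripts"].to_numpy(),
                          min_transcripts=min_transcripts)
    if overrides is not None:
        key = cohort.cells["sample_id"] + ":" + cohort.cells["cell_id"]
        omap = dict(zip(overrides["sample_id"] + ":" + overrides["cell_id"],
                        overrides["type_label"]))
        labels = pd.Series([omap.get(k, l) for k, l in zip(key, labels)],
                           name="type_label")
    cohort.cells["type_label"] = labels.to_numpy()
    cohort.cells["qc_pass"] = (labels != LOWQ).to_numpy()
    return labels
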