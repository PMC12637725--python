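"""Niche clustering and annotation.

Niches are clustered on their aggregated expression: library-normalised
log counts, top principal components, shared-nearest-neighbour graph
(Jaccard weights), Leiden modularity optimisation at a configurable
resolution. Clusters are annotated by the niche-marker catalog (argmax mean
marker z-score, lexicographic tie-break, low-confidence flag below a
z-score floor); immune niches are subclustered with the same machinery at a
finer resolution and labelled from the immune-subtype catalog.
"""

from __future__ import annotations

import warnings

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .cell_typing import normalize_expression
from .errors import ConfigurationError
from .tiling import NicheSet

DEFAULT_N_NEIGHBORS = 30
DEFAULT_RESOLUTION_MAJOR = 0.6
DEFAULT_RESOLUTION_IMMUNE = 7.0
DEFAULT_N_PCS = 50
LOW_CONFIDENCE_FLOOR = 0.5
DEFAULT_MERGE_THRESHOLD = 0.40
IMMUNE_UNRESOLVED = "immune-unresolved"


def _snn_graph(pcs: np.ndarray, n_neighbors: int) -> ig.Graph:
    n = len(pcs)
    nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, n)).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    neigh = [set(row[1:]) for row in idx]
    edges, weights = [], []
    for i in range(n):
        for j in idx[i][1:]:
            j = int(j)
            if j <= i:
                continue
            shared = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = shared / union if union else 0.0
            # keep every kNN edge at a small floor weight so no node is
            # isolated from the community search
            edges.append((i, j))
            weights.append(max(w, 1.0 / (3.0 * max(len(neigh[i]), 1))))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_niches(normalized: sp.spmatrix | np.ndarray,
                   n_neighbors: int = DEFAULT_N_NEIGHBORS,
                   resolution: float = DEFAULT_RESOLUTION_MAJOR,
                   seed: int = 0,
                   n_pcs: int = DEFAULT_N_PCS,
                   min_cluster_size: int = 5,
                   merge_threshold: float | None = DEFAULT_MERGE_THRESHOLD
                   ) -> np.ndarray:
    """Leiden community detection on an SNN graph of niche expression PCs.

    Micro-communities smaller than ``min_cluster_size`` are absorbed into
    the most similar larger cluster (cosine of centroid expression), and
    clusters whose expression centroids are nearly indistinguishable
    (cosine similarity >= ``merge_threshold``) are agglomerated — splitting
    a transcriptional family across communities is a resolution artefact,
    not structure. Pass ``merge_threshold=None`` to disable.
    """
    x = np.asarray(sp.csr_matrix(normalized).todense())
    n = x.shape[0]
    if n < 2:
        raise ConfigurationError("need at least 2 niches to cluster")
    if n <= n_neighbors:
        warnings.warn(
            f"n_neighbors={n_neighbors} clamped to {n - 1} (only {n} niches)")
        n_neighbors = n - 1
    k = min(n_pcs, min(x.shape) - 1)
    if k >= 1:
        pcs = PCA(n_components=k, svd_solver="auto",
                  random_state=0).fit_transform(x - x.mean(axis=0))
    else:
        pcs = x
    g = _snn_graph(pcs, n_neighbors)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight" if g.ecount() else None,
        resolution_parameter=resolution, seed=seed, n_iterations=-1)
    labels = np.asarray(part.membership, int)
    labels = _absorb_small_clusters(labels, pcs, min_cluster_size)
    if merge_threshold is not None:
        labels = _merge_similar_clusters(labels, x, merge_threshold)
    # relabel consecutively by cluster size (largest first), ties by id
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels], int)


def _merge_similar_clusters(labels: np.ndarray, x: np.ndarray,
                            threshold: float) -> np.ndarray:
    """Agglomerate clusters whose standardized centroids exceed ``threshold``.

    Similarity is the cosine between cluster centroids in gene-standardized
    (z-score) space: standardization cancels the shared baseline that makes
    all niches look alike and emphasises each cluster's discriminative
    genes, so communities split out of one transcriptional family remain
    close while genuinely distinct families stay apart.
    """
    labels = labels.copy()
    sd = x.std(axis=0)
    z = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    while True:
        ids = np.unique(labels)
        if len(ids) < 2:
            return labels
        cents = np.array([z[labels == i].mean(axis=0) for i in ids])
        cents /= np.maximum(np.linalg.norm(cents, axis=1, keepdims=True),
                            1e-12)
        sim = cents @ cents.T
        np.fill_diagonal(sim, -np.inf)
        a, b = np.unravel_index(int(np.argmax(sim)), sim.shape)
        if sim[a, b] < threshold:
            return labels
        labels[labels == ids[max(a, b)]] = ids[min(a, b)]


def _absorb_small_clusters(labels: np.ndarray, pcs: np.ndarray,
                           min_size: int) -> np.ndarray:
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        small = ids[counts < min_size]
        big = ids[counts >= min_size]
        if len(small) == 0 or len(big) == 0:
            return labels
        cents = {i: pcs[labels == i].mean(axis=0) for i in ids}
        tid = small[0]
        c = cents[tid]
        c = c / max(np.linalg.norm(c), 1e-12)
        sims = {b: float(np.dot(c, cents[b] / max(np.linalg.norm(cents[b]), 1e-12)))
                for b in big}
        best = max(sorted(sims), key=lambda b: sims[b])
        labels[labels == tid] = best


def _marker_zscores(normalized: sp.spmatrix | np.ndarray,
                    genes: list[str],
                    catalog: dict[str, list[str]]) -> pd.DataFrame:
    """Per-niche mean marker z-score for each catalog type."""
    x = np.asarray(sp.csr_matrix(normalized).todense())
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    z = (x - mu) / np.where(sd > 0, sd, 1.0)
    gene_idx = {g: i for i, g in enumerate(genes)}
    out = {}
    for t in sorted(catalog):
        cols = [gene_idx[g] for g in catalog[t] if g in gene_idx]
        if not cols:
            raise ConfigurationError(f"no catalog genes of {t!r} in panel")
        out[t] = z[:, cols].mean(axis=1)
    return pd.DataFrame(out)


def annotate_niche_types(clusters: np.ndarray,
                         normalized: sp.spmatrix | np.ndarray,
                         genes: list[str],
                         catalog: dict[str, list[str]],
                         floor: float = LOW_CONFIDENCE_FLOOR) -> pd.DataFrame:
    """Label every cluster by its argmax mean marker z-score.

    Returns a frame indexed by cluster id with columns ``label``, ``score``
    and ``low_confidence`` (True when the best score is below ``floor``).
    """
    scores = _marker_zscores(normalized, genes, catalog)
    scores["__cluster"] = np.asarray(clusters, int)
    by_cluster = scores.groupby("__cluster").mean()
    # idxmax picks the lexicographically first type on exact ties
    label = by_cluster.idxmax(axis=1)
    best = by_cluster.max(axis=1)
    return pd.DataFrame({
        "label": label, "score": best, "low_confidence": best < floor,
    })


def subcluster_immune(normalized_immune: sp.spmatrix | np.ndarray,
                      genes: list[str],
                      catalog: dict[str, list[str]],
                      seed: int = 0,
                      n_neighbors: int = DEFAULT_N_NEIGHBORS,
                      resolution: float = DEFAULT_RESOLUTION_IMMUNE,
                      floor: float = LOW_CONFIDENCE_FLOOR
                      ) -> tuple[np.ndarray, pd.DataFrame]:
    """Subcluster immune niches and label subclusters from the immune catalog.

    Returns (per-niche subcluster ids, per-cluster annotation frame). With
    fewer than 2 immune niches every niche is labelled ``immune-unresolved``
    (cluster id -1).
    """
    x = sp.csr_matrix(normalized_immune)
    if x.shape[0] < 2:
        ann = pd.DataFrame({"label": [IMMUNE_UNRESOLVED], "score": [np.nan],
                            "low_confidence": [True]}, index=[-1])
        return np.full(x.shape[0], -1, int), ann
    # no centroid agglomeration here: subtypes of one family are expected
    # to be transcriptionally close
    sub = cluster_niches(x, n_neighbors=n_neighbors, resolution=resolution,
                         seed=seed, merge_threshold=None)
    ann = annotate_niche_types(sub, x, genes, catalog, floor=floor)
    return sub, ann


def type_niches(niches: NicheSet,
                major_catalog: dict[str, list[str]],
                immune_catalog: dict[str, list[str]] | None = None,
                immune_label: str = "immune",
                n_neighbors: int = DEFAULT_N_NEIGHBORS,
                resolution: float = DEFAULT_RESOLUTION_MAJOR,
                immune_resolution: float = DEFAULT_RESOLUTION_IMMUNE,
                seed: int = 0) -> NicheSet:
    """Cluster + annotate a cohort's niches in place.

    Adds ``cluster``, ``major_type``, ``major_low_confidence`` columns to the
    niche table, and ``subcluster``/``subtype`` for immune niches when an
    immune catalog is supplied.
    """
    norm = normalize_expression(niches.counts)
    clusters = cluster_niches(norm, n_neighbors=n_neighbors,
                              resolution=resolution, seed=seed)
    ann = annotate_niche_types(clusters, norm, niches.genes, major_catalog)
    table = niches.table
    table["cluster"] = clusters
    table["major_type"] = ann["label"].reindex(clusters).to_numpy()
    table["major_low_confidence"] = (
        ann["low_confidence"].reindex(clusters).to_numpy())
    table["subtype"] = ""
    table["subcluster"] = -1
    if immune_catalog is not None:
        mask = (table["major_type"] == immune_label).to_numpy()
        if mask.any():
            sub, sub_ann = subcluster_immune(
                norm[np.flatnonzero(mask)], niches.genes, immune_catalog,
                seed=seed, n_neighbors=n_neighbors,
                resolution=immune_resolution)
            table.loc[mask, "subcluster"] = sub
            table.loc[mask, "subtype"] = (
                sub_ann["label"].reindex(sub).to_numpy())
    return niches
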