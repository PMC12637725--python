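"""Spatial niche tiling.

Cells of one sample are joined by a Delaunay triangulation pruned at a
maximum edge length; niches are grown greedily on that graph: seeds are
visited in a seeded random order, and a growing tile repeatedly absorbs the
adjacent unassigned cell whose normalised expression is most cosine-similar
to the tile mean, stopping at the target size (or below the coherence
threshold). Undersized leftovers are merged into their most similar adjacent
tile, so tiles stay contiguous and approximately fixed-size. This is a
transparent surrogate for natural-boundary tissue tiling: same contract
(contiguous, expression-coherent, ~fixed-size tiles), simpler objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError, cKDTree
from shapely.geometry import MultiPoint

from .cell_typing import normalize_expression
from .errors import ConfigurationError

DEFAULT_MAX_EDGE_UM = 30.0
DEFAULT_TARGET_SIZE = 15
DEFAULT_COHERENCE_THRESHOLD = 0.5
DEFAULT_BUFFER_UM = 5.0


@dataclass
class SpatialGraph:
    """Pruned Delaunay graph over one sample's cell centroids."""

    n_nodes: int
    edges: np.ndarray      # (m, 2) int, i < j
    lengths: np.ndarray    # (m,) edge length in um

    neighbors: list[np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        self.neighbors = [np.array(sorted(v), dtype=int) for v in nbrs]


def build_spatial_graph(xy: np.ndarray,
                        max_edge_um: float = DEFAULT_MAX_EDGE_UM) -> SpatialGraph:
    """Delaunay triangulation pruned to edges <= ``max_edge_um``.

    Degenerate inputs (fewer than 3 points, collinear points) fall back to a
    3-nearest-neighbour graph with the same pruning.
    """
    xy = np.asarray(xy, float).reshape(-1, 2)
    n = len(xy)
    if n == 0:
        raise ConfigurationError("cannot build a graph over zero cells")
    pairs: np.ndarray
    if n == 1:
        pairs = np.empty((0, 2), int)
    else:
        try:
            if n < 3:
                raise QhullError("too few points")
            tri = Delaunay(xy)
            s = tri.simplices
            pairs = np.vstack([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
        except QhullError:
            k = min(3, n - 1)
            tree = cKDTree(xy)
            _, idx = tree.query(xy, k=k + 1)
            rows = np.repeat(np.arange(n), k)
            cols = idx[:, 1:].ravel()
            pairs = np.column_stack([rows, cols])
        pairs = np.sort(pairs, axis=1)
        pairs = np.unique(pairs, axis=0)
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    lengths = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1) \
        if len(pairs) else np.empty(0)
    keep = lengths <= max_edge_um
    return SpatialGraph(n, pairs[keep], lengths[keep])


def tile_niches(graph: SpatialGraph, expression: np.ndarray,
                target_size: int = DEFAULT_TARGET_SIZE,
                coherence_threshold: float = DEFAULT_COHERENCE_THRESHOLD,
                rng: np.random.Generator | None = None,
                min_tile_size: int | None = None) -> np.ndarray:
    """Greedy region-growing tiling; returns a tile id per cell.

    ``expression`` is the dense normalised cell x gene matrix of the sample.
    ``min_tile_size`` (default ``max(1, target_size // 3)``) controls the
    post-pass that merges undersized tiles into their most similar adjacent
    tile; isolated undersized tiles are kept.
    """
    if target_size < 1:
        raise ConfigurationError("target_size must be >= 1")
    rng = rng or np.random.default_rng(0)
    n = graph.n_nodes
    expression = np.asarray(expression, float)
    if expression.shape[0] != n:
        raise ConfigurationError("expression rows must match graph nodes")
    norms = np.maximum(np.linalg.norm(expression, axis=1), 1e-12)
    unit = expression / norms[:, None]

    assign = np.full(n, -1, int)
    order = rng.permutation(n)
    tile_sums: list[np.ndarray] = []
    tile_sizes: list[int] = []
    if target_size > 1:
        for seed in order:
            if assign[seed] >= 0:
                continue
            tid = len(tile_sums)
            assign[seed] = tid
            total = expression[seed].copy()
            size = 1
            frontier = {int(c) for c in graph.neighbors[seed] if assign[c] < 0}
            while size < target_size and frontier:
                cand = np.fromiter(sorted(frontier), int)
                mean = total / size
                mnorm = max(np.linalg.norm(mean), 1e-12)
                sims = unit[cand] @ (mean / mnorm)
                best = int(cand[int(np.argmax(sims))])
                if sims.max() < coherence_threshold:
                    break
                assign[best] = tid
                total += expression[best]
                size += 1
                frontier.discard(best)
                frontier.update(
                    int(c) for c in graph.neighbors[best] if assign[c] < 0)
            tile_sums.append(total)
            tile_sizes.append(size)
    else:
        for i, seed in enumerate(np.sort(order)):
            assign[seed] = seed
        tile_sums = [expression[i].copy() for i in range(n)]
        tile_sizes = [1] * n
        assign = np.arange(n)

    # merge undersized tiles into the most similar adjacent tile
    if min_tile_size is None:
        min_tile_size = max(1, target_size // 3)
    if min_tile_size > 1 and len(graph.edges):
        sizes = np.array(tile_sizes)
        sums = np.array(tile_sums)
        tile_adj: dict[int, set[int]] = {}
        for i, j in graph.edges:
            a, b = int(assign[i]), int(assign[j])
            if a != b:
                tile_adj.setdefault(a, set()).add(b)
                tile_adj.setdefault(b, set()).add(a)
        # smallest first so chains of fragments coalesce
        for tid in sorted(range(len(sizes)), key=lambda t: (sizes[t], t)):
            if sizes[tid] >= min_tile_size:
                continue
            nbrs = sorted(tile_adj.get(tid, ()))
            nbrs = [b for b in nbrs if b != tid and sizes[b] > 0]
            if not nbrs:
                continue
            mean = sums[tid] / sizes[tid]
            mnorm = max(np.linalg.norm(mean), 1e-12)
            nb_means = sums[nbrs] / sizes[nbrs, None]
            nb_norms = np.maximum(np.linalg.norm(nb_means, axis=1), 1e-12)
            sims = (nb_means / nb_norms[:, None]) @ (mean / mnorm)
            best = nbrs[int(np.argmax(sims))]
            assign[assign == tid] = best
            sums[best] += sums[tid]
            sizes[best] += sizes[tid]
            sizes[tid] = 0
            merged_nbrs = tile_adj.pop(tid, set())
            for b in merged_nbrs:
                tile_adj[b].discard(tid)
                if b != best:
                    tile_adj[b].add(best)
                    tile_adj.setdefault(best, set()).add(b)

    # relabel consecutively in order of first appearance
    uniq, labels = np.unique(assign, return_inverse=True)
    return labels


def aggregate_expression(counts: sp.spmatrix, assignment: np.ndarray,
                         n_tiles: int | None = None) -> sp.csr_matrix:
    """Exact integer group-by sum of cell counts into tile counts."""
    assignment = np.asarray(assignment, int)
    counts = sp.csr_matrix(counts)
    if len(assignment) != counts.shape[0]:
        raise ConfigurationError("assignment length must match counts rows")
    k = n_tiles if n_tiles is not None else (assignment.max() + 1 if len(assignment) else 0)
    ind = sp.coo_matrix(
        (np.ones(len(assignment), int), (assignment, np.arange(len(assignment)))),
        shape=(k, counts.shape[0]))
    return (ind @ counts).tocsr()


def polygonize(xy: np.ndarray, assignment: np.ndarray,
               buffer_um: float = DEFAULT_BUFFER_UM) -> dict[int, object]:
    """Convex hull per tile; degenerate tiles buffered to a small disk."""
    out: dict[int, object] = {}
    assignment = np.asarray(assignment, int)
    for tid in np.unique(assignment):
        pts = xy[assignment == tid]
        geom = MultiPoint([tuple(p) for p in pts]).convex_hull
        if geom.geom_type != "Polygon" or geom.area <= 0:
            geom = geom.buffer(buffer_um, quad_segs=16)
        out[int(tid)] = geom
    return out


@dataclass
class NicheSet:
    """All niches of a cohort: table, assignment, counts, polygons, graphs."""

    table: pd.DataFrame            # niche_id, sample_id, n_cells, area_um2, ...
    assignment: pd.Series          # cell key 'sample:cell' -> niche_id
    counts: sp.csr_matrix          # niche x gene, aligned with table rows
    genes: list[str]
    polygons: dict[str, object]
    graphs: dict[str, tuple[pd.Index, SpatialGraph]]

    @property
    def niche_ids(self) -> pd.Index:
        return pd.Index(self.table["niche_id"])


def tile_cohort(cohort, max_edge_um: float = DEFAULT_MAX_EDGE_UM,
                target_size: int = DEFAULT_TARGET_SIZE,
                coherence_threshold: float = DEFAULT_COHERENCE_THRESHOLD,
                seed: int = 0,
                buffer_um: float = DEFAULT_BUFFER_UM) -> NicheSet:
    """Tile every sample of a typed cohort into niches.

    Only QC-passing cells are tiled; low-quality cells belong to no niche.
    """
    norm = normalize_expression(cohort.counts)
    tables, polys, blocks, graphs = [], {}, [], {}
    assign_keys: list[str] = []
    assign_vals: list[str] = []
    for s_idx, sid in enumerate(cohort.sample_ids):
        mask = ((cohort.cells["sample_id"] == sid)
                & cohort.cells["qc_pass"]).to_numpy()
        if not mask.any():
            continue
        rows = np.flatnonzero(mask)
        xy = cohort.cells.loc[mask, ["x_um", "y_um"]].to_numpy(float)
        keys = (cohort.cells.loc[mask, "sample_id"] + ":"
                + cohort.cells.loc[mask, "cell_id"])
        graph = build_spatial_graph(xy, max_edge_um)
        expr = np.asarray(norm[rows].todense())
        rng = np.random.default_rng(seed + s_idx)
        labels = tile_niches(graph, expr, target_size,
                             coherence_threshold, rng)
        k = labels.max() + 1
        agg = aggregate_expression(cohort.counts[rows], labels, k)
        geo = polygonize(xy, labels, buffer_um)
        niche_ids = [f"{sid}:n{t:04d}" for t in range(k)]
        sizes = np.bincount(labels, minlength=k)
        cx = np.bincount(labels, weights=xy[:, 0], minlength=k) / sizes
        cy = np.bincount(labels, weights=xy[:, 1], minlength=k) / sizes
        tables.append(pd.DataFrame({
            "niche_id": niche_ids, "sample_id": sid,
            "n_cells": sizes, "x_um": cx, "y_um": cy,
            "area_um2": [geo[t].area for t in range(k)],
        }))
        polys.update({niche_ids[t]: geo[t] for t in range(k)})
        blocks.append(agg)
        graphs[sid] = (pd.Index(keys), graph)
        assign_keys.extend(keys)
        assign_vals.extend(niche_ids[t] for t in labels)
    table = pd.concat(tables, ignore_index=True)
    return NicheSet(
        table=table,
        assignment=pd.Series(assign_vals, index=pd.Index(assign_keys),
                             name="niche_id"),
        counts=sp.vstack(blocks).tocsr(),
        genes=list(cohort.genes),
        polygons=polys,
        graphs=graphs,
    )
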