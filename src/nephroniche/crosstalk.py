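"""Spatially aware interaction statistics.

Niche-level adjacency (two niches are neighbours iff some pair of their
member cells shares an edge of the cell-level spatial graph), adjacency-
restricted ligand-receptor interaction strength, the fibrosis-adjacency
probability of immune subniches with abundance normalisation, transcript
source attribution (which cell types emit a gene's spots), and Pearson
correlation between module scores.

The interaction strength of a ligand-receptor axis in one sample is the
mean over ordered adjacent niche pairs (i, j) of L_i * R_j, where L and R
are the niches' mean normalised ligand/receptor expression min-max scaled
per gene within the sample. The definition is a transparent surrogate for
proximity-weighted communication scores: it is zero whenever ligand and
receptor are never expressed in adjacent niches and is invariant to niche
relabelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .cell_typing import normalize_expression
from .cohort import UNASSIGNED
from .errors import ConfigurationError
from .tiling import NicheSet, SpatialGraph

AIN, ATN = "AIN", "ATN"


# ---------------------------------------------------------------------------
# niche adjacency

def build_niche_adjacency(assignment: np.ndarray,
                          graph: SpatialGraph) -> set[tuple[int, int]]:
    """Undirected niche-niche edges of one sample (no self-edges).

    ``assignment`` maps each graph node to its niche index. An edge (a, b)
    with a < b exists iff at least one cell-level edge joins the niches.
    """
    assignment = np.asarray(assignment, int)
    if len(assignment) != graph.n_nodes:
        raise ConfigurationError("assignment must cover all graph nodes")
    edges: set[tuple[int, int]] = set()
    for i, j in graph.edges:
        a, b = int(assignment[i]), int(assignment[j])
        if a != b:
            edges.add((min(a, b), max(a, b)))
    return edges


def cohort_niche_adjacency(niches: NicheSet) -> dict[str, set[tuple[str, str]]]:
    """Niche-id adjacency per sample for a tiled cohort."""
    out: dict[str, set[tuple[str, str]]] = {}
    for sid, (keys, graph) in niches.graphs.items():
        ids = niches.assignment.reindex(keys).to_numpy()
        uniq = pd.unique(ids)
        code = {nid: i for i, nid in enumerate(uniq)}
        assignment = np.array([code[v] for v in ids])
        pairs = build_niche_adjacency(assignment, graph)
        out[sid] = {(uniq[a], uniq[b]) for a, b in pairs}
    return out


# ---------------------------------------------------------------------------
# ligand-receptor interaction strength

def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def lr_interaction_strength(niches: NicheSet,
                            pairs: list[tuple[str, str, str]],
                            metadata: pd.DataFrame,
                            n_perm: int = 200,
                            seed: int = 0) -> pd.DataFrame:
    """Per-axis per-sample interaction strength with a permutation p.

    Strength = mean over ordered adjacent niche pairs (i, j) of
    ``L_i * R_j`` with per-sample min-max-scaled mean normalised
    expression. The null shuffles niche positions within the sample
    (permuting the expression profiles over niches) and recomputes the
    strength. Samples with fewer than 2 niches report strength 0 with the
    ``degenerate`` flag.
    """
    norm = normalize_expression(niches.counts)
    x = np.asarray(norm.todense())
    gene_idx = {g: i for i, g in enumerate(niches.genes)}
    for lig, rec, _ in pairs:
        for g in (lig, rec):
            if g not in gene_idx:
                raise ConfigurationError(f"gene {g!r} not in panel")
    adjacency = cohort_niche_adjacency(niches)
    table = niches.table.reset_index(drop=True)
    row_of = {nid: i for i, nid in enumerate(table["niche_id"])}
    rng = np.random.default_rng(seed)
    rows = []
    for sid in metadata["sample_id"]:
        sample_rows = np.flatnonzero((table["sample_id"] == sid).to_numpy())
        n_niches = len(sample_rows)
        edges = adjacency.get(sid, set())
        # ordered pairs: both directions of every undirected edge
        ordered = [(row_of[a], row_of[b]) for a, b in edges]
        ordered += [(j, i) for i, j in ordered]
        degenerate = n_niches < 2 or not ordered
        src = np.array([i for i, _ in ordered], int)
        dst = np.array([j for _, j in ordered], int)
        # map absolute row -> position within sample for permutation
        pos_of = {r: k for k, r in enumerate(sample_rows)}
        src_pos = np.array([pos_of[r] for r in src], int) if len(src) else src
        dst_pos = np.array([pos_of[r] for r in dst], int) if len(dst) else dst
        for lig, rec, axis in pairs:
            lvec = _minmax(x[sample_rows, gene_idx[lig]]) \
                if n_niches else np.zeros(0)
            rvec = _minmax(x[sample_rows, gene_idx[rec]]) \
                if n_niches else np.zeros(0)
            if degenerate:
                rows.append({"sample_id": sid, "axis": axis,
                             "strength": 0.0, "p_value": 1.0,
                             "degenerate": True})
                continue
            strength = float((lvec[src_pos] * rvec[dst_pos]).mean())
            null = np.empty(n_perm)
            for b in range(n_perm):
                perm = rng.permutation(n_niches)
                null[b] = (lvec[perm[src_pos]] * rvec[perm[dst_pos]]).mean()
            p = float((1 + (null >= strength).sum()) / (n_perm + 1))
            rows.append({"sample_id": sid, "axis": axis,
                         "strength": strength, "p_value": p,
                         "degenerate": False})
    out = pd.DataFrame(rows)
    cond = metadata.set_index("sample_id")["condition"]
    out["condition"] = out["sample_id"].map(cond)
    return out


def lr_condition_totals(strengths: pd.DataFrame) -> pd.DataFrame:
    """Per-condition per-axis summed strength (the global contrast)."""
    return (strengths.groupby(["condition", "axis"])["strength"]
            .sum().unstack("axis"))


# ---------------------------------------------------------------------------
# fibrosis adjacency

def fibrosis_adjacency(niches: NicheSet, metadata: pd.DataFrame,
                       fibrotic_label: str = "fibrotic",
                       subtype_column: str = "subtype") -> pd.DataFrame:
    """Probability that an immune subniche directly neighbours fibrosis.

    Per sample and immune subtype t:
      raw  = (# niches of t with >=1 fibrotic neighbour) / (# niches of t)
      norm = raw / (fraction of all non-fibrotic niches in the sample with
                    >=1 fibrotic neighbour)
    Subtypes absent in a sample give missing values (not zero); samples
    without fibrotic niches give all-missing with a warning. Per-condition
    means are included in the result attributes.
    """
    table = niches.table.reset_index(drop=True)
    if "major_type" not in table.columns:
        raise ConfigurationError("niches must be typed before this analysis")
    adjacency = cohort_niche_adjacency(niches)
    subtypes = sorted(
        t for t in table.loc[table[subtype_column] != "", subtype_column]
        .unique())
    rows = []
    for sid in metadata["sample_id"]:
        sub = table[table["sample_id"] == sid]
        fibrotic = set(sub.loc[sub["major_type"] == fibrotic_label,
                               "niche_id"])
        neigh: dict[str, set[str]] = {nid: set() for nid in sub["niche_id"]}
        for a, b in adjacency.get(sid, set()):
            neigh.setdefault(a, set()).add(b)
            neigh.setdefault(b, set()).add(a)
        if not fibrotic:
            warnings.warn(f"sample {sid} has no fibrotic niches")
            for t in subtypes:
                rows.append({"sample_id": sid, "subtype": t,
                             "raw": np.nan, "normalized": np.nan})
            continue
        non_fib = sub[sub["major_type"] != fibrotic_label]
        touches = non_fib["niche_id"].map(
            lambda nid: bool(neigh.get(nid, set()) & fibrotic))
        baseline = float(touches.mean()) if len(non_fib) else np.nan
        for t in subtypes:
            mine = sub[sub[subtype_column] == t]
            if len(mine) == 0:
                rows.append({"sample_id": sid, "subtype": t,
                             "raw": np.nan, "normalized": np.nan})
                continue
            raw = float(mine["niche_id"].map(
                lambda nid: bool(neigh.get(nid, set()) & fibrotic)).mean())
            norm = raw / baseline if baseline and baseline > 0 else np.nan
            rows.append({"sample_id": sid, "subtype": t,
                         "raw": raw, "normalized": norm})
    out = pd.DataFrame(rows)
    cond = metadata.set_index("sample_id")["condition"]
    out["condition"] = out["sample_id"].map(cond)
    means = (out.groupby(["condition", "subtype"])[["raw", "normalized"]]
             .mean())
    out.attrs["condition_means"] = means
    return out


# ---------------------------------------------------------------------------
# transcript attribution

def transcript_attribution(transcripts: pd.DataFrame,
                           cells: pd.DataFrame,
                           gene: str,
                           type_subset: list[str] | None = None,
                           label_column: str = "type_label") -> pd.Series:
    """Fraction of a gene's cell-assigned spots owned by each cell type.

    Restricted to ``type_subset`` when given (e.g. immune types only);
    fractions sum to 1 over the reported types. Zero matching spots return
    an empty series (flagged via ``attrs['no_spots']``).
    """
    spots = transcripts[(transcripts["gene"] == gene)
                        & (transcripts["cell_id"] != UNASSIGNED)]
    if len(spots) == 0:
        out = pd.Series(dtype=float, name=gene)
        out.attrs["no_spots"] = True
        return out
    key = spots["sample_id"] + ":" + spots["cell_id"]
    label_of = dict(zip(cells["sample_id"] + ":" + cells["cell_id"],
                        cells[label_column]))
    labels = key.map(label_of)
    if type_subset is not None:
        labels = labels[labels.isin(type_subset)]
    if len(labels) == 0:
        out = pd.Series(dtype=float, name=gene)
        out.attrs["no_spots"] = True
        return out
    frac = labels.value_counts(normalize=True).sort_index()
    frac.name = gene
    frac.attrs["no_spots"] = False
    frac.attrs["n_spots"] = int(len(labels))
    return frac


# ---------------------------------------------------------------------------
# module-score correlation

@dataclass
class ScoreCorrelation:
    r: float
    p_value: float
    n: int
    degenerate: bool = False


def score_correlation(scores_a: np.ndarray, scores_b: np.ndarray,
                      subset: np.ndarray | None = None) -> ScoreCorrelation:
    """Pearson correlation between two module-score vectors.

    ``subset`` optionally restricts to a niche subset (mask or indices).
    Zero variance in either score yields a flagged, undefined result.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if subset is not None:
        a, b = a[subset], b[subset]
    if len(a) < 3:
        raise ConfigurationError("need at least 3 units for a correlation")
    if a.std() == 0 or b.std() == 0:
        return ScoreCorrelation(r=float("nan"), p_value=float("nan"),
                                n=len(a), degenerate=True)
    r, p = stats.pearsonr(a, b)
    return ScoreCorrelation(r=float(r), p_value=float(p), n=len(a))
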