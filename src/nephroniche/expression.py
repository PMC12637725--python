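"""Niche-level expression analytics.

Differential expression (Wilcoxon rank-sum on normalised niche profiles),
a rank-based gene-module score in [0, 1] (Mann-Whitney style with a rank
cap, invariant to monotone transforms of expression), classical preranked
gene-set enrichment (weighted Kolmogorov-Smirnov running sum with a
gene-label permutation null), the top-100 fibrotic transcriptional
signature, area-normalised pseudobulk densities, and transcript/protein
concordance against a paired proteomics table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import UNASSIGNED
from .errors import ConfigurationError

AIN, ATN = "AIN", "ATN"


# ---------------------------------------------------------------------------
# differential expression

def differential_expression(normalized: sp.spmatrix | np.ndarray,
                            genes: list[str],
                            group_a: np.ndarray,
                            group_b: np.ndarray,
                            pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene log2 fold change of group means + Wilcoxon rank-sum test.

    ``group_a``/``group_b`` are boolean masks or index arrays over rows.
    Genes constant across both groups get p = 1 by convention. Returns a
    frame with ``gene, log2fc, p_value, q_value`` (BH).
    """
    x = np.asarray(sp.csr_matrix(normalized).todense())
    a, b = x[group_a], x[group_b]
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ConfigurationError("both groups must be non-empty")
    log2fc = np.log2((a.mean(axis=0) + pseudocount)
                     / (b.mean(axis=0) + pseudocount))
    p = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if np.ptp(np.concatenate([a[:, j], b[:, j]])) == 0:
            continue
        p[j] = stats.mannwhitneyu(a[:, j], b[:, j],
                                  alternative="two-sided").pvalue
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"gene": genes, "log2fc": log2fc,
                         "p_value": p, "q_value": q})


# ---------------------------------------------------------------------------
# rank-based module score

def module_score(expression: np.ndarray, genes: list[str],
                 gene_set: list[str],
                 r_max: int | None = None) -> np.ndarray:
    """Mann-Whitney-style gene-set score per unit, in [0, 1].

    Genes are ranked by expression within each unit (descending; average
    ranks on ties), ranks are capped at ``r_max``, and

        U = sum_i min(rank_i, r_max) - n(n+1)/2
        score = 1 - U / (n * r_max)

    so a unit whose set genes occupy the top n ranks scores 1 and one whose
    set genes all sit at or beyond ``r_max`` scores 0. Being rank-based the
    score is invariant to any monotone transform of expression.
    ``r_max`` defaults to ``min(1500, n_genes)``.
    """
    if not gene_set:
        raise ConfigurationError("gene set is empty")
    gene_idx = {g: i for i, g in enumerate(genes)}
    missing = [g for g in gene_set if g not in gene_idx]
    if missing:
        raise ConfigurationError(
            f"gene set members absent from panel: {missing[:5]}")
    x = np.asarray(sp.csr_matrix(expression).todense()) \
        if sp.issparse(expression) else np.atleast_2d(np.asarray(expression,
                                                                 float))
    n_genes = x.shape[1]
    if r_max is None:
        r_max = min(1500, n_genes)
    n = len(gene_set)
    if r_max < n:
        raise ConfigurationError("r_max must be >= gene-set size")
    cols = np.array([gene_idx[g] for g in gene_set])
    # rank 1 = highest expression; average ranks on ties
    ranks = stats.rankdata(-x, axis=1, method="average")
    capped = np.minimum(ranks[:, cols], float(r_max))
    u = capped.sum(axis=1) - n * (n + 1) / 2.0
    return 1.0 - u / (n * float(r_max))


# ---------------------------------------------------------------------------
# preranked GSEA

def _enrichment_score(order: np.ndarray, weights: np.ndarray,
                      in_set: np.ndarray) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    w = weights[order]
    member = in_set[order]
    hit = np.where(member, w, 0.0)
    hit_total = hit.sum()
    miss_total = float((~member).sum())
    if hit_total == 0 or miss_total == 0:
        return 0.0
    running = np.cumsum(hit / hit_total - (~member) / miss_total)
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(statistic: pd.Series, gene_set: list[str],
                   weight: float = 1.0, n_perm: int = 1000,
                   seed: int = 0) -> dict:
    """Classical preranked GSEA for one gene set.

    ``statistic`` maps every panel gene to its ranking statistic (e.g.
    signed -log10 p). The enrichment score is the extremum of the weighted
    Kolmogorov-Smirnov running sum over genes sorted by decreasing
    statistic, with hit weights ``|s|**weight``. The null permutes gene
    labels; NES divides ES by the mean |null ES| of matching sign and the
    two-sided p comes from the matching-sign null tail.
    """
    stat = pd.Series(statistic).astype(float)
    missing = [g for g in gene_set if g not in stat.index]
    if missing:
        raise ConfigurationError(
            f"gene set members missing a statistic: {missing[:5]}")
    if len(gene_set) >= len(stat):
        raise ConfigurationError("gene set must be smaller than the panel")
    genes = stat.index.to_numpy()
    values = stat.to_numpy()
    order = np.argsort(-values, kind="stable")
    in_set = np.isin(genes, list(gene_set))
    weights = np.abs(values) ** weight
    es = _enrichment_score(order, weights, in_set)

    rng = np.random.default_rng(seed)
    n = len(genes)
    k = int(in_set.sum())
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm_set = np.zeros(n, bool)
        perm_set[rng.choice(n, size=k, replace=False)] = True
        null[b] = _enrichment_score(order, weights, perm_set)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if len(same_sign) == 0:
        nes, p = np.nan, 1.0 / (n_perm + 1)
    else:
        nes = es / np.abs(same_sign).mean()
        p = (1 + (np.abs(same_sign) >= abs(es)).sum()) / (len(same_sign) + 1)
        p = float(min(1.0, 2.0 * p * len(same_sign) / n_perm))
    return {"es": es, "nes": float(nes), "p_value": float(p),
            "set_size": k, "n_perm": n_perm}


def rank_statistic(de: pd.DataFrame) -> pd.Series:
    """Standard preranked input: signed -log10(p) x sign(log2FC)."""
    p = np.clip(de["p_value"].to_numpy(), 1e-300, 1.0)
    s = -np.log10(p) * np.sign(de["log2fc"].to_numpy())
    return pd.Series(s, index=de["gene"].to_numpy())


# ---------------------------------------------------------------------------
# fibrotic signature

def fibrosis_signature(de: pd.DataFrame, n_genes: int = 100) -> list[str]:
    """Top differentially expressed genes of the fibrosis-vs-rest contrast.

    Genes are ranked by ascending q, then descending log2FC, then gene name
    (fully deterministic); exactly ``n_genes`` are returned, or all eligible
    genes with a warning when fewer are available. Only genes with finite
    statistics and positive log2FC (up in fibrosis) are eligible.
    """
    d = de[np.isfinite(de["q_value"]) & np.isfinite(de["log2fc"])
           & (de["log2fc"] > 0)]
    d = d.sort_values(["q_value", "log2fc", "gene"],
                      ascending=[True, False, True], kind="stable")
    if len(d) < n_genes:
        warnings.warn(
            f"only {len(d)} eligible genes for a {n_genes}-gene signature")
    return d["gene"].head(n_genes).tolist()


# ---------------------------------------------------------------------------
# area-normalised pseudobulk + proteomics concordance

def pseudobulk_area_normalized(transcripts: pd.DataFrame,
                               metadata: pd.DataFrame,
                               gene_list: list[str] | None = None,
                               include_unassigned: bool = False
                               ) -> pd.DataFrame:
    """Sample x gene transcript densities (counts per mm^2 of biopsy).

    Counts cell-assigned transcript spots per sample and gene, divided by
    the sample's biopsy area. Unassigned spots are excluded unless
    ``include_unassigned``.
    """
    t = transcripts
    if not include_unassigned:
        t = t[t["cell_id"] != UNASSIGNED]
    if gene_list is not None:
        t = t[t["gene"].isin(gene_list)]
    counts = pd.crosstab(t["sample_id"], t["gene"])
    counts = counts.reindex(index=metadata["sample_id"],
                            columns=gene_list or sorted(counts.columns),
                            fill_value=0).fillna(0)
    areas = metadata.set_index("sample_id")["biopsy_area_mm2"]
    return counts.div(areas, axis=0)


def proteomics_concordance(densities: pd.DataFrame,
                           protein_table: pd.DataFrame,
                           pairs: list[str],
                           metadata: pd.DataFrame) -> pd.DataFrame:
    """Direction agreement between transcript densities and protein levels.

    For every gene/protein name in ``pairs`` the sign of the AIN-ATN mean
    difference is computed on both modalities; ``agree`` marks matching
    signs and the ``separated_*`` flags mark complete separation
    (min of one condition above the max of the other) on each modality.
    Unpairable names are skipped with a warning.
    """
    cond = metadata.set_index("sample_id")["condition"]
    rows = []
    for name in pairs:
        if name not in densities.columns or name not in protein_table.columns:
            warnings.warn(f"{name!r} missing from one modality; skipped")
            continue
        rec: dict = {"pair": name}
        for label, table in (("rna", densities), ("protein", protein_table)):
            v = table[name].reindex(cond.index).astype(float)
            ain, atn = v[cond == AIN].dropna(), v[cond == ATN].dropna()
            rec[f"{label}_diff"] = ain.mean() - atn.mean()
            rec[f"separated_{label}"] = bool(
                len(ain) and len(atn)
                and (ain.min() > atn.max() or atn.min() > ain.max()))
        rec["agree"] = bool(np.sign(rec["rna_diff"])
                            == np.sign(rec["protein_diff"]))
        rows.append(rec)
    return pd.DataFrame(rows)
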