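"""Condition differences in composition, three ways.

* Pooled-proportion fold changes per cell type (the AIN pool's proportion
  over the ATN pool's, with stratified bootstrap CIs),
* covarying-neighbourhood association: each cell's (or niche's) local
  sample-composition profile, obtained by random-walk smoothing on an
  expression kNN graph, is correlated with the condition label across
  samples; significance comes from permuting condition labels over samples
  (all 70 assignments are enumerated for a 4+4 design),
* a beta-binomial regression of per-sample niche-type counts on condition
  with a likelihood-ratio test — an explicit maximum-likelihood stand-in
  for Bayesian compositional models, reporting a logit-scale slope.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, stats
from scipy.stats import betabinom
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError

AIN, ATN = "AIN", "ATN"


# ---------------------------------------------------------------------------
# pooled-proportion fold changes

def celltype_fold_changes(labels: pd.Series, sample_ids: pd.Series,
                          metadata: pd.DataFrame, n_boot: int = 200,
                          seed: int = 0,
                          exclude: tuple[str, ...] = ("LowQ",)
                          ) -> pd.DataFrame:
    """AIN/ATN pooled-proportion ratio per cell type with bootstrap CIs.

    ``labels``/``sample_ids`` are aligned per-cell vectors; cells whose label
    is in ``exclude`` are dropped. The fold is the ratio of pooled
    proportions (cells pooled within condition, not averaged over samples);
    per-sample ratios are also returned for transparency. A zero ATN
    proportion yields ``inf`` with the ``infinite`` flag set. The bootstrap
    resamples cells within each sample (stratified) to respect the cohort
    design.
    """
    labels = pd.Series(labels).reset_index(drop=True)
    sample_ids = pd.Series(sample_ids).reset_index(drop=True)
    keep = ~labels.isin(exclude)
    labels, sample_ids = labels[keep], sample_ids[keep]
    cond_of = dict(zip(metadata["sample_id"], metadata["condition"]))
    cond = sample_ids.map(cond_of)
    if set(cond.unique()) != {AIN, ATN}:
        raise ConfigurationError("both conditions must have QC-passing cells")

    types = sorted(labels.unique())
    rng = np.random.default_rng(seed)

    def pooled_folds(lab: pd.Series, cnd: pd.Series) -> pd.Series:
        tab = pd.crosstab(cnd, lab).reindex(index=[AIN, ATN],
                                            columns=types, fill_value=0)
        prop = tab.div(tab.sum(axis=1), axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return prop.loc[AIN] / prop.loc[ATN]

    point = pooled_folds(labels, cond)

    # stratified bootstrap: resample cells within each sample
    by_sample = {s: np.flatnonzero(sample_ids.to_numpy() == s)
                 for s in metadata["sample_id"]}
    boots = np.empty((n_boot, len(types)))
    lab_arr = labels.to_numpy()
    cond_arr = cond.to_numpy()
    for b in range(n_boot):
        rows = np.concatenate([
            idx[rng.integers(len(idx), size=len(idx))]
            for s, idx in sorted(by_sample.items()) if len(idx)])
        boots[b] = pooled_folds(pd.Series(lab_arr[rows]),
                                pd.Series(cond_arr[rows])).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(np.where(np.isfinite(boots), boots, np.nan),
                              2.5, axis=0)
        hi = np.nanpercentile(np.where(np.isfinite(boots), boots, np.nan),
                              97.5, axis=0)

    per_sample = pd.crosstab(sample_ids, labels).reindex(columns=types,
                                                         fill_value=0)
    per_sample = per_sample.div(per_sample.sum(axis=1), axis=0)

    out = pd.DataFrame({
        "cell_type": types,
        "fold": point.to_numpy(),
        "ci_low": lo,
        "ci_high": hi,
        "infinite": ~np.isfinite(point.to_numpy()),
        "direction": np.where(point.to_numpy() >= 1.0, AIN, ATN),
    })
    out.attrs["per_sample_proportions"] = per_sample
    return out


# ---------------------------------------------------------------------------
# covarying-neighbourhood association

@dataclass
class NeighborhoodAssociation:
    """Per-unit association scores with permutation significance."""

    scores: np.ndarray          # per-unit correlation with condition
    p_values: np.ndarray        # per-unit permutation p
    q_values: np.ndarray        # BH-adjusted
    global_p: float
    significant: np.ndarray     # FDR < alpha mask
    n_permutations: int


def _condition_vector(metadata: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    samples = metadata["sample_id"].tolist()
    y = (metadata["condition"] == AIN).to_numpy(float)
    return samples, y


def _enumerate_labelings(y: np.ndarray, n_perm: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Distinct condition assignments (row 0 is the observed one)."""
    n = len(y)
    k = int(y.sum())
    combos = list(itertools.combinations(range(n), k))
    all_perms = np.zeros((len(combos), n))
    for i, c in enumerate(combos):
        all_perms[i, list(c)] = 1.0
    obs = np.flatnonzero((all_perms == y).all(axis=1))[0]
    order = np.concatenate([[obs], np.delete(np.arange(len(combos)), obs)])
    all_perms = all_perms[order]
    if n_perm >= len(combos) - 1:
        if n_perm > len(combos) - 1:
            warnings.warn(
                f"n_perm={n_perm} exceeds the {len(combos) - 1} distinct "
                "non-identity labelings; enumerating exactly")
        return all_perms
    pick = 1 + rng.choice(len(combos) - 1, size=n_perm, replace=False)
    return np.vstack([all_perms[0], all_perms[pick]])


def neighborhood_profiles(expression: sp.spmatrix | np.ndarray,
                          sample_ids: pd.Series, samples: list[str],
                          n_neighbors: int = 30, n_steps: int = 3,
                          n_pcs: int = 30) -> np.ndarray:
    """Random-walk-smoothed sample-membership fractions per unit.

    Builds a kNN graph in PC space of the normalised expression, then runs
    ``n_steps`` of the row-stochastic random walk on one-hot
    sample-membership columns. Row ``i`` of the result is the fraction of
    unit ``i``'s smoothed neighbourhood mass originating from each sample.
    """
    x = np.asarray(sp.csr_matrix(expression).todense())
    n = x.shape[0]
    k = min(n_pcs, min(x.shape) - 1)
    pcs = PCA(n_components=k, random_state=0).fit_transform(
        x - x.mean(axis=0)) if k >= 1 else x
    nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, n)).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    rows = np.repeat(np.arange(n), idx.shape[1] - 1)
    cols = idx[:, 1:].ravel()
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)),
                        shape=(n, n)).tocsr()
    adj = adj + adj.T  # symmetrise
    deg = np.asarray(adj.sum(axis=1)).ravel()
    walk = sp.diags(1.0 / np.maximum(deg, 1)) @ adj
    member = np.zeros((n, len(samples)))
    sample_arr = np.asarray(sample_ids)
    for j, s in enumerate(samples):
        member[:, j] = sample_arr == s
    prof = member
    for _ in range(n_steps):
        prof = walk @ prof
    row_sum = prof.sum(axis=1, keepdims=True)
    return prof / np.maximum(row_sum, 1e-12)


def neighborhood_association(expression: sp.spmatrix | np.ndarray,
                             sample_ids: pd.Series,
                             metadata: pd.DataFrame,
                             n_neighbors: int = 30, n_steps: int = 3,
                             n_perm: int = 1000, seed: int = 0,
                             alpha: float = 0.05) -> NeighborhoodAssociation:
    """CNA-style per-unit condition association with a permutation null.

    The per-unit score is the Pearson correlation, across samples, between
    the unit's neighbourhood sample-composition profile and the condition
    indicator. Global and per-unit p-values come from permuting condition
    labels over samples (exact enumeration when few samples); per-unit FDR
    is Benjamini-Hochberg.
    """
    per_cond = metadata.groupby("condition")["sample_id"].nunique()
    if (per_cond.reindex([AIN, ATN]).fillna(0) < 2).any():
        raise ConfigurationError("need >=2 samples per condition")
    samples, y = _condition_vector(metadata)
    prof = neighborhood_profiles(expression, sample_ids, samples,
                                 n_neighbors, n_steps)
    rng = np.random.default_rng(seed)
    labelings = _enumerate_labelings(y, n_perm, rng)

    def scores_for(yv: np.ndarray) -> np.ndarray:
        yc = yv - yv.mean()
        pc = prof - prof.mean(axis=1, keepdims=True)
        num = pc @ yc
        den = np.sqrt((pc ** 2).sum(axis=1) * (yc ** 2).sum())
        return np.divide(num, den, out=np.zeros_like(num), where=den > 0)

    all_scores = np.array([scores_for(lv) for lv in labelings])
    obs = all_scores[0]
    null = all_scores  # include observed for a valid permutation p
    stat = (null ** 2).mean(axis=1)
    global_p = float((stat >= stat[0]).mean())
    p = (np.abs(null) >= np.abs(obs)[None, :]).mean(axis=0)
    q = multipletests(p, method="fdr_bh")[1]
    return NeighborhoodAssociation(
        scores=obs, p_values=p, q_values=q, global_p=global_p,
        significant=q < alpha, n_permutations=len(labelings) - 1)


# ---------------------------------------------------------------------------
# beta-binomial composition model

def _betabinom_nll(params: np.ndarray, k: np.ndarray, n: np.ndarray,
                   x: np.ndarray, null: bool) -> float:
    if null:
        b0, log_phi = params
        eta = np.full_like(x, b0)
    else:
        b0, b1, log_phi = params
        eta = b0 + b1 * x
    mu = 1.0 / (1.0 + np.exp(-eta))
    phi = math.exp(min(log_phi, 20.0))
    a = np.clip(mu * phi, 1e-8, None)
    b = np.clip((1.0 - mu) * phi, 1e-8, None)
    ll = betabinom.logpmf(k, n, a, b)
    if not np.isfinite(ll).all():
        return 1e12
    return -float(ll.sum())


def _fit_betabinom(k: np.ndarray, n: np.ndarray, x: np.ndarray,
                   null: bool) -> tuple[np.ndarray, float]:
    p0 = np.clip(k.sum() / max(n.sum(), 1), 1e-4, 1 - 1e-4)
    b0 = math.log(p0 / (1 - p0))
    starts = ([[b0, 2.0], [b0, 5.0]] if null
              else [[b0, 0.0, 2.0], [b0, 1.0, 5.0], [b0, -1.0, 5.0]])
    best: tuple[np.ndarray, float] | None = None
    for s0 in starts:
        res = optimize.minimize(
            _betabinom_nll, np.asarray(s0, float), args=(k, n, x, null),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
        if best is None or res.fun < best[1]:
            best = (res.x, float(res.fun))
    assert best is not None
    return best


def composition_model(counts: pd.DataFrame, metadata: pd.DataFrame,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Beta-binomial logit regression of unit counts on condition.

    ``counts`` is a sample x unit-type table of niche (or cell) counts; the
    binomial total per sample is its row sum. For each type the model
    ``k_s ~ BetaBinom(n_s, mu_s, phi)`` with ``logit(mu_s) = b0 + b1*AIN_s``
    is fit by maximum likelihood; the condition slope is tested with a
    likelihood-ratio test (chi-square, 1 df) and a Wald CI from the profile
    curvature. Types absent in every sample are skipped with a warning.
    """
    counts = counts.reindex(metadata["sample_id"]).fillna(0).astype(int)
    totals = counts.sum(axis=1).to_numpy()
    x = (metadata.set_index("sample_id").loc[counts.index, "condition"]
         == AIN).to_numpy(float)
    rows = []
    for t in counts.columns:
        k = counts[t].to_numpy()
        if k.sum() == 0:
            warnings.warn(f"unit type {t!r} absent in all samples; skipped")
            continue
        full_par, full_nll = _fit_betabinom(k, totals, x, null=False)
        _, null_nll = _fit_betabinom(k, totals, x, null=True)
        lrt = max(0.0, 2.0 * (null_nll - full_nll))
        # F(1, n-2) reference instead of the asymptotic chi-square: with a
        # handful of samples the chi-square tail is anti-conservative
        dof = max(len(k) - 2, 1)
        p = float(stats.f.sf(lrt, 1, dof))
        slope = float(full_par[1])
        # numeric curvature of the profile likelihood in b1
        h = 1e-3
        f0 = _betabinom_nll(full_par, k, totals, x, False)
        up = full_par.copy(); up[1] += h
        dn = full_par.copy(); dn[1] -= h
        second = (_betabinom_nll(up, k, totals, x, False) - 2 * f0
                  + _betabinom_nll(dn, k, totals, x, False)) / h ** 2
        se = 1.0 / math.sqrt(second) if second > 0 else float("nan")
        rows.append({
            "unit": t, "slope": slope,
            "ci_low": slope - 1.96 * se, "ci_high": slope + 1.96 * se,
            "p_value": p,
            "direction": AIN if slope >= 0 else ATN,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = out["p_value"] < alpha
    return out
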