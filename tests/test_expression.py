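"""DE, module scoring, GSEA, fibrotic signature, pseudobulk, proteomics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nephroniche import catalogs
from nephroniche.cell_typing import normalize_expression
from nephroniche.errors import ConfigurationError
from nephroniche.expression import (differential_expression,
                                    fibrosis_signature, gsea_preranked,
                                    module_score, proteomics_concordance,
                                    pseudobulk_area_normalized,
                                    rank_statistic)


class TestDifferentialExpression:
    def test_identical_groups_give_zero_fold(self):
        x = np.random.default_rng(0).poisson(3, size=(10, 5)).astype(float)
        both = np.arange(10)
        de = differential_expression(x, list("ABCDE"), both, both)
        np.testing.assert_allclose(de["log2fc"], 0.0)

    def test_exclusive_gene_is_top_hit(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(2, size=(20, 4)).astype(float)
        x[:10, 0] += 50.0
        x[:, 3] = 1.0  # constant gene -> p = 1 by convention
        de = differential_expression(x, list("ABCD"),
                                     np.arange(10), np.arange(10, 20))
        de = de.set_index("gene")
        assert de.loc["A", "log2fc"] > 0
        assert de.loc["A", "p_value"] == de["p_value"].min()
        assert de.loc["D", "p_value"] == 1.0

    def test_wilcoxon_matches_exact_enumeration(self):
        # brute-force null distribution of the rank-sum statistic at n <= 10
        rng = np.random.default_rng(2)
        a = rng.normal(size=5)
        b = rng.normal(size=5) + 0.5
        values = np.concatenate([a, b])
        u_obs = stats.rankdata(values)[:5].sum() - 5 * 6 / 2
        count = 0
        total = 0
        ranks = stats.rankdata(values)
        for combo in itertools.combinations(range(10), 5):
            u = ranks[list(combo)].sum() - 5 * 6 / 2
            # two-sided: as or more extreme than observed
            if abs(u - 12.5) >= abs(u_obs - 12.5) - 1e-9:
                count += 1
            total += 1
        exact_p = count / total
        x = np.concatenate([a, b])[:, None]
        de = differential_expression(x, ["G"], np.arange(5),
                                     np.arange(5, 10))
        assert de["p_value"].iloc[0] == pytest.approx(exact_p, abs=1e-9)


def reference_module_score(values, set_idx, r_max):
    """Literal transcription of the capped Mann-Whitney score formula."""
    ranks = stats.rankdata(-np.asarray(values, float), method="average")
    capped = [min(ranks[i], r_max) for i in set_idx]
    n = len(set_idx)
    u = sum(capped) - n * (n + 1) / 2
    return 1.0 - u / (n * r_max)


class TestModuleScore:
    def test_top_genes_score_one(self):
        x = np.array([[9.0, 8.0, 1.0, 0.5, 0.1]])
        s = module_score(x, list("ABCDE"), ["A", "B"], r_max=5)
        assert s[0] == pytest.approx(1.0)

    def test_uniform_ties_match_formula(self):
        x = np.full((1, 6), 3.0)
        s = module_score(x, list("ABCDEF"), ["A", "B"], r_max=6)
        rbar = (6 + 1) / 2  # average tie rank, below the cap
        expect = 1.0 - (rbar - (2 + 1) / 2) / 6
        assert s[0] == pytest.approx(expect)

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        x = rng.gamma(1.0, 2.0, size=(100, 30))
        gene_set = ["g2", "g11", "g17", "g23", "g29"]
        set_idx = [genes.index(g) for g in gene_set]
        got = module_score(x, genes, gene_set, r_max=20)
        for i in range(100):
            assert got[i] == pytest.approx(
                reference_module_score(x[i], set_idx, 20), abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(1.0, 2.0, size=(20, 15))
        genes = [f"g{i}" for i in range(15)]
        s1 = module_score(x, genes, ["g3", "g7"], r_max=10)
        s2 = module_score(np.log1p(x) ** 3, genes, ["g3", "g7"], r_max=10)
        np.testing.assert_allclose(s1, s2)

    def test_bounds_and_errors(self):
        x = np.random.default_rng(5).poisson(2, size=(50, 10)).astype(float)
        genes = [f"g{i}" for i in range(10)]
        s = module_score(x, genes, ["g0", "g5", "g9"])
        assert ((0 <= s) & (s <= 1)).all()
        with pytest.raises(ConfigurationError):
            module_score(x, genes, [])
        with pytest.raises(ConfigurationError):
            module_score(x, genes, ["g0", "g1"], r_max=1)


def reference_enrichment_score(stat, gene_set, weight=1.0):
    """Brute-force running sum over the full ranking."""
    order = sorted(stat.index, key=lambda g: -stat[g])
    in_set = [g in gene_set for g in order]
    hit_w = [abs(stat[g]) ** weight if m else 0.0
             for g, m in zip(order, in_set)]
    total_hit = sum(hit_w)
    n_miss = sum(1 for m in in_set if not m)
    best = 0.0
    running = 0.0
    for w, m in zip(hit_w, in_set):
        running += (w / total_hit) if m else (-1.0 / n_miss)
        if abs(running) > abs(best):
            best = running
    return best


class TestGSEA:
    def test_degenerate_maximum(self):
        stat = pd.Series({**{f"s{i}": 2.0 for i in range(3)},
                          **{f"o{i}": 0.0 for i in range(9)}})
        res = gsea_preranked(stat, ["s0", "s1", "s2"], n_perm=50, seed=0)
        assert res["es"] == pytest.approx(1.0)

    def test_es_matches_bruteforce_on_12_gene_panel(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(12)]
        stat = pd.Series(rng.normal(size=12), index=genes)
        gene_set = ["g1", "g5", "g9"]
        res = gsea_preranked(stat, gene_set, n_perm=10, seed=0)
        assert res["es"] == pytest.approx(
            reference_enrichment_score(stat, set(gene_set)), abs=1e-12)

    def test_es_bounded(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(40)]
        for trial in range(5):
            stat = pd.Series(rng.normal(size=40), index=genes)
            res = gsea_preranked(stat, genes[:6], n_perm=20, seed=trial)
            assert -1.0 <= res["es"] <= 1.0

    def test_p_superuniform_under_random_statistic(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(50)]
        ps = []
        for trial in range(100):
            stat = pd.Series(rng.normal(size=50), index=genes)
            res = gsea_preranked(stat, genes[:8], n_perm=99, seed=trial)
            ps.append(res["p_value"])
        assert np.mean(np.array(ps) < 0.05) <= 0.10

    def test_set_larger_than_panel_rejected(self):
        stat = pd.Series(np.ones(4), index=list("ABCD"))
        with pytest.raises(ConfigurationError):
            gsea_preranked(stat, list("ABCD"))

    def test_planted_condition_signs(self, run1):
        # AIN-vs-ATN niche ranking: the interferon-gamma response set
        # enriches positively; oxidative phosphorylation depletes in the
        # tubular-niche ranking
        tab = run1.niches.table
        cond = tab["sample_id"].map(run1.condition_of).to_numpy()
        de = differential_expression(run1.norm_niche, run1.niches.genes,
                                     cond == "AIN", cond == "ATN")
        stat = rank_statistic(de)
        res = gsea_preranked(stat, catalogs.GENE_SETS["IFNg Response"],
                             n_perm=200, seed=0)
        assert res["nes"] > 0 and res["p_value"] < 0.05
        tubular = tab["major_type"].isin([
            "proximal tubule", "thick ascending limb",
            "distal convoluted tubule", "collecting duct",
            "injured proximal tubule"]).to_numpy()
        de_t = differential_expression(
            run1.norm_niche, run1.niches.genes,
            tubular & (cond == "AIN"), tubular & (cond == "ATN"))
        res_ox = gsea_preranked(
            rank_statistic(de_t),
            catalogs.GENE_SETS["Oxidative Phosphorylation"],
            n_perm=200, seed=0)
        assert res_ox["nes"] < 0 and res_ox["p_value"] < 0.05


class TestFibrosisSignature:
    def _de(self, n, rng):
        return pd.DataFrame({
            "gene": [f"g{i}" for i in range(n)],
            "log2fc": rng.normal(1.0, 0.2, n),
            "p_value": rng.uniform(size=n),
            "q_value": rng.uniform(size=n),
        })

    def test_exactly_100_genes(self):
        de = self._de(250, np.random.default_rng(9))
        assert len(fibrosis_signature(de)) == 100

    def test_truncates_with_warning(self):
        de = self._de(40, np.random.default_rng(10))
        with pytest.warns(UserWarning, match="40 eligible"):
            sig = fibrosis_signature(de)
        assert len(sig) == 40

    def test_deterministic(self):
        de = self._de(300, np.random.default_rng(11))
        assert fibrosis_signature(de) == fibrosis_signature(
            de.sample(frac=1.0, random_state=0))

    def test_resident_myeloid_ranks_first(self, run1):
        import warnings as _w
        tab = run1.niches.table
        fib = (tab["major_type"] == "fibrotic").to_numpy()
        de = differential_expression(run1.norm_niche, run1.niches.genes,
                                     fib, ~fib)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            sig = fibrosis_signature(de)
        assert len(sig) >= 80
        scores = module_score(run1.norm_niche, run1.niches.genes, sig)
        imm = tab["subtype"] != ""
        means = (pd.Series(scores[imm.to_numpy()])
                 .groupby(tab.loc[imm, "subtype"].to_numpy()).mean())
        assert means.idxmax() == "M2-like"


class TestPseudobulk:
    def _toy(self):
        t = pd.DataFrame({
            "sample_id": ["S0"] * 300 + ["S1"] * 100,
            "gene": ["CXCL9"] * 300 + ["CXCL9"] * 100,
            "x_um": 0.0, "y_um": 0.0,
            "cell_id": "c1",
        })
        meta = pd.DataFrame({"sample_id": ["S0", "S1"],
                             "condition": ["AIN", "ATN"],
                             "biopsy_area_mm2": [2.0, 1.0]})
        return t, meta

    def test_arithmetic_and_zero_gene(self):
        t, meta = self._toy()
        d = pseudobulk_area_normalized(t, meta, ["CXCL9", "EGF"])
        assert d.loc["S0", "CXCL9"] == pytest.approx(150.0)
        assert d.loc["S1", "CXCL9"] == pytest.approx(100.0)
        assert d.loc["S0", "EGF"] == 0.0

    def test_doubling_area_halves_density(self):
        t, meta = self._toy()
        d1 = pseudobulk_area_normalized(t, meta, ["CXCL9"])
        meta2 = meta.assign(biopsy_area_mm2=meta["biopsy_area_mm2"] * 2)
        d2 = pseudobulk_area_normalized(t, meta2, ["CXCL9"])
        np.testing.assert_allclose(d2.to_numpy(), d1.to_numpy() / 2)

    def test_density_times_area_conserves_counts(self, run1):
        cohort = run1.cohort
        d = pseudobulk_area_normalized(cohort.transcripts, cohort.samples,
                                       catalogs.PROTEOMICS_GENES)
        areas = cohort.samples.set_index("sample_id")["biopsy_area_mm2"]
        total = float((d.mul(areas, axis=0)).to_numpy().sum())
        t = cohort.transcripts
        expect = ((t["cell_id"] != "")
                  & t["gene"].isin(catalogs.PROTEOMICS_GENES)).sum()
        assert total == pytest.approx(float(expect))


class TestProteomicsConcordance:
    def test_identical_tables_fully_agree(self):
        meta = pd.DataFrame({"sample_id": ["S0", "S1", "S2", "S3"],
                             "condition": ["AIN", "AIN", "ATN", "ATN"],
                             "biopsy_area_mm2": 1.0})
        d = pd.DataFrame({"CXCL9": [5.0, 6.0, 1.0, 2.0]},
                         index=meta["sample_id"])
        out = proteomics_concordance(d, d.copy(), ["CXCL9"], meta)
        assert out["agree"].all()
        assert out["separated_rna"].all()

    def test_planted_signs_on_default_cohort(self, run1):
        # transcript densities separate conditions for the interferon
        # chemokines; a synthetic protein table built with the published
        # direction signs agrees on direction for every pair
        cohort = run1.cohort
        dens = pseudobulk_area_normalized(cohort.transcripts, cohort.samples,
                                          catalogs.PROTEOMICS_GENES)
        rng = np.random.default_rng(0)
        cond = cohort.samples.set_index("sample_id")["condition"]
        protein = pd.DataFrame(index=dens.index)
        for g in catalogs.PROTEOMICS_GENES:
            up_in_ain = g != "EGF"
            base = np.where((cond == "AIN") == up_in_ain, 8.0, 2.0)
            protein[g] = base + rng.normal(0, 0.5, len(base))
        out = proteomics_concordance(dens, protein,
                                     catalogs.PROTEOMICS_GENES,
                                     cohort.samples)
        out = out.set_index("pair")
        assert out["agree"].all()
        for g in ("CXCL9", "CXCL10", "CXCL11"):
            assert out.loc[g, "rna_diff"] > 0
            assert out.loc[g, "separated_rna"], g

    def test_unpairable_name_skipped(self):
        meta = pd.DataFrame({"sample_id": ["S0", "S1"],
                             "condition": ["AIN", "ATN"],
                             "biopsy_area_mm2": 1.0})
        d = pd.DataFrame({"CXCL9": [1.0, 2.0]}, index=meta["sample_id"])
        with pytest.warns(UserWarning, match="GHOST"):
            out = proteomics_concordance(d, d, ["CXCL9", "GHOST"], meta)
        assert list(out["pair"]) == ["CXCL9"]
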