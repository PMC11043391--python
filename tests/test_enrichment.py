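"""Enrichment statistics: hypergeometric ORA, BH, TF activity, ES, module scores."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from screenkit.enrichment import (
    GeneSetCollection,
    benjamini_hochberg,
    combined_score,
    de_gene_list,
    hypergeometric_enrich,
    infer_tf_activity,
    module_score,
    normalize_counts,
    preranked_es,
)
from screenkit import synthetic as syn


def _genes(n, prefix="G"):
    return [f"{prefix}{i + 1:04d}" for i in range(n)]


class TestHypergeometric:
    def test_zero_overlap_saturates_at_one(self):
        bg = _genes(50)
        sets = GeneSetCollection({"S": frozenset(bg[:10])})
        res = hypergeometric_enrich(bg[10:20], sets, bg)
        assert res["p"].iloc[0] == 1.0

    def test_full_overlap_closed_form(self):
        # N=100, K=10, n=10, k=10 -> p = 1 / C(100, 10)
        bg = _genes(100)
        sets = GeneSetCollection({"S": frozenset(bg[:10])})
        res = hypergeometric_enrich(bg[:10], sets, bg)
        assert res["p"].iloc[0] == pytest.approx(1 / math.comb(100, 10), rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_pmf_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(30, 80))
        K = int(rng.integers(5, 15))
        n = int(rng.integers(5, 20))
        bg = _genes(N)
        members = rng.choice(bg, K, replace=False)
        query = rng.choice(bg, n, replace=False)
        res = hypergeometric_enrich(query, GeneSetCollection({"S": frozenset(members)}), bg)
        k = len(set(members) & set(query))
        expected = sum(
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
            for i in range(k, min(K, n) + 1)
        )
        assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-10)

    def test_query_outside_background_rejected(self):
        bg = _genes(10)
        sets = GeneSetCollection({"S": frozenset(bg[:3])})
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrich(["NOT_THERE"], sets, bg)

    def test_monotone_decreasing_in_overlap(self):
        bg = _genes(200)
        sets = GeneSetCollection({"S": frozenset(bg[:40])})
        ps = []
        for k in (5, 10, 15, 20):
            query = bg[:k] + bg[40 : 40 + (20 - k)]
            ps.append(hypergeometric_enrich(query, sets, bg)["p"].iloc[0])
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.037])[0] == pytest.approx(0.037)

    def test_hand_applied_step_up(self):
        out = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_statsmodels_oracle(self, seed):
        p = np.random.default_rng(seed).uniform(size=25)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(benjamini_hochberg(p), expected)

    def test_monotone_in_sorted_order_and_bounded(self):
        p = np.random.default_rng(9).uniform(size=40)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert adj.max() <= 1.0
        assert adj[np.argmax(p)] >= p.max()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.2])


class TestCombinedScore:
    def test_null_p_scores_zero(self):
        assert combined_score(1.0, 123.0) == 0.0

    @pytest.mark.parametrize("p,oddsr", [(0.01, 2.0), (1e-5, 0.5), (0.5, 10.0)])
    def test_matches_hand_formula(self, p, oddsr):
        assert combined_score(p, oddsr) == pytest.approx(-math.log(p) * oddsr)

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            combined_score(0.0, 1.0)


class TestDEGeneList:
    def test_dual_cutoff_with_inclusive_fc(self):
        stats = pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "log2fc": [np.log2(1.5), -np.log2(1.5), 2.0, 0.1],
                "p": [0.005, 0.005, 0.5, 0.001],
            }
        )
        assert de_gene_list(stats) == ["a", "b"]  # fc boundary inclusive, p strict


class TestTFActivity:
    def test_exact_target_set_attains_min_p_and_max_activity(self):
        bg = _genes(300)
        sets = GeneSetCollection(
            {
                "TF1": frozenset(bg[:20]),
                "TF2": frozenset(bg[100:120]),
                "TF3": frozenset(bg[200:220]),
            }
        )
        res = infer_tf_activity(bg[:20], sets, bg).set_index("tf")
        assert res["p"].idxmin() == "TF1"
        assert res.loc["TF1", "significant"]
        assert res["activity"].idxmax() == "TF1"
        assert res["activity"].max() == pytest.approx(1.0)  # log2(1 + 1)

    def test_null_false_significance_near_nominal(self):
        bg = _genes(2000)
        sets = syn.random_gene_sets(bg, n_sets=50, set_size=200, seed=0, prefix="TF")
        rng = np.random.default_rng(1)
        flags = []
        for seed in range(40):
            query = rng.choice(bg, 400, replace=False)
            res = infer_tf_activity(query, sets, bg)
            flags.append(res["significant"].to_numpy())
        rate = np.concatenate(flags).mean()
        assert rate <= 0.02


class TestPrerankedES:
    def test_hand_computed_running_sum(self):
        # 10 genes, 3-member set at ranks 1, 4, 5; weight 1
        scores = np.array([5.0, 4.0, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5, 0.4, 0.1])
        genes = [f"g{i}" for i in range(10)]
        ranked = pd.Series(scores, index=genes)
        gene_set = {"g0", "g3", "g4"}
        hit_w = {0: 5.0, 3: 2.5, 4: 2.0}
        denom = sum(hit_w.values())
        run, expected = 0.0, 0.0
        for i in range(10):
            run += hit_w[i] / denom if i in hit_w else -1 / 7
            if abs(run) > abs(expected):
                expected = run
        es, _ = preranked_es(ranked, gene_set, n_permutations=10, seed=0)
        assert es == pytest.approx(expected, rel=1e-12)

    def test_top_block_equal_scores_reaches_one_unweighted(self):
        ranked = pd.Series(np.ones(10), index=[f"g{i}" for i in range(10)])
        es, _ = preranked_es(ranked, {"g0", "g1", "g2"}, n_permutations=10, seed=0,
                             weight=0.0)
        assert es == pytest.approx(1.0 - 0.0)

    def test_whole_list_set_degenerates_to_zero(self):
        ranked = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="entire"):
            es, p = preranked_es(ranked, {"a", "b", "c"})
        assert es == 0.0 and p == 1.0

    def test_empty_intersection_rejected(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError, match="intersect"):
            preranked_es(ranked, {"zzz"})

    def test_planted_top_set_significant(self):
        rng = np.random.default_rng(3)
        scores = np.sort(rng.normal(size=200))[::-1]
        ranked = pd.Series(scores, index=[f"g{i}" for i in range(200)])
        es, p = preranked_es(ranked, {f"g{i}" for i in range(15)},
                             n_permutations=500, seed=4)
        assert es > 0.5 and p < 0.01


class TestModuleScore:
    def _matrix(self, seed=0, n_genes=300, n_cells=80):
        rng = np.random.default_rng(seed)
        raw = pd.DataFrame(
            rng.negative_binomial(2, 0.3, size=(n_genes, n_cells)),
            index=_genes(n_genes),
            columns=[f"c{i}" for i in range(n_cells)],
        )
        return normalize_counts(raw)

    def test_constant_matrix_scores_exactly_zero(self):
        expr = pd.DataFrame(
            np.ones((50, 20)), index=_genes(50), columns=[f"c{i}" for i in range(20)]
        )
        scores = module_score(expr, _genes(50)[:5], seed=0)
        assert (scores == 0.0).all()

    def test_null_signature_mean_score_near_zero(self):
        expr = self._matrix(seed=1)
        rng = np.random.default_rng(2)
        sig = rng.choice(expr.index, 30, replace=False)
        scores = module_score(expr, sig, seed=3)
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) < 3 * max(se, 1e-3)

    def test_planted_shift_detected_between_arms(self):
        from screenkit.highcontent import wilcoxon_rank_sum

        rng = np.random.default_rng(4)
        n_genes, n_cells = 400, 1000  # 500 cells per arm
        raw = rng.negative_binomial(2, 0.3, size=(n_genes, n_cells)).astype(float)
        sig_idx = rng.choice(n_genes, 25, replace=False)
        raw[np.ix_(sig_idx, np.arange(500, n_cells))] *= np.e  # ~1 log-unit up-shift
        expr = normalize_counts(
            pd.DataFrame(raw, index=_genes(n_genes), columns=[f"c{i}" for i in range(n_cells)])
        )
        scores = module_score(expr, [expr.index[i] for i in sig_idx], seed=5)
        p = wilcoxon_rank_sum(scores.iloc[:500], scores.iloc[500:])
        assert scores.iloc[500:].mean() > scores.iloc[:500].mean()
        assert p < 1e-3

    def test_absent_signature_genes_dropped_with_warning(self):
        expr = self._matrix(seed=6)
        with pytest.warns(UserWarning, match="absent"):
            scores = module_score(expr, [expr.index[0], "MISSING"], seed=0)
        assert len(scores) == expr.shape[1]
        with pytest.raises(ValueError, match="no signature gene"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                module_score(expr, ["MISSING"], seed=0)
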