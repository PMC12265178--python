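import numpy as np
import pandas as pd
import pytest
from scipy import stats

from periscope.enrichment import (
    MAX_FINITE_STATISTIC,
    RankedList,
    bootstrap_stability,
    leading_edge_genes,
    preranked_gsea,
    rank_genes,
    ssgsea_scores,
)
from periscope.io_formats import GeneSet, GeneSetCollection
from periscope.preprocess import TransformedMatrix

from _oracles import brute_preranked_es, brute_ssgsea_score


def _tm(values, genes=None, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return TransformedMatrix(genes, samples, values)


class TestSsgsea:
    def test_matches_oracle_small_case(self):
        tm = _tm([[5.0], [4.0], [3.0], [2.0], [1.0]])
        sets = GeneSetCollection([GeneSet("TOP2", "", ["G0", "G1"])])
        em = ssgsea_scores(tm, sets, weight=0.25, min_set_size=1, normalize=False)
        expected = brute_ssgsea_score(
            {f"G{i}": 5.0 - i for i in range(5)}, {"G0", "G1"}, 0.25
        )
        assert em.scores[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_rank_invariance_constant_shift(self, small_transformed, marker_sets):
        em = ssgsea_scores(small_transformed, marker_sets)
        shifted = TransformedMatrix(
            list(small_transformed.gene_ids),
            list(small_transformed.sample_ids),
            small_transformed.values + 7.3,
        )
        em2 = ssgsea_scores(shifted, marker_sets)
        assert np.allclose(em.scores, em2.scores)

    def test_whole_universe_set_degenerate_decrement(self):
        tm = _tm([[3.0], [2.0], [1.0]])
        sets = GeneSetCollection([GeneSet("ALL", "", ["G0", "G1", "G2"])])
        em = ssgsea_scores(tm, sets, min_set_size=1, normalize=False)
        expected = brute_ssgsea_score({f"G{i}": 3.0 - i for i in range(3)}, {"G0", "G1", "G2"}, 0.25)
        assert em.scores[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_random_universes_match_oracle(self):
        """1000 random universes up to 20 genes agree with enumeration."""
        rng = np.random.default_rng(12)
        for _ in range(1000):
            n = int(rng.integers(3, 21))
            m = int(rng.integers(1, n + 1))
            expr = rng.normal(size=n)
            genes = [f"G{i}" for i in range(n)]
            members = list(rng.choice(genes, size=m, replace=False))
            weight = float(rng.choice([0.0, 0.25, 1.0]))
            tm = _tm(expr[:, None], genes=genes)
            em = ssgsea_scores(
                tm,
                GeneSetCollection([GeneSet("S", "", members)]),
                weight=weight,
                min_set_size=1,
                normalize=False,
            )
            expected = brute_ssgsea_score(dict(zip(genes, expr)), set(members), weight)
            assert em.scores[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_small_sets_dropped_with_warning(self, small_transformed):
        sets = GeneSetCollection(
            [GeneSet("TINY", "", ["G000"]), GeneSet("OK", "", [f"G{i:03d}" for i in range(6)])]
        )
        with pytest.warns(UserWarning, match="TINY"):
            em = ssgsea_scores(small_transformed, sets, min_set_size=5)
        assert em.set_names == ["OK"]

    def test_column_permutation_equivariance(self, small_transformed, marker_sets):
        em = ssgsea_scores(small_transformed, marker_sets)
        perm = [2, 0, 1, 3, 5, 4, 7, 6]
        permuted = small_transformed.subset_samples(
            [small_transformed.sample_ids[i] for i in perm]
        )
        em2 = ssgsea_scores(permuted, marker_sets)
        assert np.allclose(em.scores[:, perm], em2.scores)


class TestRankGenes:
    def test_welch_t_hand_case(self):
        values = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [0, 0, 0, 0, 0, 0.0]])
        tm = _tm(values)
        ranked = rank_genes(tm, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        stat = dict(zip(ranked.gene_ids, ranked.statistics))
        assert stat["G0"] == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-9)

    def test_identical_groups_zero_statistic(self):
        tm = _tm(np.tile([[1.0, 2.0, 5.0]], (4, 2)).reshape(4, 6))
        ranked = rank_genes(tm, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        assert np.allclose(ranked.statistics, 0.0)

    def test_degenerate_paired_sentinel_ranks_first(self):
        values = np.array([[3.0, 4.0, 1.0, 2.0], [0.5, 0.1, 0.4, 0.3]])
        tm = _tm(values, samples=["a1", "a2", "b1", "b2"])
        paired = {"a1": "p1", "a2": "p2", "b1": "p1", "b2": "p2"}
        ranked = rank_genes(tm, ["a1", "a2"], ["b1", "b2"], paired_by=paired)
        assert ranked.gene_ids[0] == "G0"
        assert ranked.statistics[0] == MAX_FINITE_STATISTIC

    def test_sample_in_both_groups_rejected(self, small_transformed):
        with pytest.raises(Exception, match="both groups"):
            rank_genes(small_transformed, ["S0", "S1"], ["S1", "S2"])


class TestPrerankedGsea:
    def test_top_set_positive_and_matches_oracle(self):
        ranked = RankedList([f"G{i}" for i in range(6)], [3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        sets = GeneSetCollection([GeneSet("TOP", "", ["G0", "G1"])])
        res = preranked_gsea(ranked, sets, n_perm=200, seed=0)
        es_oracle, le_oracle = brute_preranked_es(
            ranked.gene_ids, list(ranked.statistics), {"G0", "G1"}, 1.0
        )
        assert res.table.loc["TOP", "es"] > 0
        assert res.table.loc["TOP", "es"] == pytest.approx(es_oracle, abs=1e-12)
        assert leading_edge_genes(res, "TOP") == le_oracle

    def test_random_cases_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(4, 21))
            stats_ = np.sort(rng.normal(size=n))[::-1]
            genes = [f"G{i}" for i in range(n)]
            m = int(rng.integers(1, n))
            members = set(rng.choice(genes, size=m, replace=False))
            ranked = RankedList(genes, stats_)
            res = preranked_gsea(
                ranked, GeneSetCollection([GeneSet("S", "", sorted(members))]),
                n_perm=100, seed=1,
            )
            es_oracle, le_oracle = brute_preranked_es(genes, list(stats_), members, 1.0)
            assert res.table.loc["S", "es"] == pytest.approx(es_oracle, abs=1e-9)
            assert leading_edge_genes(res, "S") == le_oracle

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(9)
        stats_ = np.sort(rng.normal(size=30))[::-1]
        genes = [f"G{i}" for i in range(30)]
        members = sorted(rng.choice(genes, size=8, replace=False))
        sets = GeneSetCollection([GeneSet("S", "", members)])
        fwd = preranked_gsea(RankedList(genes, stats_), sets, n_perm=500, seed=3)
        rev = preranked_gsea(
            RankedList(genes[::-1], -stats_[::-1]), sets, n_perm=500, seed=3
        )
        assert fwd.table.loc["S", "es"] == pytest.approx(-rev.table.loc["S", "es"], abs=1e-12)
        assert abs(fwd.table.loc["S", "nes"]) == pytest.approx(
            abs(rev.table.loc["S", "nes"]), rel=0.25
        )

    def test_pvalues_never_zero_and_nes_sign(self):
        rng = np.random.default_rng(2)
        stats_ = np.sort(rng.normal(size=40))[::-1]
        genes = [f"G{i}" for i in range(40)]
        sets = GeneSetCollection(
            [GeneSet(f"S{k}", "", sorted(rng.choice(genes, size=6, replace=False))) for k in range(5)]
        )
        res = preranked_gsea(RankedList(genes, stats_), sets, n_perm=100, seed=0)
        assert (res.table["pval"] >= 1 / 101).all()
        assert (np.sign(res.table["nes"]) == np.sign(res.table["es"])).all()
        assert (res.table["padj"] >= res.table["pval"]).all()

    def test_single_set_padj_equals_pval(self):
        ranked = RankedList([f"G{i}" for i in range(10)], np.linspace(2, -2, 10))
        sets = GeneSetCollection([GeneSet("S", "", ["G0", "G3"])])
        res = preranked_gsea(ranked, sets, n_perm=100, seed=0)
        assert res.table["padj"].iloc[0] == res.table["pval"].iloc[0]

    def test_oversized_set_rejected(self):
        ranked = RankedList(["G0", "G1"], [1.0, -1.0])
        sets = GeneSetCollection([GeneSet("BIG", "", ["G0", "G1", "G2"])])
        with pytest.raises(Exception, match="larger"):
            preranked_gsea(ranked, sets, n_perm=100, seed=0)

    def test_null_pvalues_uniform(self):
        """Random sets on random lists give uniform permutation p-values."""
        rng = np.random.default_rng(7)
        pvals = []
        genes = [f"G{i}" for i in range(40)]
        for rep in range(500):
            stats_ = np.sort(rng.normal(size=40))[::-1]
            members = sorted(rng.choice(genes, size=8, replace=False))
            res = preranked_gsea(
                RankedList(genes, stats_),
                GeneSetCollection([GeneSet("S", "", members)]),
                n_perm=400,
                seed=rng,
            )
            pvals.append(res.table["pval"].iloc[0])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestLeadingEdge:
    def test_set_at_top_returns_whole_set(self):
        ranked = RankedList([f"G{i}" for i in range(10)], np.linspace(3, -3, 10))
        sets = GeneSetCollection([GeneSet("S", "", ["G0", "G1", "G2"])])
        res = preranked_gsea(ranked, sets, n_perm=100, seed=0)
        assert leading_edge_genes(res, "S") == ["G0", "G1", "G2"]

    def test_bottom_set_mirror_case(self):
        ranked = RankedList([f"G{i}" for i in range(10)], np.linspace(3, -3, 10))
        sets = GeneSetCollection([GeneSet("S", "", ["G7", "G8", "G9"])])
        res = preranked_gsea(ranked, sets, n_perm=100, seed=0)
        assert res.table.loc["S", "es"] < 0
        assert leading_edge_genes(res, "S") == ["G7", "G8", "G9"]

    def test_unknown_set_raises(self):
        ranked = RankedList(["G0", "G1", "G2"], [1.0, 0.0, -1.0])
        res = preranked_gsea(
            ranked, GeneSetCollection([GeneSet("S", "", ["G0"])]), n_perm=100, seed=0
        )
        with pytest.raises(KeyError):
            leading_edge_genes(res, "NOPE")


class TestBootstrapStability:
    def _contrast(self, effect):
        rng = np.random.default_rng(21)
        n_genes, per_group = 40, 10
        genes = [f"G{i}" for i in range(n_genes)]
        values = rng.normal(size=(n_genes, 2 * per_group))
        values[:8, :per_group] += effect  # first 8 genes up in group A
        samples = [f"A{i}" for i in range(per_group)] + [f"B{i}" for i in range(per_group)]
        tm = TransformedMatrix(genes, samples, values)
        sets = GeneSetCollection(
            [GeneSet("TRUE_BLOCK", "", genes[:8]), GeneSet("NULL_BLOCK", "", genes[20:28])]
        )
        return tm, samples[:per_group], samples[per_group:], sets

    def test_strong_effect_fully_stable(self):
        tm, a, b, sets = self._contrast(effect=4.0)
        res = bootstrap_stability(tm, a, b, sets, n_iter=20, seed=0, n_perm=200)
        assert res.table.loc["TRUE_BLOCK", "stability_fraction"] == 1.0

    def test_null_block_rarely_called(self):
        tm, a, b, sets = self._contrast(effect=4.0)
        res = bootstrap_stability(tm, a, b, sets, n_iter=20, seed=0, n_perm=200)
        assert res.table.loc["NULL_BLOCK", "stability_fraction"] < 0.2

    def test_single_iteration_fraction_binary(self):
        tm, a, b, sets = self._contrast(effect=4.0)
        res = bootstrap_stability(tm, a, b, sets, n_iter=1, seed=0, n_perm=200)
        assert set(res.table["stability_fraction"]) <= {0.0, 1.0}

    def test_counts_bounded_by_iterations(self):
        tm, a, b, sets = self._contrast(effect=1.0)
        res = bootstrap_stability(tm, a, b, sets, n_iter=10, seed=1, n_perm=100)
        total = res.table["n_enriched_positive"] + res.table["n_enriched_negative"]
        assert (total <= res.table["n_iterations"]).all()
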