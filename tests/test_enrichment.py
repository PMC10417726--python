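"""Running-sum enrichment score against brute-force oracles, permutation
significance calibration, and hypergeometric over-representation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lnctrace as lt
from lnctrace.errors import ConfigError, ValidationError
from lnctrace.io import GeneSet, GeneSetCollection


def brute_force_es(symbols, metrics, members, exponent=1.0):
    """Independent step-by-step running-sum evaluation."""
    members = set(members)
    hits = [s in members for s in symbols]
    m = sum(hits)
    total = sum(abs(v) ** exponent for s, v in zip(symbols, metrics)
                if s in members)
    running, best, value = [], 0.0, 0.0
    for s, v in zip(symbols, metrics):
        if s in members:
            value += (abs(v) ** exponent) / total if total > 0 else 1.0 / m
        else:
            value -= 1.0 / (len(symbols) - m)
        running.append(value)
        if abs(value) > abs(best):
            best = value
    return best, running


def _ranked(metrics, prefix="g"):
    order = sorted(range(len(metrics)), key=lambda i: (-metrics[i], f"{prefix}{i}"))
    return lt.RankedList(tuple(f"{prefix}{i}" for i in order),
                         np.asarray([metrics[i] for i in order], dtype=float),
                         "stat")


class TestRanking:
    def _result(self, pairs):
        df = pd.DataFrame(pairs, columns=["gene_id", "wald_stat"])
        df["base_mean"] = 1.0
        df["log2fc"] = df["wald_stat"] / 2
        df["se"] = 0.5
        df["pvalue"] = 0.5
        df["padj"] = 0.5
        return lt.DEResult(table=df, contrast=("WT", 6))

    def test_descending_metric_order(self):
        ranked = lt.rank_genes(self._result([("a", 2.0), ("b", -1.0), ("c", 3.0)]))
        assert ranked.symbols == ("c", "a", "b")

    def test_ties_broken_lexicographically(self):
        ranked = lt.rank_genes(self._result([("zz", 1.0), ("aa", 1.0)]))
        assert ranked.symbols == ("aa", "zz")

    def test_invariant_to_input_row_order(self):
        rows = [("a", 2.0), ("b", -1.0), ("c", 3.0)]
        r1 = lt.rank_genes(self._result(rows))
        r2 = lt.rank_genes(self._result(rows[::-1]))
        assert r1.symbols == r2.symbols

    def test_duplicate_symbols_rejected(self):
        with pytest.raises(ValidationError, match="dup"):
            lt.rank_genes(self._result([("dup", 1.0), ("dup", 2.0)]))


class TestEnrichmentScore:
    def test_set_of_top_gene_scores_one(self):
        ranked = _ranked([3.0, 2.0, 1.0, 0.5])
        es, running = lt.enrichment_score(ranked, {ranked.symbols[0]})
        assert es == pytest.approx(1.0)
        assert running[0] == pytest.approx(1.0)

    def test_set_of_bottom_gene_scores_negative(self):
        ranked = _ranked([3.0, 2.0, 1.0, 0.5])
        es, _ = lt.enrichment_score(ranked, {ranked.symbols[-1]})
        assert es < 0

    def test_reversed_ranking_flips_sign_for_singleton_set(self):
        metrics = [3.0, 2.0, 1.0, 0.5]
        ranked = _ranked(metrics)
        top = {ranked.symbols[0]}
        es_fwd, _ = lt.enrichment_score(ranked, top)
        reversed_list = lt.RankedList(ranked.symbols[::-1],
                                      ranked.metrics[::-1], "stat")
        es_rev, _ = lt.enrichment_score(reversed_list, top)
        assert np.sign(es_fwd) == -np.sign(es_rev)

    @pytest.mark.parametrize("exponent", [0.0, 1.0, 2.0])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_random_lists(self, seed, exponent):
        rng = np.random.default_rng(seed)
        metrics = np.round(rng.normal(size=20), 3)
        ranked = _ranked(list(metrics))
        members = set(rng.choice(ranked.symbols, size=6, replace=False))
        es, running = lt.enrichment_score(ranked, members, exponent)
        es_bf, running_bf = brute_force_es(ranked.symbols, ranked.metrics,
                                           members, exponent)
        assert es == pytest.approx(es_bf, abs=1e-12)
        np.testing.assert_allclose(running, running_bf, atol=1e-12)

    def test_exponent_zero_equals_classic_ks_statistic(self):
        rng = np.random.default_rng(7)
        metrics = rng.normal(size=20)
        ranked = _ranked(list(metrics))
        members = set(rng.choice(ranked.symbols, size=5, replace=False))
        es, _ = lt.enrichment_score(ranked, members, weight_exponent=0.0)
        # direct KS: signed max difference of hit/miss empirical CDFs
        hits = np.array([s in members for s in ranked.symbols])
        d = np.cumsum(hits / hits.sum() - (~hits) / (~hits).sum())
        assert es == pytest.approx(d[np.argmax(np.abs(d))], abs=1e-12)

    def test_uniform_metric_scaling_leaves_es_unchanged(self):
        rng = np.random.default_rng(9)
        metrics = np.abs(rng.normal(size=30)) + 0.1
        ranked = _ranked(list(metrics))
        members = set(rng.choice(ranked.symbols, size=8, replace=False))
        es1, _ = lt.enrichment_score(ranked, members)
        scaled = lt.RankedList(ranked.symbols, ranked.metrics * 37.5, "stat")
        es2, _ = lt.enrichment_score(scaled, members)
        assert es1 == pytest.approx(es2, rel=1e-12)

    def test_whole_list_set_rejected(self):
        ranked = _ranked([2.0, 1.0])
        with pytest.raises(ValidationError):
            lt.enrichment_score(ranked, set(ranked.symbols))


class TestGseaPreranked:
    def test_planted_top_decile_set_attains_minimal_p(self):
        rng = np.random.default_rng(0)
        metrics = np.sort(rng.normal(size=500))[::-1]
        ranked = lt.RankedList(tuple(f"g{i:03d}" for i in range(500)),
                               metrics, "stat")
        coll = GeneSetCollection([GeneSet("TOP", "top decile",
                                          ranked.symbols[:50])])
        out = lt.gsea_preranked(ranked, coll, n_permutations=1000, seed=1)
        p = out.loc[out.set_name == "TOP", "pvalue"].iloc[0]
        assert p == pytest.approx(2.0 / 1001)  # add-one floor
        assert p <= 0.002
        assert out["NES"].iloc[0] > 1

    def test_random_set_on_random_ranking_is_usually_null(self):
        # A random set on a random ranking follows the permutation null, so
        # the p<=0.05 rate must stay within 3 binomial sigma of nominal.
        rng = np.random.default_rng(2)
        n_reject = 0
        for rep in range(100):
            metrics = rng.normal(size=120)
            order = np.argsort(metrics)[::-1]
            ranked = lt.RankedList(tuple(f"g{i}" for i in order),
                                   metrics[order], "stat")
            members = tuple(rng.choice(ranked.symbols, size=10, replace=False))
            coll = GeneSetCollection([GeneSet("R", "random", members)])
            out = lt.gsea_preranked(ranked, coll, n_permutations=200,
                                    seed=rep, min_size=5)
            n_reject += int(out["pvalue"].iloc[0] <= 0.05)
        assert n_reject <= 5 + 3 * np.sqrt(100 * 0.05 * 0.95)

    def test_p_stable_against_ten_fold_larger_permutation_run(self):
        rng = np.random.default_rng(3)
        metrics = rng.normal(size=200)
        metrics[:12] += 1.2  # moderate enrichment: p away from the floor
        order = np.argsort(metrics)[::-1]
        ranked = lt.RankedList(tuple(f"g{i}" for i in order), metrics[order],
                               "stat")
        coll = GeneSetCollection([GeneSet("S", "set",
                                          tuple(f"g{i}" for i in range(12)))])
        p_small = lt.gsea_preranked(ranked, coll, 500, seed=5)["pvalue"].iloc[0]
        p_big = lt.gsea_preranked(ranked, coll, 5000, seed=6)["pvalue"].iloc[0]
        mc_sd = np.sqrt(p_big * (1 - p_big) / 500)
        assert abs(p_small - p_big) <= 2 * (4 * mc_sd + 2 / 501)

    def test_zero_permutations_is_parameter_error(self):
        ranked = _ranked([3.0, 2.0, 1.0, 0.5, 0.1])
        coll = GeneSetCollection([GeneSet("S", "s", ranked.symbols[:2])])
        with pytest.raises(ConfigError):
            lt.gsea_preranked(ranked, coll, n_permutations=0)

    def test_out_of_size_bounds_sets_skipped_with_warning(self):
        ranked = _ranked(list(np.linspace(5, 1, 30)))
        coll = GeneSetCollection([GeneSet("TINY", "t", ranked.symbols[:2])])
        with pytest.warns(UserWarning, match="size bounds"):
            out = lt.gsea_preranked(ranked, coll, 10, min_size=5)
        assert len(out) == 0


class TestORA:
    def test_worked_hypergeometric_example(self):
        # universe 20, set cap universe 5, query 4, overlap 3
        universe = [f"u{i}" for i in range(20)]
        members = tuple(universe[:5])
        query = set(universe[:3]) | {universe[10]}
        coll = GeneSetCollection([GeneSet("S", "s", members)])
        out = lt.ora_hypergeometric(query, coll, universe)
        exact = sum(stats.hypergeom.pmf(k, 20, 5, 4) for k in (3, 4))
        assert out["pvalue"].iloc[0] == pytest.approx(exact, abs=1e-12)
        assert out["pvalue"].iloc[0] == pytest.approx(155 / 4845, abs=1e-9)

    def test_zero_overlap_is_clearly_null(self):
        universe = [f"u{i}" for i in range(20)]
        coll = GeneSetCollection([GeneSet("S", "s", tuple(universe[:5]))])
        out = lt.ora_hypergeometric(set(universe[10:14]), coll, universe)
        assert out["pvalue"].iloc[0] > 0.5

    def test_query_equals_set_equals_universe_gives_p_one(self):
        universe = ["a", "b", "c"]
        coll = GeneSetCollection([GeneSet("S", "s", tuple(universe))])
        out = lt.ora_hypergeometric(set(universe), coll, universe)
        assert out["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_query_outside_universe_trimmed_with_warning(self):
        universe = ["a", "b", "c", "d"]
        coll = GeneSetCollection([GeneSet("S", "s", ("a", "b"))])
        with pytest.warns(UserWarning, match="dropped"):
            out = lt.ora_hypergeometric({"a", "zzz"}, coll, universe)
        assert out["query_size"].iloc[0] == 1
        assert out["overlap"].iloc[0] <= min(out["set_size_in_universe"].iloc[0],
                                             out["query_size"].iloc[0])
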