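"""Window geometry, correlation arithmetic and screen behaviour."""

import numpy as np
import pandas as pd
import pytest

import lnctrace as lt
from lnctrace.cispair import ScreenConfig, genomic_distance, pairs_frame
from lnctrace.errors import ConfigError, ValidationError
from lnctrace.io import GeneAnnotation, GeneAnnotations


def _gene(gid, start, end, chrom="chr1", biotype="protein_coding", strand="+"):
    return GeneAnnotation(gid, gid, chrom, start, end, strand, biotype)


class TestClassify:
    def test_partition_by_biotype(self):
        ann = GeneAnnotations([
            _gene("p1", 0, 10), _gene("l1", 20, 30, biotype="lncRNA"),
            _gene("p2", 40, 50), _gene("o1", 60, 70, biotype="other")])
        lnc, pcg, other = lt.classify_biotypes(["p1", "l1", "p2", "o1"], ann)
        assert (lnc, pcg, other) == (["l1"], ["p1", "p2"], ["o1"])

    def test_empty_set_gives_empty_lists(self):
        ann = GeneAnnotations([])
        assert lt.classify_biotypes([], ann) == ([], [], [])

    def test_missing_genes_warned_and_other(self):
        ann = GeneAnnotations([_gene("p1", 0, 10)])
        with pytest.warns(UserWarning, match="ghost"):
            lnc, pcg, other = lt.classify_biotypes(["p1", "ghost"], ann)
        assert other == ["ghost"]

    def test_matches_brute_force_lookup_on_fixture(self, default_sim):
        _, ann, truth, _, _ = default_sim
        degs = sorted(truth.de_genes)
        lnc, pcg, other = lt.classify_biotypes(degs, ann)
        for g in degs:
            bucket = {"lncRNA": lnc, "protein_coding": pcg}.get(
                ann[g].biotype, other)
            assert g in bucket


class TestWindow:
    LNC = _gene("lnc", 1_000_000, 1_001_000, biotype="lncRNA")

    def test_gap_inside_window_is_candidate(self):
        pcg = _gene("p", 1_400_000, 1_402_000)
        out = lt.window_candidates(self.LNC, [pcg], 500_000)
        assert out == [(pcg, 399_000)]

    def test_gap_outside_window_excluded(self):
        pcg = _gene("p", 1_600_000, 1_602_000)
        assert lt.window_candidates(self.LNC, [pcg], 500_000) == []

    def test_boundary_gap_is_inclusive(self):
        pcg = _gene("p", 1_501_000, 1_502_000)  # gap exactly 500,000
        out = lt.window_candidates(self.LNC, [pcg], 500_000)
        assert out and out[0][1] == 500_000

    def test_overlap_means_distance_zero(self):
        pcg = _gene("p", 1_000_500, 1_003_000)
        assert lt.window_candidates(self.LNC, [pcg])[0][1] == 0

    def test_other_chromosome_never_candidate(self):
        pcg = _gene("p", 1_000_000, 1_001_000, chrom="chr2")
        assert lt.window_candidates(self.LNC, [pcg]) == []

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(4)
        genes = []
        for i in range(200):
            start = int(rng.integers(0, 5_000_000))
            genes.append(_gene(
                f"g{i:03d}", start, start + int(rng.integers(100, 10_000)),
                chrom=f"chr{rng.integers(1, 3)}",
                biotype="lncRNA" if i % 4 == 0 else "protein_coding"))
        lncs = [g for g in genes if g.biotype == "lncRNA"]
        pcgs = [g for g in genes if g.biotype == "protein_coding"]
        for lnc in lncs:
            fast = {(p.gene_id, d) for p, d in
                    lt.window_candidates(lnc, pcgs, 500_000)}
            brute = set()
            for p in pcgs:
                if p.chrom == lnc.chrom:
                    gap = max(0, max(lnc.start, p.start) - min(lnc.end, p.end))
                    if gap <= 500_000:
                        brute.add((p.gene_id, gap))
            assert fast == brute

    def test_alternative_distance_anchors(self):
        a = _gene("a", 100, 200, strand="+")
        b = _gene("b", 1_000, 2_000, strand="-")
        assert genomic_distance(a, b, "start_to_start") == 900
        assert genomic_distance(a, b, "tss_to_tss") == abs(100 - 1_999)


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(1.0, 6.0)
        r, p = lt.pearson_with_p(x, 2 * x)
        assert r == 1.0 and p == 0.0
        r, p = lt.pearson_with_p(x, -x)
        assert r == -1.0 and p == 0.0

    def test_worked_example_r_08_fails_p_threshold(self):
        r, p = lt.pearson_with_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)
        assert p == pytest.approx(0.2, abs=0.01)
        assert not p < 0.01  # meets r >= 0.8 yet fails the p filter

    def test_constant_vector_is_error(self):
        with pytest.raises(ValidationError, match="constant"):
            lt.pearson_with_p([1, 1, 1], [1, 2, 3])

    def test_too_short_vectors_rejected(self):
        with pytest.raises(ValidationError):
            lt.pearson_with_p([1, 2], [3, 4])


def _screen_inputs(default_sim, default_de):
    _, ann, truth, _, _ = default_sim
    filtered, norm, de = default_de
    wt_up = lt.call_degs(de["WT"], 2.0, 0.1, "up").gene_ids
    lnc, pcg, _ = lt.classify_biotypes(wt_up, ann)
    scope = [s.sample_id for s in filtered.samples
             if s.genotype == "WT" and s.condition == "tumor"]
    log_expr = np.log2(norm.normalized[scope] + 1.0)
    lnc = [g for g in lnc if g in log_expr.index]
    pcg = [g for g in pcg if g in log_expr.index]
    return log_expr, lnc, pcg, ann, truth


class TestScreen:
    def test_planted_pairs_recovered_and_decoys_behave(self, default_sim,
                                                       default_de):
        log_expr, lnc, pcg, ann, truth = _screen_inputs(default_sim, default_de)
        pairs = lt.screen_pairs(log_expr, lnc, pcg, ann)
        reported = {(p.lncRNA_id, p.pcg_id) for p in lt.reported_pairs(pairs)}
        for pair in truth.cis_pairs:
            assert tuple(pair) in reported
        decoy = {tuple(d) for d in truth.decoy_pairs}
        decoy_eval = [p for p in pairs if (p.lncRNA_id, p.pcg_id) in decoy]
        assert len(decoy_eval) >= 40
        frac_p = np.mean([p.passes_p for p in decoy_eval])
        assert frac_p <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / len(decoy_eval))

    def test_impossible_r_threshold_empties_report_not_evaluation(
            self, default_sim, default_de):
        log_expr, lnc, pcg, ann, _ = _screen_inputs(default_sim, default_de)
        pairs = lt.screen_pairs(log_expr, lnc, pcg, ann,
                                ScreenConfig(r_min=1.0, p_max=0.5))
        assert pairs  # evaluated list nonempty
        assert all(not p.passes_r or p.pearson_r == 1.0 for p in pairs)

    def test_sample_shuffle_invariance(self, default_sim, default_de):
        log_expr, lnc, pcg, ann, _ = _screen_inputs(default_sim, default_de)
        pairs1 = lt.screen_pairs(log_expr, lnc, pcg, ann)
        shuffled = log_expr[list(np.random.default_rng(0).permutation(
            log_expr.columns))]
        pairs2 = lt.screen_pairs(shuffled, lnc, pcg, ann)
        assert [(p.lncRNA_id, p.pcg_id, round(p.pearson_r, 12))
                for p in pairs1] == \
            [(p.lncRNA_id, p.pcg_id, round(p.pearson_r, 12)) for p in pairs2]

    def test_enlarging_window_or_lowering_r_never_removes_pairs(
            self, default_sim, default_de):
        log_expr, lnc, pcg, ann, _ = _screen_inputs(default_sim, default_de)
        tight = {(p.lncRNA_id, p.pcg_id)
                 for p in lt.reported_pairs(lt.screen_pairs(
                     log_expr, lnc, pcg, ann,
                     ScreenConfig(window_bp=200_000, r_min=0.9)))}
        loose = {(p.lncRNA_id, p.pcg_id)
                 for p in lt.reported_pairs(lt.screen_pairs(
                     log_expr, lnc, pcg, ann,
                     ScreenConfig(window_bp=500_000, r_min=0.8)))}
        assert tight <= loose

    def test_fraction_significant_under_global_null(self):
        # 200 adjacent decoy pairs with iid expression: the p<0.01 rate obeys
        # its nominal level within Monte-Carlo tolerance.
        rng = np.random.default_rng(5)
        genes, lnc_ids, pcg_ids = [], [], []
        for i in range(200):
            base = i * 2_000_000
            genes.append(_gene(f"l{i:03d}", base, base + 1_000,
                               chrom=f"chr{i % 5}", biotype="lncRNA"))
            genes.append(_gene(f"p{i:03d}", base + 5_000, base + 6_000,
                               chrom=f"chr{i % 5}"))
            lnc_ids.append(f"l{i:03d}")
            pcg_ids.append(f"p{i:03d}")
        ann = GeneAnnotations(genes)
        expr = pd.DataFrame(rng.normal(size=(400, 12)),
                            index=[g.gene_id for g in genes])
        pairs = lt.screen_pairs(expr, lnc_ids, pcg_ids, ann)
        assert len(pairs) == 200
        frac = np.mean([p.passes_p for p in pairs])
        assert frac <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / 200)

    def test_tiny_sample_scope_is_config_error(self):
        ann = GeneAnnotations([_gene("l", 0, 10, biotype="lncRNA"),
                               _gene("p", 20, 30)])
        expr = pd.DataFrame(np.ones((2, 2)), index=["l", "p"])
        with pytest.raises(ConfigError):
            lt.screen_pairs(expr, ["l"], ["p"], ann)


class TestPairTable:
    def test_report_columns_and_round_trip(self, tmp_path, default_sim,
                                           default_de):
        log_expr, lnc, pcg, ann, _ = _screen_inputs(default_sim, default_de)
        pairs = lt.screen_pairs(log_expr, lnc, pcg, ann)
        path = tmp_path / "pairs.tsv"
        lt.write_pair_table(pairs, path)
        back = lt.cispair.read_pair_table(path)
        assert list(back.columns) == ["lncRNA", "protein_coding_gene", "PCC",
                                      "p_value", "distance_bp", "n_samples"]
        rep = lt.reported_pairs(pairs)
        assert len(back) == len(rep)
        np.testing.assert_allclose(back["PCC"].to_numpy(),
                                   [p.pearson_r for p in rep], rtol=1e-6)

    def test_empty_report_writes_header_only(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        lt.write_pair_table([], path)
        back = lt.cispair.read_pair_table(path)
        assert len(back) == 0
        assert list(back.columns) == ["lncRNA", "protein_coding_gene", "PCC",
                                      "p_value", "distance_bp", "n_samples"]
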