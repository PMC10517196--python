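import numpy as np
import pytest

from pathprs.io_formats import RegionSpec, SummaryStatRecord
from pathprs.pathway_annotation import PathwaySnpSet
from pathprs.prs_core import (
    ClumpSpec,
    build_score_matrix,
    compute_prs,
    exclude_region,
    flip_variant,
    harmonize_weights,
    ld_clump,
    ok_weights,
    pairwise_r2,
    restrict_to_pathway,
    threshold_by_p,
)

from _oracles import greedy_clump_reference, r2_matrix
from conftest import make_genotypes, make_stats

APOE_REGION = RegionSpec("19", 44_400_000, 46_500_000)


def _pathway(snp_ids, pathway_id="P1"):
    return PathwaySnpSet(
        pathway_id=pathway_id,
        description="",
        gene_ids=frozenset(),
        snp_ids=frozenset(snp_ids),
        n_genes_resolved=0,
        includes_apoe_region=False,
    )


class TestHarmonize:
    def _stat(self, a1, a2, beta=0.2, bp=1000):
        return SummaryStatRecord("rs1", "1", bp, a1, a2, beta, 0.01)

    def test_alt_ref_orientation_keeps_sign(self):
        G = make_genotypes(np.zeros((2, 1)), ref="G", alt="A")
        ws, report = harmonize_weights([self._stat("A", "G")], G)
        assert ws[0].status == "ok"
        assert ws[0].orientation == "same" and ws[0].beta_alt == 0.2
        assert report.n_ok == 1

    def test_ref_alt_orientation_flips_sign(self):
        G = make_genotypes(np.zeros((2, 1)), ref="A", alt="G")
        ws, _ = harmonize_weights([self._stat("A", "G")], G)
        assert ws[0].orientation == "flipped" and ws[0].beta_alt == -0.2

    def test_palindromic_pair_dropped(self):
        G = make_genotypes(np.zeros((2, 1)), ref="A", alt="T")
        ws, report = harmonize_weights([self._stat("A", "T")], G)
        assert ws[0].status == "ambiguous_dropped" and ws[0].beta_alt is None
        assert report.n_ambiguous == 1

    def test_mismatched_alleles_dropped(self):
        G = make_genotypes(np.zeros((2, 1)), ref="A", alt="G")
        ws, report = harmonize_weights([self._stat("A", "C")], G)
        assert ws[0].status == "mismatch_dropped"
        assert report.n_mismatch == 1

    def test_unmatched_position_counted(self):
        G = make_genotypes(np.zeros((2, 1)))
        ws, report = harmonize_weights([self._stat("G", "A", bp=99_999)], G)
        assert ws == [] and report.n_unmatched == 1

    def test_conflicting_duplicates_all_dropped(self):
        G = make_genotypes(np.zeros((2, 1)), ref="A", alt="G")
        stats = [self._stat("G", "A"), self._stat("G", "C")]
        with pytest.warns(UserWarning, match="conflicting"):
            ws, report = harmonize_weights(stats, G)
        assert all(w.status == "mismatch_dropped" for w in ws)
        assert report.n_mismatch == 2


class TestSelection:
    def _weights(self, ps=(0.001, 0.0011, 1.0), bps=None):
        n = len(ps)
        G = make_genotypes(np.zeros((2, n)), bps=bps)
        ws, _ = harmonize_weights(make_stats(G, ps=ps), G)
        return ws

    def test_threshold_boundary_inclusive(self):
        ws = self._weights()
        kept = threshold_by_p(ws, 0.001)
        assert [w.p for w in kept] == [0.001]

    def test_threshold_one_is_identity(self):
        ws = self._weights()
        assert threshold_by_p(ws, 1.0) == ok_weights(ws)

    def test_apoe_exclude_and_only_partition(self):
        G = make_genotypes(
            np.zeros((2, 3)),
            bps=[44_399_999, 45_000_000, 46_500_000],
            chrom="19",
        )
        ws, _ = harmonize_weights(make_stats(G), G)
        excluded = exclude_region(ws, APOE_REGION, "exclude")
        only = exclude_region(ws, APOE_REGION, "only")
        assert {w.variant_id for w in excluded} == {"v1"}  # 44,399,999 outside
        assert {w.variant_id for w in only} == {"v2", "v3"}
        assert sorted(w.variant_id for w in excluded + only) == [
            w.variant_id for w in ws
        ]

    def test_other_chromosome_unaffected_by_exclude(self):
        G = make_genotypes(np.zeros((2, 1)), bps=[45_000_000], chrom="18")
        ws, _ = harmonize_weights(make_stats(G), G)
        assert exclude_region(ws, APOE_REGION, "exclude") == ws
        assert exclude_region(ws, APOE_REGION, "only") == []

    def test_restrict_intersection_and_commutation(self):
        G = make_genotypes(np.zeros((2, 10)))
        ps = [0.001 * (i + 1) for i in range(10)]
        ws, _ = harmonize_weights(make_stats(G, ps=ps), G)
        pw = _pathway({"v1", "v2", "v3"})
        assert {w.variant_id for w in restrict_to_pathway(ws, pw)} == pw.snp_ids
        a = threshold_by_p(restrict_to_pathway(ws, pw), 0.002)
        b = restrict_to_pathway(threshold_by_p(ws, 0.002), pw)
        assert a == b

    def test_disjoint_restriction_warns_empty(self):
        G = make_genotypes(np.zeros((2, 2)))
        ws, _ = harmonize_weights(make_stats(G), G)
        with pytest.warns(UserWarning):
            assert restrict_to_pathway(ws, _pathway({"nope"})) == []


class TestLdClump:
    def test_three_snp_worked_example(self, rng):
        # construct dosages with r2(A,B) > 0.2, r2(A,C) and r2(B,C) < 0.2
        n = 40
        a = rng.integers(0, 3, n).astype(float)
        b = a.copy()
        flip = rng.random(n) < 0.25
        b[flip] = rng.integers(0, 3, int(flip.sum()))
        c = rng.integers(0, 3, n).astype(float)
        dosage = np.column_stack([a, b, c])
        r2 = r2_matrix(dosage)
        assert r2[0, 1] > 0.2 and r2[0, 2] < 0.2 and r2[1, 2] < 0.2
        G = make_genotypes(dosage, bps=[100_000, 200_000, 300_000])
        ws, _ = harmonize_weights(make_stats(G, ps=[1e-5, 1e-4, 1e-3]), G)
        kept = ld_clump(ws, G, ClumpSpec())
        assert [w.variant_id for w in kept] == ["v1", "v3"]

    def test_single_snp_selects_itself(self):
        G = make_genotypes(np.array([[0.0], [1.0], [2.0]]))
        ws, _ = harmonize_weights(make_stats(G), G)
        assert [w.variant_id for w in ld_clump(ws, G, ClumpSpec())] == ["v1"]

    def test_window_is_hard_bound(self):
        # identical columns (r2 = 1) but 600 kb apart -> both kept
        col = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        G = make_genotypes(
            np.column_stack([col, col]), bps=[1_000_000, 1_600_001]
        )
        ws, _ = harmonize_weights(make_stats(G, ps=[1e-5, 1e-3]), G)
        kept = ld_clump(ws, G, ClumpSpec())
        assert [w.variant_id for w in kept] == ["v1", "v2"]

    def test_zero_variance_variant_cannot_clump(self):
        col = np.array([0.0, 1.0, 2.0, 1.0])
        flat = np.ones(4)
        G = make_genotypes(np.column_stack([flat, col]), bps=[100, 200])
        ws, _ = harmonize_weights(make_stats(G, ps=[1e-6, 1e-3]), G)
        kept = ld_clump(ws, G, ClumpSpec())
        assert [w.variant_id for w in kept] == ["v1", "v2"]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_reference(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 13))
        n = 30
        dosage = rng.integers(0, 3, (n, m)).astype(float)
        # ties in p exercise the (p, bp, id) tie-break
        ps = rng.choice([1e-4, 1e-3, 1e-2, 0.1], m)
        bps = np.sort(rng.choice(np.arange(1, 2_000_000, 1000), m, replace=False))
        G = make_genotypes(dosage, bps=[int(b) for b in bps])
        ws, _ = harmonize_weights(make_stats(G, ps=ps), G)
        kept = ld_clump(ws, G, ClumpSpec())
        snps = [
            {"id": w.variant_id, "chrom": w.chrom, "bp": w.bp, "p": w.p}
            for w in ok_weights(ws)
        ]
        expected = greedy_clump_reference(snps, r2_matrix(dosage))
        assert [w.variant_id for w in kept] == expected

    def test_order_invariant_given_tie_break(self, rng):
        dosage = rng.integers(0, 3, (25, 8)).astype(float)
        ps = [0.01] * 8  # all tied: bp breaks ties
        G = make_genotypes(dosage, bps=[1000 * i for i in range(1, 9)])
        ws, _ = harmonize_weights(make_stats(G, ps=ps), G)
        ref = [w.variant_id for w in ld_clump(ws, G, ClumpSpec())]
        for _ in range(5):
            perm = list(rng.permutation(len(ws)))
            shuffled = [ws[i] for i in perm]
            assert [w.variant_id for w in ld_clump(shuffled, G, ClumpSpec())] == ref


class TestComputePrs:
    def test_hand_computed_weighted_sum(self):
        G = make_genotypes(np.array([[0.0, 1.0, 2.0]]))
        ws, _ = harmonize_weights(make_stats(G, betas=[0.1, -0.2, 0.3]), G)
        scores, n = compute_prs(G, ws)
        assert n == 3
        assert scores[0] == pytest.approx(0.4, abs=1e-15)

    def test_zero_betas_zero_scores(self):
        G = make_genotypes(np.array([[0.0, 2.0], [1.0, 1.0]]))
        ws, _ = harmonize_weights(make_stats(G, betas=[0.0, 0.0]), G)
        scores, _ = compute_prs(G, ws)
        np.testing.assert_array_equal(scores, [0.0, 0.0])

    def test_mean_imputation_uses_twice_alt_freq(self):
        # non-missing dosages [1,0,1,0] -> alt freq 0.25 -> imputed 0.5
        col = np.array([np.nan, 1.0, 0.0, 1.0, 0.0])[:, None]
        G = make_genotypes(col)
        ws, _ = harmonize_weights(make_stats(G, betas=[0.4]), G)
        scores, _ = compute_prs(G, ws, missing_policy="mean_impute")
        assert scores[0] == pytest.approx(0.2, abs=1e-15)

    def test_omit_policy_skips_missing_term(self):
        col = np.array([np.nan, 1.0])[:, None]
        G = make_genotypes(col)
        ws, _ = harmonize_weights(make_stats(G, betas=[0.4]), G)
        scores, _ = compute_prs(G, ws, missing_policy="omit")
        assert scores[0] == 0.0 and scores[1] == pytest.approx(0.4)

    def test_empty_weights_all_missing(self):
        G = make_genotypes(np.zeros((3, 1)))
        scores, n = compute_prs(G, [])
        assert n == 0 and np.isnan(scores).all()


class TestScoreMatrix:
    def _small_sim(self, rng, n=80, m=12):
        dosage = rng.integers(0, 3, (n, m)).astype(float)
        bps = [100_000 * (j + 1) for j in range(m)]
        G = make_genotypes(dosage, bps=bps)
        ps = rng.uniform(1e-6, 1.0, m)
        betas = rng.normal(0, 0.1, m)
        ws, _ = harmonize_weights(make_stats(G, betas=betas, ps=ps), G)
        return G, ws

    def test_column_combinatorics(self, rng):
        G, ws = self._small_sim(rng)
        pw = _pathway({"v1", "v2", "v3"})
        region = RegionSpec("1", 1_100_000, 1_200_000)
        table = build_score_matrix(
            G, ws, [pw], ClumpSpec(), region,
            modes=("with_apoe", "no_apoe"), thresholds=(1.0,),
        )
        assert table.scores.shape == (80, 4)  # 2 labels x 1 threshold x 2 modes
        assert set(table.labels()) == {"genome_wide", "P1"}

    def test_apoe_free_pathway_columns_identical(self, rng):
        G, ws = self._small_sim(rng)
        region = RegionSpec("1", 1_100_000, 1_200_000)  # v11, v12
        pw = _pathway({"v1", "v2", "v3"}, "immune")  # disjoint from region
        table = build_score_matrix(
            G, ws, [pw], ClumpSpec(), region,
            modes=("with_apoe", "no_apoe"), thresholds=(1.0,),
        )
        np.testing.assert_array_equal(
            table.column("immune", 1.0, "with_apoe").to_numpy(),
            table.column("immune", 1.0, "no_apoe").to_numpy(),
        )

    def test_apoe_only_uses_region_snps_pre_clump(self, rng):
        G, ws = self._small_sim(rng)
        region = RegionSpec("1", 1_100_000, 1_200_000)
        table = build_score_matrix(
            G, ws, [], ClumpSpec(r2_max=0.99), region,
            modes=("apoe_only",), thresholds=(1.0,),
        )
        region_ws = exclude_region(ok_weights(ws), region, "only")
        expected, n = compute_prs(G, ld_clump(region_ws, G, ClumpSpec(r2_max=0.99)))
        np.testing.assert_allclose(
            table.column("genome_wide", 1.0, "apoe_only").to_numpy(), expected
        )
        assert table.n_snps_used[("genome_wide", 1.0, "apoe_only")] == n

    def test_n_snps_monotone_in_threshold(self, rng):
        G, ws = self._small_sim(rng, n=60, m=20)
        region = RegionSpec("1", 1, 2)
        spec = ClumpSpec()
        table = build_score_matrix(
            G, ws, [], spec, region, modes=("with_apoe",)
        )
        counts = [
            table.n_snps_used[("genome_wide", t, "with_apoe")]
            for t in sorted(spec.all_thresholds())
        ]
        assert counts == sorted(counts)

    def test_allele_flip_invariance(self, rng):
        """Flipping ref/alt of a variant shifts scores by a constant only."""
        G, ws = self._small_sim(rng)
        stats = make_stats(G, betas=list(rng.normal(0, 0.1, 12)),
                           ps=list(rng.uniform(0, 1, 12)))
        ws, _ = harmonize_weights(stats, G)
        scores, _ = compute_prs(G, ok_weights(ws))
        G2 = flip_variant(G, "v5")
        ws2, _ = harmonize_weights(stats, G2)
        assert [w.orientation for w in ws2] != [w.orientation for w in ws]
        scores2, _ = compute_prs(G2, ok_weights(ws2))
        offsets = scores2 - scores
        np.testing.assert_allclose(offsets, offsets[0], atol=1e-10)


class TestPairwiseR2:
    def test_matches_corrcoef_without_missing(self, rng):
        X = rng.integers(0, 3, (50, 6)).astype(float)
        ours = pairwise_r2(X[:, 0], X[:, 1:])
        expected = [np.corrcoef(X[:, 0], X[:, j]) [0, 1] ** 2 for j in range(1, 6)]
        np.testing.assert_allclose(ours, expected, atol=1e-12)

    def test_pairwise_complete_with_missing(self):
        x = np.array([0.0, 1.0, 2.0, np.nan, 1.0])
        y = np.array([0.0, 1.0, np.nan, 2.0, 0.0])
        mask = ~np.isnan(x) & ~np.isnan(y)
        expected = np.corrcoef(x[mask], y[mask])[0, 1] ** 2
        assert pairwise_r2(x, y)[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gives_zero(self):
        x = np.ones(10)
        y = np.arange(10, dtype=float)
        assert pairwise_r2(x, y)[0] == 0.0
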