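import json

import numpy as np
import pytest

from pathprs.io_formats import (
    read_gene_sets,
    read_genotypes,
    read_phenotype_table,
    read_summary_stats,
)
from pathprs.pathway_annotation import build_pathway_snp_sets, map_snps_to_genes
from pathprs.synthetic_data import (
    PathwaySimSpec,
    RoiSimSpec,
    SimConfig,
    SimConfigError,
    simulate_annotation,
    simulate_discovery_sumstats,
    simulate_genotypes,
    simulate_target_phenotypes,
    write_simulation,
)


def small_config(seed=11, **kw):
    defaults = dict(
        seed=seed,
        n_target=300,
        n_discovery=1000,
        n_snps=200,
        n_genes=20,
        block_size=20,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfigValidation:
    def test_block_size_must_divide_n_snps(self):
        with pytest.raises(SimConfigError, match="block_size"):
            SimConfig(n_snps=500, block_size=23)

    def test_pathway_gene_index_bounds_checked(self):
        with pytest.raises(SimConfigError, match="nonexistent gene"):
            SimConfig(pathways=(PathwaySimSpec("P", "", (99,)),))

    def test_roi_link_must_name_known_pathway(self):
        with pytest.raises(SimConfigError, match="unknown pathway"):
            SimConfig(rois=(RoiSimSpec("r", "cortical", "NOPE"),))


class TestGenotypeSimulation:
    def test_same_seed_identical_matrices(self):
        cfg = small_config()
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosage, b.dosage)
        assert a.sample_ids == b.sample_ids

    def test_different_seeds_differ(self):
        a = simulate_genotypes(small_config(seed=1))
        b = simulate_genotypes(small_config(seed=2))
        assert np.nanmean(a.dosage != b.dosage) > 0.1

    def test_empirical_maf_tracks_target(self):
        from pathprs.synthetic_data import derive_law

        cfg = small_config(n_target=2000, missing_rate=0.0)
        law = derive_law(cfg)
        G = simulate_genotypes(cfg)
        emp = G.alt_freq()
        within = np.abs(emp - law.mafs) <= 0.03
        assert within.mean() >= 0.95

    def test_block_ld_structure(self):
        cfg = small_config(n_target=1000, within_block_r=0.9, missing_rate=0.0)
        G = simulate_genotypes(cfg)
        D = G.dosage
        within, across = [], []
        rng = np.random.default_rng(0)
        corr = np.corrcoef(D.T) ** 2
        for _ in range(300):
            i, j = rng.integers(0, cfg.n_snps, 2)
            if i == j:
                continue
            (within if i // cfg.block_size == j // cfg.block_size else across).append(
                corr[i, j]
            )
        assert np.median(within) > 0.2
        assert np.median(across) < 0.01

    def test_missingness_rate_applied(self):
        cfg = small_config(missing_rate=0.05)
        G = simulate_genotypes(cfg)
        assert np.isnan(G.dosage).mean() == pytest.approx(0.05, abs=0.01)


class TestDiscoverySumstats:
    def test_null_pvalues_uniform(self):
        """With no planted effects, ~5% of SNPs reach p < 0.05."""
        fracs = []
        for seed in range(5):
            cfg = SimConfig(
                seed=seed,
                n_target=50,
                n_discovery=2000,
                n_snps=500,
                pathways=(),
                rois=(),
                apoe_effect=0.0,
            )
            stats = simulate_discovery_sumstats(cfg)
            fracs.append(np.mean([s.p < 0.05 for s in stats]))
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_single_strong_snp_attains_min_p(self):
        """A lone standardized effect of 0.3 dominates the discovery scan."""
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            cfg = small_config(
                seed=seed,
                n_discovery=5000,
                pathways=(),
                rois=(),
                apoe_effect=0.3,
                apoe_gene_index=19,
            )
            from pathprs.synthetic_data import derive_law

            law = derive_law(cfg)
            causal = law.variant_ids[int(np.nonzero(law.apoe_effect_vec)[0][0])]
            stats = simulate_discovery_sumstats(cfg)
            best = min(stats, key=lambda s: s.p)
            hits += best.variant_id == causal
        assert hits >= n_seeds - 1

    def test_ld_leakage_onto_null_neighbours(self):
        """Null SNPs sharing a block with the causal SNP inherit signal."""
        cfg = small_config(
            seed=5, n_discovery=4000, pathways=(), rois=(),
            apoe_effect=0.3, within_block_r=0.9,
        )
        from pathprs.synthetic_data import derive_law

        law = derive_law(cfg)
        causal_idx = int(np.nonzero(law.apoe_effect_vec)[0][0])
        block = causal_idx // cfg.block_size
        stats = simulate_discovery_sumstats(cfg)
        sds = np.array([2 * s.maf * (1 - s.maf) for s in stats]) ** 0.5
        std_beta = np.abs([s.beta for s in stats]) * sds
        same_block = [
            std_beta[j]
            for j in range(cfg.n_snps)
            if j // cfg.block_size == block and j != causal_idx
        ]
        distant = [
            std_beta[j] for j in range(cfg.n_snps) if j // cfg.block_size != block
        ]
        assert np.mean(same_block) > 5 * np.mean(distant)


class TestAnnotation:
    def test_tiling_maps_each_snp_to_exactly_one_gene(self):
        cfg = small_config()
        G = simulate_genotypes(cfg)
        genes, _, _ = simulate_annotation(cfg)
        mapping = map_snps_to_genes(G.variants, genes, 0.0)
        assert len(mapping) == cfg.n_snps
        assert all(len(gs) == 1 for gs in mapping.values())

    def test_shared_genes_give_exact_snp_overlap(self):
        cfg = small_config(
            pathways=(
                PathwaySimSpec("A", "", (0, 1, 2)),
                PathwaySimSpec("B", "", (2, 3, 4)),
            ),
            rois=(),
        )
        G = simulate_genotypes(cfg)
        genes, pathways, region = simulate_annotation(cfg)
        mapping = map_snps_to_genes(G.variants, genes, 0.0)
        sets = build_pathway_snp_sets(
            pathways, mapping, set(G.variants["variant_id"]), region, G.variants
        )
        overlap = sets[0].snp_ids & sets[1].snp_ids
        spg = cfg.snps_per_gene
        expected = set(G.variants["variant_id"][2 * spg : 3 * spg])  # gene 2
        assert overlap == expected

    def test_apoe_free_pathway_flagged_n(self):
        cfg = small_config()  # PW_IMMUNE avoids gene 19 by construction
        G = simulate_genotypes(cfg)
        genes, pathways, region = simulate_annotation(cfg)
        mapping = map_snps_to_genes(G.variants, genes, 0.0)
        sets = build_pathway_snp_sets(
            pathways, mapping, set(G.variants["variant_id"]), region, G.variants
        )
        flags = {s.pathway_id: s.includes_apoe_region for s in sets}
        assert flags == {"PW_LIPID": True, "PW_TAU": True, "PW_IMMUNE": False}


class TestPhenotypes:
    def test_degenerate_noise_limit_recovers_linear_combination(self):
        from pathprs.synthetic_data import derive_law

        cfg = small_config(
            noise_sd=1e-12,
            covariate_effects={},
            missing_rate=0.0,
            n_pcs=0,
        )
        G = simulate_genotypes(cfg)
        law = derive_law(cfg)
        ph = simulate_target_phenotypes(G, cfg)
        roi = cfg.rois[0]  # linked to PW_LIPID, sign -1
        burden = G.dosage @ law.effects_by_pathway[roi.linked_pathway]
        z = (burden - burden.mean()) / burden.std()
        expected = roi.base + roi.sign * roi.effect_size * z
        np.testing.assert_allclose(
            ph.data[roi.name].to_numpy(), expected, atol=1e-6
        )

    def test_roi_linked_to_empty_pathway_errors(self):
        with pytest.raises(SimConfigError):
            SimConfig(
                pathways=(PathwaySimSpec("P", "", ()),),
                rois=(RoiSimSpec("r", "cortical", "P"),),
            )

    def test_covariate_columns_present_and_complete(self):
        cfg = small_config()
        G = simulate_genotypes(cfg)
        ph = simulate_target_phenotypes(G, cfg)
        for col in ph.covariate_columns:
            assert ph.data[col].notna().all()
        assert [c for c in ph.covariate_columns if c.startswith("PC")] == [
            f"PC{i + 1}" for i in range(cfg.n_pcs)
        ]


class TestFileEmission:
    def test_byte_identical_across_runs(self, tmp_path):
        cfg = small_config()
        p1 = write_simulation(cfg, tmp_path / "a")
        p2 = write_simulation(cfg, tmp_path / "b")
        for key in p1:
            b1 = open(p1[key], "rb").read()
            b2 = open(p2[key], "rb").read()
            assert b1 == b2, key

    def test_round_trips_through_readers(self, tmp_path):
        cfg = small_config(missing_rate=0.02)
        paths = write_simulation(cfg, tmp_path)
        G = simulate_genotypes(cfg)
        back = read_genotypes(paths["genotypes"], fmt="vcf")
        np.testing.assert_array_equal(back.dosage, G.dosage)
        records, report = read_summary_stats(paths["sumstats"])
        assert report.n_rejected == 0
        generated = simulate_discovery_sumstats(cfg)
        assert records == generated  # float repr round-trip is exact
        genes, pathways, _ = read_gene_sets(paths["pathways_gmt"], paths["genes_bed"])
        assert len(genes) == cfg.n_genes and len(pathways) == len(cfg.pathways)
        ph = simulate_target_phenotypes(G, cfg)
        back_ph = read_phenotype_table(
            paths["phenotypes"], ph.roi_columns, ph.covariate_columns
        )
        np.testing.assert_allclose(
            back_ph.data[ph.roi_columns].to_numpy(),
            ph.data[ph.roi_columns].to_numpy(),
        )
        truth = json.load(open(paths["truth"]))
        assert set(truth["pathway_effects"]) == {p.pathway_id for p in cfg.pathways}
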