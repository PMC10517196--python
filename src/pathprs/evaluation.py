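"""Statistical validation experiments on synthetic cohorts.

These helpers run the full analysis (simulate -> annotate -> harmonize ->
score -> associate) in memory over many seeded replicates and summarize
the operating characteristics a user should check before trusting results
on real data: type-I error calibration on null cohorts, power and sign
recovery for a planted pathway effect, and the variance-explained profile
across P-value thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import GridSpec, run_association_grid
from .pathway_annotation import build_pathway_snp_sets, map_snps_to_genes
from .prs_core import (
    APOE_MODES,
    GENOME_WIDE,
    ClumpSpec,
    ScoreTable,
    build_score_matrix,
    harmonize_weights,
)
from .synthetic_data import (
    SimConfig,
    dense_weak_config,
    null_config,
    planted_config,
    roi_families,
    sign_flip_config,
    simulate_annotation,
    simulate_discovery_sumstats,
    simulate_genotypes,
    simulate_target_phenotypes,
)


@dataclass
class AnalysisArtifacts:
    scores: ScoreTable
    associations: pd.DataFrame


def run_synthetic_analysis(
    cfg: SimConfig,
    thresholds: tuple[float, ...] | None = None,
    modes: tuple[str, ...] = APOE_MODES,
    clump_spec: ClumpSpec | None = None,
) -> AnalysisArtifacts:
    """Simulate one study and run the scoring + association stages on it."""
    clump_spec = clump_spec or ClumpSpec()
    G = simulate_genotypes(cfg)
    stats = simulate_discovery_sumstats(cfg)
    genes, pathways, apoe_region = simulate_annotation(cfg)
    ph = simulate_target_phenotypes(G, cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        weights, _ = harmonize_weights(stats, G)
        snp_map = map_snps_to_genes(G.variants, genes, window_kb=0.0)
        sets = build_pathway_snp_sets(
            pathways, snp_map, {r.variant_id for r in stats}, apoe_region, G.variants
        )
        table = build_score_matrix(
            G, weights, sets, clump_spec, apoe_region,
            modes=modes, thresholds=thresholds,
        )
        grid = GridSpec(roi_families=roi_families(cfg))
        assoc = run_association_grid(table, ph, grid)
    return AnalysisArtifacts(scores=table, associations=assoc)


def null_calibration(
    n_replicates: int = 50, base_seed: int = 0, threshold: float = 0.5
) -> dict:
    """Fraction of grid cells with p < 0.05 on cohorts with no planted effects.

    Uses the null study conditions (n = 1000 target samples, 500 SNPs,
    three pathways, null ROIs) at one lenient threshold so score columns
    are well populated; under the null the fraction should sit near 0.05.
    """
    n_sig = 0
    n_cells = 0
    for rep in range(n_replicates):
        cfg = null_config(base_seed + rep)
        art = run_synthetic_analysis(
            cfg, thresholds=(threshold,), modes=("with_apoe",)
        )
        est = art.associations[art.associations["estimable"]]
        n_sig += int((est["p"] < 0.05).sum())
        n_cells += len(est)
    return {
        "fraction_significant": n_sig / n_cells if n_cells else float("nan"),
        "n_cells": n_cells,
        "n_replicates": n_replicates,
    }


def power_recovery(
    n_replicates: int = 50,
    base_seed: int = 1000,
    effect_size: float = 0.15,
    sign: int = -1,
) -> dict:
    """Detection of a planted (pathway, ROI) effect across replicates.

    A standardized pathway effect (default 0.15, negative direction) is
    planted on one subcortical ROI in a 2 000-sample target cohort; the
    planted cell is (PW_TAU score, that ROI) at the primary threshold.
    Reports the fraction of replicates where that cell reaches p < 0.05,
    the fraction of detections with the planted sign, and the fraction of
    replicates where it is the smallest-q cell of its FDR block.
    """
    spec = ClumpSpec()
    detected = 0
    sign_correct = 0
    top_q = 0
    for rep in range(n_replicates):
        cfg = planted_config(base_seed + rep, effect_size=effect_size, sign=sign)
        art = run_synthetic_analysis(
            cfg, thresholds=(spec.primary_threshold,), modes=("with_apoe",)
        )
        a = art.associations
        cell = a[(a["score_label"] == "PW_TAU") & (a["roi"] == "hippocampus_volume")]
        assert len(cell) == 1
        cell = cell.iloc[0]
        if cell["estimable"] and cell["p"] < 0.05:
            detected += 1
            if np.sign(cell["beta"]) == sign:
                sign_correct += 1
        block = a[a["estimable"]]
        if len(block) and block.loc[block["q"].idxmin(), "roi"] == "hippocampus_volume" \
                and block.loc[block["q"].idxmin(), "score_label"] == "PW_TAU":
            top_q += 1
    return {
        "power": detected / n_replicates,
        "sign_correct_fraction": sign_correct / detected if detected else float("nan"),
        "top_q_fraction": top_q / n_replicates,
        "n_replicates": n_replicates,
    }


def sign_flip_recovery(n_replicates: int = 25, base_seed: int = 5000) -> dict:
    """Opposite planted directions on two ROIs driven by the same pathway.

    Emulates the older/younger direction flip: among replicates where both
    linked cells are detected (p < 0.05), reports how often the recovered
    betas have opposite signs with the planted orientation.
    """
    spec = ClumpSpec()
    both_detected = 0
    opposite = 0
    for rep in range(n_replicates):
        cfg = sign_flip_config(base_seed + rep)
        art = run_synthetic_analysis(
            cfg, thresholds=(spec.primary_threshold,), modes=("with_apoe",)
        )
        a = art.associations
        older = a[(a["score_label"] == "PW_TAU") & (a["roi"] == "hippocampus_older_volume")].iloc[0]
        younger = a[(a["score_label"] == "PW_TAU") & (a["roi"] == "hippocampus_younger_volume")].iloc[0]
        if older["p"] < 0.05 and younger["p"] < 0.05:
            both_detected += 1
            if older["beta"] < 0 < younger["beta"]:
                opposite += 1
    return {
        "both_detected": both_detected,
        "opposite_sign_fraction": opposite / both_detected if both_detected else float("nan"),
        "n_replicates": n_replicates,
    }


def threshold_profile(
    n_replicates: int = 20, base_seed: int = 9000
) -> dict:
    """Delta R^2 of the genome-wide score across the P-threshold ladder.

    Uses the dense-weak-effect conditions (every SNP weakly causal) so
    lenient thresholds admit more true signal.  Reports the fraction of
    replicates in which delta R^2 at the most lenient threshold (0.5) is
    at least its value at the most stringent (1e-6), plus the mean profile.
    """
    spec = ClumpSpec()
    thresholds = spec.all_thresholds()  # decreasing: 0.5 ... 1e-6
    profiles = []
    n_non_decreasing = 0
    for rep in range(n_replicates):
        cfg = dense_weak_config(base_seed + rep)
        art = run_synthetic_analysis(cfg, thresholds=thresholds, modes=("with_apoe",))
        a = art.associations
        gw = a[(a["score_label"] == GENOME_WIDE) & (a["roi"] == "hippocampus_volume")]
        prof = (
            gw.set_index("threshold")["delta_r2_prs"].reindex(list(thresholds)).to_numpy()
        )
        profiles.append(prof)
        lenient, stringent = prof[0], prof[-1]
        if np.isnan(stringent):  # empty column at 1e-6 counts as zero signal
            stringent = 0.0
        if lenient >= stringent:
            n_non_decreasing += 1
    return {
        "fraction_non_decreasing": n_non_decreasing / n_replicates,
        "thresholds": [float(t) for t in thresholds],
        "mean_profile": np.nanmean(np.array(profiles, dtype=float), axis=0).tolist(),
        "n_replicates": n_replicates,
    }
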