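"""Simulation-based calibration studies for the mapping pipeline.

These routines regenerate synthetic panels with known truth and measure
the operating characteristics of the methods: 2-LOD support-interval
coverage of a true QTL, genome-wide type-I error of the permutation
threshold, heritability recovery, and the power of the stratified
sign-concordance test under shared cross-study genetics.  They are what
the test suite and the reproduction script run; problem sizes are
arguments so studies can be scaled.
"""

from __future__ import annotations

import numpy as np

from . import assoc, concordance, quantgen, scan, simulate
from .containers import SimTruth

__all__ = [
    "two_lod_coverage",
    "permutation_type_one_error",
    "heritability_recovery",
    "cross_study_concordance_detection",
]


def two_lod_coverage(
    n_panels: int = 100,
    n_rils: int = 500,
    n_positions: int = 500,
    chrom_length_cm: float = 100.0,
    qtl_var_frac: float = 0.10,
    expected_segments: float = 8.0,
    seed: int = 0,
) -> dict:
    """Coverage of 2-LOD intervals around the top peak of single-QTL scans.

    Each panel has hard founder assignments, one additive QTL with
    N(0, 1) founder effects placed uniformly on the interior of the map,
    and strain-mean noise solved so the QTL explains ``qtl_var_frac`` of
    the strain-mean variance.  The interval is the contiguous run of
    positions around the maximum-LOD position with LOD >= peak - 2.
    """
    positions = np.linspace(0.0, chrom_length_cm, n_positions, endpoint=False)
    ss = np.random.SeedSequence(seed)
    hits = 0
    margin = n_positions // 10
    for s, child in enumerate(ss.spawn(n_panels)):
        s1, s2, s3 = child.generate_state(3) % (2**31)
        rng = np.random.default_rng(s1)
        haps = simulate.simulate_founder_mosaics(
            n_rils,
            8,
            positions,
            expected_segments=expected_segments,
            assignment_certainty=1.0,
            seed=int(s2),
        )
        qtl = float(positions[rng.integers(margin, n_positions - margin)])
        truth = SimTruth(
            qtl_positions=[qtl],
            founder_effects=[list(rng.normal(0.0, 1.0, 8))],
            target_h2=qtl_var_frac,
        )
        ph = simulate.simulate_ril_phenotypes(haps, truth, n_reps=1, seed=int(s3))
        y = ph.set_index("strain")["value"]
        curve = scan.lod_scan(haps, y)
        peak = scan.call_peaks(curve, threshold=float(curve.lod.max()))[0]
        hits += peak.ci_low <= qtl <= peak.ci_high
    return {"coverage": hits / n_panels, "n_panels": n_panels, "hits": hits}


def permutation_type_one_error(
    n_panels: int = 200,
    n_rils: int = 200,
    n_positions: int = 150,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Fraction of null panels with any LOD above their own threshold."""
    positions = np.linspace(0.0, 100.0, n_positions, endpoint=False)
    ss = np.random.SeedSequence(seed)
    exceed = 0
    for child in ss.spawn(n_panels):
        s1, s2, s3 = child.generate_state(3) % (2**31)
        haps = simulate.simulate_founder_mosaics(
            n_rils, 8, positions, expected_segments=8.0,
            assignment_certainty=0.95, seed=int(s1),
        )
        truth = SimTruth(target_h2=0.0)
        ph = simulate.simulate_ril_phenotypes(haps, truth, n_reps=1, seed=int(s2))
        y = ph.set_index("strain")["value"]
        curve = scan.lod_scan(haps, y)
        thr = scan.permutation_threshold(
            haps, y, n_perm=n_perm, alpha=alpha, seed=int(s3)
        )
        exceed += bool((curve.lod > thr).any())
    return {"type_one_error": exceed / n_panels, "n_panels": n_panels}


def heritability_recovery(
    target_h2: float,
    n_sims: int = 50,
    n_strains: int = 800,
    n_reps: int = 8,
    n_qtl: int = 3,
    seed: int = 0,
) -> dict:
    """Mean ANOVA heritability estimate over replicate simulations."""
    positions = np.arange(0.0, 30.0, 1.0)
    qtl_pos = [5.0, 15.0, 25.0][:n_qtl]
    ss = np.random.SeedSequence(seed)
    ests = []
    for child in ss.spawn(n_sims):
        s1, s2, s3 = child.generate_state(3) % (2**31)
        rng = np.random.default_rng(s1)
        haps = simulate.simulate_founder_mosaics(
            n_strains, 8, positions, expected_segments=3.0,
            assignment_certainty=0.95, seed=int(s2),
        )
        if target_h2 > 0:
            truth = SimTruth(
                qtl_positions=qtl_pos,
                founder_effects=[list(rng.normal(0, 1, 8)) for _ in qtl_pos],
                target_h2=target_h2,
            )
        else:
            truth = SimTruth(target_h2=0.0)
        ph = simulate.simulate_ril_phenotypes(haps, truth, n_reps=n_reps, seed=int(s3))
        ests.append(quantgen.broad_sense_heritability(ph).h2_broad)
    ests = np.asarray(ests)
    return {
        "mean_estimate": float(ests.mean()),
        "sd": float(ests.std(ddof=1)),
        "n_sims": n_sims,
    }


def cross_study_concordance_detection(
    n_sims: int = 50,
    n_lines: int = 200,
    n_snps: int = 500,
    n_causal: int = 20,
    effect_sd: float = 1.0,
    noise_sd: float = 3.0,
    top_k: int = 50,
    n_iter: int = 200,
    statistic: str = "same_sign",
    seed: int = 0,
) -> dict:
    """Power of the stratified bootstrap concordance test.

    Two studies phenotype the same simulated panel with independent noise
    but shared causal SNPs; each replicate asks whether the observed
    top-SNP concordance exceeds the null's 97.5th percentile.
    """
    ss = np.random.SeedSequence(seed)
    wins = 0
    observed, null_means = [], []
    for child in ss.spawn(n_sims):
        s1, s2 = child.generate_state(2) % (2**31)
        study_params = [
            {"shift": 0.0, "scale": 1.0, "noise_sd": noise_sd},
            {"shift": 50.0, "scale": 1.0, "noise_sd": noise_sd},
        ]
        geno, (px, py), _ = simulate.simulate_line_panel(
            n_lines=n_lines,
            n_snps=n_snps,
            n_causal=n_causal,
            effect_sd=effect_sd,
            n_studies=2,
            study_params=study_params,
            seed=int(s1),
        )
        table = assoc.associate(geno, px)
        top = assoc.select_top_snps(table, "topk", top_k)
        res = concordance.concordance_test(
            geno, px, py, top, n_iter=n_iter, statistic=statistic, seed=int(s2)
        )
        wins += res.observed > res.null_interval[1]
        observed.append(res.observed)
        null_means.append(res.null_mean)
    return {
        "detection_rate": wins / n_sims,
        "mean_observed": float(np.mean(observed)),
        "mean_null": float(np.mean(null_means)),
        "n_sims": n_sims,
    }
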