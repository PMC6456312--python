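"""Synthetic mapping panels with recorded ground truth.

Three generators cover the data shapes the toolkit consumes:

* :func:`simulate_founder_mosaics` — a multiparental RIL panel whose
  genomes are first-order Markov mosaics of founder haplotypes along a
  genetic map, emitted as founder-probability vectors (the block-length
  scale, not the breeding design, is what downstream methods see);
* :func:`simulate_ril_phenotypes` — replicate phenotypes whose strain
  genetic values follow the additive founder-effect model the QTL scan
  fits, with environmental noise solved analytically to hit a target
  broad-sense heritability;
* :func:`simulate_line_panel` — a homozygous inbred-line panel with
  biallelic SNPs, a shared polygenic score, and several "studies" that
  re-phenotype the same lines with different means, scales and noise;
* :func:`simulate_plate` — assay-plate absorbances constructed by
  inverting the triglyceride formula, so the round trip is exact at
  zero noise.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assay import (
    DEFAULT_CORRECTION_FACTOR,
    DEFAULT_STANDARD_CONCENTRATION,
    PlateReads,
)
from .containers import FounderHaplotypeMatrix, GenotypeMatrix, SimTruth

__all__ = [
    "simulate_founder_mosaics",
    "simulate_ril_phenotypes",
    "simulate_line_panel",
    "simulate_plate",
]


def simulate_founder_mosaics(
    n_rils: int,
    n_founders: int = 8,
    positions: np.ndarray | None = None,
    expected_segments: float = 8.0,
    assignment_certainty: float = 0.95,
    seed: int = 0,
    chrom: str | np.ndarray = "1",
) -> FounderHaplotypeMatrix:
    """Markov founder mosaics along a genetic map.

    Each RIL starts from a uniformly chosen founder; between adjacent
    grid positions the founder switches with probability proportional to
    the map distance, scaled so the expected number of mosaic blocks per
    chromosome equals ``expected_segments``; a switch picks uniformly
    among the other founders.  The emitted probability rows put
    ``assignment_certainty`` on the true local founder and spread the
    remainder uniformly — emulating soft haplotype assignments.

    Parameters
    ----------
    positions
        Map grid in cM (default: 100 cM at 0.5 cM steps).
    assignment_certainty
        Must exceed 1/n_founders (the true founder stays the argmax) and
        be at most 1 (hard assignments).
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if positions is None:
        positions = np.arange(0.0, 100.0, 0.5)
    positions = np.asarray(positions, dtype=float)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    if not (1.0 / n_founders < assignment_certainty <= 1.0):
        raise ValueError(
            f"assignment_certainty must lie in (1/{n_founders}, 1]"
        )
    if expected_segments < 1:
        raise ValueError("expected_segments must be at least 1")
    rng = np.random.default_rng(seed)
    n_pos = len(positions)
    gaps = np.diff(positions)
    total_len = positions[-1] - positions[0]
    # E[switches] = sum of per-gap switch probabilities = segments - 1.
    rate = (expected_segments - 1.0) / total_len if total_len > 0 else 0.0
    p_switch = np.minimum(rate * gaps, 1.0)

    state = rng.integers(0, n_founders, size=n_rils)
    states = np.empty((n_rils, n_pos), dtype=np.int64)
    states[:, 0] = state
    for j in range(1, n_pos):
        switch = rng.random(n_rils) < p_switch[j - 1]
        # uniform over the other founders
        jump = rng.integers(1, n_founders, size=n_rils)
        state = np.where(switch, (state + jump) % n_founders, state)
        states[:, j] = state

    off = (1.0 - assignment_certainty) / (n_founders - 1)
    probs = np.full((n_rils, n_pos, n_founders), off)
    ii, jj = np.meshgrid(np.arange(n_rils), np.arange(n_pos), indexing="ij")
    probs[ii, jj, states] = assignment_certainty
    chrom_arr = (
        np.full(n_pos, chrom) if np.isscalar(chrom) else np.asarray(chrom)
    )
    return FounderHaplotypeMatrix(
        rils=np.array([f"RIL{i + 1:04d}" for i in range(n_rils)]),
        chrom=chrom_arr,
        positions=positions,
        probs=probs,
    )


def _genetic_values(haps: FounderHaplotypeMatrix, truth: SimTruth) -> np.ndarray:
    g = np.zeros(haps.n_rils)
    for pos, eff in zip(truth.qtl_positions, truth.founder_effects):
        idx = haps.position_index(pos)
        g += haps.probs[:, idx, :] @ np.asarray(eff, dtype=float)
    return g


def simulate_ril_phenotypes(
    haps: FounderHaplotypeMatrix,
    truth: SimTruth,
    n_reps: int = 2,
    covariate_shifts: dict[str, float] | None = None,
    polygenic_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate phenotypes under the additive founder-effect model.

    The strain genetic value is the sum over QTL of (probability row ·
    founder effect vector), plus optional polygenic noise.  Replicates
    add i.i.d. environmental noise whose SD is solved from the realized
    genetic variance so that V_G / (V_G + V_E) equals
    ``truth.target_h2`` (the replicate-level broad-sense heritability);
    the solved SD is recorded in ``truth.env_sd``.  Subpopulation labels
    are assigned round-robin and shifted additively.

    Returns a long table with columns ``strain, subpop, replicate,
    value``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    rng = np.random.default_rng(seed)
    g = _genetic_values(haps, truth)
    if polygenic_sd > 0:
        g = g + rng.normal(0.0, polygenic_sd, size=haps.n_rils)
    v_g = float(np.var(g))
    h2 = truth.target_h2
    if h2 >= 1.0:
        env_sd = 0.0
    elif h2 <= 0.0:
        if v_g > 0:
            raise ValueError(
                "target_h2 = 0 is unattainable with nonzero genetic variance"
            )
        env_sd = 1.0
    else:
        if v_g == 0:
            raise ValueError(
                "target_h2 > 0 is unattainable with zero genetic variance"
            )
        env_sd = float(np.sqrt(v_g * (1.0 - h2) / h2))
    truth.env_sd = env_sd

    shifts = covariate_shifts or {"pA1": 0.0}
    subpops = list(shifts)
    labels = [subpops[i % len(subpops)] for i in range(haps.n_rils)]
    shift_vec = np.array([shifts[lab] for lab in labels])

    rows = []
    for rep in range(1, n_reps + 1):
        noise = (
            rng.normal(0.0, env_sd, size=haps.n_rils) if env_sd > 0 else 0.0
        )
        values = g + shift_vec + noise
        rows.append(
            pd.DataFrame(
                {
                    "strain": haps.rils,
                    "subpop": labels,
                    "replicate": rep,
                    "value": values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_line_panel(
    n_lines: int = 200,
    n_snps: int = 2000,
    maf_beta: tuple[float, float] = (0.8, 0.8),
    maf_min: float = 0.05,
    n_causal: int = 20,
    effect_sd: float = 0.3,
    n_studies: int = 3,
    study_params: list[dict[str, float]] | None = None,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[pd.Series], SimTruth]:
    """Homozygous inbred-line panel with multi-study phenotypes.

    SNP minor-allele frequencies are drawn from a Beta distribution
    truncated to ``[maf_min, 0.5]``; each line is homozygous for the
    minor allele with probability equal to that frequency (allele counts
    in {0, 2}, no linkage disequilibrium).  ``n_causal`` SNPs get
    N(0, effect_sd²) per-allele-copy effects; the resulting polygenic
    score drives every study's phenotype:

        y_s = shift_s + scale_s · score + N(0, noise_s²)

    so studies share genetic signal but differ in mean, scale and noise.
    Returns the genotypes, one line-mean Series per study, and the truth
    record.
    """
    if n_causal > n_snps:
        raise ValueError("n_causal cannot exceed n_snps")
    if not 0 < maf_min < 0.5:
        raise ValueError("maf_min must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    if study_params is None:
        study_params = [
            {"shift": 0.0, "scale": 1.0, "noise_sd": 1.0} for _ in range(n_studies)
        ]
    if len(study_params) != n_studies:
        raise ValueError("study_params length must equal n_studies")

    a, b = maf_beta
    maf = np.empty(n_snps)
    filled = 0
    while filled < n_snps:
        draw = rng.beta(a, b, size=2 * (n_snps - filled)) * 0.5
        draw = draw[draw >= maf_min]
        take = min(len(draw), n_snps - filled)
        maf[filled : filled + take] = draw[:take]
        filled += take

    minor_hom = rng.random((n_lines, n_snps)) < maf[None, :]
    # The emulated panel is pre-filtered at the MAF floor, so columns whose
    # *realized* frequency falls outside [maf_min, 0.5] are redrawn.
    for _ in range(1000):
        freq = minor_hom.mean(axis=0)
        bad = np.nonzero(np.minimum(freq, 1 - freq) < maf_min)[0]
        if bad.size == 0:
            break
        minor_hom[:, bad] = rng.random((n_lines, bad.size)) < maf[None, bad]
    else:
        raise RuntimeError("could not realize the requested MAF floor")
    # orient counts as copies of the alternate allele = the minor allele
    counts = np.where(minor_hom, 2.0, 0.0)
    line_ids = np.array([f"line_{i + 1:03d}" for i in range(n_lines)])
    snp_ids = np.array([f"snp_{j + 1:05d}" for j in range(n_snps)])
    geno = GenotypeMatrix(
        line_ids=line_ids,
        snp_ids=snp_ids,
        chrom=np.full(n_snps, "2L"),
        pos=np.arange(1, n_snps + 1) * 100,
        counts=counts,
        ref=np.full(n_snps, "A"),
        alt=np.full(n_snps, "T"),
    )

    causal_idx = rng.choice(n_snps, size=n_causal, replace=False)
    effects = rng.normal(0.0, effect_sd, size=n_causal)
    score = counts[:, causal_idx] @ effects if n_causal else np.zeros(n_lines)

    phenos = []
    for s, pars in enumerate(study_params):
        noise = rng.normal(0.0, pars["noise_sd"], size=n_lines) if pars[
            "noise_sd"
        ] > 0 else 0.0
        y = pars["shift"] + pars["scale"] * score + noise
        phenos.append(pd.Series(y, index=line_ids, name=f"study_{s + 1}"))

    truth = SimTruth(
        causal_snps={snp_ids[i]: float(e) for i, e in zip(causal_idx, effects)},
        study_params=study_params,
        seed=seed,
    )
    return geno, phenos, truth


def simulate_plate(
    true_concentrations: np.ndarray,
    standard_concentration: float = DEFAULT_STANDARD_CONCENTRATION,
    correction_factor: float = DEFAULT_CORRECTION_FACTOR,
    noise_sd: float = 0.0,
    seed: int = 0,
    fa_std: float = 0.9,
    ia_blank: float = 0.05,
    baseline: float = 0.2,
    free_glycerol: float = 0.3,
) -> tuple[PlateReads, pd.DataFrame]:
    """Assay-plate absorbances consistent with known concentrations.

    The final absorbance of each sample well is constructed by inverting
    the triglyceride formula at the given plate controls, so the
    noise-free round trip recovers ``true_concentrations`` exactly.
    Gaussian noise of SD ``noise_sd`` is added independently to every
    individual scan read (baseline, free-glycerol and final scans of
    sample wells; standard final reads; blank scans).

    Returns the :class:`PlateReads` plus the long-format well table
    accepted by :func:`qgmap.assay.plate_table_concentrations`.
    """
    conc = np.atleast_1d(np.asarray(true_concentrations, dtype=float))
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    denom = fa_std - ia_blank * correction_factor
    if denom <= 0:
        raise ValueError("chosen plate controls give a non-positive denominator")
    n = len(conc)

    base = np.full(n, baseline) + rng.normal(0, noise_sd, n)
    free = np.full(n, free_glycerol) + rng.normal(0, noise_sd, n)
    ia_true = free_glycerol - baseline
    fa_clean = conc / standard_concentration * denom + ia_true * correction_factor
    fa = fa_clean + rng.normal(0, noise_sd, n)

    std_final = fa_std + rng.normal(0, noise_sd, 3)
    blank_base = 0.1 + rng.normal(0, noise_sd)
    blank_free = 0.1 + ia_blank + rng.normal(0, noise_sd)

    strains = np.array([f"S{i + 1:03d}" for i in range(n)])
    plate = PlateReads(
        fa_sample=fa,
        ia_sample=free - base,
        fa_std=float(np.mean(std_final)),
        ia_blank=float(blank_free - blank_base),
        correction_factor=correction_factor,
        standard_concentration=standard_concentration,
        sample_ids=strains,
        strains=strains,
    )
    rows = [
        {
            "plate": "P1",
            "well": f"W{i + 1:03d}",
            "role": "sample",
            "strain": strains[i],
            "baseline_abs": base[i],
            "free_glycerol_abs": free[i],
            "final_abs": fa[i],
        }
        for i in range(n)
    ]
    for j in range(3):
        rows.append(
            {
                "plate": "P1",
                "well": f"STD{j + 1}",
                "role": "standard",
                "strain": "",
                "baseline_abs": np.nan,
                "free_glycerol_abs": np.nan,
                "final_abs": std_final[j],
            }
        )
    rows.append(
        {
            "plate": "P1",
            "well": "BLANK",
            "role": "blank",
            "strain": "",
            "baseline_abs": blank_base,
            "free_glycerol_abs": blank_free,
            "final_abs": np.nan,
        }
    )
    return plate, pd.DataFrame(rows)
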