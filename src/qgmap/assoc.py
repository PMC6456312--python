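"""Line-mean association testing for homozygous inbred panels.

Each SNP is tested by ordinary least squares of the line-mean phenotype
on the alternate-allele count (0 or 2 in a fully inbred panel), with
optional fixed-effect covariates.  The reported additive effect follows
the half-difference convention:

    a = (mean of major-allele homozygotes − mean of minor-allele
         homozygotes) / 2

so a > 0 means the major allele raises the trait.  When covariates are
supplied, class means are taken on covariate-residualized phenotypes.

Top-SNP selection supports Benjamini–Hochberg FDR (the conventional
relaxed cutoff is 0.2 for these panels), a fixed p-value cutoff
(10⁻⁵ is customary), or the k smallest p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix

__all__ = [
    "associate",
    "additive_effect",
    "additive_effects",
    "select_top_snps",
    "across_study_mean",
]


def _align_lines(
    geno: GenotypeMatrix, pheno: pd.Series, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    pheno = pd.Series(pheno)
    shared = [l for l in geno.line_ids if l in pheno.index]
    if not shared:
        raise ValueError("no lines shared between genotypes and phenotypes")
    keep = np.isin(geno.line_ids, shared)
    y = pheno.reindex(geno.line_ids[keep]).to_numpy(dtype=float)
    counts = geno.counts[keep]
    x0 = None
    if covariates is not None:
        cov = pd.DataFrame(covariates).reindex(geno.line_ids[keep])
        if cov.isna().any().any():
            raise ValueError("covariates incomplete for phenotyped lines")
        cols = [np.ones((len(y), 1))]
        for name in cov.columns:
            col = cov[name]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float).reshape(-1, 1))
            else:
                cols.append(pd.get_dummies(col, drop_first=True).to_numpy(float))
        x0 = np.hstack(cols)
    return counts, y, x0


def _residualize_cov(y: np.ndarray, x0: np.ndarray | None) -> np.ndarray:
    if x0 is None:
        return y
    coef, _, _, _ = np.linalg.lstsq(x0, y, rcond=None)
    return y - x0 @ coef


def additive_effect(counts_col: np.ndarray, y: np.ndarray) -> float:
    """Half the difference between major- and minor-homozygote means.

    ``counts_col`` holds alternate-allele counts in {0, 2} (NaN missing).
    The rarer allele among genotyped lines is the minor allele; at
    frequency exactly 0.5 the reference (count 0) allele is major.
    """
    g = np.asarray(counts_col, dtype=float)
    ok = ~(np.isnan(g) | np.isnan(y))
    g, yv = g[ok], np.asarray(y, dtype=float)[ok]
    alt_hom = g == 2
    ref_hom = g == 0
    n_alt, n_ref = int(alt_hom.sum()), int(ref_hom.sum())
    if n_alt == 0 or n_ref == 0:
        raise ValueError("additive effect undefined: a homozygote class is empty")
    alt_freq = n_alt / (n_alt + n_ref)
    mean_alt, mean_ref = yv[alt_hom].mean(), yv[ref_hom].mean()
    if alt_freq > 0.5:  # alt is major
        return (mean_alt - mean_ref) / 2.0
    return (mean_ref - mean_alt) / 2.0


def additive_effects(
    geno: GenotypeMatrix,
    pheno: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> np.ndarray:
    """Vector of half-difference additive effects, NaN where undefined."""
    counts, y, x0 = _align_lines(geno, pheno, covariates)
    yr = _residualize_cov(y, x0)
    return _additive_effects_array(counts, yr)


def _additive_effects_array(counts: np.ndarray, y: np.ndarray) -> np.ndarray:
    miss = np.isnan(counts)
    alt_hom = (counts == 2) & ~miss
    ref_hom = (counts == 0) & ~miss
    n_alt = alt_hom.sum(axis=0).astype(float)
    n_ref = ref_hom.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_alt = (alt_hom * y[:, None]).sum(axis=0) / n_alt
        mean_ref = (ref_hom * y[:, None]).sum(axis=0) / n_ref
        alt_major = n_alt / np.maximum(n_alt + n_ref, 1) > 0.5
        a = np.where(alt_major, mean_alt - mean_ref, mean_ref - mean_alt) / 2.0
    a[(n_alt == 0) | (n_ref == 0)] = np.nan
    return a


def associate(
    geno: GenotypeMatrix,
    pheno: pd.Series,
    covariates: pd.DataFrame | None = None,
    min_class: int = 4,
    min_lines: int = 30,
) -> pd.DataFrame:
    """Per-SNP regression of line means on allele count.

    Returns a table with the two-sided slope p-value, the half-difference
    additive effect ``a``, homozygote class counts, and MAF.  SNPs whose
    smaller homozygote class is below ``min_class`` are flagged
    ``ok = False`` and excluded from downstream top-SNP selection;
    monomorphic SNPs are additionally given p = NaN.  Missing genotype
    calls are dropped per SNP (complete-case).
    """
    counts, y, x0 = _align_lines(geno, pheno, covariates)
    n = len(y)
    if n < min_lines:
        raise ValueError(f"need at least {min_lines} lines ({n} available)")
    yr = _residualize_cov(y, x0)
    k_cov = 0 if x0 is None else np.linalg.matrix_rank(x0) - 1

    miss = np.isnan(counts)
    obs = (~miss).sum(axis=0).astype(float)
    # Slope test on covariate-residualized phenotype *and* genotype
    # (Frisch–Waugh–Lovell), so the no-missing path reproduces the full
    # OLS fit exactly.  With missing calls the covariate fit is shared
    # (missing entries imputed at the SNP mean before residualizing) — a
    # documented approximation only exercised when calls are missing.
    g = np.where(miss, 0.0, counts)
    if x0 is not None:
        with np.errstate(invalid="ignore"):
            snp_mean = np.where(obs > 0, g.sum(axis=0) / obs, 0.0)
        g_filled = np.where(miss, snp_mean[None, :], counts)
        g = _residualize_cov(g_filled, x0)
        g = np.where(miss, 0.0, g)
    yv = np.where(miss, 0.0, yr[:, None])
    sg = g.sum(axis=0)
    sy = (yv * ~miss).sum(axis=0)
    gbar = sg / obs
    ybar = sy / obs
    sxx = (g**2).sum(axis=0) - obs * gbar**2
    sxy = (g * yv).sum(axis=0) - obs * gbar * ybar
    syy = ((yv**2) * ~miss).sum(axis=0) - obs * ybar**2
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = sxy / sxx
        rss = syy - slope * sxy
        df = obs - 2 - k_cov
        se = np.sqrt(np.maximum(rss, 0.0) / np.maximum(df, 1) / sxx)
        t = slope / se
    p = np.where(
        (sxx > 0) & (df > 0),
        2.0 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), np.maximum(df, 1)),
        np.nan,
    )
    # Perfect fits (rss ~ 0) give t = inf -> p = 0; zero-variance
    # phenotype gives p = 1 by convention.
    p = np.where((sxx > 0) & (df > 0) & ~np.isfinite(t) & (syy > 0), 0.0, p)
    p = np.where((syy <= 1e-300) & (sxx > 0), 1.0, p)

    a = _additive_effects_array(counts, yr)
    alt_hom = (counts == 2) & ~miss
    ref_hom = (counts == 0) & ~miss
    n_alt = alt_hom.sum(axis=0)
    n_ref = ref_hom.sum(axis=0)
    alt_major = geno.alt_frequency() > 0.5
    n_major = np.where(alt_major, n_alt, n_ref)
    n_minor = np.where(alt_major, n_ref, n_alt)
    ok = (n_minor >= min_class) & (n_major >= min_class) & ~np.isnan(p)
    return pd.DataFrame(
        {
            "snp": geno.snp_ids,
            "chrom": geno.chrom,
            "pos": geno.pos,
            "p_value": p,
            "additive_effect": a,
            "n_major_hom": n_major.astype(int),
            "n_minor_hom": n_minor.astype(int),
            "maf": geno.maf(),
            "ok": ok,
        }
    )


def select_top_snps(
    assoc: pd.DataFrame,
    mode: str = "fdr",
    cutoff: float = 0.2,
) -> list:
    """Top-SNP selection by FDR, fixed p cutoff, or smallest-k p-values.

    ``fdr`` applies the Benjamini–Hochberg step-up adjustment and keeps
    adjusted p < cutoff; ``pfixed`` keeps raw p < cutoff; ``topk`` keeps
    the ``int(cutoff)`` smallest raw p (ties broken by |a| descending,
    then SNP id).  Flagged records (``ok = False``) are never selected.
    """
    from statsmodels.stats.multitest import multipletests

    usable = assoc[assoc["ok"] & assoc["p_value"].notna()]
    if usable.empty:
        return []
    if mode == "fdr":
        _, p_adj, _, _ = multipletests(
            usable["p_value"].to_numpy(), alpha=cutoff, method="fdr_bh"
        )
        return list(usable.loc[p_adj < cutoff, "snp"])
    if mode == "pfixed":
        return list(usable.loc[usable["p_value"] < cutoff, "snp"])
    if mode == "topk":
        k = int(cutoff)
        ordered = usable.assign(_absa=usable["additive_effect"].abs()).sort_values(
            ["p_value", "_absa", "snp"], ascending=[True, False, True]
        )
        return list(ordered["snp"].head(k))
    raise ValueError(f"unknown mode {mode!r}")


def across_study_mean(phenos: list[pd.Series]) -> pd.Series:
    """Unweighted per-line mean over studies, restricted to shared lines."""
    if len(phenos) < 2:
        raise ValueError("need at least 2 studies")
    series = [pd.Series(p).dropna() for p in phenos]
    shared = series[0].index
    for s in series[1:]:
        shared = shared.intersection(s.index)
    if len(shared) == 0:
        raise ValueError("no lines shared across all studies")
    stacked = pd.concat([s.reindex(shared) for s in series], axis=1)
    out = stacked.mean(axis=1)
    out.name = "across_study_mean"
    return out
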