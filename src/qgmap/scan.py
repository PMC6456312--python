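"""Haplotype-regression genome scan for multiparental RIL panels.

At every mapped position the strain-mean trait is regressed on the
additive probabilities that each founder contributed the local haplotype.
The scan statistic is

    LOD = (n / 2) * log10(RSS_null / RSS_full)

where the null model holds the intercept and any covariates and the full
model adds the founder-probability columns (one dropped to absorb the
sum-to-one constraint).  Genome-wide significance comes from permuting
phenotype rows against haplotype rows and taking an upper quantile of the
per-permutation maximum LOD; QTL location uncertainty is summarized by
2-LOD support intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FounderHaplotypeMatrix

__all__ = [
    "LodCurve",
    "QtlPeak",
    "lod_scan",
    "permutation_threshold",
    "call_peaks",
    "founder_effects_at",
    "variance_explained_at",
    "scan_summary",
]

# LOD is capped at (n/2)*16 when the full model fits exactly (RSS_full = 0).
_LOD_CAP_FACTOR = 8.0
_RANK_TOL = 1e-10


@dataclass
class LodCurve:
    """LOD score per mapped position."""

    chrom: np.ndarray
    positions: np.ndarray
    lod: np.ndarray
    capped: np.ndarray | None = None  # True where RSS_full underflowed to 0

    def __post_init__(self) -> None:
        if self.capped is None:
            self.capped = np.zeros(len(self.lod), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos_cM": self.positions, "lod": self.lod}
        )


@dataclass
class QtlPeak:
    """A called QTL: location, 2-LOD support interval, effects."""

    chrom: str
    peak_position: float
    peak_lod: float
    ci_low: float
    ci_high: float
    founder_effects: np.ndarray | None = None
    panel_mean: float | None = None
    var_explained: float | None = None  # percent of strain-mean variance
    peak_index: int = -1


def _align_phenotype(
    haps: FounderHaplotypeMatrix,
    pheno: pd.Series,
    covariates: pd.DataFrame | None,
) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Reorder phenotype (and covariates) to the haplotype strain order."""
    pheno = pd.Series(pheno)
    missing = [s for s in haps.rils if s not in pheno.index]
    if missing:
        raise ValueError(
            f"{len(missing)} strains in the haplotype matrix lack phenotypes "
            f"(first: {missing[0]!r})"
        )
    y = pheno.reindex(haps.rils).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype contains missing values after alignment")
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates).reindex(haps.rils)
        if cov.isna().any().any():
            raise ValueError("covariate columns incomplete after alignment")
    return y, cov


def _null_design(n: int, covariates: pd.DataFrame | None) -> np.ndarray:
    """Intercept plus dummy-coded / numeric covariate columns."""
    cols = [np.ones((n, 1))]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float).reshape(-1, 1))
            else:
                dummies = pd.get_dummies(col, drop_first=True)
                cols.append(dummies.to_numpy(dtype=float))
    return np.hstack(cols)


def _orthonormal_null(x0: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the null design's column space."""
    q, r = np.linalg.qr(x0)
    keep = np.abs(np.diag(r)) > _RANK_TOL * max(1.0, np.abs(r).max())
    return q[:, keep]


def _residualize(q0: np.ndarray, a: np.ndarray) -> np.ndarray:
    return a - q0 @ (q0.T @ a)


def _founder_bases(
    probs: np.ndarray, q0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position orthonormal bases for the founder columns.

    For each position, the first ``k - 1`` founder-probability columns are
    residualized against the null design and reduced by SVD to an
    orthonormal basis of their column space (rank-deficient positions —
    e.g. a locus where every strain has the same founder — contribute
    fewer directions).  Returns the stacked bases ``(P, n, k-1)`` and a
    mask of retained directions.
    """
    h = np.transpose(probs[:, :, :-1], (1, 0, 2))  # (P, n, k-1)
    hr = h - np.einsum("ij,jk,pkl->pil", q0, q0.T, h, optimize=True)
    u, s, _ = np.linalg.svd(hr, full_matrices=False)
    smax = s.max(axis=1, keepdims=True)
    keep = s > np.maximum(smax, 1.0) * 1e-9
    return u * keep[:, None, :], keep


def _lod_from_rss(rss0: np.ndarray, rss1: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    cap = _LOD_CAP_FACTOR * n
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rss1 > 0, rss0 / np.maximum(rss1, 1e-300), np.inf)
        lod = 0.5 * n * np.log10(np.maximum(ratio, 1.0))
    capped = ~np.isfinite(lod) | (lod > cap)
    lod = np.where(capped, cap, lod)
    return lod, capped


def _check_rank(n: int, x0: np.ndarray, n_founders: int) -> None:
    p_full = x0.shape[1] + n_founders - 1
    if n <= p_full:
        raise ValueError(
            f"{n} strains cannot support a model with {p_full} parameters"
        )


def lod_scan(
    haps: FounderHaplotypeMatrix,
    pheno: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> LodCurve:
    """LOD score at every mapped position.

    Parameters
    ----------
    haps
        Founder haplotype probabilities.
    pheno
        Strain-mean trait values indexed by strain id.
    covariates
        Optional per-strain covariates (numeric, or categorical columns
        which are dummy-coded), indexed by strain id.
    """
    y, cov = _align_phenotype(haps, pheno, covariates)
    n = len(y)
    x0 = _null_design(n, cov)
    _check_rank(n, x0, haps.n_founders)
    q0 = _orthonormal_null(x0)
    yr = _residualize(q0, y)
    rss0 = float(yr @ yr)
    if rss0 <= _RANK_TOL:
        warnings.warn("phenotype has no residual variance; LOD curve is zero")
        lod = np.zeros(haps.n_positions)
        return LodCurve(haps.chrom.copy(), haps.positions.copy(), lod)
    u, _ = _founder_bases(haps.probs, q0)
    proj = np.einsum("pnk,n->pk", u, yr, optimize=True)
    rss1 = rss0 - (proj**2).sum(axis=1)
    lod, capped = _lod_from_rss(np.full(haps.n_positions, rss0), rss1, n)
    return LodCurve(haps.chrom.copy(), haps.positions.copy(), lod, capped)


def permutation_threshold(
    haps: FounderHaplotypeMatrix,
    pheno: pd.Series,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    return_max_lods: bool = False,
):
    """Genome-wide LOD threshold from phenotype permutations.

    Phenotype rows are shuffled against haplotype rows ``n_perm`` times
    (covariate rows stay attached to their phenotype rows, preserving the
    phenotype–covariate association under the no-linkage null); the
    threshold is the ``1 - alpha`` empirical quantile of the maximum LOD
    over positions.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    y, cov = _align_phenotype(haps, pheno, covariates)
    n = len(y)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)], axis=1)
    x0 = _null_design(n, cov)
    _check_rank(n, x0, haps.n_founders)
    q0 = _orthonormal_null(x0)
    yr0 = _residualize(q0, y)
    rss0 = float(yr0 @ yr0)
    if rss0 <= _RANK_TOL:
        raise ValueError("phenotype has no residual variance; cannot permute")

    # Permuting (phenotype, covariate) rows jointly against the haplotypes
    # is the same scan applied to inverse-permuted haplotype rows.  With no
    # covariates the null space (the intercept) is permutation-invariant,
    # so every permutation shares the founder bases and the whole batch
    # reduces to one tensor contraction.  With covariates the founder
    # columns must be re-residualized per permutation, so each permutation
    # costs one scan.
    if cov is None:
        u, _ = _founder_bases(haps.probs, q0)
        yperm = yr0[perms]  # (n, n_perm); mean-free, so rss0 is unchanged
        proj = np.einsum("pnk,nb->pkb", u, yperm, optimize=True)
        rss1 = rss0 - (proj**2).sum(axis=1)  # (P, n_perm)
        lod, _ = _lod_from_rss(np.full_like(rss1, rss0), rss1, n)
        max_lods = lod.max(axis=0)
    else:
        max_lods = np.empty(n_perm)
        for b in range(n_perm):
            inv = np.argsort(perms[:, b])
            u, _ = _founder_bases(haps.probs[inv], q0)
            proj = np.einsum("pnk,n->pk", u, yr0, optimize=True)
            rss1 = rss0 - (proj**2).sum(axis=1)
            lod, _ = _lod_from_rss(np.full_like(rss1, rss0), rss1, n)
            max_lods[b] = lod.max()
    threshold = float(np.quantile(max_lods, 1.0 - alpha))
    if return_max_lods:
        return threshold, max_lods
    return threshold


def call_peaks(
    curve: LodCurve,
    threshold: float,
    min_peak_separation: float = 10.0,
) -> list[QtlPeak]:
    """Local maxima above threshold with 2-LOD support intervals.

    Candidates are taken in descending LOD order; a candidate is
    suppressed if it lies within ``min_peak_separation`` cM of an
    already-called peak on the same chromosome, or inside that peak's
    2-LOD interval.  Each interval is the maximal contiguous run of
    positions around the peak with ``lod >= peak_lod - 2``, clipped at
    chromosome ends.
    """
    if len(curve.lod) == 0:
        raise ValueError("empty LOD curve")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    lod = curve.lod
    chrom = np.asarray(curve.chrom)
    pos = curve.positions
    candidates = []
    for i in range(len(lod)):
        if lod[i] < threshold:
            continue
        left_ok = i == 0 or chrom[i - 1] != chrom[i] or lod[i - 1] <= lod[i]
        right_ok = (
            i == len(lod) - 1 or chrom[i + 1] != chrom[i] or lod[i + 1] <= lod[i]
        )
        if left_ok and right_ok:
            candidates.append(i)
    candidates.sort(key=lambda i: -lod[i])

    peaks: list[QtlPeak] = []
    for i in candidates:
        suppressed = False
        for p in peaks:
            if p.chrom != chrom[i]:
                continue
            if abs(pos[i] - p.peak_position) <= min_peak_separation:
                suppressed = True
                break
            if p.ci_low <= pos[i] <= p.ci_high:
                suppressed = True
                break
        if suppressed:
            continue
        lo = i
        while lo > 0 and chrom[lo - 1] == chrom[i] and lod[lo - 1] >= lod[i] - 2.0:
            lo -= 1
        hi = i
        while (
            hi < len(lod) - 1
            and chrom[hi + 1] == chrom[i]
            and lod[hi + 1] >= lod[i] - 2.0
        ):
            hi += 1
        peaks.append(
            QtlPeak(
                chrom=str(chrom[i]),
                peak_position=float(pos[i]),
                peak_lod=float(lod[i]),
                ci_low=float(pos[lo]),
                ci_high=float(pos[hi]),
                peak_index=i,
            )
        )
    peaks.sort(key=lambda p: (p.chrom, p.peak_position))
    return peaks


def _full_fit_at(
    haps: FounderHaplotypeMatrix,
    y: np.ndarray,
    cov: pd.DataFrame | None,
    idx: int,
) -> tuple[np.ndarray, float, float]:
    """Least-squares fit of the full model at one position.

    Returns (founder coefficient vector with the dropped founder at 0,
    RSS_null, RSS_full).
    """
    n = len(y)
    x0 = _null_design(n, cov)
    _check_rank(n, x0, haps.n_founders)
    h = haps.probs[:, idx, :-1]
    x = np.hstack([x0, h])
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    rss_full = float(resid @ resid)
    q0 = _orthonormal_null(x0)
    yr = _residualize(q0, y)
    rss_null = float(yr @ yr)
    beta = np.zeros(haps.n_founders)
    beta[:-1] = coef[x0.shape[1] :]
    return beta, rss_null, rss_full


def founder_effects_at(
    haps: FounderHaplotypeMatrix,
    pheno: pd.Series,
    covariates: pd.DataFrame | None = None,
    position: float | None = None,
    index: int | None = None,
) -> tuple[np.ndarray, float]:
    """Founder effects at a position, as deviations from the panel mean.

    The full-model founder coefficients are re-centered by the
    probability-weighted founder mean, so the reported deviations sum to
    ~0 when founders are equally represented.  Returns
    ``(effects, panel_mean)`` where ``panel_mean`` is the mean phenotype.
    """
    y, cov = _align_phenotype(haps, pheno, covariates)
    idx = haps.position_index(position) if index is None else index
    beta, _, _ = _full_fit_at(haps, y, cov, idx)
    pbar = haps.probs[:, idx, :].mean(axis=0)
    effects = beta - pbar @ beta
    return effects, float(np.mean(y))


def variance_explained_at(
    haps: FounderHaplotypeMatrix,
    pheno: pd.Series,
    covariates: pd.DataFrame | None = None,
    position: float | None = None,
    index: int | None = None,
) -> float:
    """Percent reduction in residual variance at a position (0–100)."""
    y, cov = _align_phenotype(haps, pheno, covariates)
    idx = haps.position_index(position) if index is None else index
    _, rss_null, rss_full = _full_fit_at(haps, y, cov, idx)
    if rss_null <= _RANK_TOL:
        warnings.warn("constant phenotype: variance explained reported as 0")
        return 0.0
    return 100.0 * (1.0 - rss_full / rss_null)


def scan_summary(
    haps: FounderHaplotypeMatrix,
    pheno: pd.Series,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_peak_separation: float = 10.0,
    seed: int = 0,
) -> dict:
    """Full scan: LOD curve, permutation threshold, annotated peaks.

    Peaks carry founder effects, panel mean and variance explained; the
    summary also reports the sum of per-peak variances explained
    ("total variance explained, assuming independence and additivity").
    """
    curve = lod_scan(haps, pheno, covariates)
    threshold = permutation_threshold(
        haps, pheno, covariates, n_perm=n_perm, alpha=alpha, seed=seed
    )
    peaks = call_peaks(curve, threshold, min_peak_separation)
    for p in peaks:
        p.founder_effects, p.panel_mean = founder_effects_at(
            haps, pheno, covariates, index=p.peak_index
        )
        p.var_explained = variance_explained_at(
            haps, pheno, covariates, index=p.peak_index
        )
    return {
        "curve": curve,
        "threshold": threshold,
        "peaks": peaks,
        "total_var_explained": float(sum(p.var_explained for p in peaks)),
    }
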