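"""Cross-study sign concordance of SNP additive effects.

Two studies that phenotype the same inbred panel can be compared through
the *direction* of each SNP's additive effect.  The observed statistic
is the proportion of one study's top SNPs whose effects agree in the
second study; the null distribution comes from repeatedly drawing random
SNP sets of the same size, stratified so their minor-allele-frequency
composition matches the top set bin-for-bin (an ordinary nonparametric
bootstrap, sampling with replacement).

Frequency strata: [0.05–0.1], (0.1–0.2], (0.2–0.3], (0.3–0.4], (0.4–0.5].

Two statistics are supported and the null is always built under the same
statistic as the observed value:

* ``positive_both`` — the effect is positive in both studies;
* ``same_sign``     — the two effects share a sign (both nonzero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import additive_effects
from .containers import GenotypeMatrix

__all__ = [
    "MAF_BIN_EDGES",
    "StratumSpec",
    "ConcordanceResult",
    "stratify_top_snps",
    "observed_concordance",
    "null_distribution",
    "empirical_p",
    "concordance_test",
]

MAF_BIN_EDGES = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
_BIN_LABELS = ("0.05-0.1", ">0.1-0.2", ">0.2-0.3", ">0.3-0.4", ">0.4-0.5")


@dataclass
class StratumSpec:
    """Per-MAF-bin counts of a top-SNP set."""

    counts: np.ndarray  # length 5

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (5,) or np.any(self.counts < 0):
            raise ValueError("counts must be 5 non-negative integers")

    @property
    def n_snps(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": _BIN_LABELS, "count": self.counts})


@dataclass
class ConcordanceResult:
    observed: float | None
    statistic: str
    null_samples: np.ndarray
    null_mean: float
    null_interval: tuple[float, float]  # central 95%
    empirical_p: float | None = None
    n_top_used: int | None = None
    n_top_excluded: int | None = None
    sampled_indices: np.ndarray | None = field(default=None, repr=False)


def _maf_bin(maf: np.ndarray) -> np.ndarray:
    """Bin index 0–4; the lower edge 0.05 closes into the first bin and
    each internal edge closes its lower bin (MAF 0.1 -> bin 0)."""
    m = np.asarray(maf, dtype=float)
    out = np.digitize(m, MAF_BIN_EDGES[1:-1], right=True)
    bad = np.isnan(m) | (m < MAF_BIN_EDGES[0]) | (m > MAF_BIN_EDGES[-1])
    return np.where(bad, -1, out)


def stratify_top_snps(
    top_snps: list, maf: pd.Series | dict
) -> StratumSpec:
    """MAF-bin composition of a top-SNP set."""
    maf = pd.Series(maf)
    counts = np.zeros(5, dtype=int)
    for snp in top_snps:
        if snp not in maf.index:
            raise KeyError(f"no MAF recorded for SNP {snp!r}")
        b = _maf_bin(np.array([maf[snp]]))[0]
        if b < 0:
            raise ValueError(
                f"SNP {snp!r} has MAF {maf[snp]:.4g} outside (0.05, 0.5]"
            )
        counts[b] += 1
    return StratumSpec(counts)


def _concordant(a_x: np.ndarray, a_y: np.ndarray, statistic: str) -> np.ndarray:
    if statistic == "positive_both":
        return (a_x > 0) & (a_y > 0)
    if statistic == "same_sign":
        return np.sign(a_x) * np.sign(a_y) > 0  # zero effects non-concordant
    raise ValueError(f"unknown statistic {statistic!r}")


def observed_concordance(
    top_snps: list,
    effects_x: pd.Series,
    effects_y: pd.Series,
    statistic: str = "same_sign",
) -> tuple[float, int, int]:
    """Concordance proportion of the top SNPs across two studies.

    SNPs whose effect is undefined in either study (empty homozygote
    class) are excluded and counted.  Returns
    ``(proportion, n_used, n_excluded)``.
    """
    ex = pd.Series(effects_x).reindex(top_snps)
    ey = pd.Series(effects_y).reindex(top_snps)
    ok = ex.notna() & ey.notna()
    n_used = int(ok.sum())
    if n_used == 0:
        raise ValueError("no top SNP has a defined effect in both studies")
    conc = _concordant(ex[ok].to_numpy(), ey[ok].to_numpy(), statistic)
    return float(conc.mean()), n_used, int(len(top_snps) - n_used)


def null_distribution(
    geno: GenotypeMatrix,
    pheno_x: pd.Series,
    pheno_y: pd.Series,
    strata: StratumSpec,
    n_snps: int | None = None,
    n_iter: int = 1000,
    statistic: str = "positive_both",
    seed: int = 0,
    covariates_x: pd.DataFrame | None = None,
    covariates_y: pd.DataFrame | None = None,
) -> ConcordanceResult:
    """Frequency-stratified bootstrap null for cross-study concordance.

    Each iteration samples SNPs with replacement, matching the per-bin
    counts of ``strata``, computes the additive effect of every sampled
    SNP in both studies, and records the concordant proportion.  SNPs
    with an undefined effect in either study are ineligible for sampling.
    """
    if n_snps is not None and n_snps != strata.n_snps:
        raise ValueError("n_snps disagrees with the stratum counts")
    a_x = additive_effects(geno, pheno_x, covariates_x)
    a_y = additive_effects(geno, pheno_y, covariates_y)
    maf = geno.maf()
    bins = _maf_bin(maf)
    eligible = ~np.isnan(a_x) & ~np.isnan(a_y)
    rng = np.random.default_rng(seed)
    pools = []
    for b in range(5):
        pool = np.nonzero(eligible & (bins == b))[0]
        if strata.counts[b] > 0 and pool.size == 0:
            raise ValueError(
                f"stratum {_BIN_LABELS[b]} requires {strata.counts[b]} SNPs "
                "but no eligible SNP falls in that bin"
            )
        pools.append(pool)
    total = strata.n_snps
    samples = np.empty((n_iter, total), dtype=int)
    props = np.empty(n_iter)
    conc_all = _concordant(a_x, a_y, statistic)
    for it in range(n_iter):
        start = 0
        for b in range(5):
            c = strata.counts[b]
            if c:
                samples[it, start : start + c] = rng.choice(pools[b], size=c)
                start += c
        props[it] = conc_all[samples[it]].mean()
    lo, hi = np.percentile(props, [2.5, 97.5])
    return ConcordanceResult(
        observed=None,
        statistic=statistic,
        null_samples=props,
        null_mean=float(props.mean()),
        null_interval=(float(lo), float(hi)),
        sampled_indices=samples,
    )


def empirical_p(observed: float, null_samples: np.ndarray) -> float:
    """One-sided (greater) add-one empirical p-value."""
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size == 0:
        raise ValueError("null_samples is empty")
    return float((1 + (null_samples >= observed).sum()) / (1 + null_samples.size))


def concordance_test(
    geno: GenotypeMatrix,
    pheno_x: pd.Series,
    pheno_y: pd.Series,
    top_snps: list,
    n_iter: int = 1000,
    statistic: str = "positive_both",
    seed: int = 0,
    covariates_x: pd.DataFrame | None = None,
    covariates_y: pd.DataFrame | None = None,
) -> ConcordanceResult:
    """Observed top-SNP concordance against its stratified bootstrap null.

    Convenience wrapper: stratifies the top set by MAF, computes the
    observed proportion, builds the null under the same statistic, and
    attaches the one-sided empirical p-value.
    """
    maf = pd.Series(geno.maf(), index=geno.snp_ids)
    strata = stratify_top_snps(top_snps, maf)
    a_x = pd.Series(additive_effects(geno, pheno_x, covariates_x), index=geno.snp_ids)
    a_y = pd.Series(additive_effects(geno, pheno_y, covariates_y), index=geno.snp_ids)
    obs, n_used, n_excl = observed_concordance(top_snps, a_x, a_y, statistic)
    res = null_distribution(
        geno,
        pheno_x,
        pheno_y,
        strata,
        n_iter=n_iter,
        statistic=statistic,
        seed=seed,
        covariates_x=covariates_x,
        covariates_y=covariates_y,
    )
    res.observed = obs
    res.n_top_used = n_used
    res.n_top_excluded = n_excl
    res.empirical_p = empirical_p(obs, res.null_samples)
    return res
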