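# Methods notes

This note records the models the toolkit implements, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer should know about.

## Haplotype-regression scan

The scan treats each strain's trait as a strain *mean* and fits, at
every mapped position, the linear model

    y = X0 a + H b + e

where `X0` is an intercept plus optional covariate columns (categorical
covariates are dummy-coded) and `H` holds the founder-probability
columns with the last founder dropped: the probabilities sum to one, so
the full founder basis is collinear with the intercept. The statistic is
`LOD = (n/2)·log10(RSS_null/RSS_full)`, the line-mean scan statistic
standard for multiparental panels. Implementation detail: founder
columns are residualized against `X0` and reduced per position by SVD to
an orthonormal basis, so rank-deficient positions (e.g. a locus where
every strain carries the same founder) lose directions gracefully and
score LOD = 0 rather than producing spurious projections. A perfect
full-model fit (RSS_full = 0, possible in noise-free simulations) is
capped at LOD = 8n and flagged, avoiding infinities.

Reported founder effects are the full-model coefficients with the
dropped founder at zero, re-centered by the probability-weighted founder
mean; this makes the eight reported deviations founder-symmetric and
sum-to-zero under balanced representation. The panel mean reported with
them is the plain phenotype mean. Variance explained at a position is
`100·(1 − RSS_full/RSS_null)` on strain means; a scan summary also sums
it over called peaks, a total that assumes QTL independence and
additivity and can exceed what a joint model would give.

### Permutation threshold

Phenotype rows are permuted against haplotype rows with covariate rows
kept attached to their phenotypes, preserving phenotype–covariate
structure under the no-linkage null; the threshold is the (1 − α)
empirical quantile of the per-permutation maximum LOD (default 1000
permutations, α = 0.05). Without covariates the intercept-only null
space is permutation-invariant and all permutations share one set of
per-position bases, reducing the whole batch to a single tensor
contraction; with covariates each permutation requires re-residualizing
the founder columns against the permuted covariate rows, so each
permutation costs one scan. Both paths are exact and agree on trivial
covariates (tested).

### Peak calling

Local maxima above threshold are accepted greedily in descending LOD;
later candidates are suppressed within 10 cM of an accepted peak (the
`min_peak_separation` default — the separation rule for distinct peaks
on one chromosome is not standardized, so the value is configurable) or
inside an accepted peak's 2-LOD interval. Each interval is the maximal
contiguous run with LOD ≥ peak − 2, clipped at chromosome ends. A known
limitation: a strong QTL in a mosaic genome can carry a long-range
linked shoulder that survives both suppression rules and is called as a
secondary peak; coverage statements in the validation studies therefore
refer to the maximum-LOD peak.

## Heritability

Broad-sense heritability is estimated from replicate-level data by
one-way random-effects ANOVA: `V_E = MS_within`,
`V_G = (MS_among − MS_within)/n₀` with the Sokal–Rohlf effective
replicate number `n₀ = (N − Σnᵢ²/N)/(s − 1)` for unbalanced designs, and
`H² = V_G/(V_G + V_E)` with negative `V_G` truncated to zero (H²
reported as 0). A REML route (random strain intercept) is exposed
alongside; the two agree within 0.02 on balanced designs of ≥ 200
strains (tested).

## Founder prediction and haplotype means

Predicted founder value = grand mean + Σ_q w_q β_{q,f} / Σ_q w_q, with
w_q the peak's variance explained. Weights are normalized to sum to one
— the aggregation is a weighted mean, invariant to rescaling all
weights, a documented choice since "weighted by the variance explained"
does not pin down a normalization. Peak sets from separate scans (e.g.
per sex) can be pooled before weighting. Haplotype-group means harden
soft probabilities by argmax with a minimum assignment probability of
0.8 (configurable; hardening thresholds for mosaic panels are
conventionally in this range), excluding unassignable strains and
reporting empty founders with missing means.

## Inbred-line association

Per-SNP inference is OLS of line means on alternate-allele counts
(0/2), two-sided p from the slope t statistic. With covariates, both
phenotype and genotype are residualized first (Frisch–Waugh–Lovell), so
the no-missing path reproduces the full joint fit exactly; missing calls
are handled complete-case per SNP, with the covariate fit shared across
SNPs (an approximation exercised only when calls are missing). The
additive effect is half the major-minus-minor homozygote class-mean
difference, computed on covariate-residualized phenotypes when
covariates are supplied; at a frequency tie of exactly 0.5 the reference
allele is designated major (deterministic). SNPs with fewer than 4
lines in either homozygote class are flagged and excluded from top-SNP
selection; zero-variance phenotypes give p = 1 rather than NaN.
Population-structure and symbiont adjustments enter as ordinary
covariate columns; no mixed model or relatedness matrix is fitted.

## Sign concordance

Both statistics — positive-in-both and same-sign (zero effects count as
non-concordant) — are implemented; observed and null are always computed
under the same statistic. The null samples SNP sets with replacement
(ordinary nonparametric bootstrap), matching the top set's MAF-bin
composition exactly in every iteration; bins are [0.05–0.1],
(0.1–0.2], (0.2–0.3], (0.3–0.4], (0.4–0.5], with each internal edge
closing its lower bin. SNPs whose effect is undefined in either study
(an empty homozygote class) are excluded from the observed proportion
(and counted) and are ineligible for null sampling — the effect is
undefined, not zero. The empirical p-value is one-sided (greater) with
the add-one rule, so it is never exactly zero.

## Assay calculation

`conc = C_std·[FA_s − IA_s·F]/[FA_std − IA_blank·F]`, `F = 0.8`
(a kit constant, configurable), `C_std = 2.5 mg/ml`. Controls are
per-plate only: three standard wells averaged, one blank. Non-positive
denominators abort the plate; negative sample results are flagged but
never truncated, preserving information for QC.

## Synthetic data: what it does and does not emulate

* **RIL mosaics** are first-order Markov chains on the map grid:
  per-gap switch probability proportional to map distance, scaled so the
  expected block count per chromosome matches `expected_segments`
  (default 8 per 100 cM — a free parameter, not calibrated to a real
  panel); after a switch the new founder is uniform over the others.
  Probability rows put `assignment_certainty` on the true founder. This
  reproduces the block-length scale and soft-assignment structure
  downstream methods consume, not the intercross pedigree, founder
  allele sharing, or realistic recombination interference.
* **RIL phenotypes** follow exactly the additive founder-effect model
  the scan fits: genetic value = Σ_QTL (probability row · effect
  vector), optional polygenic noise, environmental noise solved
  analytically from the realized genetic variance so that
  `V_G/(V_G+V_E)` equals the target replicate-level H² — making
  heritability recovery a sharp test. Subpopulation labels are assigned
  round-robin with additive shifts. `target_h2 = 0` requires zero
  genetic variance (the environmental SD then defaults to 1);
  `target_h2 > 0` with no genetic variance is rejected.
* **Line panels** draw MAFs from Beta(0.8, 0.8)/2 truncated to
  [0.05, 0.5]; each line is homozygous minor with probability equal to
  the SNP's frequency — no linkage disequilibrium beyond what
  homozygosity induces, so association hits are exactly the causal SNPs
  plus noise. Columns whose realized frequency drifts below the floor
  are redrawn (the emulated panel is pre-filtered at MAF ≥ 0.05). All
  studies share one polygenic score with study-specific shift, scale and
  noise, inducing cross-study correlation without shared environment.
* **Plates** are built by inverting the assay formula at fixed controls,
  with independent Gaussian noise added to every individual scan read;
  the zero-noise round trip is exact to 1e-10.

Because phenotypes are generated under the fitted model, passing tests
demonstrate correctness and calibration of the *methods*, not robustness
to model misspecification (non-additivity, epistasis, LD, shared
environment) in real data.

## Validation studies and problem sizes

`qgmap.validation` packages four simulation studies, run by the test
suite and the reproduction script at these sizes (chosen to give tight
Monte-Carlo error at desk scale; all sizes are arguments):

* interval coverage: 100 panels × 500 RILs × 500 positions, hard
  assignments, single QTL at ~10% of strain-mean variance; expected
  coverage ≈ 95% (binomial band 88–99%);
* permutation type-I error: 200 null panels of 200 RILs × 150
  positions, 200 permutations each at α = 0.05; expected exceedance
  0.02–0.10;
* heritability recovery: 50 simulations × 800 strains × 8 replicates at
  H² ∈ {0, 0.5, 0.75}; mean estimate within ±0.03;
* concordance power: 50 replicates of two studies on 200 lines × 500
  SNPs, 20 causal SNPs (effect SD 1.0, study noise SD 3.0 — noise
  dominating single-SNP signal, the regime where single-study GWAS finds
  little), top-50 selection, same-sign statistic, 200-iteration null;
  detection expected in ≥ 90% of replicates.

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`; study replicates via `SeedSequence.spawn`),
so every result is a pure function of (parameters, seed).

## Known limitations

* No interval mapping between grid positions, no epistasis or
  sex-interaction models; sex-specific mapping is done by scanning sexes
  separately.
* The association model is fixed-effects only; panels with strong
  relatedness structure need their adjustments supplied as covariates.
* The peak-separation rule is a documented stand-in (see above).
* Variance-explained totals over peaks assume independent, additive QTL.
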