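"""Shared in-memory containers for mapping-panel data.

Two panel designs are represented:

* a multiparental panel of recombinant inbred lines (RILs), each a mosaic
  of founder haplotypes, carried as per-position founder-probability
  vectors (:class:`FounderHaplotypeMatrix`);
* a panel of fully inbred, homozygous lines genotyped at biallelic SNPs,
  carried as allele counts in {0, 2} (:class:`GenotypeMatrix`).

Phenotypes travel as plain pandas objects: replicate-level tables with
columns ``strain``/``replicate``/``value`` (plus optional ``sex`` and
covariates), or line means as a :class:`pandas.Series` indexed by strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FounderHaplotypeMatrix", "GenotypeMatrix", "SimTruth"]


@dataclass
class FounderHaplotypeMatrix:
    """Per-RIL, per-position founder haplotype probabilities.

    Parameters
    ----------
    rils
        Strain identifiers, one per row of ``probs``.
    chrom
        Chromosome label per mapped position.
    positions
        Genetic map coordinate (cM) per position; strictly increasing
        within each chromosome.
    probs
        Array of shape ``(n_rils, n_positions, n_founders)``; each
        length-``n_founders`` vector sums to 1.
    founders
        Founder labels (default ``A1..A<k>``).
    """

    rils: np.ndarray
    chrom: np.ndarray
    positions: np.ndarray
    probs: np.ndarray
    founders: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rils = np.asarray(self.rils)
        self.chrom = np.asarray(self.chrom)
        self.positions = np.asarray(self.positions, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if not self.founders:
            self.founders = [f"A{i + 1}" for i in range(self.probs.shape[2])]
        self.validate()

    @property
    def n_rils(self) -> int:
        return self.probs.shape[0]

    @property
    def n_positions(self) -> int:
        return self.probs.shape[1]

    @property
    def n_founders(self) -> int:
        return self.probs.shape[2]

    def validate(self, atol: float = 1e-6) -> None:
        if self.probs.ndim != 3:
            raise ValueError("probs must have shape (n_rils, n_positions, n_founders)")
        n, p, k = self.probs.shape
        if len(self.rils) != n or len(self.positions) != p or len(self.chrom) != p:
            raise ValueError("rils/positions/chrom lengths do not match probs shape")
        if len(self.founders) != k:
            raise ValueError("founder labels do not match probs shape")
        if np.any(self.probs < -atol) or np.any(self.probs > 1 + atol):
            raise ValueError("haplotype probabilities outside [0, 1]")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=atol):
            raise ValueError("haplotype probability rows must sum to 1")
        for c in pd.unique(self.chrom):
            pos_c = self.positions[self.chrom == c]
            if np.any(np.diff(pos_c) <= 0):
                raise ValueError(
                    f"positions must be strictly increasing within chromosome {c!r}"
                )

    def position_index(self, position: float, chrom: str | None = None) -> int:
        """Index of an exact grid position (optionally chromosome-scoped)."""
        mask = np.isclose(self.positions, position)
        if chrom is not None:
            mask &= self.chrom == chrom
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise KeyError(f"position {position} not on the haplotype grid")
        return int(idx[0])


@dataclass
class GenotypeMatrix:
    """Homozygous inbred-line genotypes at biallelic SNPs.

    ``counts`` holds the number of copies of the alternate allele per
    (line, SNP): 0 or 2 for an inbred panel, NaN for missing calls.
    The *minor* allele at a SNP is whichever of ref/alt is rarer among
    the genotyped lines; ties designate the reference allele as major.
    """

    line_ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    counts: np.ndarray  # (n_lines, n_snps), values in {0, 2, nan}
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.line_ids), len(self.snp_ids)):
            raise ValueError("counts shape does not match line/snp ids")
        valid = np.isnan(self.counts) | (self.counts == 0) | (self.counts == 2)
        if not valid.all():
            raise ValueError("allele counts must be 0, 2 or missing (inbred panel)")
        if self.ref is None:
            self.ref = np.array(["A"] * len(self.snp_ids))
        if self.alt is None:
            self.alt = np.array(["T"] * len(self.snp_ids))

    @property
    def n_lines(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def alt_frequency(self) -> np.ndarray:
        """Frequency of the alternate allele among genotyped lines, per SNP."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.counts, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP (NaN where all calls missing)."""
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)

    def minor_is_alt(self) -> np.ndarray:
        """True where the alternate allele is the minor one.

        At frequency exactly 0.5 the reference allele is designated major,
        so the alternate counts as minor.
        """
        return self.alt_frequency() <= 0.5

    def filter_maf(self, maf_min: float = 0.05) -> "GenotypeMatrix":
        keep = self.maf() >= maf_min
        return self.take_snps(np.nonzero(keep)[0])

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            line_ids=self.line_ids,
            snp_ids=self.snp_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            counts=self.counts[:, idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Counts as a line × SNP DataFrame."""
        return pd.DataFrame(self.counts, index=self.line_ids, columns=self.snp_ids)


@dataclass
class SimTruth:
    """Ground truth recorded by the synthetic-data generators.

    For RIL panels: QTL map positions and per-QTL founder-effect vectors.
    For line panels: causal SNP ids with per-allele-copy effect sizes and
    the per-study (shift, scale, noise SD) parameters.
    """

    qtl_positions: list[float] = field(default_factory=list)
    founder_effects: list[list[float]] = field(default_factory=list)
    target_h2: float = 0.0
    causal_snps: dict[str, float] = field(default_factory=dict)
    study_params: list[dict[str, float]] = field(default_factory=list)
    seed: int = 0
    env_sd: float | None = None  # realized environmental SD, filled by generators

    def __post_init__(self) -> None:
        if len(self.qtl_positions) != len(self.founder_effects):
            raise ValueError("qtl_positions and founder_effects lengths differ")
        if not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError("target_h2 must lie in [0, 1]")
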