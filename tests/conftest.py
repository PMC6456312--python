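import numpy as np
import pandas as pd
import pytest

from qgmap.containers import FounderHaplotypeMatrix, GenotypeMatrix, SimTruth


@pytest.fixture
def two_founder_panel():
    """Six strains, two founders, hard assignments at three positions.

    Position 5.0 splits the panel 3/3 between founders; position 1.0 is
    fully collinear (everyone founder A); position 9.0 repeats the split.
    Phenotypes {10, 12, 11} for founder-A strains and {14, 16, 15} for
    founder-B strains give the classic hand-computable least-squares
    instance: RSS_null = 28, RSS_full = 4.
    """
    probs = np.zeros((6, 3, 2))
    probs[:, 0, 0] = 1.0  # collinear position
    for i in range(6):
        f = 0 if i < 3 else 1
        probs[i, 1, f] = 1.0
        probs[i, 2, f] = 1.0
    haps = FounderHaplotypeMatrix(
        rils=np.array([f"S{i}" for i in range(6)]),
        chrom=np.array(["1", "1", "1"]),
        positions=np.array([1.0, 5.0, 9.0]),
        probs=probs,
        founders=["A", "B"],
    )
    pheno = pd.Series([10.0, 12.0, 11.0, 14.0, 16.0, 15.0], index=haps.rils)
    return haps, pheno


@pytest.fixture
def random_soft_panel():
    """A small stochastic panel with soft assignments for oracle checks."""
    rng = np.random.default_rng(7)
    n, p, k = 40, 6, 4
    raw = rng.gamma(1.0, 1.0, size=(n, p, k))
    probs = raw / raw.sum(axis=2, keepdims=True)
    haps = FounderHaplotypeMatrix(
        rils=np.array([f"R{i:02d}" for i in range(n)]),
        chrom=np.array(["1"] * 3 + ["2"] * 3),
        positions=np.array([0.0, 5.0, 10.0, 0.0, 4.0, 8.0]),
        probs=probs,
    )
    pheno = pd.Series(rng.normal(size=n), index=haps.rils)
    covariates = pd.DataFrame(
        {"subpop": np.where(np.arange(n) % 2 == 0, "pA1", "pA2")},
        index=haps.rils,
    )
    return haps, pheno, covariates


@pytest.fixture
def hand_genotypes():
    """Four lines, one SNP with counts {0, 0, 2, 2}."""
    return GenotypeMatrix(
        line_ids=np.array(["l1", "l2", "l3", "l4"]),
        snp_ids=np.array(["s1"]),
        chrom=np.array(["2L"]),
        pos=np.array([100]),
        counts=np.array([[0.0], [0.0], [2.0], [2.0]]),
    )


def make_truth(**kw) -> SimTruth:
    return SimTruth(**kw)
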