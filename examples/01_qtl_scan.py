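"""Map a QTL in a simulated multiparental RIL panel.

Builds an 8-founder panel of 400 recombinant inbred lines, plants one
additive QTL at 40 cM explaining ~15% of strain-mean variance, then runs
the haplotype-probability LOD scan with a 1000-permutation genome-wide
threshold and calls peaks with 2-LOD support intervals.
"""

import numpy as np

from qgmap import scan, simulate
from qgmap.containers import SimTruth

rng = np.random.default_rng(1)
positions = np.arange(0.0, 100.0, 0.5)

haps = simulate.simulate_founder_mosaics(
    n_rils=400, n_founders=8, positions=positions,
    expected_segments=8, assignment_certainty=0.95, seed=11,
)
truth = SimTruth(
    qtl_positions=[40.0],
    founder_effects=[list(rng.normal(0.0, 1.0, 8))],
    target_h2=0.15,
)
pheno = simulate.simulate_ril_phenotypes(haps, truth, n_reps=2, seed=12)
strain_means = pheno.groupby("strain")["value"].mean()

out = scan.scan_summary(haps, strain_means, n_perm=1000, alpha=0.05, seed=13)
curve, thr = out["curve"], out["threshold"]
print(f"max LOD          : {curve.lod.max():.2f} at {curve.positions[curve.lod.argmax()]:.1f} cM")
print(f"5% LOD threshold : {thr:.2f}  (1000 permutations)")
for p in out["peaks"]:
    print(
        f"peak at {p.peak_position:.1f} cM, LOD {p.peak_lod:.2f}, "
        f"2-LOD interval [{p.ci_low:.1f}, {p.ci_high:.1f}] cM, "
        f"variance explained {p.var_explained:.1f}%"
    )
print(f"true QTL position: {truth.qtl_positions[0]:.1f} cM")
# The top peak should sit near 40 cM with its 2-LOD interval (an
# approximate 95% confidence interval for QTL location) covering it.
# Variance explained is reported on strain means, so with 2 replicates
# it exceeds the replicate-level 15% target; long-range linkage in the
# mosaic genomes can also surface a secondary shoulder peak.
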