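"""Predict founder phenotypes from mapped QTL effects.

After mapping, each QTL carries per-founder effects (deviations from the
panel mean) and a variance-explained weight.  Averaging the effects with
those weights gives a predicted trait value per founder line, which is
then regressed on the founders' true genetic values.
"""

import numpy as np

from qgmap import quantgen, scan, simulate
from qgmap.containers import SimTruth

rng = np.random.default_rng(3)
positions = np.arange(0.0, 100.0, 0.5)
haps = simulate.simulate_founder_mosaics(
    n_rils=700, n_founders=8, positions=positions,
    expected_segments=8, assignment_certainty=1.0, seed=31,
)
effects = [list(rng.normal(0, 1.2, 8)) for _ in range(2)]
truth = SimTruth(
    qtl_positions=[25.0, 70.0], founder_effects=effects, target_h2=0.3
)
pheno = simulate.simulate_ril_phenotypes(haps, truth, n_reps=2, seed=32)
strain_means = pheno.groupby("strain")["value"].mean()

out = scan.scan_summary(haps, strain_means, n_perm=300, alpha=0.05, seed=33)
pred = quantgen.predict_founder_phenotypes(
    out["peaks"], grand_mean=float(strain_means.mean())
)
true_founder_value = np.asarray(effects).sum(axis=0)
rep = quantgen.correlate_predicted_actual(pred["predicted"], true_founder_value)
print(pred.round(2).to_string(index=False))
print(
    f"measured-on-predicted regression: slope {rep['slope']:.2f} ± "
    f"{rep['slope_se']:.2f}, R² {rep['r_squared_pct']:.1f}%, "
    f"F({rep['df_model']},{rep['df_resid']}) = {rep['f_stat']:.2f}, p = {rep['f_p']:.3g}"
)
# A strong positive slope and high R² mean the QTL effects recover the
# founders' true summed genetic contributions.
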