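"""Variance components, heritability and founder-level prediction.

Broad-sense heritability H² for an inbred panel is the among-strain share
of the total phenotypic variance, V_G / (V_G + V_E), with V_G and V_E
estimated from replicate measurements by either a one-way random-effects
ANOVA (method of moments, with the Sokal–Rohlf effective replicate number
for unbalanced designs) or REML.

Founder-level prediction aggregates the founder effects of mapped QTL,
weighting each QTL by the fraction of strain-mean variance it explains,
to give a predicted trait value for each founder line — comparable with
the founders' measured phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FounderHaplotypeMatrix
from .scan import QtlPeak

__all__ = [
    "HeritabilityResult",
    "broad_sense_heritability",
    "predict_founder_phenotypes",
    "correlate_predicted_actual",
    "haplotype_group_means",
]


@dataclass
class HeritabilityResult:
    v_genetic: float
    v_residual: float
    h2_broad: float
    n_strains: int
    n_obs: int
    method: str


def broad_sense_heritability(
    pheno: pd.DataFrame,
    value_col: str = "value",
    strain_col: str = "strain",
    method: str = "anova",
) -> HeritabilityResult:
    """Broad-sense heritability from replicate-level phenotypes.

    Parameters
    ----------
    pheno
        Long table with one row per replicate measurement.
    method
        ``"anova"`` — one-way random-effects method-of-moments estimator
        with effective replicate number n0 = (N − Σnᵢ²/N)/(s − 1);
        ``"reml"`` — linear mixed model with a random strain intercept.

    Negative genetic-variance estimates are truncated to zero, so H² is
    reported as 0 when strains do not vary beyond replicate noise.
    """
    df = pheno[[strain_col, value_col]].dropna()
    groups = df.groupby(strain_col)[value_col]
    counts = groups.count()
    s = len(counts)
    big_n = int(counts.sum())
    if s < 2:
        raise ValueError("need at least 2 strains to estimate genetic variance")
    if big_n - s < 1:
        raise ValueError(
            "no strain has replicate measurements; genetic and residual "
            "variance cannot be separated"
        )
    if method == "anova":
        means = groups.mean()
        grand = df[value_col].mean()
        ss_within = float(((df[value_col] - df[strain_col].map(means)) ** 2).sum())
        ss_among = float((counts * (means - grand) ** 2).sum())
        ms_among = ss_among / (s - 1)
        ms_within = ss_within / (big_n - s)
        n0 = (big_n - float((counts**2).sum()) / big_n) / (s - 1)
        v_g = (ms_among - ms_within) / n0
        v_e = ms_within
    elif method == "reml":
        import statsmodels.formula.api as smf

        fit = smf.mixedlm(
            f"{value_col} ~ 1", df, groups=df[strain_col]
        ).fit(reml=True, method="lbfgs")
        v_g = float(fit.cov_re.iloc[0, 0])
        v_e = float(fit.scale)
    else:
        raise ValueError(f"unknown method {method!r}")
    v_g = max(v_g, 0.0)
    total = v_g + v_e
    h2 = v_g / total if total > 0 else 0.0
    return HeritabilityResult(v_g, v_e, h2, s, big_n, method)


def predict_founder_phenotypes(
    peaks: list[QtlPeak],
    grand_mean: float,
    founders: list[str] | None = None,
) -> pd.DataFrame:
    """Predicted founder trait values from QTL effects.

    Each founder's prediction is the grand mean plus the
    variance-explained-weighted average of its per-QTL effects:

        predicted_f = grand_mean + Σ_q w_q · β_{q,f} / Σ_q w_q

    with w_q the percent of strain-mean variance explained by QTL q
    (weights normalized to sum to 1, so scaling all weights by a positive
    constant leaves predictions unchanged).  Peak sets from separate
    scans (e.g. per sex) may simply be pooled in ``peaks``.
    """
    if not peaks:
        raise ValueError("need at least one QTL peak")
    effects = np.array([p.founder_effects for p in peaks], dtype=float)
    weights = np.array([p.var_explained for p in peaks], dtype=float)
    if np.any(weights < 0):
        raise ValueError("variance-explained weights must be non-negative")
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("all variance-explained weights are zero")
    predicted = grand_mean + (weights[:, None] * effects).sum(axis=0) / wsum
    k = effects.shape[1]
    if founders is None:
        founders = [f"A{i + 1}" for i in range(k)]
    return pd.DataFrame({"founder": founders, "predicted": predicted})


def correlate_predicted_actual(
    predicted: np.ndarray | pd.Series,
    measured: np.ndarray | pd.Series,
    group: np.ndarray | pd.Series | None = None,
) -> dict:
    """OLS of measured founder phenotypes on QTL-based predictions.

    Optionally includes a categorical group factor (e.g. mapping panel)
    as an additive covariate.  Returns slope ± SE, intercept, R² (percent),
    the model F statistic with its degrees of freedom, and p-values.
    """
    import statsmodels.api as sm

    x = np.asarray(predicted, dtype=float)
    y = np.asarray(measured, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points for a meaningful regression")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    design = pd.DataFrame({"predicted": x})
    if group is not None:
        design = pd.concat(
            [design, pd.get_dummies(pd.Series(group), drop_first=True, dtype=float)],
            axis=1,
        )
    fit = sm.OLS(y, sm.add_constant(design)).fit()
    return {
        "slope": float(fit.params["predicted"]),
        "slope_se": float(fit.bse["predicted"]),
        "slope_p": float(fit.pvalues["predicted"]),
        "intercept": float(fit.params["const"]),
        "r_squared_pct": float(100.0 * fit.rsquared),
        "f_stat": float(fit.fvalue),
        "f_p": float(fit.f_pvalue),
        "df_model": int(fit.df_model),
        "df_resid": int(fit.df_resid),
        "n": len(x),
    }


def haplotype_group_means(
    haps: FounderHaplotypeMatrix,
    pheno: pd.Series,
    position: float | None = None,
    index: int | None = None,
    min_assignment_prob: float = 0.8,
) -> pd.DataFrame:
    """Mean phenotype of RILs grouped by assigned founder haplotype.

    Each RIL is assigned the founder with the highest probability at the
    position, provided that probability reaches ``min_assignment_prob``;
    otherwise the RIL is excluded.  Founders with no assigned RILs appear
    with ``n = 0`` and a missing mean.
    """
    idx = haps.position_index(position) if index is None else index
    y = pd.Series(pheno).reindex(haps.rils).to_numpy(dtype=float)
    probs = haps.probs[:, idx, :]
    best = probs.argmax(axis=1)
    ok = probs[np.arange(len(best)), best] >= min_assignment_prob
    ok &= ~np.isnan(y)
    rows = []
    for f in range(haps.n_founders):
        sel = ok & (best == f)
        rows.append(
            {
                "founder": haps.founders[f],
                "n": int(sel.sum()),
                "mean": float(np.mean(y[sel])) if sel.any() else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    if out["n"].sum() == 0:
        raise ValueError(
            "no RIL reaches min_assignment_prob; lower the threshold or "
            "use harder haplotype assignments"
        )
    return out
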