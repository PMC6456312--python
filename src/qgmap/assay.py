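"""Enzymatic triglyceride assay: absorbance to concentration.

A coupled-enzyme microplate assay reads each well three times at 540 nm:
a baseline scan, a free-glycerol scan, and a final (triglyceride) scan.
The serum triglyceride concentration of a sample is

    conc = C_std * [FA_sample − IA_sample·F] / [FA_std − IA_blank·F]

where FA is the final absorbance, IA the initial absorbance (free
glycerol scan minus baseline scan), F a kit correction factor
(default 0.8), C_std the glycerol standard concentration (default
2.5 mg/ml), FA_std the mean final absorbance of the standard wells and
IA_blank the initial absorbance of the blank well.  Negative results are
flagged (measurement noise), never silently truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlateReads",
    "triglyceride_concentration",
    "strain_triglyceride_mean",
    "plate_table_concentrations",
]

DEFAULT_CORRECTION_FACTOR = 0.8
DEFAULT_STANDARD_CONCENTRATION = 2.5  # mg/ml


@dataclass
class PlateReads:
    """One assay plate: sample absorbances plus per-plate controls."""

    fa_sample: np.ndarray  # final absorbance per sample well (AU)
    ia_sample: np.ndarray  # free-glycerol minus baseline, per sample (AU)
    fa_std: float  # mean final absorbance of the standard wells (AU)
    ia_blank: float  # initial absorbance of the blank well (AU)
    correction_factor: float = DEFAULT_CORRECTION_FACTOR
    standard_concentration: float = DEFAULT_STANDARD_CONCENTRATION
    sample_ids: np.ndarray | None = None
    strains: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fa_sample = np.atleast_1d(np.asarray(self.fa_sample, dtype=float))
        self.ia_sample = np.atleast_1d(np.asarray(self.ia_sample, dtype=float))
        if self.fa_sample.shape != self.ia_sample.shape:
            raise ValueError("fa_sample and ia_sample shapes differ")

    @property
    def denominator(self) -> float:
        return self.fa_std - self.ia_blank * self.correction_factor


def triglyceride_concentration(
    plate: PlateReads, return_flags: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Per-sample triglyceride concentration (mg/ml).

    Raises if the plate denominator ``FA_std − IA_blank·F`` is not
    positive (invalid controls).  With ``return_flags=True`` also
    returns a boolean mask of negative (noise-dominated) results.
    """
    denom = plate.denominator
    if denom <= 0:
        raise ValueError(
            f"invalid plate: FA_std - IA_blank*F = {denom:.4g} is not positive"
        )
    numer = plate.fa_sample - plate.ia_sample * plate.correction_factor
    conc = plate.standard_concentration * numer / denom
    if return_flags:
        return conc, conc < 0
    return conc


def strain_triglyceride_mean(
    samples: pd.DataFrame,
    strain_col: str = "strain",
    conc_col: str = "concentration",
) -> pd.DataFrame:
    """Unweighted strain means over replicate samples, with counts."""
    grouped = samples.groupby(strain_col)[conc_col]
    out = grouped.agg(mean="mean", n_samples="count").reset_index()
    return out


def plate_table_concentrations(
    table: pd.DataFrame,
    correction_factor: float = DEFAULT_CORRECTION_FACTOR,
    standard_concentration: float = DEFAULT_STANDARD_CONCENTRATION,
) -> pd.DataFrame:
    """Concentrations from a long-format plate table.

    Expected columns: ``plate, well, role, strain, baseline_abs,
    free_glycerol_abs, final_abs`` with role in {sample, standard,
    blank}.  Controls are used per plate only (three standard wells
    averaged, one blank).  Returns one row per sample well with its
    concentration and a negative-result flag.
    """
    required = {
        "plate",
        "well",
        "role",
        "strain",
        "baseline_abs",
        "free_glycerol_abs",
        "final_abs",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    out_rows = []
    for plate_id, grp in table.groupby("plate"):
        std = grp[grp["role"] == "standard"]
        blank = grp[grp["role"] == "blank"]
        if std.empty or blank.empty:
            raise ValueError(f"plate {plate_id!r} lacks standard or blank wells")
        fa_std = float(std["final_abs"].mean())
        ia_blank = float(
            (blank["free_glycerol_abs"] - blank["baseline_abs"]).iloc[0]
        )
        samples = grp[grp["role"] == "sample"]
        plate = PlateReads(
            fa_sample=samples["final_abs"].to_numpy(),
            ia_sample=(
                samples["free_glycerol_abs"] - samples["baseline_abs"]
            ).to_numpy(),
            fa_std=fa_std,
            ia_blank=ia_blank,
            correction_factor=correction_factor,
            standard_concentration=standard_concentration,
        )
        conc, flags = triglyceride_concentration(plate, return_flags=True)
        for (_, row), c, f in zip(samples.iterrows(), conc, flags):
            out_rows.append(
                {
                    "plate": plate_id,
                    "well": row["well"],
                    "strain": row["strain"],
                    "concentration": c,
                    "negative_flag": bool(f),
                }
            )
    return pd.DataFrame(out_rows)
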