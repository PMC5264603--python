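"""Efficiency-corrected relative quantification of locus copy number.

The standard curve gives each primer pair's amplification efficiency
E = 10^(-1/slope) (a perfectly doubling assay has slope -log10(2)^-1 ~
-3.32 and E = 2).  Copy-number ratios relative to a 2-copy calibrator DNA
use the efficiency-corrected (Pfaffl) form

    ratio = E_target^dCt_target / E_ref^dCt_ref,
    dCt = mean Ct(calibrator) - mean Ct(sample),

with the reference locus (an RNaseP-style internal control) cancelling
input-amount differences.  Replicate wells are averaged on the Ct scale
before the ratio (the protocol's convention); averaging on the linear
2^-Ct scale is available behind a flag.  Ratios classify as: < 0.6 loss,
0.8-1.2 (inclusive) two copies, > 1.4 gain; the unstated gaps
[0.6, 0.8) and (1.2, 1.4] are reported as indeterminate rather than
forced into a category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import CopyStateThresholds

LOSS = "loss"
TWO_COPIES = "two_copies"
GAIN = "gain"
INDETERMINATE = "indeterminate"


@dataclass
class QpcrAssay:
    """Replicate Ct values for one sample/assay with calibrator bindings."""

    sample_id: str
    target_ct: np.ndarray
    ref_ct: np.ndarray
    calibrator_target_ct: np.ndarray
    calibrator_ref_ct: np.ndarray
    E_target: float = 2.0
    E_ref: float = 2.0

    def __post_init__(self) -> None:
        for name in ("target_ct", "ref_ct", "calibrator_target_ct", "calibrator_ref_ct"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if arr.size < 1:
                raise ValueError(f"{name}: at least one replicate is required")
            if np.any(arr <= 0):
                raise ValueError(f"{name}: Ct values must be positive")
            setattr(self, name, arr)
        if self.E_target <= 1 or self.E_ref <= 1:
            raise ValueError("amplification efficiencies must exceed 1")


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency from a Ct-vs-log10(input) standard curve.

    E = 10^(-1/slope); a slope of -3.3219 gives E = 2 (perfect doubling).
    Efficiencies outside the plausible 1.6-2.1 band trigger a warning,
    not an error.
    """

    if slope >= 0:
        raise ValueError("a standard-curve slope must be negative")
    e = 10.0 ** (-1.0 / slope)
    if e > 2.1 or e < 1.6:
        warnings.warn(
            f"amplification efficiency {e:.3f} outside the plausible 1.6-2.1 band",
            stacklevel=2,
        )
    return e


def _avg(ct: np.ndarray, scale: str) -> float:
    if scale == "ct":
        return float(np.mean(ct))
    if scale == "linear":
        return float(-np.log2(np.mean(2.0 ** (-ct))))
    raise ValueError(f"unknown averaging scale {scale!r}")


def pfaffl_ratio(assay: QpcrAssay, averaging: str = "ct") -> float:
    """Efficiency-corrected copy-number ratio of a sample vs the calibrator."""
    d_t = _avg(assay.calibrator_target_ct, averaging) - _avg(assay.target_ct, averaging)
    d_r = _avg(assay.calibrator_ref_ct, averaging) - _avg(assay.ref_ct, averaging)
    return assay.E_target**d_t / assay.E_ref**d_r


def classify_copy(ratio: float, t: CopyStateThresholds | None = None) -> str:
    """Categorical copy state from a calibrator-relative ratio."""
    if t is None:
        t = CopyStateThresholds()
    if ratio < 0:
        raise ValueError("a copy-number ratio cannot be negative")
    if ratio < t.loss_below:
        return LOSS
    if t.two_copy_low <= ratio <= t.two_copy_high:
        return TWO_COPIES
    if ratio > t.gain_above:
        return GAIN
    return INDETERMINATE


def analyse_plate(plate, thresholds: CopyStateThresholds | None = None) -> pd.DataFrame:
    """Pfaffl ratio and copy-state call for every sample of a plate."""
    rows = []
    for sample in plate.target_ct:
        assay = QpcrAssay(
            sample_id=sample,
            target_ct=plate.target_ct[sample],
            ref_ct=plate.ref_ct[sample],
            calibrator_target_ct=plate.calibrator_target_ct,
            calibrator_ref_ct=plate.calibrator_ref_ct,
            E_target=plate.assay.E_target,
            E_ref=plate.assay.E_ref,
        )
        ratio = pfaffl_ratio(assay)
        rows.append((sample, ratio, classify_copy(ratio, thresholds)))
    return pd.DataFrame(rows, columns=["sample", "ratio", "state"])


def read_plate_table(path, E_target: float = 2.0, E_ref: float = 2.0) -> list[QpcrAssay]:
    """Read a plate TSV (sample, role, is_calibrator, replicate, ct) into
    per-sample assays bound to the plate's calibrator wells."""

    df = pd.read_csv(path, sep="\t")
    required = {"sample", "role", "is_calibrator", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"plate table needs columns {sorted(required)}")
    is_cal = df["is_calibrator"].astype(bool)
    cal = df[is_cal]
    if cal.empty:
        raise ValueError("plate has no calibrator wells")
    cal_t = cal.loc[cal["role"] == "target", "ct"].to_numpy()
    cal_r = cal.loc[cal["role"] == "reference", "ct"].to_numpy()
    assays = []
    for sample, sub in df[~is_cal].groupby("sample", sort=False):
        assays.append(
            QpcrAssay(
                sample_id=str(sample),
                target_ct=sub.loc[sub["role"] == "target", "ct"].to_numpy(),
                ref_ct=sub.loc[sub["role"] == "reference", "ct"].to_numpy(),
                calibrator_target_ct=cal_t,
                calibrator_ref_ct=cal_r,
                E_target=E_target,
                E_ref=E_ref,
            )
        )
    return assays
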