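"""Rigid-body motion summaries and motion regression.

The two summary statistics follow the printed definitions literally:
translations (mm) and rotations (deg) are summed in quadrature without
unit conversion.  An optional degrees-to-mm conversion on a 50 mm sphere
is available but off by default.

* mean displacement:   time-average of the 6-parameter Euclidean norm
* displacement speed:  time-average of the norm of per-TR parameter
  changes
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .parcellation import ParcellatedSeries

MOTION_COLUMNS = ("TraX", "TraY", "TraZ", "RotX", "RotY", "RotZ")

#: radius (mm) used for the optional deg->mm rotation conversion
ROTATION_SPHERE_MM = 50.0


@dataclass
class MotionTrace:
    """T x 6 realignment parameters: TraX/Y/Z in mm, RotX/Y/Z in deg."""

    params: np.ndarray
    tr: float = 1.0

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValidationError("motion trace must be a T x 6 table")
        if self.params.shape[0] < 2:
            raise ValidationError("motion trace needs at least 2 time points")
        if not np.all(np.isfinite(self.params)):
            raise ValidationError("motion trace contains non-finite values")
        if self.tr <= 0:
            raise ValidationError("tr must be positive")

    @property
    def n_timepoints(self) -> int:
        return int(self.params.shape[0])


def _effective_params(trace: MotionTrace, convert_rotations: bool) -> np.ndarray:
    p = trace.params.copy()
    if convert_rotations:
        p[:, 3:] *= ROTATION_SPHERE_MM * math.pi / 180.0
    return p


def mean_displacement(trace: MotionTrace,
                      convert_rotations: bool = False) -> float:
    """Time-average of sqrt(TraX^2 + ... + RotZ^2)."""
    p = _effective_params(trace, convert_rotations)
    return float(np.sqrt((p ** 2).sum(axis=1)).mean())


def displacement_speed(trace: MotionTrace,
                       convert_rotations: bool = False) -> float:
    """Time-average of the norm of successive per-TR parameter changes."""
    p = _effective_params(trace, convert_rotations)
    d = np.diff(p, axis=0)
    return float(np.sqrt((d ** 2).sum(axis=1)).mean())


def regress_motion(series: ParcellatedSeries,
                   trace: MotionTrace) -> ParcellatedSeries:
    """Residualize each region on [intercept + 6 motion parameters].

    Rank-deficient designs (e.g. an all-zero trace) are handled by the
    least-squares pseudo-inverse; residuals are orthogonal to every
    motion column and demeaned.
    """
    if series.n_timepoints != trace.n_timepoints:
        raise ValidationError(
            f"series has {series.n_timepoints} time points but motion trace "
            f"has {trace.n_timepoints}")
    design = np.column_stack(
        [np.ones(trace.n_timepoints), trace.params])
    beta, *_ = np.linalg.lstsq(design, series.data, rcond=None)
    resid = series.data - design @ beta
    return ParcellatedSeries(data=resid, tr=series.tr,
                             run_label=series.run_label)


def qc_report(trace: MotionTrace, max_translation_mm: float = 3.0,
              max_rotation_deg: float = 3.0) -> dict:
    """Exclusion-threshold QC as a report, not a hard failure."""
    max_tra = float(np.abs(trace.params[:, :3]).max())
    max_rot = float(np.abs(trace.params[:, 3:]).max())
    return {
        "mean_displacement": mean_displacement(trace),
        "displacement_speed": displacement_speed(trace),
        "max_translation_mm": max_tra,
        "max_rotation_deg": max_rot,
        "passed": bool(max_tra <= max_translation_mm
                       and max_rot <= max_rotation_deg),
    }


def write_motion(trace: MotionTrace, path) -> None:
    pd.DataFrame(trace.params, columns=list(MOTION_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_motion(path, tr: float = 1.0) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"motion table missing column(s) {missing}")
    return MotionTrace(params=df[list(MOTION_COLUMNS)].to_numpy(dtype=float),
                       tr=tr)
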