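"""Regional coupling between graph strength and PET uptake.

The per-region graph-strength summary is the elementwise maximum over
all neuronal networks; both it and the PET map are z-scored (sample,
n-1 sd) and compared by Pearson correlation with a two-sided p-value
from the t-transform ``t = r * sqrt((n-2)/(1-r^2))`` on n-2 degrees of
freedom.  Skewness is the bias-uncorrected third standardized moment.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .graph import GraphStrengthMap


@dataclass
class CouplingResult:
    r: float
    p: float
    n: int
    gs_skewness: float | None = None
    pet_skewness: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def max_gs_map(strength_maps: Sequence[GraphStrengthMap | np.ndarray]) -> np.ndarray:
    """Elementwise maximum of the given per-region strength vectors."""
    if len(strength_maps) == 0:
        raise ValidationError("need at least one neuronal network")
    arrays = [m.s if isinstance(m, GraphStrengthMap) else
              np.asarray(m, dtype=float).ravel() for m in strength_maps]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValidationError("strength maps must have equal length")
    return np.max(np.vstack(arrays), axis=0)


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize with the sample (n-1) standard deviation."""
    x = np.asarray(x, dtype=float).ravel()
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


def sample_skewness(x: np.ndarray) -> float:
    """Bias-uncorrected third standardized moment."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise ValidationError("skewness needs at least 3 values")
    if x.std() == 0:
        raise ValidationError("skewness of a constant vector is undefined")
    return float(stats.skew(x, bias=True))


def pearson_with_p(x: np.ndarray, y: np.ndarray,
                   skewness: bool = True) -> CouplingResult:
    """Pearson r with a two-sided p from the n-2 dof t-transform."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError("vectors must have equal length")
    n = x.size
    if n < 3:
        raise ValidationError("correlation needs at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("correlation of a constant vector is undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CouplingResult(
        r=r, p=p, n=n,
        gs_skewness=sample_skewness(x) if skewness else None,
        pet_skewness=sample_skewness(y) if skewness else None,
    )


def gs_pet_coupling(strength_maps: Sequence[GraphStrengthMap],
                    pet_values: np.ndarray,
                    global_mean_scale: bool = False) -> CouplingResult:
    """Full chain: max-GS map, optional PET global-mean scaling,
    z-scoring of both vectors, then Pearson with the t-based p."""
    gs = max_gs_map(strength_maps)
    pet = np.asarray(pet_values, dtype=float).ravel()
    if pet.size != gs.size:
        raise ValidationError("PET map length does not match strength maps")
    if global_mean_scale:
        mean = pet.mean()
        if mean == 0:
            raise ValidationError("PET global mean is zero; cannot scale")
        pet = pet / mean
    return pearson_with_p(zscore(gs), zscore(pet))
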