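"""Ratio-of-fit (ROF) variability statistics.

For each network the regions whose graph strength exceeds half of the
network's maximum are selected; ROF compares that selection to the
binary template mask:

    ROF = (selected regions inside the mask
           - selected regions outside the mask) / mask size

so ROF = 1 means the selection reproduces the mask exactly and negative
values indicate spill-over outside the network.  Test-retest variability
is summarized by delta-ROF (first minus second acquisition, with a
missing acquisition contributing 0) and by the mean absolute delta-ROF
over the nine networks.  Both conventions (missing -> 0 and the fixed
nine-network denominator) are reverse-engineered from the reference
table and documented as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import ValidationError
from .graph import GraphStrengthMap

HALF_MAX_FACTOR = 0.5
N_NETWORKS = 9


@dataclass
class RofRecord:
    """Selection counts and ROF for one network in one acquisition."""

    network: str
    acquisition: str
    in_count: int
    out_count: int
    missing_count: int
    mask_size: int
    rof: float
    neuronal: bool = True

    def __post_init__(self) -> None:
        if self.in_count + self.missing_count != self.mask_size:
            raise ValidationError(
                "in_count + missing_count must equal mask_size")


@dataclass
class VariabilityReport:
    """Per-network delta-ROF plus the patient-level summary."""

    delta_rof: dict[str, float]
    mean_abs_delta_rof: float
    best_acquisition: dict[str, str | None]


def select_regions(gs: GraphStrengthMap,
                   region_ids: np.ndarray | None = None) -> set[int]:
    """Regions with strength strictly above half the network maximum.

    Returns region ids when ``region_ids`` is given, else 0-based
    indices.  An all-zero map selects nothing (with a warning).
    """
    s = gs.s
    smax = s.max() if s.size else 0.0
    if smax <= 0:
        warnings.warn(f"all-zero strength map for network {gs.network!r}",
                      stacklevel=2)
        return set()
    idx = np.flatnonzero(s > HALF_MAX_FACTOR * smax)
    if region_ids is None:
        return set(int(i) for i in idx)
    region_ids = np.asarray(region_ids)
    return set(int(region_ids[i]) for i in idx)


def rof(selected: Iterable[int], mask: Iterable[int], network: str = "",
        acquisition: str = "", neuronal: bool = True) -> RofRecord:
    """Count in/out/missing regions and form the ratio of fit."""
    mask = set(mask)
    if not mask:
        raise ValidationError("mask must be nonempty")
    selected = set(selected)
    in_count = len(selected & mask)
    out_count = len(selected - mask)
    missing = len(mask - selected)
    return RofRecord(
        network=network,
        acquisition=acquisition,
        in_count=in_count,
        out_count=out_count,
        missing_count=missing,
        mask_size=len(mask),
        rof=(in_count - out_count) / len(mask),
        neuronal=neuronal,
    )


def delta_rof(rof_t1: float | None, rof_t2: float | None) -> float:
    """First-minus-second ROF; a missing acquisition contributes 0."""
    a = 0.0 if rof_t1 is None else float(rof_t1)
    b = 0.0 if rof_t2 is None else float(rof_t2)
    return a - b


def mean_abs_delta_rof(deltas: Mapping[str, float] | Iterable[float],
                       n_networks: int = N_NETWORKS) -> float:
    """Mean |delta-ROF| over the fixed network denominator.

    Networks absent from ``deltas`` contribute 0 (doubly-missing case).
    """
    values = (list(deltas.values()) if isinstance(deltas, Mapping)
              else list(deltas))
    if len(values) > n_networks:
        raise ValidationError(
            f"got {len(values)} networks but denominator is {n_networks}")
    return float(np.sum(np.abs(values)) / n_networks)


def best_acquisition(rof_t1: float | None, rof_t2: float | None,
                     neuronal_t1: bool = True,
                     neuronal_t2: bool = True) -> str | None:
    """Label of the neuronal acquisition with the higher ROF.

    Missing (None) acquisitions count as non-neuronal.  Ties go to the
    first acquisition; if neither qualifies, returns None.
    """
    ok1 = neuronal_t1 and rof_t1 is not None
    ok2 = neuronal_t2 and rof_t2 is not None
    if ok1 and ok2:
        return "T1" if rof_t1 >= rof_t2 else "T2"
    if ok1:
        return "T1"
    if ok2:
        return "T2"
    return None


def percent_neuronal(flags: Iterable[bool],
                     expected: int = 2 * N_NETWORKS) -> int:
    """Percentage of neuronal network-instances, rounded to integer.

    The denominator is the full 2-acquisition x 9-network grid.
    """
    flags = list(flags)
    if len(flags) != expected:
        raise ValidationError(
            f"expected {expected} network-instances, got {len(flags)}")
    return round(100.0 * sum(bool(f) for f in flags) / expected)


def variability_report(
    records_t1: Mapping[str, RofRecord | None],
    records_t2: Mapping[str, RofRecord | None],
    networks: Iterable[str],
) -> VariabilityReport:
    """Assemble delta-ROF, mean |delta-ROF| and best-acquisition choices.

    A record that exists but is flagged non-neuronal is treated as
    missing, matching the convention that only neuronal acquisitions
    carry a reportable ROF.
    """
    networks = list(networks)
    deltas: dict[str, float] = {}
    best: dict[str, str | None] = {}
    for net in networks:
        r1, r2 = records_t1.get(net), records_t2.get(net)
        v1 = r1.rof if (r1 is not None and r1.neuronal) else None
        v2 = r2.rof if (r2 is not None and r2.neuronal) else None
        deltas[net] = delta_rof(v1, v2)
        best[net] = best_acquisition(v1, v2,
                                     neuronal_t1=v1 is not None,
                                     neuronal_t2=v2 is not None)
    return VariabilityReport(
        delta_rof=deltas,
        mean_abs_delta_rof=mean_abs_delta_rof(deltas),
        best_acquisition=best,
    )
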