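"""End-to-end analysis: motion regression -> ICA -> classification ->
network assignment -> graph strength -> ROF variability -> PET coupling.

The entry point is :func:`analyze_patient`, which consumes two
parcellated runs (plus optional motion traces and a PET map) and
produces per-acquisition ROF records, the test-retest variability
report, and metabolic-coupling results for the best-acquisition and
concatenated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ica, rof
from .coupling import CouplingResult, gs_pet_coupling
from .errors import ValidationError
from .graph import GraphStrengthMap, network_strength_map
from .motion import MotionTrace, qc_report, regress_motion
from .parcellation import ParcellatedSeries, PetRoiMap, RoiAtlas, \
    concatenate_runs


@dataclass
class AcquisitionResult:
    """One acquisition's components, assignment and per-network ROF."""

    label: str
    assignment: ica.NetworkAssignment
    rof_records: dict[str, rof.RofRecord]
    strength_maps: dict[str, GraphStrengthMap]
    qc: dict | None = None


@dataclass
class AnalysisResult:
    acquisitions: dict[str, AcquisitionResult]
    variability: rof.VariabilityReport
    percent_neuronal: int
    coupling_best: CouplingResult | None = None
    coupling_concat: CouplingResult | None = None
    seeds: dict[str, int] = field(default_factory=dict)


def analyze_acquisition(series: ParcellatedSeries, atlas: RoiAtlas,
                        k: int = ica.DEFAULT_K, seed: int = 0,
                        motion: MotionTrace | None = None,
                        label: str | None = None) -> AcquisitionResult:
    """Single-acquisition chain: regression, ICA, assignment, ROF."""
    label = label or series.run_label
    qc = None
    if motion is not None:
        qc = qc_report(motion)
        series = regress_motion(series, motion)
    components = ica.decompose(series, k=k, seed=seed)
    flags = [ica.classify_neuronal(fp)[0]
             for fp in ica.fingerprints(components)]
    assignment = ica.assign_networks(components, atlas, neuronal_flags=flags)

    records: dict[str, rof.RofRecord] = {}
    strengths: dict[str, GraphStrengthMap] = {}
    for net, (comp, _gof, neuronal) in assignment.assigned.items():
        gs = network_strength_map(components.zmaps[comp], network=net,
                                  acquisition=label)
        strengths[net] = gs
        selected = rof.select_regions(gs, region_ids=atlas.region_ids)
        records[net] = rof.rof(selected, atlas.rsn_templates[net],
                               network=net, acquisition=label,
                               neuronal=neuronal)
    return AcquisitionResult(label=label, assignment=assignment,
                             rof_records=records, strength_maps=strengths,
                             qc=qc)


def _neuronal_strengths(acq: AcquisitionResult) -> dict[str, GraphStrengthMap]:
    return {net: gs for net, gs in acq.strength_maps.items()
            if acq.assignment.is_neuronal(net)}


def analyze_patient(run_t1: ParcellatedSeries, run_t2: ParcellatedSeries,
                    atlas: RoiAtlas, k: int = ica.DEFAULT_K, seed: int = 0,
                    motion_t1: MotionTrace | None = None,
                    motion_t2: MotionTrace | None = None,
                    pet: PetRoiMap | None = None) -> AnalysisResult:
    """Two-acquisition test-retest analysis of one patient.

    ICA seeds for the T1/T2/concatenated decompositions are derived
    deterministically from ``seed``.
    """
    seeds = {"T1": seed, "T2": seed + 1, "concat": seed + 2}
    run_t1.run_label, run_t2.run_label = "T1", "T2"
    acq1 = analyze_acquisition(run_t1, atlas, k=k, seed=seeds["T1"],
                               motion=motion_t1, label="T1")
    acq2 = analyze_acquisition(run_t2, atlas, k=k, seed=seeds["T2"],
                               motion=motion_t2, label="T2")
    concat = concatenate_runs(
        regress_motion(run_t1, motion_t1) if motion_t1 else run_t1,
        regress_motion(run_t2, motion_t2) if motion_t2 else run_t2)
    acq_c = analyze_acquisition(concat, atlas, k=k, seed=seeds["concat"],
                                label="concat")

    networks = list(atlas.rsn_templates)
    variability = rof.variability_report(acq1.rof_records, acq2.rof_records,
                                         networks)
    flags = []
    for acq in (acq1, acq2):
        flags += [acq.assignment.is_neuronal(net) for net in networks]
    pct = rof.percent_neuronal(flags, expected=2 * len(networks))

    coupling_best = coupling_concat = None
    if pet is not None:
        best_maps = []
        for net in networks:
            choice = variability.best_acquisition.get(net)
            if choice == "T1":
                best_maps.append(acq1.strength_maps[net])
            elif choice == "T2":
                best_maps.append(acq2.strength_maps[net])
        if best_maps:
            coupling_best = gs_pet_coupling(best_maps, pet.values)
        concat_maps = list(_neuronal_strengths(acq_c).values())
        if concat_maps:
            coupling_concat = gs_pet_coupling(concat_maps, pet.values)

    return AnalysisResult(
        acquisitions={"T1": acq1, "T2": acq2, "concat": acq_c},
        variability=variability,
        percent_neuronal=pct,
        coupling_best=coupling_best,
        coupling_concat=coupling_concat,
        seeds=seeds,
    )


def rof_table(result: AnalysisResult, networks: list[str]) -> list[dict]:
    """Table-1-style rows: per-network In/Out/ROF per acquisition plus
    delta-ROF.  Non-neuronal acquisitions leave their cells blank."""
    rows = []
    acq1 = result.acquisitions["T1"]
    acq2 = result.acquisitions["T2"]
    for net in networks:
        row: dict = {"network": net}
        for tag, acq in (("t1", acq1), ("t2", acq2)):
            rec = acq.rof_records.get(net)
            if rec is not None and rec.neuronal:
                row[f"in_{tag}"] = rec.in_count
                row[f"out_{tag}"] = rec.out_count
                row[f"rof_{tag}"] = round(rec.rof, 2)
            else:
                row[f"in_{tag}"] = row[f"out_{tag}"] = row[f"rof_{tag}"] = None
        row["delta_rof"] = round(result.variability.delta_rof[net], 2)
        rows.append(row)
    return rows
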