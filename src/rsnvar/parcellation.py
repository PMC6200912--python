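"""Parcellation-level I/O: atlases, region time series, PET ROI maps.

All voxel-level inputs (NIfTI label images, 4D BOLD, 3D PET) are reduced
to region-level tables as early as possible; everything downstream works
on T x N matrices and length-N vectors.  Reduction is the unweighted mean
over the voxels of each labeled region.  Label image and functional
images must share a grid -- no resampling is performed here.

Text formats
------------
* series TSV: one row per time point, one column per region, header row
  of region ids.
* label table TSV: columns ``region_id``, ``name``.
* template table TSV: columns ``network``, ``region_id`` (one row per
  membership).
* PET TSV: columns ``region_id``, ``uptake``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ValidationError

#: Canonical order of the nine resting-state network templates.
RSN_NAMES = (
    "auditory",
    "DMN",
    "ECNL",
    "ECNR",
    "salience",
    "sensorimotor",
    "VL",
    "VM",
    "VO",
)


@dataclass
class RoiAtlas:
    """A parcellation: ordered region ids, names, and network templates.

    Parameters
    ----------
    region_ids:
        Unique positive integer labels, ascending.
    region_names:
        Mapping id -> human-readable name.
    rsn_templates:
        Mapping network name -> set of member region ids (binary masks).
    label_image, affine:
        Optional 3D integer label volume and its affine, used to reduce
        voxel images to regions.
    """

    region_ids: np.ndarray
    region_names: dict[int, str] = field(default_factory=dict)
    rsn_templates: dict[str, frozenset[int]] = field(default_factory=dict)
    label_image: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.region_ids.size < 2:
            raise ValidationError("atlas needs at least 2 regions")
        if np.any(self.region_ids <= 0):
            raise ValidationError("region ids must be positive integers")
        if len(np.unique(self.region_ids)) != self.region_ids.size:
            raise ValidationError("region ids must be unique")
        self.region_ids = np.sort(self.region_ids)
        id_set = set(self.region_ids.tolist())
        for net, members in self.rsn_templates.items():
            bad = set(members) - id_set
            if bad:
                raise ValidationError(
                    f"template {net!r} references unknown region id(s) "
                    f"{sorted(bad)}"
                )
            self.rsn_templates[net] = frozenset(int(i) for i in members)

    @property
    def n_regions(self) -> int:
        return int(self.region_ids.size)

    def index_of(self, region_id: int) -> int:
        """Column index of a region id in series/vector order."""
        idx = np.searchsorted(self.region_ids, region_id)
        if idx >= self.region_ids.size or self.region_ids[idx] != region_id:
            raise ValidationError(f"unknown region id {region_id}")
        return int(idx)

    def member_indices(self, network: str) -> np.ndarray:
        """Sorted column indices of a template's member regions."""
        members = self.rsn_templates[network]
        return np.array(sorted(self.index_of(i) for i in members), dtype=int)


@dataclass
class ParcellatedSeries:
    """T x N region time series with its repetition time and run label."""

    data: np.ndarray
    tr: float
    run_label: str = "run"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("series must be a 2D (T x N) matrix")
        if self.data.shape[0] < 2:
            raise ValidationError("series needs at least 2 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("series contains non-finite values")
        if self.tr <= 0:
            raise ValidationError("tr must be positive")

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_regions(self) -> int:
        return int(self.data.shape[1])


@dataclass
class PetRoiMap:
    """Per-region PET uptake values (length N, atlas order)."""

    values: np.ndarray
    zscored: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("PET map contains non-finite values")
        if self.zscored:
            if abs(self.values.mean()) > 1e-6 or abs(self.values.std(ddof=1) - 1) > 1e-6:
                raise ValidationError("zscored flag set but values are not z-scored")


# ---------------------------------------------------------------------------
# Atlas I/O


def write_atlas(atlas: RoiAtlas, label_image_path, label_table_path,
                template_table_path) -> None:
    """Write an atlas as NIfTI label image + label/template TSV tables."""
    if atlas.label_image is not None:
        affine = atlas.affine if atlas.affine is not None else np.eye(4)
        img = nib.Nifti1Image(atlas.label_image.astype(np.int32), affine)
        nib.save(img, str(label_image_path))
    labels = pd.DataFrame({
        "region_id": atlas.region_ids,
        "name": [atlas.region_names.get(int(i), f"region_{i}")
                 for i in atlas.region_ids],
    })
    labels.to_csv(label_table_path, sep="\t", index=False)
    rows = [
        {"network": net, "region_id": rid}
        for net in atlas.rsn_templates
        for rid in sorted(atlas.rsn_templates[net])
    ]
    pd.DataFrame(rows, columns=["network", "region_id"]).to_csv(
        template_table_path, sep="\t", index=False)


def read_atlas(label_image_path, label_table_path,
               template_table_path) -> RoiAtlas:
    """Read an atlas from its NIfTI label image and TSV tables.

    ``label_image_path`` may be None for a purely tabular atlas.
    """
    labels = pd.read_csv(label_table_path, sep="\t")
    for col in ("region_id", "name"):
        if col not in labels.columns:
            raise ValidationError(f"label table missing column {col!r}")
    ids = labels["region_id"].to_numpy(dtype=int)
    if len(np.unique(ids)) != len(ids):
        dup = labels["region_id"][labels["region_id"].duplicated()].iloc[0]
        raise ValidationError(f"label table has duplicate region id {dup}")
    names = dict(zip(ids.tolist(), labels["name"].astype(str)))

    tmpl = pd.read_csv(template_table_path, sep="\t")
    for col in ("network", "region_id"):
        if col not in tmpl.columns:
            raise ValidationError(f"template table missing column {col!r}")
    id_set = set(ids.tolist())
    templates: dict[str, set[int]] = {}
    for net, rid in zip(tmpl["network"], tmpl["region_id"].astype(int)):
        if rid not in id_set:
            raise ValidationError(
                f"template {net!r} references region id {rid} absent from "
                "the label table")
        templates.setdefault(str(net), set()).add(rid)

    label_image = affine = None
    if label_image_path is not None and Path(label_image_path).exists():
        img = nib.load(str(label_image_path))
        label_image = np.asarray(img.dataobj).astype(int)
        affine = img.affine
    return RoiAtlas(
        region_ids=ids,
        region_names=names,
        rsn_templates={k: frozenset(v) for k, v in templates.items()},
        label_image=label_image,
        affine=affine,
    )


# ---------------------------------------------------------------------------
# Voxel -> region reduction


def _label_means(volume: np.ndarray, label_image: np.ndarray,
                 region_ids: np.ndarray) -> np.ndarray:
    """Mean of ``volume`` over the voxels of each labeled region."""
    flat_labels = label_image.ravel()
    flat = volume.ravel()
    idx = np.searchsorted(region_ids, flat_labels)
    idx_clipped = np.minimum(idx, region_ids.size - 1)
    valid = region_ids[idx_clipped] == flat_labels
    counts = np.bincount(idx_clipped[valid], minlength=region_ids.size)
    if np.any(counts == 0):
        missing = region_ids[counts == 0]
        raise ValidationError(
            f"label image has no voxels for region id(s) {missing.tolist()}")
    sums = np.bincount(idx_clipped[valid], weights=flat[valid],
                       minlength=region_ids.size)
    return sums / counts


def extract_series(bold_img, atlas: RoiAtlas) -> ParcellatedSeries:
    """Reduce a 4D BOLD image to a T x N region-mean series.

    ``bold_img`` is a nibabel image or (data, tr) tuple; TR is taken from
    the image header zooms when available.
    """
    if atlas.label_image is None:
        raise ValidationError("atlas has no label image for extraction")
    if isinstance(bold_img, tuple):
        data, tr = np.asarray(bold_img[0], dtype=float), float(bold_img[1])
    else:
        data = np.asarray(bold_img.dataobj).astype(float)
        zooms = bold_img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if data.ndim != 4:
        raise ValidationError("BOLD image must be 4D")
    if data.shape[:3] != atlas.label_image.shape:
        raise ValidationError(
            f"BOLD grid {data.shape[:3]} does not match label image grid "
            f"{atlas.label_image.shape}")
    T = data.shape[3]
    out = np.empty((T, atlas.n_regions))
    for t in range(T):
        out[t] = _label_means(data[..., t], atlas.label_image,
                              atlas.region_ids)
    return ParcellatedSeries(data=out, tr=tr, run_label="extracted")


def pet_roi_means(pet_img, atlas: RoiAtlas) -> PetRoiMap:
    """Reduce a 3D PET image to per-region mean uptake."""
    if atlas.label_image is None:
        raise ValidationError("atlas has no label image for extraction")
    data = (np.asarray(pet_img.dataobj).astype(float)
            if not isinstance(pet_img, np.ndarray)
            else np.asarray(pet_img, dtype=float))
    if data.ndim != 3:
        raise ValidationError("PET image must be 3D")
    if data.shape != atlas.label_image.shape:
        raise ValidationError(
            f"PET grid {data.shape} does not match label image grid "
            f"{atlas.label_image.shape}")
    return PetRoiMap(values=_label_means(data, atlas.label_image,
                                         atlas.region_ids))


# ---------------------------------------------------------------------------
# Run concatenation


def concatenate_runs(run1: ParcellatedSeries, run2: ParcellatedSeries,
                     standardize: bool = True) -> ParcellatedSeries:
    """Join two runs along time, optionally standardizing each run first.

    Standardization demeans each region and scales it to unit variance
    within each run before joining, removing inter-run offset/scale.
    """
    if run1.n_regions != run2.n_regions:
        raise ValidationError(
            f"region count mismatch: {run1.n_regions} vs {run2.n_regions}")
    if abs(run1.tr - run2.tr) > 1e-12:
        raise ValidationError(f"tr mismatch: {run1.tr} vs {run2.tr}")

    def _std(x: np.ndarray) -> np.ndarray:
        x = x - x.mean(axis=0, keepdims=True)
        sd = x.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        return x / sd

    parts = ((_std(run1.data), _std(run2.data)) if standardize
             else (run1.data, run2.data))
    return ParcellatedSeries(data=np.vstack(parts), tr=run1.tr,
                             run_label="concat")


# ---------------------------------------------------------------------------
# Tabular I/O


def write_series(series: ParcellatedSeries, atlas: RoiAtlas, path) -> None:
    df = pd.DataFrame(series.data, columns=[str(i) for i in atlas.region_ids])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_series(path, tr: float, run_label: str = "run") -> ParcellatedSeries:
    df = pd.read_csv(path, sep="\t")
    if df.isna().any().any():
        raise ValidationError(f"series table {path} contains missing values")
    return ParcellatedSeries(data=df.to_numpy(dtype=float), tr=tr,
                             run_label=run_label)


def write_pet_map(pet: PetRoiMap, atlas: RoiAtlas, path) -> None:
    pd.DataFrame({"region_id": atlas.region_ids,
                  "uptake": pet.values}).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_pet_map(path, atlas: RoiAtlas | None = None) -> PetRoiMap:
    df = pd.read_csv(path, sep="\t")
    for col in ("region_id", "uptake"):
        if col not in df.columns:
            raise ValidationError(f"PET table missing column {col!r}")
    df = df.sort_values("region_id")
    if atlas is not None and not np.array_equal(
            df["region_id"].to_numpy(dtype=int), atlas.region_ids):
        raise ValidationError("PET table region ids do not match the atlas")
    return PetRoiMap(values=df["uptake"].to_numpy(dtype=float))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
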