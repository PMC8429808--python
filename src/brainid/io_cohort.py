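"""Scan/atlas/cohort I/O, volume cropping, ROI pooling and stratified splits.

Scans are 4D NIfTI-1 images (X, Y, Z, T); the atlas is a 3D integer-labeled
parcellation on the same grid (0 = background, 1..R = ROI ids); the cohort
table is a CSV with header ``subject_id,group,age,sex``. Volumes are used in
their stored voxel order — the input is assumed already preprocessed and
co-registered with the atlas, so no resampling or reorientation happens here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume4D",
    "AtlasVolume",
    "RoiTimeSeries",
    "SplitSpec",
    "load_scan",
    "save_scan",
    "load_atlas",
    "crop_volume",
    "pool_rois",
    "load_subject_table",
    "save_subject_table",
    "stratified_split",
]

GROUPS = ("patient", "control")
SEXES = ("m", "f")
SPLITS = ("train1", "train2", "test")


@dataclass
class Volume4D:
    """A single subject's 4D scan: (X, Y, Z, T) voxel grid plus metadata.

    ``crop_window``, when present, records the spatial window (per-axis
    (start, stop) pairs) this volume occupies inside its parent grid.
    """

    data: np.ndarray
    voxel_size_mm: np.ndarray
    subject_id: str
    crop_window: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D requires 4 dims, got {self.data.ndim}")
        if any(d < 1 for d in self.data.shape):
            raise ValueError(f"all dims must be >= 1, got shape {self.data.shape}")
        n_bad = int(np.count_nonzero(~np.isfinite(self.data)))
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel values")
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float).reshape(3)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class AtlasVolume:
    """Integer-labeled ROI parcellation; 0 is background, 1..R are ROIs."""

    labels: np.ndarray
    roi_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"atlas must be 3D, got {self.labels.ndim} dims")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integer-valued")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        if not self.roi_names:
            self.roi_names = [f"roi{r}" for r in range(1, int(self.labels.max()) + 1)]

    @property
    def n_rois(self) -> int:
        return int(self.labels.max())


@dataclass
class RoiTimeSeries:
    """T × R matrix of ROI-pooled signals; ``roi_ids`` maps columns to labels."""

    values: np.ndarray
    roi_ids: np.ndarray
    subject_id: str

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class SplitSpec:
    """Partition of a cohort into train1 / train2 / test."""

    assignment: dict[str, str]
    seed: int

    def subjects(self, split: str) -> list[str]:
        return sorted(s for s, sp in self.assignment.items() if sp == split)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["subject_id", "split"]
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "SplitSpec":
        df = pd.read_csv(path, dtype=str)
        return cls(dict(zip(df["subject_id"], df["split"])), seed=seed)


def load_scan(path: str | Path) -> Volume4D:
    """Load a 4D NIfTI scan, rejecting non-4D and non-finite data."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path.name}: not a 4D scan (found {img.ndim} dims)")
    data = np.asanyarray(img.dataobj)
    voxel = np.asarray(img.header.get_zooms()[:3], dtype=float)
    subject_id = path.name.removesuffix(".gz").removesuffix(".nii")
    return Volume4D(data=data, voxel_size_mm=voxel, subject_id=subject_id)


def save_scan(vol: Volume4D, path: str | Path) -> None:
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    img.header.set_zooms(tuple(vol.voxel_size_mm) + (1.0,))
    nib.save(img, str(path))


def load_atlas(path: str | Path, roi_names: Sequence[str] | None = None) -> AtlasVolume:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"atlas must be 3D, got {img.ndim} dims")
    labels = np.rint(np.asanyarray(img.dataobj)).astype(np.int32)
    return AtlasVolume(labels=labels, roi_names=list(roi_names or []))


def save_atlas(atlas: AtlasVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), np.eye(4))
    nib.save(img, str(path))


def crop_volume(
    vol: Volume4D,
    target_shape: Sequence[int],
    mode: str = "center",
    offset: Sequence[int] | None = None,
) -> Volume4D:
    """Crop the spatial dims to ``target_shape``, leaving the time axis alone.

    ``mode='center'`` centers the window (ties resolved toward the origin);
    ``mode='offset'`` places the window at an explicit per-axis start. The
    window used is recorded in ``crop_window`` for provenance.
    """
    target = tuple(int(t) for t in target_shape)
    if len(target) != 3:
        raise ValueError("target_shape must have 3 entries")
    shape = vol.spatial_shape
    for ax, (t, s) in enumerate(zip(target, shape)):
        if t > s:
            raise ValueError(
                f"target shape {target} exceeds volume shape {shape} on axis {ax}"
            )
        if t < 1:
            raise ValueError("target dims must be >= 1")
    if mode == "center":
        starts = tuple((s - t) // 2 for s, t in zip(shape, target))
    elif mode == "offset":
        if offset is None:
            raise ValueError("mode='offset' requires an offset")
        starts = tuple(int(o) for o in offset)
        for ax, (o, t, s) in enumerate(zip(starts, target, shape)):
            if o < 0 or o + t > s:
                raise ValueError(f"offset window out of bounds on axis {ax}")
    else:
        raise ValueError(f"unknown crop mode {mode!r}")
    window = tuple((o, o + t) for o, t in zip(starts, target))
    sl = tuple(slice(a, b) for a, b in window)
    return Volume4D(
        data=vol.data[sl + (slice(None),)].copy(),
        voxel_size_mm=vol.voxel_size_mm,
        subject_id=vol.subject_id,
        crop_window=window,
    )


def pool_rois(vol: Volume4D, atlas: AtlasVolume) -> RoiTimeSeries:
    """Average the signal over each atlas ROI, giving a T × R time series.

    ROIs with no voxels on this grid are excluded with a warning so that
    downstream correlation matrices never see constant all-zero columns.
    """
    if atlas.labels.shape != vol.spatial_shape:
        raise ValueError(
            f"atlas shape {atlas.labels.shape} != scan grid {vol.spatial_shape}"
        )
    n_rois = atlas.n_rois
    if n_rois == 0:
        raise ValueError("no ROIs: atlas is all background")
    flat_labels = atlas.labels.reshape(-1)
    flat = vol.data.reshape(-1, vol.n_timepoints)
    counts = np.bincount(flat_labels, minlength=n_rois + 1)[1:]
    present = np.flatnonzero(counts > 0) + 1
    if len(present) < n_rois:
        missing = sorted(set(range(1, n_rois + 1)) - set(present.tolist()))
        warnings.warn(
            f"excluding {len(missing)} empty ROI(s): {missing}", stacklevel=2
        )
    if len(present) == 0:
        raise ValueError("no ROIs: every ROI is empty on this grid")
    # sum voxel signals per label with one bincount per timepoint
    sums = np.empty((vol.n_timepoints, len(present)))
    for t in range(vol.n_timepoints):
        all_sums = np.bincount(flat_labels, weights=flat[:, t], minlength=n_rois + 1)
        sums[t] = all_sums[present]
    values = sums / counts[present - 1]
    return RoiTimeSeries(values=values, roi_ids=present, subject_id=vol.subject_id)


def load_subject_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    return validate_subject_table(df)


def save_subject_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_subject_table(table).to_csv(path, index=False)


def validate_subject_table(table: pd.DataFrame) -> pd.DataFrame:
    required = ["subject_id", "group", "age", "sex"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"subject table missing columns: {missing}")
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dup}")
    if not set(table["group"]).issubset(GROUPS):
        raise ValueError(f"group values must be in {GROUPS}")
    if not set(table["sex"]).issubset(SEXES):
        raise ValueError(f"sex values must be in {SEXES}")
    if (table["age"] <= 0).any():
        raise ValueError("ages must be positive")
    return table[required].copy()


def stratified_split(
    table: pd.DataFrame,
    counts: Mapping[str, tuple[int, int]],
    strata: Sequence[str] = ("group", "sex", "age"),
    seed: int = 0,
) -> SplitSpec:
    """Assign subjects to splits with exact per-group counts, balancing strata.

    ``counts`` maps split name to ``(n_patients, n_controls)`` and must sum
    to the table's group sizes. Within each (group × sex × age-tertile) cell
    subjects are dealt across splits proportionally to the splits' remaining
    quota, walking cells in a canonical order with a seeded shuffle inside
    each cell, so age and sex are balanced in expectation while the per-group
    counts come out exact. Deterministic given the seed and invariant to the
    input row order (rows are first sorted canonically by subject_id).
    """
    table = validate_subject_table(table)
    split_names = list(counts)
    for name in split_names:
        if len(counts[name]) != 2:
            raise ValueError("each count entry must be (n_patients, n_controls)")
    group_sizes = table["group"].value_counts()
    for gi, group in enumerate(GROUPS):
        want = sum(int(counts[s][gi]) for s in split_names)
        have = int(group_sizes.get(group, 0))
        if want != have:
            raise ValueError(
                f"counts for {group} sum to {want} but table has {have}"
            )
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for gi, group in enumerate(GROUPS):
        sub = table[table["group"] == group].sort_values("subject_id")
        if len(sub) == 0:
            continue
        remaining = {s: int(counts[s][gi]) for s in split_names}
        # age tertiles within the group; degenerate ages collapse cells
        ages = sub["age"].to_numpy(dtype=float)
        terts = np.quantile(ages, [1 / 3, 2 / 3])
        tert_idx = np.searchsorted(terts, ages, side="right")
        cells: dict[tuple[str, int], list[str]] = {}
        for sid, sex, t in zip(sub["subject_id"], sub["sex"], tert_idx):
            cells.setdefault((sex, int(t)), []).append(sid)
        for key in sorted(cells):
            members = cells[key]
            rng.shuffle(members)
            for sid in members:
                total = sum(remaining.values())
                probs = np.array([remaining[s] / total for s in split_names])
                choice = split_names[rng.choice(len(split_names), p=probs)]
                assignment[sid] = choice
                remaining[choice] -= 1
    for name in split_names:
        if not any(v == name for v in assignment.values()):
            raise ValueError(f"split {name!r} is empty")
    return SplitSpec(assignment=assignment, seed=seed)
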