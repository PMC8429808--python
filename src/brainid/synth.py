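"""Synthetic multi-subject rs-fMRI cohorts with known identity/group/age structure.

Each simulated voxel value is

    v(x, t) = B(x) + a_sig * S_i(x) + a_grp * G(x) * 1[patient_i]
            + a_age * A(x) * z(age_i) + eps(x, t)

where ``B`` is a smooth ellipsoidal "brain" baseline, ``S_i`` is a per-subject
smoothed Gaussian random field that is *constant over time* (keyed by subject
id and the cohort seed, so two scans of the same subject share it), ``G`` and
``A`` are fixed smooth group/age effect maps, ``z`` the cohort-standardized
age, and ``eps`` i.i.d. Gaussian temporal noise. A persistent spatial
signature plus i.i.d. noise is exactly the structure that makes a *single*
timepoint sufficient to identify the subject, which is the premise the
encoder's pretext task relies on. Fields are Gaussian-smoothed so signatures
are spatially structured rather than white. No hemodynamics, physiological
noise, scanner drift or realistic connectivity is modeled.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_cohort import AtlasVolume, Volume4D, save_atlas, save_scan, save_subject_table

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "make_cohort",
    "simulate_scan",
    "simulate_dataset",
    "make_block_atlas",
    "write_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic scan generator.

    signature_amplitude / noise_sd is the identifiability knob: at 0 a
    nearest-mean classifier on raw volumes is at chance, and for large
    ratios it approaches perfect single-timepoint identification.
    """

    grid_shape: tuple[int, int, int] = (24, 28, 24)
    n_timepoints: int = 40
    signature_amplitude: float = 5.0
    group_amplitude: float = 0.0
    age_amplitude: float = 0.0
    noise_sd: float = 1.0
    smoothing_sigma_vox: float = 1.5
    baseline_amplitude: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(d < 1 for d in self.grid_shape):
            raise ValueError(f"bad grid shape {self.grid_shape}")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        for name in ("signature_amplitude", "group_amplitude", "age_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class SimulatedDataset:
    """Scans plus the ground-truth maps the generator used (for assertions)."""

    scans: list[Volume4D]
    cohort: pd.DataFrame
    signatures: dict[str, np.ndarray]
    group_map: np.ndarray
    age_map: np.ndarray
    brain_mask: np.ndarray
    cfg: SimConfig

    def __iter__(self) -> Iterator[Volume4D]:
        return iter(self.scans)


def make_cohort(
    n_patients: int,
    n_controls: int,
    age_range: tuple[float, float] = (18.0, 65.0),
    seed: int = 0,
    male_fraction: float = 0.7,
) -> pd.DataFrame:
    """Build a cohort table with the requested group sizes.

    Ages are uniform on ``age_range``; sex is assigned at ``male_fraction``
    (the source cohort this emulates was ~3/4 male). Deterministic by seed.
    """
    if n_patients < 0 or n_controls < 0:
        raise ValueError("counts must be >= 0")
    n = n_patients + n_controls
    if n == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        group = "patient" if i < n_patients else "control"
        rows.append(
            {
                "subject_id": f"sub{i:04d}",
                "group": group,
                "age": round(float(rng.uniform(*age_range)), 1),
                "sex": "m" if rng.random() < male_fraction else "f",
            }
        )
    return pd.DataFrame(rows)


def _subject_seed(subject_id: str, seed: int) -> int:
    """Stable sub-seed per subject so signatures survive regeneration order."""
    h = hashlib.sha256(f"{seed}:{subject_id}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _smooth_field(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    raw = rng.standard_normal(cfg.grid_shape)
    if cfg.smoothing_sigma_vox > 0:
        sm = ndimage.gaussian_filter(raw, cfg.smoothing_sigma_vox)
        sd = sm.std()
        if sd > 0:
            sm = sm / sd  # keep unit variance after smoothing
        return sm
    return raw


def brain_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoid inscribed in the grid at 90% of the half-axes."""
    coords = np.indices(grid_shape).astype(float)
    half = (np.asarray(grid_shape) - 1) / 2.0
    dist = sum(
        ((coords[a] - half[a]) / (0.9 * half[a])) ** 2 for a in range(3)
    )
    return dist <= 1.0


def _fixed_maps(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mask = brain_mask(cfg.grid_shape)
    rng = np.random.default_rng(_subject_seed("__maps__", cfg.seed))
    baseline = cfg.baseline_amplitude * ndimage.gaussian_filter(
        mask.astype(float), max(cfg.smoothing_sigma_vox, 1.0)
    )
    group_map = _smooth_field(rng, cfg) * mask
    age_map = _smooth_field(rng, cfg) * mask
    return baseline, group_map, age_map, mask


def subject_signature(subject_id: str, cfg: SimConfig) -> np.ndarray:
    """The subject's persistent spatial signature field (masked, unit scale)."""
    rng = np.random.default_rng(_subject_seed(subject_id, cfg.seed))
    return _smooth_field(rng, cfg) * brain_mask(cfg.grid_shape)


def simulate_scan(
    subject: pd.Series | dict,
    cfg: SimConfig,
    age_stats: tuple[float, float] | None = None,
    rep: int = 0,
) -> Volume4D:
    """Simulate one subject's 4D scan under the additive signature model.

    ``age_stats`` (mean, sd) standardizes age; when None the age effect uses
    a fixed (40, 12) reference so single-scan calls remain deterministic.
    Repeated calls for the same subject id and config share the signature
    field; ``rep`` indexes independent scan sessions, which share the
    signature but draw fresh temporal noise.
    """
    sid = str(subject["subject_id"])
    baseline, group_map, age_map, _ = _fixed_maps(cfg)
    sig = subject_signature(sid, cfg)
    mean_img = baseline + cfg.signature_amplitude * sig
    if cfg.group_amplitude > 0 and subject["group"] == "patient":
        mean_img = mean_img + cfg.group_amplitude * group_map
    if cfg.age_amplitude > 0:
        mu, sd = age_stats if age_stats is not None else (40.0, 12.0)
        z = (float(subject["age"]) - mu) / sd if sd > 0 else 0.0
        mean_img = mean_img + cfg.age_amplitude * z * age_map
    noise_rng = np.random.default_rng(_subject_seed(f"{sid}:noise:{rep}", cfg.seed))
    data = mean_img[..., None] + noise_rng.normal(
        0.0, cfg.noise_sd, size=cfg.grid_shape + (cfg.n_timepoints,)
    )
    return Volume4D(
        data=data.astype(np.float32),
        voxel_size_mm=np.array([3.0, 3.0, 3.0]),
        subject_id=sid,
    )


def simulate_dataset(cohort: pd.DataFrame, cfg: SimConfig) -> SimulatedDataset:
    """One scan per cohort row, plus the ground-truth maps for assertions."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    baseline, group_map, age_map, mask = _fixed_maps(cfg)
    ages = cohort["age"].to_numpy(dtype=float)
    age_stats = (float(ages.mean()), float(ages.std()) if len(ages) > 1 else 1.0)
    scans = []
    signatures = {}
    for _, row in cohort.iterrows():
        scans.append(simulate_scan(row, cfg, age_stats=age_stats))
        signatures[str(row["subject_id"])] = subject_signature(
            str(row["subject_id"]), cfg
        )
    return SimulatedDataset(
        scans=scans,
        cohort=cohort.reset_index(drop=True),
        signatures=signatures,
        group_map=group_map,
        age_map=age_map,
        brain_mask=mask,
        cfg=cfg,
    )


def make_block_atlas(
    grid_shape: tuple[int, int, int], n_per_axis: tuple[int, int, int] = (3, 3, 3)
) -> AtlasVolume:
    """Partition the ellipsoidal brain mask into rectangular-block ROIs.

    A crude stand-in for an anatomical parcellation: the grid is divided into
    ``prod(n_per_axis)`` blocks and each block's in-mask voxels form one ROI
    (empty blocks are dropped and labels renumbered contiguously).
    """
    mask = brain_mask(tuple(grid_shape))
    edges = [
        np.linspace(0, s, n + 1).astype(int) for s, n in zip(grid_shape, n_per_axis)
    ]
    labels = np.zeros(tuple(grid_shape), dtype=np.int32)
    next_label = 1
    for i in range(n_per_axis[0]):
        for j in range(n_per_axis[1]):
            for k in range(n_per_axis[2]):
                block = np.zeros_like(mask)
                block[
                    edges[0][i] : edges[0][i + 1],
                    edges[1][j] : edges[1][j + 1],
                    edges[2][k] : edges[2][k + 1],
                ] = True
                sel = block & mask
                if sel.any():
                    labels[sel] = next_label
                    next_label += 1
    return AtlasVolume(labels=labels)


def write_dataset(
    dataset: SimulatedDataset, out_dir: str | Path, atlas: AtlasVolume | None = None
) -> Path:
    """Write scans as NIfTI plus the subject CSV, mirroring the real-data layout."""
    out = Path(out_dir)
    (out / "scans").mkdir(parents=True, exist_ok=True)
    for scan in dataset.scans:
        save_scan(scan, out / "scans" / f"{scan.subject_id}.nii.gz")
    save_subject_table(dataset.cohort, out / "subjects.csv")
    if atlas is not None:
        save_atlas(atlas, out / "atlas.nii.gz")
    return out
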