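"""Comparison feature extractors: ROI-pooled signals, PCA, connectivity.

Each baseline produces per-timepoint feature vectors (or, for connectivity,
one vector per subject) that flow through the same identity-feature and
precision@k machinery as the encoder features, so all methods are evaluated
on an identical surface.

The PCA baseline is fit on the training-1 timepoints (observations) over
cropped voxels (variables), mean-centered, and applied unchanged to the
other splits — mirroring how the encoder learns from training 1 only. For
small component counts the exact LAPACK solver is used; beyond 100
components a randomized solver keeps memory and time bounded (loadings then
orthonormal to solver tolerance rather than machine precision).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .features import FeatureSet
from .io_cohort import RoiTimeSeries, Volume4D

__all__ = [
    "PcaModel",
    "ConnectivityFeature",
    "roi_features",
    "fit_pca",
    "project_pca",
    "pca_features",
    "connectivity",
    "connectivity_features",
    "voxel_matrix",
]


def roi_features(ts: RoiTimeSeries) -> FeatureSet:
    """Each row of the T × R ROI time series becomes a timepoint feature."""
    t = ts.n_timepoints
    return FeatureSet(
        values=ts.values.copy(),
        subject_ids=np.array([ts.subject_id] * t, dtype=object),
        timepoints=np.arange(t),
    )


def roi_features_many(series: Sequence[RoiTimeSeries]) -> FeatureSet:
    sets = [roi_features(ts) for ts in series]
    return FeatureSet(
        np.concatenate([s.values for s in sets]),
        np.concatenate([s.subject_ids for s in sets]),
        np.concatenate([s.timepoints for s in sets]),
    )


@dataclass
class PcaModel:
    """Principal-component loadings fit on training timepoints."""

    components: np.ndarray  # (m, n_voxels), orthonormal rows
    explained_variance: np.ndarray  # (m,), non-increasing
    mean: np.ndarray  # (n_voxels,) training mean
    m: int

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(
            out / "pca.npz",
            components=self.components,
            explained_variance=self.explained_variance,
            mean=self.mean,
        )
        return out

    @classmethod
    def load(cls, out_dir: str | Path) -> "PcaModel":
        with np.load(Path(out_dir) / "pca.npz") as f:
            return cls(
                components=f["components"],
                explained_variance=f["explained_variance"],
                mean=f["mean"],
                m=f["components"].shape[0],
            )


def voxel_matrix(scans: Sequence[Volume4D]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack all timepoints into (n_timepoints_total, n_voxels) + annotations."""
    rows, sids, tps = [], [], []
    for vol in scans:
        rows.append(np.moveaxis(vol.data, -1, 0).reshape(vol.n_timepoints, -1))
        sids.extend([vol.subject_id] * vol.n_timepoints)
        tps.extend(range(vol.n_timepoints))
    return (
        np.concatenate(rows, axis=0),
        np.array(sids, dtype=object),
        np.array(tps),
    )


def fit_pca(x: np.ndarray, m: int, seed: int = 0) -> PcaModel:
    """Top-m principal components of (observations × voxels) data."""
    x = np.asarray(x, dtype=float)
    limit = min(x.shape[0] - 1, x.shape[1])
    if m < 1 or m > limit:
        raise ValueError(f"m={m} out of range [1, {limit}] for data {x.shape}")
    solver = "full" if m <= 100 else "randomized"
    pca = _SkPCA(n_components=m, svd_solver=solver, random_state=seed)
    pca.fit(x)
    return PcaModel(
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        mean=pca.mean_,
        m=m,
    )


def project_pca(model: PcaModel, x: np.ndarray) -> np.ndarray:
    """Centered projection onto the loadings; accepts one vector or a matrix."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None]
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"dimension {x.shape[1]} != training voxel count {model.mean.shape[0]}"
        )
    proj = (x - model.mean) @ model.components.T
    return proj[0] if single else proj


def reconstruct_pca(model: PcaModel, scores: np.ndarray) -> np.ndarray:
    return np.atleast_2d(scores) @ model.components + model.mean


def pca_features(model: PcaModel, scans: Sequence[Volume4D]) -> FeatureSet:
    """Project every timepoint of every scan onto the principal components."""
    x, sids, tps = voxel_matrix(scans)
    return FeatureSet(project_pca(model, x), sids, tps)


@dataclass
class ConnectivityFeature:
    """Static functional connectivity: ROI × ROI Pearson correlation matrix."""

    matrix: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)

    @property
    def vector(self) -> np.ndarray:
        """Upper triangle excluding the diagonal, length R(R-1)/2."""
        r = self.matrix.shape[0]
        iu = np.triu_indices(r, k=1)
        return self.matrix[iu]


def connectivity(ts: RoiTimeSeries) -> ConnectivityFeature:
    """Pearson correlations among the ROI-pooled time series over the scan.

    Uses the full scan (no windowing). Constant ROI columns have undefined
    correlation and raise, naming the offending ROI ids.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    sd = ts.values.std(axis=0)
    const = np.flatnonzero(sd == 0)
    if len(const):
        names = ts.roi_ids[const].tolist()
        raise ValueError(f"constant ROI time series (cannot correlate): {names}")
    mat = np.corrcoef(ts.values, rowvar=False)
    np.fill_diagonal(mat, 1.0)
    return ConnectivityFeature(matrix=mat, subject_id=ts.subject_id)


def connectivity_features(series: Sequence[RoiTimeSeries]):
    """Per-subject connectivity vectors as an IdentitySet-like feature table.

    Connectivity is one vector per subject (not per timepoint), so it enters
    the downstream classifiers directly as each subject's identity feature.
    """
    from .features import IdentitySet

    feats = [connectivity(ts) for ts in series]
    order = np.argsort([f.subject_id for f in feats])
    return IdentitySet(
        values=np.stack([feats[i].vector for i in order]),
        subject_ids=np.array([feats[i].subject_id for i in order], dtype=object),
        n_averaged=np.array([series[i].n_timepoints for i in order]),
    )
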