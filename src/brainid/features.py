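"""Per-timepoint feature vectors, identity features, and precision@k.

The encoder's dense-layer (pre-softmax) output for one timepoint is the
*classification* feature vector. Subtracting each vector's element mean —
which leaves softmax output untouched — gives the *classification+* variant.
Averaging a subject's vectors over time yields their *identity feature*.
Cluster quality is scored by precision@k: for each identity feature, rank
every feature vector in the pooled set by Euclidean distance and count what
fraction of the k nearest belong to that subject; with k equal to the
per-subject timepoint count, a perfectly clustered embedding scores 1.

These code paths are the single evaluation surface: the baseline extractors
(ROI pooling, PCA) feed their vectors through the same FeatureSet /
identity-feature / precision@k machinery as the encoder.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .encoder import TrainedEncoder
from .io_cohort import Volume4D

__all__ = [
    "FeatureSet",
    "IdentitySet",
    "PrecisionReport",
    "extract_features",
    "center_features",
    "identity_features",
    "precision_at_k",
]

VARIANTS = ("classification", "classification_plus")


@dataclass
class FeatureSet:
    """Feature vectors for a set of (subject, timepoint) pairs.

    ``values`` is (n, D); ``subject_ids`` and ``timepoints`` are parallel
    per-row annotations.
    """

    values: np.ndarray
    subject_ids: np.ndarray
    timepoints: np.ndarray
    variant: str = "classification"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.timepoints = np.asarray(self.timepoints, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_vectors, dim)")
        n = len(self.values)
        if len(self.subject_ids) != n or len(self.timepoints) != n:
            raise ValueError("annotations must match values row count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def subjects(self) -> list[str]:
        return sorted(set(self.subject_ids.tolist()))

    def for_subject(self, subject_id: str) -> "FeatureSet":
        m = self.subject_ids == subject_id
        return FeatureSet(
            self.values[m], self.subject_ids[m], self.timepoints[m], self.variant
        )

    def subset(self, subject_ids: Sequence[str]) -> "FeatureSet":
        keep = set(subject_ids)
        m = np.array([s in keep for s in self.subject_ids])
        return FeatureSet(
            self.values[m], self.subject_ids[m], self.timepoints[m], self.variant
        )

    def to_frame(self) -> pd.DataFrame:
        dim = self.values.shape[1]
        df = pd.DataFrame(self.values, columns=[f"v{i+1}" for i in range(dim)])
        df.insert(0, "timepoint", self.timepoints)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path, variant: str = "classification") -> "FeatureSet":
        df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
        cols = [c for c in df.columns if c.startswith("v")]
        return cls(
            df[cols].to_numpy(), df["subject_id"].to_numpy(),
            df["timepoint"].to_numpy(), variant,
        )


@dataclass
class IdentitySet:
    """Per-subject identity features (temporal means of feature vectors)."""

    values: np.ndarray
    subject_ids: np.ndarray
    n_averaged: np.ndarray
    variant: str = "classification"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.n_averaged = np.asarray(self.n_averaged, dtype=int)

    def __len__(self) -> int:
        return len(self.values)

    def vector(self, subject_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.subject_ids == subject_id)
        if len(idx) != 1:
            raise KeyError(subject_id)
        return self.values[idx[0]]

    def subset(self, subject_ids: Sequence[str]) -> "IdentitySet":
        order = [list(self.subject_ids).index(s) for s in subject_ids]
        return IdentitySet(
            self.values[order], self.subject_ids[order],
            self.n_averaged[order], self.variant,
        )

    def to_frame(self) -> pd.DataFrame:
        dim = self.values.shape[1]
        df = pd.DataFrame(self.values, columns=[f"v{i+1}" for i in range(dim)])
        df.insert(0, "n", self.n_averaged)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path, variant: str = "classification") -> "IdentitySet":
        df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
        cols = [c for c in df.columns if c.startswith("v")]
        return cls(
            df[cols].to_numpy(), df["subject_id"].to_numpy(),
            df["n"].to_numpy(), variant,
        )


@dataclass
class PrecisionReport:
    """Per-identity precision@k plus its mean."""

    per_subject: pd.DataFrame  # columns: subject_id, precision
    k: int

    @property
    def mean(self) -> float:
        return float(self.per_subject["precision"].mean())

    def save(self, path: str | Path) -> None:
        self.per_subject.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        return f"mean precision@{self.k} = {self.mean:.4f} over {len(self.per_subject)} subjects"


def tsne_embedding(features: FeatureSet, seed: int = 0, **kwargs) -> np.ndarray:
    """2-D t-SNE embedding of the feature vectors, for visual inspection only.

    Thin wrapper over scikit-learn's implementation; t-SNE preserves local
    neighborhoods but not global structure, so the embedding is qualitative
    and nothing downstream depends on it.
    """
    from sklearn.manifold import TSNE

    kwargs.setdefault("perplexity", min(30.0, max(2.0, len(features) / 4)))
    return TSNE(n_components=2, random_state=seed, init="pca",
                **kwargs).fit_transform(features.values)


def extract_features(
    enc: TrainedEncoder, scans: Sequence[Volume4D]
) -> FeatureSet:
    """Dense-layer output for every timepoint of every scan (classification)."""
    values, sids, tps = [], [], []
    for vol in scans:
        x = np.moveaxis(vol.data, -1, 0)
        values.append(enc.logits(x))
        sids.extend([vol.subject_id] * vol.n_timepoints)
        tps.extend(range(vol.n_timepoints))
    return FeatureSet(
        np.concatenate(values, axis=0), np.array(sids, dtype=object),
        np.array(tps), "classification",
    )


def center_features(features: FeatureSet) -> FeatureSet:
    """classification -> classification+: subtract each vector's element mean.

    Softmax is shift-invariant, so the encoder's posterior is unchanged;
    geometrically this projects onto the hyperplane orthogonal to the
    all-ones direction. Idempotent.
    """
    centered = features.values - features.values.mean(axis=1, keepdims=True)
    return FeatureSet(
        centered, features.subject_ids, features.timepoints, "classification_plus"
    )


def identity_features(features: FeatureSet) -> IdentitySet:
    """Per-subject temporal mean of the feature vectors."""
    if len(features) == 0:
        raise ValueError("no feature vectors")
    subjects = features.subjects
    values = np.stack(
        [features.values[features.subject_ids == s].mean(axis=0) for s in subjects]
    )
    counts = np.array(
        [int(np.sum(features.subject_ids == s)) for s in subjects]
    )
    return IdentitySet(values, np.array(subjects, dtype=object), counts,
                       features.variant)


def precision_at_k(
    features: FeatureSet, identities: IdentitySet, k: int
) -> PrecisionReport:
    """precision@k of each identity feature over the pooled vector set.

    All feature vectors (every subject's, pooled) are ranked by Euclidean
    distance to the identity feature, ascending; precision@k is the fraction
    of the k nearest that belong to the identity's subject. Ranking ties are
    broken stably by (distance, subject_id, timepoint) so degenerate inputs
    stay deterministic. The identity feature itself is a centroid, not an
    observation, and is never part of the ranked pool. Distances are taken
    in the raw feature space, with no standardization.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(features):
        raise ValueError(
            f"k={k} exceeds the pooled feature count {len(features)}"
        )
    present = set(features.subject_ids.tolist())
    missing = [s for s in identities.subject_ids if s not in present]
    if missing:
        raise ValueError(f"identities with no feature vectors present: {missing}")
    if identities.values.shape[1] != features.values.shape[1]:
        raise ValueError("identity / feature dimensionality mismatch")
    dists = cdist(identities.values, features.values)  # (S, N)
    rows = []
    for i, sid in enumerate(identities.subject_ids):
        # stable tie-break: distance, then subject_id, then timepoint
        order = np.lexsort((features.timepoints, features.subject_ids.astype(str),
                            dists[i]))
        top = order[:k]
        hits = int(np.sum(features.subject_ids[top] == sid))
        rows.append({"subject_id": sid, "precision": hits / k})
    report = pd.DataFrame(rows)
    return PrecisionReport(per_subject=report, k=k)
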