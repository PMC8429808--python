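"""Baseline feature extractors: ROI pooling, PCA, functional connectivity.

All baselines flow through the same identity-feature / precision@k code path
as the encoder features, so methods are compared on an identical surface.
"""

import numpy as np

from brainid import (
    connectivity,
    fit_pca,
    identity_features,
    make_cohort,
    pca_features,
    pool_rois,
    precision_at_k,
)
from brainid.baselines import roi_features_many, voxel_matrix
from brainid.synth import SimConfig, make_block_atlas, simulate_dataset

cohort = make_cohort(3, 3, seed=4)
cfg = SimConfig(grid_shape=(16, 16, 16), n_timepoints=20,
                signature_amplitude=5.0, noise_sd=1.0, seed=4)
dataset = simulate_dataset(cohort, cfg)
atlas = make_block_atlas((16, 16, 16), (2, 2, 2))
print(f"atlas: {atlas.n_rois} block ROIs inside the ellipsoidal brain mask")

series = [pool_rois(scan, atlas) for scan in dataset.scans]
roi_fs = roi_features_many(series)
rep = precision_at_k(roi_fs, identity_features(roi_fs), k=20)
print(f"ROI-pooled signals: {rep.summary()}")

x, _, _ = voxel_matrix(dataset.scans)
pca = fit_pca(x, m=3)
share = pca.explained_variance / pca.explained_variance.sum()
print(f"PCA: top-3 components, explained-variance shares {np.round(share, 3)}")
pca_fs = pca_features(pca, dataset.scans)
rep = precision_at_k(pca_fs, identity_features(pca_fs), k=20)
print(f"PCA projections:    {rep.summary()}")

conn = connectivity(series[0])
print(f"\nconnectivity matrix for {conn.subject_id}: "
      f"{conn.matrix.shape[0]}x{conn.matrix.shape[0]} Pearson correlations, "
      f"vectorized upper triangle has {conn.vector.size} entries")
print("off-diagonal range: "
      f"[{conn.vector.min():.3f}, {conn.vector.max():.3f}]")
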