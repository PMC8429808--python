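import numpy as np
import pandas as pd
import pytest

import brainid as bi
from brainid.synth import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_cohort() -> pd.DataFrame:
    return bi.make_cohort(3, 3, age_range=(20, 60), seed=7)


@pytest.fixture(scope="session")
def tiny_sim(tiny_cohort):
    """Six subjects on an 8x8x8 grid with a strong identity signature."""
    cfg = SimConfig(
        grid_shape=(8, 8, 8), n_timepoints=10, signature_amplitude=5.0,
        group_amplitude=2.0, noise_sd=1.0, smoothing_sigma_vox=1.0, seed=3,
    )
    return simulate_dataset(tiny_cohort, cfg)


@pytest.fixture(scope="session")
def tiny_encoder(tiny_sim):
    """A briefly trained 1-block encoder on the tiny cohort (shared, read-only)."""
    enc = bi.EncoderConfig(
        input_shape=(8, 8, 8), n_subjects=6, n_blocks=1, base_channels=2,
        n_tail_convs=1,
    )
    tr = bi.TrainConfig(lr_schedule=((1e-3, 120),), batch_size=6, seed=5,
                        eval_every=20)
    labels = list(range(6))
    trained = bi.train_encoder(tiny_sim.scans, labels, enc, tr)
    return trained, tiny_sim.scans, labels


def random_feature_set(rng, n_subjects=3, n_per=4, dim=2, spread=1.0, sep=0.0):
    """FeatureSet with optional per-subject cluster separation."""
    values, sids, tps = [], [], []
    for s in range(n_subjects):
        center = rng.normal(0, sep, dim) if sep else np.zeros(dim)
        for t in range(n_per):
            values.append(center + rng.normal(0, spread, dim))
            sids.append(f"s{s}")
            tps.append(t)
    return bi.FeatureSet(np.array(values), np.array(sids, dtype=object),
                         np.array(tps))
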