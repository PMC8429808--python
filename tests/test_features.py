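"""Feature extraction, identity features and the precision@k metric."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import brainid as bi
from brainid import nn
from brainid.features import (
    FeatureSet,
    center_features,
    extract_features,
    identity_features,
    precision_at_k,
)
from conftest import random_feature_set


class TestExtractFeatures:
    def test_one_vector_per_timepoint(self, tiny_encoder):
        trained, scans, _ = tiny_encoder
        feats = extract_features(trained, scans[:2])
        assert len(feats) == 2 * scans[0].n_timepoints
        assert feats.variant == "classification"

    def test_identical_timepoints_identical_vectors(self, tiny_encoder):
        trained, scans, _ = tiny_encoder
        vol = scans[0]
        dup = bi.Volume4D(
            data=np.repeat(vol.data[..., :1], 2, axis=-1),
            voxel_size_mm=vol.voxel_size_mm, subject_id="dup",
        )
        feats = extract_features(trained, [dup])
        np.testing.assert_array_equal(feats.values[0], feats.values[1])

    def test_matches_per_timepoint_loop(self, tiny_encoder):
        """Oracle: evaluate the dense layer one timepoint at a time."""
        trained, scans, _ = tiny_encoder
        vol = scans[0]
        feats = extract_features(trained, [vol])
        for t in range(vol.n_timepoints):
            single = trained.logits(vol.data[..., t])[0]
            np.testing.assert_allclose(feats.values[t], single, rtol=1e-5)


class TestCenterFeatures:
    def test_simple_mean_subtraction(self):
        fs = FeatureSet(np.array([[1.0, 2.0, 3.0]]), np.array(["a"], object),
                        np.array([0]))
        out = center_features(fs)
        np.testing.assert_allclose(out.values, [[-1.0, 0.0, 1.0]])
        assert out.variant == "classification_plus"

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        fs = random_feature_set(rng, 2, 3, 5)
        once = center_features(fs)
        twice = center_features(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-15)

    def test_centered_vectors_have_zero_mean(self):
        rng = np.random.default_rng(1)
        out = center_features(random_feature_set(rng, 3, 4, 7))
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-9)

    def test_softmax_untouched(self):
        rng = np.random.default_rng(2)
        fs = random_feature_set(rng, 2, 2, 6)
        out = center_features(fs)
        np.testing.assert_allclose(
            nn.softmax(fs.values), nn.softmax(out.values), atol=1e-12
        )


class TestIdentityFeatures:
    def test_two_vector_mean(self):
        fs = FeatureSet(np.array([[0.0, 2.0], [2.0, 0.0]]),
                        np.array(["a", "a"], object), np.array([0, 1]))
        ids = identity_features(fs)
        np.testing.assert_allclose(ids.values, [[1.0, 1.0]])
        assert ids.n_averaged[0] == 2

    def test_single_vector_is_itself(self):
        fs = FeatureSet(np.array([[3.0, 4.0]]), np.array(["a"], object),
                        np.array([0]))
        np.testing.assert_allclose(identity_features(fs).values, [[3.0, 4.0]])

    def test_centering_commutes_with_averaging(self):
        """Mean-subtraction is linear, so it commutes with the temporal mean."""
        rng = np.random.default_rng(3)
        fs = random_feature_set(rng, 3, 5, 6)
        a = identity_features(center_features(fs)).values
        b = center_features_identity(identity_features(fs))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_empty_set_rejected(self):
        fs = FeatureSet(np.zeros((0, 3)), np.array([], object), np.array([], int))
        with pytest.raises(ValueError, match="no feature"):
            identity_features(fs)


def center_features_identity(ids):
    return ids.values - ids.values.mean(axis=1, keepdims=True)


def brute_force_precision(features: FeatureSet, identities, k: int):
    """O(N^2) oracle: full stable sort by (distance, subject_id, timepoint)."""
    out = {}
    for i, sid in enumerate(identities.subject_ids):
        c = identities.values[i]
        rows = sorted(
            range(len(features)),
            key=lambda j: (
                float(np.linalg.norm(features.values[j] - c)),
                str(features.subject_ids[j]),
                int(features.timepoints[j]),
            ),
        )
        hits = sum(1 for j in rows[:k] if features.subject_ids[j] == sid)
        out[sid] = hits / k
    return out


class TestPrecisionAtK:
    def test_tight_clusters_give_precision_one(self):
        """Well-separated per-subject clusters score exactly 1."""
        rng = np.random.default_rng(4)
        fs = random_feature_set(rng, 5, 20, 8, spread=1.0, sep=0.0)
        # move clusters far apart: separation 100x the spread
        for i, s in enumerate(sorted(set(fs.subject_ids))):
            fs.values[fs.subject_ids == s] += 100.0 * i
        ids = identity_features(fs)
        rep = precision_at_k(fs, ids, k=20)
        assert rep.mean == 1.0
        assert (rep.per_subject["precision"] == 1.0).all()

    def test_k1_own_vector_closest(self):
        fs = FeatureSet(np.array([[0.0], [10.0]]),
                        np.array(["a", "b"], object), np.array([0, 0]))
        ids = identity_features(fs)
        rep = precision_at_k(fs, ids, k=1)
        assert (rep.per_subject["precision"] == 1.0).all()

    def test_hand_placed_2d_instance(self):
        """3 subjects x 4 vectors in 2-D, verified against the sort oracle."""
        rng = np.random.default_rng(5)
        fs = random_feature_set(rng, 3, 4, 2, spread=2.0, sep=3.0)
        ids = identity_features(fs)
        rep = precision_at_k(fs, ids, k=4)
        oracle = brute_force_precision(fs, ids, 4)
        for _, row in rep.per_subject.iterrows():
            assert row["precision"] == pytest.approx(oracle[row["subject_id"]])

    def test_k_larger_than_pool_rejected(self):
        rng = np.random.default_rng(6)
        fs = random_feature_set(rng, 2, 3, 2)
        ids = identity_features(fs)
        with pytest.raises(ValueError, match="exceeds"):
            precision_at_k(fs, ids, k=7)

    def test_precision_bounded_by_subject_count(self):
        """precision@k <= min(1, n_i / k)."""
        rng = np.random.default_rng(7)
        fs = random_feature_set(rng, 4, 5, 3, spread=0.1, sep=10.0)
        ids = identity_features(fs)
        for k in (1, 5, 10, 20):
            rep = precision_at_k(fs, ids, k)
            bound = min(1.0, 5 / k)
            assert (rep.per_subject["precision"] <= bound + 1e-12).all()

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        fs = random_feature_set(rng, 3, 4, 5, sep=2.0)
        ids = identity_features(fs)
        shifted = FeatureSet(fs.values + 7.5, fs.subject_ids, fs.timepoints)
        ids_shift = identity_features(shifted)
        a = precision_at_k(fs, ids, 6).per_subject
        b = precision_at_k(shifted, ids_shift, 6).per_subject
        assert a.equals(b)

    def test_degenerate_identical_vectors_deterministic(self):
        fs = FeatureSet(np.zeros((6, 2)),
                        np.array(["a", "a", "b", "b", "c", "c"], object),
                        np.array([0, 1, 0, 1, 0, 1]))
        ids = identity_features(fs)
        a = precision_at_k(fs, ids, 2).per_subject
        b = precision_at_k(fs, ids, 2).per_subject
        assert a.equals(b)
        # ties broken by subject_id then timepoint: subject 'a' wins its own slot
        assert a.set_index("subject_id").loc["a", "precision"] == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        n_subjects=st.integers(2, 6),
        n_per=st.integers(1, 8),
        dim=st.integers(1, 4),
        k=st.integers(1, 20),
        seed=st.integers(0, 1000),
    )
    def test_oracle_equivalence_random_instances(self, n_subjects, n_per, dim, k,
                                                 seed):
        """Exhaustive O(N^2) sort oracle on instances of <= 48 vectors."""
        rng = np.random.default_rng(seed)
        fs = random_feature_set(rng, n_subjects, n_per, dim, spread=1.0, sep=1.0)
        k = min(k, len(fs))
        ids = identity_features(fs)
        rep = precision_at_k(fs, ids, k)
        oracle = brute_force_precision(fs, ids, k)
        for _, row in rep.per_subject.iterrows():
            assert row["precision"] == pytest.approx(oracle[row["subject_id"]])


class TestSerialization:
    def test_feature_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        fs = random_feature_set(rng, 2, 3, 4)
        fs.save(tmp_path / "f.tsv")
        loaded = FeatureSet.load(tmp_path / "f.tsv")
        np.testing.assert_allclose(loaded.values, fs.values)
        assert list(loaded.subject_ids) == list(fs.subject_ids)

    def test_identity_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        ids = identity_features(random_feature_set(rng, 3, 4, 5))
        ids.save(tmp_path / "i.tsv")
        from brainid.features import IdentitySet

        loaded = IdentitySet.load(tmp_path / "i.tsv")
        np.testing.assert_allclose(loaded.values, ids.values)
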