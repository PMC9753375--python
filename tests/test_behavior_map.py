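"""Tests of the behavior map: embedding, clustering, labels, MI, detectors."""

import numpy as np
import pytest

import loomkit as lk
from loomkit.behavior_map import (
    DEFAULT_LABEL_MAPPING,
    DefensiveThresholds,
    LabelMapping,
    apply_label_mapping,
    build_feature_space,
    cluster_phenotypes,
    compute_moving_intensity,
    detect_defensive,
    embed_nm,
)
from loomkit.decomposition import segment_nm, egocentric_align
from loomkit.dtak import kernel_matrix
from loomkit.errors import EventError, MappingError

from conftest import make_motif_segments


@pytest.fixture(scope="module")
def small_kernel():
    segments, truth = make_motif_segments(["walking", "rearing"], reps=4, seed=1)
    return kernel_matrix(segments), truth, segments


class TestEmbedding:
    def test_shape_and_determinism(self, small_kernel):
        K, truth, _ = small_kernel
        e1 = embed_nm(K, n_neighbors=10, seed=3)
        e2 = embed_nm(K, n_neighbors=10, seed=3)
        assert e1.shape == (K.n, 2)
        np.testing.assert_array_equal(e1, e2)

    def test_separates_two_motif_classes(self, small_kernel):
        from sklearn.metrics import silhouette_score

        K, truth, _ = small_kernel
        emb = embed_nm(K, n_neighbors=10, seed=0)
        assert silhouette_score(emb, truth) > 0.5

    def test_requires_normalized_kernel(self, small_kernel):
        K, _, _ = small_kernel
        K_raw = lk.KernelMatrix(
            values=K.values * 0.9 + 0.05, segment_ids=K.segment_ids, sigma=K.sigma,
            normalized=False,
        )
        with pytest.raises(ValueError):
            embed_nm(K_raw)

    def test_too_few_segments(self, small_kernel):
        K, _, _ = small_kernel
        with pytest.raises(ValueError):
            embed_nm(K, n_neighbors=K.n + 5)


class TestFeatureSpace:
    def test_binds_columns(self):
        emb = np.arange(80.0).reshape(40, 2)
        loco = np.linspace(0, 2, 40)
        pts = build_feature_space(emb, loco)
        assert pts.shape == (40, 3)
        np.testing.assert_array_equal(pts[:, 2], loco)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        emb, loco = rng.normal(size=(10, 2)), rng.gamma(1.0, 1.0, 10)
        perm = rng.permutation(10)
        np.testing.assert_array_equal(
            build_feature_space(emb, loco)[perm], build_feature_space(emb[perm], loco[perm])
        )

    def test_rejects_negative_loco(self):
        with pytest.raises(ValueError):
            build_feature_space(np.zeros((3, 2)), np.array([0.0, -0.1, 1.0]))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            build_feature_space(np.zeros((3, 2)), np.zeros(4))


class TestClustering:
    def test_recovers_separated_blobs(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(1)
        centers = np.array([[0, 0, 0], [30, 0, 0], [0, 30, 0]], dtype=float)
        pts = np.vstack([c + rng.normal(0, 1.0, size=(100, 3)) for c in centers])
        truth = np.repeat([0, 1, 2], 100)
        ids = cluster_phenotypes(pts, k=3)
        assert adjusted_rand_score(truth, ids) == 1.0

    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            cluster_phenotypes(np.zeros((10, 3)), k=1)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            cluster_phenotypes(np.zeros((5, 3)), k=5)

    def test_largest_cluster_is_one(self):
        rng = np.random.default_rng(2)
        pts = np.vstack(
            [rng.normal(0, 0.5, (80, 3)), rng.normal(20, 0.5, (20, 3))]
        )
        ids = cluster_phenotypes(pts, k=2)
        counts = np.bincount(ids)[1:]
        assert counts[0] == counts.max() == 80

    def test_kmeans_mode(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(15, 1, (30, 3))])
        ids = cluster_phenotypes(pts, k=2, method="kmeans", seed=0)
        assert set(ids) == {1, 2}


class TestLabelMapping:
    @pytest.mark.parametrize(
        "pid,name",
        [(13, "grooming"), (31, "stretching up"), (30, "left turning"), (7, "hunching")],
    )
    def test_reference_designations(self, pid, name):
        assert DEFAULT_LABEL_MAPPING[pid] == name

    def test_covers_forty_phenotypes_exactly(self):
        assert DEFAULT_LABEL_MAPPING.phenotype_ids() == set(range(1, 41))

    def test_apply(self):
        labels = apply_label_mapping([13, 31, 1], DEFAULT_LABEL_MAPPING)
        assert list(labels) == ["grooming", "stretching up", "running"]

    def test_unmapped_id_reported(self):
        with pytest.raises(MappingError, match="41"):
            apply_label_mapping([1, 41], DEFAULT_LABEL_MAPPING)

    def test_duplicate_assignment_rejected(self):
        with pytest.raises(MappingError):
            LabelMapping(movements={"walking": [1], "running": [1]})

    def test_roundtrip_dict(self):
        d = DEFAULT_LABEL_MAPPING.to_dict()
        again = LabelMapping.from_dict(d)
        assert again.phenotype_ids() == DEFAULT_LABEL_MAPPING.phenotype_ids()


class TestMovingIntensity:
    def test_running_more_intense_than_freezing(self):
        segments, truth = make_motif_segments(["freezing", "running"], reps=3, seed=2)
        summaries = compute_moving_intensity(segments, truth + 1)
        mi = {s.phenotype_id: s.mi for s in summaries}
        assert mi[2] > mi[1]
        assert max(mi.values()) == pytest.approx(1.0)

    def test_single_phenotype_is_one(self):
        segments, truth = make_motif_segments(["walking"], reps=2, seed=3)
        summaries = compute_moving_intensity(segments, np.ones_like(truth))
        assert summaries[0].mi == pytest.approx(1.0)
        assert summaries[0].mean_pose.shape == (16, 3)


class TestDefensiveDetection:
    def test_planted_freezing_bout_duration(self, arena, freezing_trial):
        gt = freezing_trial.ground_truth
        _, freezing = detect_defensive(
            freezing_trial.skeleton, freezing_trial.trajectory, gt.stimulus_onset, arena
        )
        planted = gt.freezing_bouts[0]
        match = [b for b in freezing if b[0] < planted[1] and b[1] > planted[0]]
        assert len(match) == 1
        assert match[0][1] - match[0][0] == pytest.approx(2.0, abs=0.1)

    def test_flight_onset_within_one_frame(self, arena, freezing_trial):
        gt = freezing_trial.ground_truth
        flight, _ = detect_defensive(
            freezing_trial.skeleton, freezing_trial.trajectory, gt.stimulus_onset, arena
        )
        assert flight is not None
        assert abs(flight[0] - gt.flight_onset) <= 1 / 30 + 1e-9

    def test_stationary_trial_has_no_flight(self, arena):
        import pandas as pd

        n = 600
        xy = np.full((n, 2), [1.0, 2.0])
        traj = pd.DataFrame({"t_s": np.arange(n) / 30, "x_cm": xy[:, 0], "y_cm": xy[:, 1]})
        flight, _ = detect_defensive(None, traj, stimulus_onset=5.0, arena=arena)
        assert flight is None

    def test_missing_onset_rejected(self, arena, freezing_trial):
        with pytest.raises(EventError):
            detect_defensive(
                freezing_trial.skeleton, freezing_trial.trajectory, None, arena
            )

    def test_thresholds_configurable(self, arena, freezing_trial):
        gt = freezing_trial.ground_truth
        th = DefensiveThresholds(flight_speed_min=1000.0)
        flight, _ = detect_defensive(
            freezing_trial.skeleton, freezing_trial.trajectory, gt.stimulus_onset, arena, th
        )
        assert flight is None
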