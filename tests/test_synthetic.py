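"""Tests of the synthetic looming-assay generator."""

import numpy as np
import pytest

import loomkit as lk
from loomkit.errors import GeometryError, LabelError, ProtocolKindError


class TestLoomingProfile:
    def test_printed_protocol_values(self, protocol):
        t, deg = lk.make_looming_profile(protocol, dt_ms=10)
        assert deg[0] == pytest.approx(2.0)  # ramp start
        assert deg[int(300 / 10)] == pytest.approx(40.0)  # end of first expansion
        # 15 x (300 + 50) + 14 x 30 ms
        assert t[-1] == pytest.approx(5670.0)

    def test_profile_bounded_during_repeats(self, protocol):
        _, deg = lk.make_looming_profile(protocol, dt_ms=5)
        active = deg > 0
        assert deg[active].min() >= protocol.start_deg
        assert deg.max() == pytest.approx(protocol.end_deg)

    def test_isi_gaps_are_zero(self, protocol):
        t, deg = lk.make_looming_profile(protocol, dt_ms=5)
        # middle of the first inter-stimulus interval
        idx = int(round((300 + 50 + 15) / 5))
        assert deg[idx] == 0.0

    def test_rejects_auditory_protocol(self):
        with pytest.raises(ProtocolKindError):
            lk.make_looming_profile(lk.StimulusProtocol(kind="auditory"), dt_ms=10)

    @pytest.mark.parametrize("dt", [0, -5, 7])
    def test_rejects_bad_dt(self, protocol, dt):
        with pytest.raises(ValueError):
            lk.make_looming_profile(protocol, dt_ms=dt)


class TestMotifTemplates:
    def test_freezing_is_immobile(self):
        s = lk.motif_template("freezing", 2.0, 30, seed=1)
        assert s.n_frames == 60
        assert lk.compute_locomotion(s).max() < 0.5

    def test_running_speed_override(self):
        s = lk.motif_template("running", 1.0, 30, params={"speed": 40.0}, seed=2)
        # oracle: finite-difference speed of the generated centroid
        centroid = s.centroid()
        step = np.linalg.norm(np.diff(centroid, axis=0), axis=1) * 30
        assert step.mean() == pytest.approx(40.0, rel=0.05)

    def test_deterministic_given_seed(self):
        a = lk.motif_template("walking", 1.0, 30, seed=5)
        b = lk.motif_template("walking", 1.0, 30, seed=5)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_unknown_label(self):
        with pytest.raises(LabelError):
            lk.motif_template("moonwalking", 1.0, 30)

    def test_too_short(self):
        with pytest.raises(ValueError):
            lk.motif_template("walking", 0.01, 30)

    def test_rearing_elevates_nose(self):
        rear = lk.motif_template("rearing", 1.0, 30, seed=3)
        walk = lk.motif_template("walking", 1.0, 30, seed=3)
        nose = lk.LANDMARKS.index("nose")
        assert rear.coords[:, nose, 2].mean() > walk.coords[:, nose, 2].mean() + 2.0

    @pytest.mark.parametrize("label,sign", [("left turning", 1.0), ("right turning", -1.0)])
    def test_turning_heading_is_signed(self, label, sign):
        s = lk.motif_template(label, 1.0, 30, seed=4)
        v = np.diff(s.centroid(), axis=0)
        headings = np.unwrap(np.arctan2(v[:, 1], v[:, 0]))
        assert sign * (headings[-1] - headings[0]) > 0.5


class TestSimulateTrial:
    def test_planted_freezing_bout(self, freezing_trial):
        gt = freezing_trial.ground_truth
        assert len(gt.freezing_bouts) == 1
        s, e = gt.freezing_bouts[0]
        assert e - s == pytest.approx(2.0, abs=1 / 30)
        assert gt.group == "Freezing"

    def test_no_freezing_means_nonfreezing(self, nonfreezing_trial):
        assert nonfreezing_trial.ground_truth.group == "Non-Freezing"
        assert nonfreezing_trial.ground_truth.freezing_bouts == []

    def test_stimulus_onset_matches_first_crossing(self, arena, freezing_trial):
        # oracle: first trigger-circle crossing of the generated centroid
        xy = freezing_trial.trajectory[["x_cm", "y_cm"]].to_numpy()
        t = freezing_trial.trajectory["t_s"].to_numpy()
        inside = np.flatnonzero(arena.in_trigger(xy))
        assert freezing_trial.ground_truth.stimulus_onset == pytest.approx(
            t[inside[0]], abs=1 / 30
        )

    def test_event_ordering(self, freezing_trial):
        gt = freezing_trial.ground_truth
        assert gt.stimulus_onset <= gt.flight_onset <= gt.refuge_entry <= gt.refuge_exit

    def test_skeleton_complete(self, freezing_trial):
        sk = freezing_trial.skeleton
        assert sk.coords.shape[1:] == (16, 3)
        assert np.isfinite(sk.coords).all()
        assert len(sk.coords) == len(freezing_trial.trajectory)

    def test_labels_cover_every_frame(self, freezing_trial):
        gt = freezing_trial.ground_truth
        assert len(gt.labels) == len(freezing_trial.trajectory)
        assert all(lbl in lk.synthetic.MOTIF_KINEMATICS for lbl in np.unique(gt.labels))

    def test_deterministic(self, arena, protocol):
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        s1 = lk.default_scenario(arena, freeze=True, rng=rng1, acclimation_s=10)
        s2 = lk.default_scenario(arena, freeze=True, rng=rng2, acclimation_s=10)
        t1 = lk.simulate_trial(arena, protocol, s1, seed=11)
        t2 = lk.simulate_trial(arena, protocol, s2, seed=11)
        np.testing.assert_array_equal(t1.skeleton.coords, t2.skeleton.coords)

    def test_path_outside_domain_rejected(self, arena, protocol):
        bad = lk.Scenario(
            legs=[lk.ScenarioLeg("walking", target=(100.0, 0.0))], acclimation_s=0.0
        )
        with pytest.raises(GeometryError):
            lk.simulate_trial(arena, protocol, bad)

    def test_overlapping_schedule_rejected(self, arena, protocol):
        legs = [
            lk.ScenarioLeg("walking", duration=2.0, start_s=0.0),
            lk.ScenarioLeg("sniffing", duration=2.0, start_s=1.0),
        ]
        with pytest.raises(lk.synthetic.ScheduleError):
            lk.simulate_trial(arena, protocol, lk.Scenario(legs=legs))


class TestSimulateCohort:
    def test_degenerate_probabilities(self):
        trials, design = lk.simulate_cohort(
            6, 5, 1.0, 0.0,
            params={"acclimation_s": 3.0, "include_skeletons": False, "p_escape": 1.0},
            seed=1,
        )
        assert (design.loc[design.sex == "male", "group"] == "Freezing").all()
        assert (design.loc[design.sex == "female", "group"] == "Non-Freezing").all()
        assert len(trials) == 11

    def test_binomial_recovery(self):
        # 3 sigma of a Binomial(400, 0.6) proportion is ~0.073
        _, design = lk.simulate_cohort(
            400, 1, 0.6, 0.5,
            params={"acclimation_s": 2.0, "include_skeletons": False},
            seed=2,
        )
        p = design.loc[design.sex == "male", "freezing"].mean()
        assert p == pytest.approx(0.6, abs=0.075)

    def test_reproducible(self):
        kw = dict(params={"acclimation_s": 3.0, "include_skeletons": False}, seed=9)
        t1, d1 = lk.simulate_cohort(3, 3, 0.7, 0.5, **kw)
        t2, d2 = lk.simulate_cohort(3, 3, 0.7, 0.5, **kw)
        assert d1.equals(d2)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(
                a.trajectory.to_numpy(), b.trajectory.to_numpy()
            )

    @pytest.mark.parametrize("p", [-0.1, 1.5])
    def test_invalid_probability(self, p):
        with pytest.raises(ValueError):
            lk.simulate_cohort(2, 2, p, 0.5)
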