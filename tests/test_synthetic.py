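"""Tests for the synthetic cohort generator: determinism, geometry, error structure."""

import numpy as np
import pytest

from gaitagree.kinematics import angle_at_vertex, angles_at_ic, detect_ic_force, detect_ic_kinematic
from gaitagree.pipeline import analyze_cohort
from gaitagree.synthetic import (
    JOINTS,
    POPULATION_IC_MEANS,
    CameraModel,
    CohortConfig,
    ErrorModel,
    GaitSimulationError,
    SegmentModel,
    implied_icc,
    mean_subject,
    pose_leg,
    project_markers,
    sagittal_view,
    sample_subject,
    simulate_cohort,
    simulate_trial,
    substream,
    synth_grf,
)


class TestSampleSubject:
    def test_zero_subject_sd_gives_identical_targets(self, small_config):
        err = ErrorModel(sd_subject=0.0)
        subs = [sample_subject(small_config, err, substream(1, 1, s)) for s in range(5)]
        for s in subs:
            assert s.profile.ic_targets == POPULATION_IC_MEANS

    def test_determinism_same_stream(self, small_config):
        err = ErrorModel()
        a = sample_subject(small_config, err, substream(3, 1, 7))
        b = sample_subject(small_config, err, substream(3, 1, 7))
        assert a.profile.ic_targets == b.profile.ic_targets
        assert a.segments == b.segments
        assert a.height_m == b.height_m

    def test_segment_lengths_scale_with_height(self, small_config):
        err = ErrorModel()
        subs = [sample_subject(small_config, err, substream(2, 1, s)) for s in range(40)]
        heights = np.array([s.height_m for s in subs])
        thighs = np.array([s.segments.thigh_length for s in subs])
        assert np.corrcoef(heights, thighs)[0, 1] > 0.95
        assert np.all(heights >= 1.40) and np.all(heights <= 2.05)

    def test_monte_carlo_target_moments(self, small_config):
        # 10 000 hip-target draws: sample mean/SD within 3 SE of the
        # configured generator parameters (33.06, 5.7)
        err = ErrorModel()
        rng = np.random.default_rng(99)
        draws = np.array([sample_subject(small_config, err, rng).profile.ic_targets["hip"]
                          for _ in range(10_000)])
        se_mean = 5.7 / np.sqrt(draws.size)
        se_sd = 5.7 / np.sqrt(2 * (draws.size - 1))
        assert abs(draws.mean() - 33.06) < 3 * se_mean
        assert abs(draws.std(ddof=1) - 5.7) < 3 * se_sd


class TestPoseLeg:
    def test_neutral_pose_collinear_and_foot_horizontal(self, subject):
        from dataclasses import replace
        profile = replace(subject.profile,
                          ic_targets={"hip": 0.0, "knee": 0.0, "ankle": 0.0},
                          pelvic_tilt_ic=0.0)
        pose = pose_leg(profile, subject.segments, profile.t_ic)
        gt, lfc, lm = pose["GT"], pose["LFC"], pose["LM"]
        assert gt[0] == pytest.approx(lfc[0], abs=1e-12)
        assert lfc[0] == pytest.approx(lm[0], abs=1e-12)  # vertically collinear
        assert pose["CAL"][1] == pytest.approx(pose["MT2"][1], abs=1e-12)  # foot level

    def test_knee_twenty_gives_inner_angle_160(self, subject):
        from dataclasses import replace
        profile = replace(subject.profile,
                          ic_targets={"hip": 0.0, "knee": 20.0, "ankle": 0.0},
                          pelvic_tilt_ic=0.0)
        pose = pose_leg(profile, subject.segments, profile.t_ic)
        inner = angle_at_vertex(pose["GT"][:2], pose["LFC"][:2], pose["LM"][:2])
        assert inner == pytest.approx(160.0, abs=1e-9)

    def test_markers_lie_in_sagittal_plane(self, subject, rng):
        for _ in range(10):
            pose = pose_leg(subject.profile, subject.segments, rng.uniform(0, 1), guard=False)
            assert all(p[2] == 0.0 for p in pose.values())

    def test_round_trip_reproduces_profile_angles(self, subject, rng):
        for _ in range(100):
            t = rng.uniform(0, 1)
            pose = pose_leg(subject.profile, subject.segments, t, guard=False)
            got = angles_at_ic(sagittal_view(pose))
            assert got.hip_deg == pytest.approx(float(subject.profile.hip(t)), abs=1e-6)
            assert got.knee_deg == pytest.approx(float(subject.profile.knee(t)), abs=1e-6)
            assert got.ankle_deg == pytest.approx(float(subject.profile.ankle(t)), abs=1e-6)

    def test_guard_range_raises(self, subject):
        from dataclasses import replace
        profile = replace(subject.profile,
                          ic_targets={"hip": 0.0, "knee": -60.0, "ankle": 0.0})
        with pytest.raises(GaitSimulationError, match="guard"):
            pose_leg(profile, subject.segments, profile.t_ic)

    def test_heel_clearance_minimum_at_ic(self, subject):
        prof = subject.profile
        ts = np.linspace(0, 1, 551, endpoint=False)
        clear = np.asarray(prof.heel_clearance(ts))
        assert clear[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(clear[1:] > 0)


class TestSegmentModel:
    def test_invalid_lengths_raise(self):
        with pytest.raises(GaitSimulationError):
            SegmentModel(thigh_length=-0.1)

    def test_oversized_marker_offset_raises(self):
        with pytest.raises(GaitSimulationError, match="0.05"):
            SegmentModel(marker_offsets={"GT": (0.06, 0.0)})


class TestProjection:
    def test_orthographic_unit_scale_is_identity_up_to_principal_point(self):
        cam = CameraModel(projection_mode="orthographic", focal_length_px=2.5,
                          lateral_distance=2.5)  # scale = 1 px/m
        u0, v0 = cam.principal_point
        pts = np.array([[0.3, 1.4, 0.0]])
        uv = project_markers(pts, cam)
        assert uv[0, 0] == pytest.approx(u0 + 0.3)
        assert uv[0, 1] == pytest.approx(v0 + 0.4)

    def test_point_on_optical_axis_hits_principal_point(self, default_cam):
        pt = np.array([[default_cam.x_position, default_cam.height, 0.0]])
        uv = project_markers(pt, default_cam)
        assert tuple(uv[0]) == default_cam.principal_point

    def test_pinhole_offset_closed_form(self, default_cam):
        # marker 0.5 m above camera height, sagittal plane at 2.5 m
        pt = np.array([[0.0, default_cam.height + 0.5, 0.0]])
        uv = project_markers(pt, default_cam)
        expected = default_cam.focal_length_px * 0.5 / 2.5
        assert uv[0, 1] - default_cam.principal_point[1] == pytest.approx(expected)

    def test_point_behind_camera_raises(self, default_cam):
        with pytest.raises(GaitSimulationError):
            project_markers(np.array([[0.0, 1.0, 10.0]]), default_cam)

    def test_perspective_converges_to_orthographic_at_distance(self):
        pts = np.array([[0.4, 1.6, 0.0], [-0.3, 0.2, 0.0]])
        ortho = project_markers(pts, CameraModel(projection_mode="orthographic"))
        for dist in (25.0, 2500.0):
            cam = CameraModel(lateral_distance=dist,
                              focal_length_px=1000.0 * dist / 2.5)  # keep in-plane scale
            persp = project_markers(pts, cam)
            assert np.allclose(persp, ortho, atol=2.5 / dist)

    def test_mapping_input_returns_mapping(self, default_cam):
        out = project_markers({"GT": np.array([0.0, 1.0, 0.0])}, default_cam)
        assert set(out) == {"GT"}


class TestSynthGRF:
    def test_zero_noise_detection_is_exact(self):
        sig, true_ic = synth_grf(contact_time_s=0.8, duration_s=1.6)
        assert detect_ic_force(sig) == true_ic
        assert sig.samples[true_ic] >= 20.0 > sig.samples[true_ic - 1]

    def test_rate_doubling_doubles_crossing_index(self):
        _, ic1 = synth_grf(contact_time_s=0.8, duration_s=1.6, rate_hz=1000)
        _, ic2 = synth_grf(contact_time_s=0.8, duration_s=1.6, rate_hz=2000)
        assert abs(ic2 - 2 * ic1) <= 1

    def test_peak_near_body_weight(self):
        sig, _ = synth_grf(contact_time_s=0.2, duration_s=1.2, mass_kg=70.0)
        peak = sig.samples.max()
        assert 0.9 * 70 * 9.81 < peak < 1.4 * 70 * 9.81

    def test_contact_outside_recording_raises(self):
        with pytest.raises(GaitSimulationError):
            synth_grf(contact_time_s=2.0, duration_s=1.0)

    def test_noise_requires_rng(self):
        with pytest.raises(GaitSimulationError):
            synth_grf(contact_time_s=0.5, duration_s=1.5, sd_noise_n=2.0)


class TestSimulateTrial:
    def test_zero_noise_measurements_equal_ground_truth(self, subject, ortho_cam):
        trial = simulate_trial(subject, {}, ErrorModel.zero(), ortho_cam,
                               substream(0, 9))
        assert trial.true_angles == subject.profile.ic_targets
        for obs in trial.video_angles:
            for j in JOINTS:
                assert obs[j] == pytest.approx(trial.true_angles[j], abs=1e-9)
        for j in JOINTS:
            assert trial.reference_angles[j] == trial.true_angles[j]

    def test_variance_partition_session_vs_observer(self, subject, ortho_cam):
        # session noise only: the two observers agree exactly with each other
        # (they digitise the same video) but sessions disagree
        err = ErrorModel(sd_session_m=0.004, sd_observer_frame=0.0,
                         sd_digitize_px=0.0, system_bias_deg=0.0,
                         sd_residual_deg=0.0, sd_reference_deg=0.0, sd_force_n=0.0)
        offsets1 = {m: v for m, v in
                    zip(["GT", "LFC", "LM"], substream(5, 2, 1).normal(0, 0.004, (3, 2)))}
        offsets2 = {m: v for m, v in
                    zip(["GT", "LFC", "LM"], substream(5, 2, 2).normal(0, 0.004, (3, 2)))}
        t1 = simulate_trial(subject, offsets1, err, ortho_cam, substream(5, 3, 1))
        t2 = simulate_trial(subject, offsets2, err, ortho_cam, substream(5, 3, 2))
        for j in JOINTS:
            assert t1.video_angles[0][j] == t1.video_angles[1][j]
            assert t2.video_angles[0][j] == t2.video_angles[1][j]
            assert t1.video_angles[0][j] != t2.video_angles[0][j]

    def test_frame_shift_equals_curve_difference(self, subject, ortho_cam):
        trial = simulate_trial(subject, {}, ErrorModel.zero(), ortho_cam, substream(0, 9))
        prof = subject.profile
        frames = [sagittal_view({m: trial.tracks_3d[m][i] for m in trial.tracks_3d},
                                frame_index=i) for i in range(trial.n_frames)]
        ic = trial.true_ic_frame
        dt = 1.0 / (ortho_cam.fps * prof.cycle_duration_s)
        shifted = angles_at_ic(frames, ic + 1)
        at_ic = angles_at_ic(frames, ic)
        expected = float(prof.hip(prof.t_ic + dt)) - float(prof.hip(prof.t_ic))
        assert shifted.hip_deg - at_ic.hip_deg == pytest.approx(expected, abs=1e-9)
        # first-order: shift ~ slope (deg/s) / fps
        slope = prof.slope_deg_per_s("hip", prof.t_ic)
        assert shifted.hip_deg - at_ic.hip_deg == pytest.approx(slope / ortho_cam.fps, rel=0.1)

    def test_force_ground_truth_aligned_with_ic_frame(self, subject, ortho_cam):
        trial = simulate_trial(subject, {}, ErrorModel.zero(), ortho_cam, substream(0, 9))
        ic_time = trial.true_ic_frame / ortho_cam.fps
        crossing_time = trial.true_ic_force_sample / trial.force.rate_hz
        assert crossing_time == pytest.approx(ic_time, abs=0.01)
        assert detect_ic_force(trial.force) == trial.true_ic_force_sample

    def test_kinematic_detector_finds_ic_at_zero_noise(self, ortho_cam, small_config):
        for s in (1, 2, 3):
            subj = sample_subject(small_config, ErrorModel(), substream(4, 1, s), index=s)
            trial = simulate_trial(subj, {}, ErrorModel.zero(), ortho_cam, substream(4, 9, s))
            detected = detect_ic_kinematic(trial.tracks_3d["CAL"][:, 1])
            assert abs(detected - trial.true_ic_frame) <= 1


class TestSimulateCohort:
    def test_row_counts_default_design(self):
        df = simulate_cohort(CohortConfig(n_subjects=4, rng_seed=0))
        # 4 subjects x 2 sessions x 5 reps x 2 observers x 2 systems x 3 joints
        assert len(df) == 4 * 2 * 5 * 2 * 2 * 3
        per_joint = df[df["joint"] == "knee"]
        assert len(per_joint) == 4 * 2 * 5 * 2 * 2

    def test_schema_and_dtypes(self):
        df = simulate_cohort(CohortConfig(n_subjects=2, rng_seed=0))
        assert list(df.columns) == ["subject", "session", "observer", "system",
                                    "repetition", "joint", "angle_deg"]
        assert set(df["system"]) == {"video", "reference"}
        assert np.isfinite(df["angle_deg"]).all()

    def test_seeded_reproducibility_bitwise(self):
        a = simulate_cohort(CohortConfig(n_subjects=3, rng_seed=42))
        b = simulate_cohort(CohortConfig(n_subjects=3, rng_seed=42))
        assert a.equals(b)
        c = simulate_cohort(CohortConfig(n_subjects=3, rng_seed=43))
        assert not a["angle_deg"].equals(c["angle_deg"])

    def test_adding_subjects_does_not_perturb_existing(self):
        small = simulate_cohort(CohortConfig(n_subjects=2, rng_seed=42))
        large = simulate_cohort(CohortConfig(n_subjects=4, rng_seed=42))
        merged = large[large["subject"] <= 2].reset_index(drop=True)
        assert small.equals(merged)

    def test_reference_rows_are_observer_independent(self):
        df = simulate_cohort(CohortConfig(n_subjects=2, rng_seed=1))
        ref = df[df["system"] == "reference"]
        pivot = ref.pivot_table(index=["subject", "session", "repetition", "joint"],
                                columns="observer", values="angle_deg")
        assert np.array_equal(pivot[1].to_numpy(), pivot[2].to_numpy())


class TestVarianceBookkeeping:
    def test_implied_icc_matches_large_cohort_estimate(self):
        """Closed-form ICC from the configured variance components agrees with
        the estimate on a large simulated cohort to within 0.02 (single fixed
        seed; Monte Carlo SE at n=1600 is well below the tolerance)."""
        err = ErrorModel()
        cam = CameraModel()
        imp_intra = implied_icc(err, contrast="intra_rater", cam=cam)
        imp_inter = implied_icc(err, contrast="inter_rater", cam=cam)
        df = simulate_cohort(CohortConfig(n_subjects=1600, rng_seed=7), err, cam)
        res = analyze_cohort(df)
        for j in JOINTS:
            est_intra = 0.5 * (res["intra_observer_1"][j]["icc_abs"].estimate
                               + res["intra_observer_2"][j]["icc_abs"].estimate)
            est_inter = res["inter_rater"][j]["icc_abs"].estimate
            assert est_intra == pytest.approx(imp_intra[j], abs=0.02)
            assert est_inter == pytest.approx(imp_inter[j], abs=0.02)


class TestErrorModelValidation:
    def test_negative_sd_raises(self):
        with pytest.raises(GaitSimulationError):
            ErrorModel(sd_session_m=-0.001)

    def test_zero_model_is_all_zeros(self):
        z = ErrorModel.zero()
        assert all(v == 0 for v in z.sd_subject.values())
        assert all(v == 0 for v in z.system_bias_deg.values())
        assert z.sd_session_m == z.sd_digitize_px == z.sd_residual_deg == 0

    def test_config_counts_validated(self):
        with pytest.raises(GaitSimulationError):
            CohortConfig(n_subjects=0)
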