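"""Generator contracts: projectile closed forms, cohort statistics,
stereo rendering and raceway event logs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import toadhop as th
from toadhop.errors import ParameterError
from toadhop.synthetic import GRAVITY_CM_S2, simulate_raceway_trial


def closed_form_range(v, elev_deg, g=GRAVITY_CM_S2):
    return v ** 2 * np.sin(np.radians(2 * elev_deg)) / g


def closed_form_apex(v, elev_deg, g=GRAVITY_CM_S2):
    return (v * np.sin(np.radians(elev_deg))) ** 2 / (2 * g)


class TestSimulateJump:
    @pytest.mark.parametrize("v,elev", [(300.0, 45.0), (250.0, 30.0), (400.0, 60.0)])
    def test_ground_truth_matches_projectile_closed_forms(self, v, elev):
        traj, truth = th.simulate_jump(
            th.JumpParams(takeoff_speed=v, takeoff_elevation=elev), fps=240)
        assert truth.distance == pytest.approx(closed_form_range(v, elev), rel=1e-9)
        assert truth.height == pytest.approx(closed_form_apex(v, elev), rel=1e-9)

    def test_known_range_and_apex_values(self):
        # v=300 cm/s at 45 deg: range 300^2/981 = 91.743 cm, apex 45000/1962
        _, truth = th.simulate_jump(
            th.JumpParams(takeoff_speed=300.0, takeoff_elevation=45.0), fps=240)
        assert truth.distance == pytest.approx(91.74311926605505, rel=1e-9)
        assert truth.height == pytest.approx(22.93577981651376, rel=1e-9)

    def test_vertical_jump_has_zero_range(self):
        _, truth = th.simulate_jump(
            th.JumpParams(takeoff_speed=200.0, takeoff_elevation=90.0), fps=240)
        assert truth.distance == pytest.approx(0.0, abs=1e-9)

    def test_planted_body_angles_bound_the_flight(self):
        traj, truth = th.simulate_jump(
            th.JumpParams(body_angle_takeoff=31.78, body_angle_landing=-22.18),
            fps=240)
        body = traj.body_vectors
        first = np.degrees(np.arctan2(body[0, 2], np.hypot(body[0, 0], body[0, 1])))
        last = np.degrees(np.arctan2(body[-1, 2], np.hypot(body[-1, 0], body[-1, 1])))
        assert first == pytest.approx(31.78, abs=1e-9)
        assert last == pytest.approx(-22.18, abs=1e-9)

    def test_frame_spacing_is_one_over_fps(self):
        traj, _ = th.simulate_jump(th.JumpParams(), fps=240)
        assert np.allclose(np.diff(traj.timestamps), 1.0 / 240.0)

    @pytest.mark.parametrize("kwargs", [
        {"takeoff_speed": -1.0}, {"takeoff_speed": 0.0},
        {"takeoff_elevation": 0.0}, {"takeoff_elevation": 95.0},
        {"body_length_axis": -2.0}, {"gravity": 0.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            th.JumpParams(**kwargs)

    def test_non_positive_fps_rejected(self):
        with pytest.raises(ParameterError):
            th.simulate_jump(th.JumpParams(), fps=0)

    @given(v=st.floats(150, 450), elev=st.floats(15, 75))
    def test_range_and_apex_closed_forms_property(self, v, elev):
        _, truth = th.simulate_jump(
            th.JumpParams(takeoff_speed=v, takeoff_elevation=elev), fps=240)
        assert truth.distance == pytest.approx(closed_form_range(v, elev), rel=1e-9)
        assert truth.height == pytest.approx(closed_form_apex(v, elev), rel=1e-9)


class TestSimulateCohort:
    def test_large_sample_mean_svl_converges_to_preset(self):
        spec = th.cohort_preset("F0", "range-core", "female")
        records = [r for r, _ in th.simulate_cohort(spec, seed=7, n=10_000)]
        svl = np.array([r.svl for r in records])
        # sample-mean sd = se*sqrt(n)/sqrt(N); allow 4 sigma
        tol = 4 * spec.trait_ses["svl"] * np.sqrt(spec.n) / np.sqrt(10_000)
        assert abs(svl.mean() - 110.06) < tol

    def test_planted_jump_distance_mean_converges(self):
        spec = th.cohort_preset("F0", "invasion-front", "female")
        g = GRAVITY_CM_S2
        cohort = th.simulate_cohort(spec, seed=8, n=10_000)
        ranges = [closed_form_range(p.takeoff_speed, p.takeoff_elevation, g)
                  for _, p in cohort]
        tol = 4 * spec.trait_ses["distance"] * np.sqrt(spec.n) / np.sqrt(10_000)
        assert np.mean(ranges) == pytest.approx(67.21, abs=tol)

    def test_same_seed_identical_draws(self):
        spec = th.cohort_preset("F1", "range-core", "male")
        a = th.simulate_cohort(spec, seed=5)
        b = th.simulate_cohort(spec, seed=5)
        assert len(a) == spec.n == 29
        for (ra, pa), (rb, pb) in zip(a, b):
            assert ra == rb
            assert pa == pb

    def test_near_degenerate_spread_pins_traits_to_means(self):
        spec = th.cohort_preset("F0", "range-core", "female")
        tiny = th.CohortSpec(
            generation=spec.generation,
            invasion_category=spec.invasion_category,
            sex_class=spec.sex_class, n=spec.n,
            trait_means=dict(spec.trait_means),
            trait_ses={t: 1e-12 for t in spec.trait_ses},
        )
        records = [r for r, _ in th.simulate_cohort(tiny, seed=1, n=20)]
        assert np.allclose([r.svl for r in records], 110.06, atol=1e-6)
        assert np.allclose([r.femur for r in records], 45.85, atol=1e-6)

    def test_allometry_couples_traits_to_svl(self):
        spec = th.cohort_preset("F0", "invasion-front", "male")
        records = [r for r, _ in th.simulate_cohort(spec, seed=3, n=4000,
                                                    allometry_corr=0.7)]
        svl = np.array([r.svl for r in records])
        femur = np.array([r.femur for r in records])
        assert np.corrcoef(svl, femur)[0, 1] == pytest.approx(0.7, abs=0.05)

    def test_juveniles_respect_svl_cutoff(self):
        spec = th.cohort_preset("F1", "range-core", "juvenile")
        records = [r for r, _ in th.simulate_cohort(spec, seed=2, n=500)]
        assert max(r.svl for r in records) < 90.0

    def test_unknown_preset_lists_valid_labels(self):
        with pytest.raises(ParameterError, match="F0/range-core/female"):
            th.cohort_preset("F0", "range-core", "tadpole")

    def test_every_table_row_maps_to_one_preset(self):
        assert len(th.COHORT_PRESETS) == 10
        assert sum(s.n for s in th.COHORT_PRESETS.values()) == 311


class TestRenderStereo:
    def test_noiseless_projection_is_exact(self, noiseless_rig):
        traj, _ = th.simulate_jump(th.JumpParams(), noiseless_rig.fps)
        obs, _tr = th.render_stereo(traj, noiseless_rig, seed=0)
        left = obs[(obs.camera == "left") & (obs.landmark == "cloaca")]
        px, _ = noiseless_rig.left.project(traj.cloaca)
        got = left.sort_values("frame")[["u", "v"]].to_numpy()
        assert np.abs(got - px).max() < 1e-9

    def test_planted_sync_offset_shifts_flash(self):
        rig = th.default_rig(pixel_noise_sd=0.0, sync_offset_frames=3)
        traj, _ = th.simulate_jump(th.JumpParams(), rig.fps)
        _, traces = th.render_stereo(traj, rig, flash_frame=10, seed=0)
        assert int(np.argmax(traces["right"])) - int(np.argmax(traces["left"])) == 3

    def test_pixel_noise_rms_matches_planted_sd(self):
        rig = th.default_rig(pixel_noise_sd=0.5)
        traj, _ = th.simulate_jump(th.JumpParams(), rig.fps)
        noisy, _ = th.render_stereo(traj, rig, seed=4)
        clean, _ = th.render_stereo(traj, th.default_rig(pixel_noise_sd=0.0), seed=4)
        key = ["camera", "frame", "landmark"]
        d = (noisy.set_index(key)[["u", "v"]] - clean.set_index(key)[["u", "v"]])
        rms = np.sqrt(np.mean(d.to_numpy() ** 2))
        assert rms == pytest.approx(0.5, abs=0.05)

    def test_point_behind_camera_flagged_not_dropped(self, noiseless_rig):
        n = 10
        base = np.tile([50.0, 0.0, 5.0], (n, 1))
        behind = base.copy()
        behind[5] = [50.0, -400.0, 5.0]  # behind the camera plane
        traj = th.Trajectory3D(np.arange(n) / 240.0, behind + [0, 0, 2], behind,
                               frame_rate=240.0)
        obs, _ = th.render_stereo(traj, noiseless_rig, seed=0)
        flags = obs[(obs.camera == "left") & (obs.landmark == "cloaca")]
        flags = flags.sort_values("frame")["visible"].to_numpy()
        assert not flags[5] and flags[[0, 1, 2, 3, 4, 6, 7, 8, 9]].all()
        assert len(flags) == n


class TestCheckerboardViews:
    def test_corners_coplanar_and_counted(self, noiseless_rig):
        views = th.generate_checkerboard_views(noiseless_rig, 10, seed=3)
        assert len(views) == 10
        for v in views:
            assert len(v.corners_3d) == v.rows * v.cols
            assert np.ptp(v.corners_3d[:, 2]) < 1e-12

    def test_clean_views_pass_qc_corrupted_view_fails(self, calibrated):
        rig, left, right, _views, _ = calibrated
        corrupted = th.generate_checkerboard_views(
            rig, 10, seed=9, corruption=[0.0] * 4 + [0.05] + [0.0] * 5)
        _, _, reports = th.calibrate_rig(corrupted)
        rejected = [r.view_id for r in reports if not r.accepted]
        assert rejected == [4]

    def test_n_poses_must_be_positive(self, noiseless_rig):
        with pytest.raises(ParameterError):
            th.generate_checkerboard_views(noiseless_rig, 0, seed=1)

    def test_same_seed_reproduces_views(self, noiseless_rig):
        a = th.generate_checkerboard_views(noiseless_rig, 5, seed=11)
        b = th.generate_checkerboard_views(noiseless_rig, 5, seed=11)
        for va, vb in zip(a, b):
            assert np.array_equal(va.corners_px_left, vb.corners_px_left)
            assert np.array_equal(va.pose_translation, vb.pose_translation)


class TestSimulateRaceway:
    def test_constant_half_metre_hops_finish_in_thirty(self):
        trial = simulate_raceway_trial(0.5, 0.0, 1.0, 0.0, seed=0)
        assert len(trial.hops) == 30
        assert trial.finished and not trial.terminated_early

    def test_certain_refusal_terminates_without_hops(self):
        trial = simulate_raceway_trial(0.5, 0.1, 1.0, 1.0, seed=0)
        assert len(trial.hops) == 0
        assert trial.terminated_early
        assert len(trial.refusals) == 10

    def test_recovered_mean_hop_within_monte_carlo_bound(self):
        trial = simulate_raceway_trial(0.6, 0.1, 2.0, 0.0, seed=12)
        hops = np.diff(np.concatenate([[0.0], trial.hops[:, 1]]))
        assert abs(hops.mean() - 0.6) < 2 * 0.1 / np.sqrt(len(hops))

    @pytest.mark.parametrize("kwargs", [
        {"hop_distance_mean": 0.0}, {"hop_interval_s": 0.0},
        {"refusal_prob": -0.1}, {"refusal_prob": 1.5},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(hop_distance_mean=0.5, hop_distance_sd=0.1,
                    hop_interval_s=1.0, refusal_prob=0.0)
        base.update(kwargs)
        with pytest.raises(ParameterError):
            simulate_raceway_trial(**base, seed=0)
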