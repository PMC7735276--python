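"""Alignment, hop detection, kinematic extraction and best-jump selection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import toadhop as th
from toadhop.errors import (
    HeadingUndefinedError,
    InsufficientFramesError,
    NoDataError,
    NoJumpDetectedError,
)
from toadhop.kinematics import JumpKinematics
from toadhop.stereo import Trajectory3D


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def rotate(traj, R, shift=(0.0, 0.0, 0.0)):
    return Trajectory3D(traj.timestamps.copy(), traj.snout @ R.T + shift,
                        traj.cloaca @ R.T + shift, traj.frame_rate)


def extract(traj, epsilon=0.1):
    aligned = th.align_trajectory(traj) if not traj.aligned else traj
    t0, t1 = th.detect_takeoff_landing(aligned, epsilon)
    return th.extract_kinematics(aligned, t0, t1)


class TestAlignTrajectory:
    def test_planar_trajectory_unchanged_up_to_translation(self):
        traj, _ = th.simulate_jump(th.JumpParams(takeoff_point=(5.0, 0.0, 2.0)),
                                   240)
        aligned = th.align_trajectory(traj)
        assert np.abs(aligned.cloaca - (traj.cloaca - traj.cloaca[0])).max() < 1e-9
        assert np.abs(aligned.cloaca[:, 1]).max() < 1e-9

    def test_rotation_about_vertical_is_removed(self):
        traj, _ = th.simulate_jump(th.JumpParams(), 240)
        a0 = th.align_trajectory(traj)
        R = random_rotation(np.random.default_rng(0))  # arbitrary rotation
        Rz37 = np.array([
            [np.cos(np.radians(37)), -np.sin(np.radians(37)), 0],
            [np.sin(np.radians(37)), np.cos(np.radians(37)), 0],
            [0, 0, 1.0]])
        a1 = th.align_trajectory(rotate(traj, Rz37, shift=(7.0, -3.0, 1.0)))
        assert np.abs(a1.cloaca - a0.cloaca).max() < 1e-9
        assert np.abs(a1.snout - a0.snout).max() < 1e-9

    def test_rigidity_preserves_all_distances(self, rng):
        traj, _ = th.simulate_jump(th.JumpParams(azimuth=8.0), 240)
        aligned = th.align_trajectory(traj)
        d0 = np.linalg.norm(traj.snout - traj.cloaca, axis=1)
        d1 = np.linalg.norm(aligned.snout - aligned.cloaca, axis=1)
        assert np.abs(d1 - d0).max() < 1e-9 * d0.max()
        step0 = np.linalg.norm(np.diff(traj.cloaca, axis=0), axis=1)
        step1 = np.linalg.norm(np.diff(aligned.cloaca, axis=0), axis=1)
        assert np.abs(step1 - step0).max() < 1e-9 * (step0.max() + 1)

    def test_lateral_noise_is_least_squares_small(self, rng):
        traj, _ = th.simulate_jump(th.JumpParams(), 240)
        noise = rng.normal(0, 0.2, len(traj))
        lateral = np.column_stack([np.zeros(len(traj)), noise,
                                   np.zeros(len(traj))])
        noisy = Trajectory3D(traj.timestamps, traj.snout + lateral,
                             traj.cloaca + lateral, traj.frame_rate)
        aligned = th.align_trajectory(noisy)
        rms_y = np.sqrt(np.mean(aligned.cloaca[:, 1] ** 2))
        # least-squares contract: residual lateral RMS cannot exceed the
        # RMS of the planted lateral perturbations
        assert rms_y <= np.sqrt(np.mean(noise ** 2))
        assert rms_y <= 0.25

    def test_vertical_hop_has_undefined_heading(self):
        traj, _ = th.simulate_jump(
            th.JumpParams(takeoff_speed=200.0, takeoff_elevation=90.0), 240)
        with pytest.raises(HeadingUndefinedError):
            th.align_trajectory(traj)


class TestDetectTakeoffLanding:
    def test_bracket_matches_analytic_flight_time(self):
        p = th.JumpParams(takeoff_speed=280.0, takeoff_elevation=42.0)
        traj, truth = th.simulate_jump(p, 240)
        aligned = th.align_trajectory(traj)
        t0, t1 = th.detect_takeoff_landing(aligned, 0.1)
        measured = (t1 - t0) / 240.0
        assert abs(measured - truth.flight_time) <= 1.0 / 240.0
        assert t0 < t0 + np.argmax(aligned.cloaca[t0:, 2]) < t1

    def test_flat_trajectory_is_no_jump(self):
        n = 40
        c = np.tile([0.0, 0.0, 0.0], (n, 1))
        traj = Trajectory3D(np.arange(n) / 240.0, c + [10, 0, 1], c, 240.0,
                            aligned=True)
        with pytest.raises(NoJumpDetectedError):
            th.detect_takeoff_landing(traj, 0.1)

    def test_epsilon_above_apex_is_no_jump(self):
        traj, truth = th.simulate_jump(th.JumpParams(), 240)
        aligned = th.align_trajectory(traj)
        with pytest.raises(NoJumpDetectedError):
            th.detect_takeoff_landing(aligned, truth.height + 1.0)


class TestExtractKinematics:
    def test_published_maximum_distance_recovery(self):
        # 342.96 cm/s at 45 deg -> 119.9 cm range
        p = th.JumpParams(takeoff_speed=342.96, takeoff_elevation=45.0)
        k = extract(th.simulate_jump(p, 240)[0])
        assert k.distance == pytest.approx(119.9, abs=342.96 / 240.0)

    def test_published_maximum_height_recovery(self):
        # vertical speed 216.54 cm/s -> apex 23.9 cm
        elev = 80.0
        p = th.JumpParams(takeoff_speed=216.54 / np.sin(np.radians(elev)),
                          takeoff_elevation=elev)
        k = extract(th.simulate_jump(p, 240)[0])
        assert k.height == pytest.approx(23.9, abs=0.5)

    def test_constructed_body_vector_angles(self):
        n = 60
        t = np.arange(n) / 240.0
        z = 20.0 * np.sin(np.pi * np.clip((t - 0.02) / 0.15, 0, 1))
        cloaca = np.column_stack([np.linspace(0, 50, n), np.zeros(n), z])
        elev = np.where(t < 0.1, np.radians(30.0), np.radians(-30.0))
        body = np.column_stack([np.cos(elev), np.zeros(n), np.sin(elev)])
        traj = Trajectory3D(t, cloaca + 11.0 * body, cloaca, 240.0, aligned=True)
        t0, t1 = th.detect_takeoff_landing(traj, 0.1)
        k = th.extract_kinematics(traj, t0, t1)
        assert k.angle_takeoff == pytest.approx(30.0, abs=1e-9)
        assert k.angle_landing == pytest.approx(-30.0, abs=1e-9)

    def test_planted_body_angles_recovered_via_pipeline(self):
        p = th.JumpParams(body_angle_takeoff=31.78, body_angle_landing=-22.18)
        k = extract(th.simulate_jump(p, 240)[0])
        assert k.angle_takeoff == pytest.approx(31.78, abs=0.5)
        assert k.angle_landing == pytest.approx(-22.18, abs=0.5)

    def test_too_short_bracket_rejected(self):
        traj, _ = th.simulate_jump(th.JumpParams(), 240)
        aligned = th.align_trajectory(traj)
        with pytest.raises(InsufficientFramesError):
            th.extract_kinematics(aligned, 5, 6)

    @given(v=st.floats(180, 420), elev=st.floats(20, 70),
           az=st.floats(-10, 10))
    def test_velocity_and_distance_invariants(self, v, elev, az):
        p = th.JumpParams(takeoff_speed=v, takeoff_elevation=elev, azimuth=az)
        traj, truth = th.simulate_jump(p, 240)
        k = extract(traj)
        assert k.max_velocity >= k.mean_velocity > 0
        assert k.distance >= 0 and k.height >= 0
        flight = truth.flight_time + 2.0 / 240.0
        assert k.distance <= k.max_velocity * flight


class TestEndToEndPlantedRecovery:
    def test_full_noiseless_chain_reproduces_planted_values(self, calibrated):
        rig, left, right, *_ = calibrated
        p = th.JumpParams(takeoff_speed=310.0, takeoff_elevation=38.0,
                          azimuth=-6.0, takeoff_point=(-5.0, 4.0, 0.0),
                          body_angle_takeoff=28.0, body_angle_landing=-19.0)
        traj, truth = th.simulate_jump(p, rig.fps)
        obs, traces = th.render_stereo(traj, rig, seed=0)
        off = th.estimate_sync_offset(traces["left"], traces["right"])
        raw = th.reconstruct_trajectory(obs, left, right, off, rig.fps)
        k = extract(th.align_trajectory(raw))
        quant = p.takeoff_speed / rig.fps
        assert k.distance == pytest.approx(truth.distance, abs=quant)
        assert k.height == pytest.approx(truth.height, abs=quant)
        assert k.angle_takeoff == pytest.approx(28.0, abs=0.5)
        assert k.angle_landing == pytest.approx(-19.0, abs=0.5)

    def test_alignment_invariance_of_kinematics(self, rng):
        traj, _ = th.simulate_jump(th.JumpParams(azimuth=5.0), 240)
        base = extract(th.align_trajectory(traj))
        for _ in range(20):
            R = random_rotation(rng)
            rotated = rotate(traj, R, shift=rng.normal(0, 10, 3))
            aligned = th.align_trajectory(rotated, vertical_axis=R[:, 2])
            k = extract(aligned)
            for attr in ("mean_velocity", "max_velocity", "distance",
                         "height", "angle_takeoff", "angle_landing"):
                assert getattr(k, attr) == pytest.approx(
                    getattr(base, attr), abs=1e-6)


class TestSelectBestJump:
    def kin(self, distance, trial):
        return JumpKinematics(mean_velocity=150.0, max_velocity=300.0,
                              distance=distance, height=10.0,
                              angle_takeoff=30.0, angle_landing=-20.0,
                              trial_id=trial)

    def test_longest_hop_wins(self):
        best = th.select_best_jump([self.kin(60.13, "t1"), self.kin(50.0, "t2")])
        assert best.distance == 60.13

    def test_single_jump_returned(self):
        only = self.kin(40.0, "t1")
        assert th.select_best_jump([only]) is only

    def test_tie_broken_by_earliest_trial(self):
        best = th.select_best_jump([self.kin(55.0, "t9"), self.kin(55.0, "t2")])
        assert best.trial_id == "t2"

    def test_empty_list_raises(self):
        with pytest.raises(NoDataError):
            th.select_best_jump([])
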