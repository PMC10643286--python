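"""World alignment: plane fitting, the two rotations, t0 and the translation."""

import numpy as np
import pytest

import stereoflight as sf
from stereoflight.alignment import (
    AlignmentError,
    NoWaterContactError,
    align_frame,
    assign_t0,
    fit_plane,
)
from stereoflight.synthetic import DEFAULT_LANDMARKS, shadow_points


def aligned_fixture(seed=1, sun_azimuth=0.0):
    """A generated flight already expressed in the analysis frame conventions."""
    cfg = sf.synthetic.replace_config(sf.FlightConfig(), sun_azimuth=sun_azimuth)
    flight = sf.generate_flight(cfg, rng_seed=seed)
    base, tip = shadow_points(sun_azimuth)
    return flight, DEFAULT_LANDMARKS.copy(), tip - base


class TestFitPlane:
    def test_flat_landmarks(self):
        normal, _, rmse = fit_plane(DEFAULT_LANDMARKS)
        assert abs(abs(normal[2]) - 1.0) < 1e-12
        assert rmse < 1e-12

    def test_noisy_plane_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-200, 200, (40, 2))
        z = 2.0 * x[:, 0] + 3.0 + rng.normal(0, 0.1, 40)
        pts = np.column_stack([x, z])
        normal, _, rmse = fit_plane(pts)
        true_n = np.array([-2.0, 0.0, 1.0]) / np.sqrt(5.0)
        angle = np.degrees(np.arccos(np.clip(abs(normal @ true_n), -1, 1)))
        assert angle < 0.5
        # TLS residuals are perpendicular distances: sd 0.1 in z is 0.1/sqrt(5)
        assert 0.02 < rmse < 0.1

    def test_collinear_landmarks_rejected(self):
        pts = np.outer(np.arange(4.0), [1.0, 2.0, 0.5])
        with pytest.raises(AlignmentError):
            fit_plane(pts)

    def test_too_few_landmarks_rejected(self):
        with pytest.raises(ValueError):
            fit_plane(np.eye(3))


class TestAssignT0:
    def test_recovers_generator_truth_within_one_frame(self):
        flight = sf.generate_flight(sf.FlightConfig(), rng_seed=3)
        alt = flight.com[:, 2] - flight.com[:, 2].min()
        vz = np.gradient(alt, 1.0 / flight.fs)
        t0 = assign_t0(alt, vz, contact_threshold=10.0)
        assert abs(t0 - flight.true_contact_index[0]) <= 1

    def test_monotone_climb_rejected(self):
        alt = np.linspace(0.0, 500.0, 200)
        vz = np.gradient(alt, 0.004)
        with pytest.raises(NoWaterContactError):
            assign_t0(alt, vz)

    def test_never_below_threshold_rejected(self):
        alt = 50.0 + 10.0 * np.sin(np.linspace(0, 6, 300))
        vz = np.gradient(alt, 0.004)
        with pytest.raises(NoWaterContactError):
            assign_t0(alt - alt.min() + 20.0, vz)

    def test_manual_override_returned_verbatim(self):
        assert assign_t0(np.zeros(5), np.zeros(5), t0_frame=3) == 3


class TestAlignFrame:
    def test_already_aligned_input_gives_identity(self):
        flight, landmarks, shadow = aligned_fixture(sun_azimuth=0.0)
        traj, frame = align_frame(flight.front, flight.rear, landmarks, shadow, fs=flight.fs)
        assert np.allclose(frame.rotation, np.eye(3), atol=1e-9)
        # the fly drifts on the water, so the lowest point sits a few mm from
        # the generator's nominal contact point; well under a body length
        assert np.linalg.norm(frame.translation[:2]) < 15.0
        assert frame.shadow_elevation_deg < 1e-6

    def test_known_sun_azimuth_rotated_out(self):
        flight, landmarks, shadow = aligned_fixture(seed=5, sun_azimuth=137.0)
        rng = np.random.default_rng(8)
        R, t = sf.synthetic.random_rigid_transform(rng)
        traj, frame = align_frame(
            flight.front @ R.T + t, flight.rear @ R.T + t, landmarks @ R.T + t, R @ shadow,
            fs=flight.fs,
        )
        # after alignment the shadow must point along -X exactly
        sh = frame.rotation @ (R @ shadow)
        assert abs(np.degrees(np.arctan2(sh[1], sh[0]))) > 180.0 - 1e-6
        assert abs(sh[2]) < 1e-6 * np.linalg.norm(sh)
        # and the flight matches the generator's own frame rotated by -sun_azimuth
        sa = np.radians(flight.sun_azimuth)
        Rz = np.array(
            [[np.cos(-sa), -np.sin(-sa), 0.0], [np.sin(-sa), np.cos(-sa), 0.0], [0.0, 0.0, 1.0]]
        )
        expected = flight.com @ Rz.T
        delta = traj.com - expected
        assert np.std(delta - delta.mean(axis=0)) < 1e-6  # rigid: constant offset only

    def test_alignment_is_rigid(self):
        flight, landmarks, shadow = aligned_fixture(seed=2, sun_azimuth=60.0)
        rng = np.random.default_rng(12)
        R, t = sf.synthetic.random_rigid_transform(rng)
        traj, _ = align_frame(
            flight.front @ R.T + t, flight.rear @ R.T + t, landmarks @ R.T + t, R @ shadow,
            fs=flight.fs,
        )
        idx = rng.integers(0, len(flight), 50)
        jdx = rng.integers(0, len(flight), 50)
        before = np.linalg.norm(flight.front[idx] - flight.rear[jdx], axis=1)
        after = np.linalg.norm(traj.front[idx] - traj.rear[jdx], axis=1)
        assert np.allclose(after, before, rtol=1e-9, atol=1e-9)

    def test_idempotent(self):
        flight, landmarks, shadow = aligned_fixture(seed=4, sun_azimuth=200.0)
        traj1, f1 = align_frame(flight.front, flight.rear, landmarks, shadow, fs=flight.fs)
        lm1 = landmarks @ f1.rotation.T - f1.translation
        sh1 = f1.rotation @ shadow
        traj2, f2 = align_frame(traj1.front, traj1.rear, lm1, sh1, fs=flight.fs)
        assert np.allclose(f2.rotation, np.eye(3), atol=1e-9)
        assert np.linalg.norm(f2.translation) < 1e-6
        assert np.allclose(traj2.front, traj1.front, atol=1e-6)

    def test_contact_point_is_origin(self):
        flight, landmarks, shadow = aligned_fixture(seed=6)
        traj, frame = align_frame(flight.front, flight.rear, landmarks, shadow, fs=flight.fs)
        k = frame.t0_index
        landing = traj.com[max(0, k - 5) : k + int(0.12 * flight.fs)]
        assert np.linalg.norm(landing, axis=1).min() < 2.0  # mm

    def test_shadow_parallel_to_normal_rejected(self):
        flight, landmarks, _ = aligned_fixture(seed=7)
        with pytest.raises(AlignmentError):
            align_frame(flight.front, flight.rear, landmarks, np.array([0.0, 0.0, 1.0]),
                        fs=flight.fs)
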