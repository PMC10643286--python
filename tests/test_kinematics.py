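"""Filtering, upsampling, derivatives, angles and path curvature."""

import numpy as np
import pytest

import stereoflight as sf
from stereoflight.alignment import Trajectory3D
from stereoflight.kinematics import (
    CURVATURE_CAP_MM,
    centre_of_mass,
    compute_kinematics,
    curvature_radius,
    lowpass_filter,
    upsample,
    wrap_angle,
)


class TestLowpass:
    def test_dc_gain_is_one(self):
        x = np.full(300, 7.3)
        assert np.allclose(lowpass_filter(x, fs=250.0), x, atol=1e-9)

    def test_passband_sine_preserved(self):
        t = np.arange(1000) / 250.0
        x = np.sin(2 * np.pi * 10.0 * t)
        y = lowpass_filter(x, fs=250.0, cutoff=100.0)
        interior = slice(100, -100)
        assert np.abs(y[interior]).max() >= 0.99

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(100), fs=250.0, cutoff=125.0)

    def test_filter_and_derivative_commute_in_the_interior(self):
        rng = np.random.default_rng(0)
        t = np.arange(2000) / 250.0
        x = np.sin(2 * np.pi * 3 * t) + 0.3 * rng.normal(size=t.size)
        a = np.gradient(lowpass_filter(x, fs=250.0), 1 / 250.0)
        b = lowpass_filter(np.gradient(x, 1 / 250.0), fs=250.0)
        mid = slice(300, -300)
        assert np.allclose(a[mid], b[mid], atol=1e-6 * np.abs(b[mid]).max())


class TestUpsample:
    def test_linear_ramp_exact(self):
        x = np.arange(10.0)
        y = upsample(x, 3)
        assert np.allclose(y, np.arange(28) / 3.0, atol=1e-12)

    def test_length_contract(self):
        assert upsample(np.zeros(50), 3).shape[0] == 3 * 49 + 1

    def test_original_samples_preserved(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        assert np.allclose(upsample(x, 3)[::3], x, atol=1e-9)

    def test_sine_interpolation_error_small(self):
        t = np.arange(250) / 250.0
        x = np.sin(2 * np.pi * 10.0 * t)
        y = upsample(x, 3)
        tf = np.arange(3 * 249 + 1) / 750.0
        assert np.abs(y - np.sin(2 * np.pi * 10.0 * tf)).max() < 1e-3

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            upsample(np.zeros(10), 0)


class TestCentreOfMass:
    def test_midpoint(self):
        assert np.allclose(centre_of_mass(np.array([2.0, 0, 0]), np.zeros(3)), [1.0, 0, 0])

    def test_coincident_points(self):
        p = np.array([1.0, 2.0, 3.0])
        assert np.allclose(centre_of_mass(p, p), p)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            centre_of_mass(np.zeros((5, 3)), np.zeros((4, 3)))


class TestCurvature:
    def test_circle_radius_recovered(self):
        # slow traversal so optional smoothing would not distort either
        theta = np.linspace(0, 2 * np.pi, 2000)
        xy = 100.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        r = curvature_radius(xy, dt=0.004)
        assert np.allclose(r[20:-20], 100.0, atol=1.0)

    def test_straight_line_hits_cap(self):
        xy = np.column_stack([np.linspace(0, 100, 200), np.zeros(200)])
        r = curvature_radius(xy, dt=0.004)
        assert np.all(r[5:-5] == CURVATURE_CAP_MM)

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            curvature_radius(np.zeros((2, 2)), dt=0.004)


def straight_trajectory(direction_deg=0.0, speed=1.0, vz=0.0, n=200, fs=250.0):
    """Level flight along a fixed compass direction, body axis along travel."""
    t = np.arange(n) / fs
    d = np.radians(direction_deg)
    com = np.column_stack(
        [1000.0 * speed * t * np.cos(d), 1000.0 * speed * t * np.sin(d),
         100.0 + 1000.0 * vz * t]
    )
    axis = 11.0 * np.array([np.cos(d), np.sin(d), 0.0])
    return Trajectory3D(t=t - 0.2, front=com + axis, rear=com - axis, fs=fs)


class TestComputeKinematics:
    def test_level_flight_along_minus_x(self):
        kin = compute_kinematics(straight_trajectory(180.0, speed=1.0))
        mid = slice(30, -30)
        assert np.allclose(np.abs(kin.bearing[mid]), 180.0, atol=1e-6)
        assert np.allclose(np.abs(kin.heading[mid]), 180.0, atol=1e-6)
        assert np.allclose(kin.vertical_velocity[mid], 0.0, atol=1e-9)
        # small passband ripple from the 100 Hz zero-phase filter
        assert np.allclose(kin.horizontal_speed[mid], 1.0, atol=1e-3)

    def test_body_along_plus_x_gives_zero_heading(self):
        kin = compute_kinematics(straight_trajectory(0.0))
        assert np.allclose(kin.heading[30:-30], 0.0, atol=1e-6)
        assert np.allclose(kin.pitch[30:-30], 0.0, atol=1e-9)

    def test_speed_pythagoras_identity(self, clean_run):
        _, _, res = clean_run
        kin = res.kinematics
        assert np.allclose(
            kin.total_speed**2,
            kin.horizontal_speed**2 + kin.vertical_velocity**2,
            rtol=1e-12,
        )
        assert np.allclose(kin.vertical_speed, np.abs(kin.vertical_velocity))

    def test_bearing_undefined_below_speed_floor(self):
        kin = compute_kinematics(straight_trajectory(45.0, speed=0.01))
        assert np.isnan(kin.bearing).all()
        assert not np.isnan(kin.heading).any()  # heading needs no motion

    def test_rotation_shifts_angles_translation_does_not(self):
        traj = straight_trajectory(30.0, speed=1.2, vz=0.1)
        kin0 = compute_kinematics(traj)
        delta = 25.0
        c, s = np.cos(np.radians(delta)), np.sin(np.radians(delta))
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        rotated = Trajectory3D(
            t=traj.t, front=traj.front @ R.T, rear=traj.rear @ R.T, fs=traj.fs
        )
        shifted = Trajectory3D(
            t=traj.t, front=traj.front + [5.0, -3.0, 2.0], rear=traj.rear + [5.0, -3.0, 2.0],
            fs=traj.fs,
        )
        kin_r = compute_kinematics(rotated)
        kin_s = compute_kinematics(shifted)
        mid = slice(30, -30)
        assert np.allclose(
            wrap_angle(kin_r.bearing[mid] - kin0.bearing[mid]), delta, atol=1e-6
        )
        assert np.allclose(
            wrap_angle(kin_r.heading[mid] - kin0.heading[mid]), delta, atol=1e-6
        )
        for name in ("bearing", "heading", "pitch"):
            assert np.allclose(getattr(kin_s, name), getattr(kin0, name),
                               atol=1e-9, equal_nan=True)

    def test_time_step_is_upsampled(self, clean_run):
        _, _, res = clean_run
        assert res.kinematics.dt == pytest.approx(1.0 / 750.0)

    def test_phase_mean_speed_recovers_generator_truth(self, clean_run):
        flight, _, res = clean_run
        means = sf.phase_means(res.kinematics, res.phases)
        truth = flight.params["total_speed_approach"]
        assert means["approach"]["total_speed"] == pytest.approx(truth, rel=0.02)


class TestWrapAngle:
    @pytest.mark.parametrize(
        "raw, wrapped", [(0.0, 0.0), (180.0, 180.0), (-180.0, 180.0), (190.0, -170.0),
                         (360.0, 0.0), (-90.0, -90.0)]
    )
    def test_interval_convention(self, raw, wrapped):
        assert wrap_angle(raw) == pytest.approx(wrapped)
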