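"""Ground-truth flight generator and the two-camera projection."""

import numpy as np
import pytest

import stereoflight as sf
from stereoflight.kinematics import wrap_angle
from stereoflight.stereo import triangulate
from stereoflight.sync import decode_counts, synchronise
from stereoflight.synthetic import (
    FlightConfig,
    generate_flight,
    lognormal_from_quartiles,
    project_to_cameras,
    replace_config,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frame_rate": 0.0},
            {"contact_duration_mean": -0.01},
            {"descent_peak_vertical_velocity": 0.4},
            {"body_length": 0.0},
            {"approach_speed_median": -1.0},
            {"inter_camera_offset": -2},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FlightConfig(**kwargs)

    def test_descent_must_fit_into_approach(self, default_config):
        cfg = replace_config(default_config, approach_duration=0.3)
        with pytest.raises(ValueError):
            generate_flight(cfg, rng_seed=0)

    def test_lognormal_matching(self):
        # the match preserves the median and the quartile ratio exactly; the
        # individual quartiles deviate only if the published pair is not
        # log-symmetric about the median
        mu, sigma = lognormal_from_quartiles(1.57, (1.32, 1.79))
        from scipy.stats import lognorm

        dist = lognorm(s=sigma, scale=np.exp(mu))
        assert dist.median() == pytest.approx(1.57)
        assert dist.ppf(0.75) / dist.ppf(0.25) == pytest.approx(1.79 / 1.32, rel=1e-9)
        assert dist.ppf(0.25) == pytest.approx(1.32, rel=0.03)


class TestGenerateFlight:
    def test_deterministic_given_seed(self, default_config):
        a = generate_flight(default_config, rng_seed=1)
        b = generate_flight(default_config, rng_seed=1)
        c = generate_flight(default_config, rng_seed=2)
        assert np.array_equal(a.front, b.front)
        assert a.true_segment_boundaries == b.true_segment_boundaries
        assert not np.array_equal(a.front, c.front)

    def test_no_saccades_straight_approach_single_segment(self, default_config):
        cfg = replace_config(default_config, saccade_rate=0.0, steady_turn_radius=None)
        flight = generate_flight(cfg, rng_seed=3)
        assert not (flight.phase_labels == "saccade").any()
        onset = np.flatnonzero(flight.phase_labels == "descent")[0]
        approach_segments = [
            (a, b) for a, b in flight.true_segment_boundaries if b <= onset
        ]
        assert len(approach_segments) == 1

    def test_body_length_constant(self, default_config):
        flight = generate_flight(default_config, rng_seed=4)
        lengths = np.linalg.norm(flight.front - flight.rear, axis=1)
        assert np.allclose(lengths, default_config.body_length, atol=1e-9)

    def test_phase_labels_partition_and_contact_below_threshold(self, default_config):
        flight = generate_flight(default_config, rng_seed=5)
        labels = set(flight.phase_labels)
        assert labels <= {"approach", "saccade", "descent", "contact", "departure"}
        contact = flight.phase_labels == "contact"
        # contact altitude stays below the (contact-referenced) threshold
        rel_alt = flight.com[:, 2] - flight.config.contact_altitude
        assert np.all(rel_alt[contact] < flight.config.landing_threshold)
        i0, i1 = flight.true_contact_index
        assert np.all(contact[i0:i1]) and contact.sum() == i1 - i0
        assert flight.true_contact_interval[0] == pytest.approx(0.0)
        assert flight.t[i0] == pytest.approx(0.0)

    def test_exactly_one_contact_interval(self, default_config):
        flight = generate_flight(default_config, rng_seed=6)
        contact = (flight.phase_labels == "contact").astype(int)
        assert np.sum(np.abs(np.diff(contact))) == 2

    def test_contact_duration_calibrated(self, default_config):
        durations = []
        for seed in range(100):
            f = generate_flight(default_config, rng_seed=seed)
            i0, i1 = f.true_contact_index
            durations.append((i1 - i0) / f.fs)
        # 3 x SEM of the configured 73 +/- 11 ms distribution over 100 flights
        assert np.mean(durations) == pytest.approx(
            default_config.contact_duration_mean, abs=0.003 + 1e-9
        )

    def test_heading_reversal_confined_to_landing(self, default_config):
        flight = generate_flight(default_config, rng_seed=7)
        com = flight.com
        v = np.gradient(com, 1.0 / flight.fs, axis=0)
        bearing = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
        body = flight.front - flight.rear
        heading = np.degrees(np.arctan2(body[:, 1], body[:, 0]))
        diff = np.abs(wrap_angle(heading - bearing))
        descent = flight.phase_labels == "descent"
        outside = (flight.phase_labels == "approach") | (flight.phase_labels == "departure")
        assert diff[descent].max() > 150.0
        assert np.median(diff[outside]) < 30.0

    def test_descent_onset_matches_configured_lead(self, default_config):
        flight = generate_flight(default_config, rng_seed=8)
        assert flight.true_descent_onset == pytest.approx(
            -default_config.descent_onset_lead, abs=0.01
        )


class TestProjection:
    def test_noiseless_round_trip(self, clean_config, cameras):
        cam_a, cam_b = cameras
        flight = generate_flight(clean_config, rng_seed=1)
        rec = project_to_cameras(flight, cam_a, cam_b, noise_sd=0.0, offset=0, rng_seed=0)
        pts = triangulate(cam_a, cam_b, rec.view_a.front_px, rec.view_b.front_px).points
        assert np.abs(pts - flight.front).max() < 1e-6

    def test_led_offset_recovered_exactly(self, clean_config, cameras):
        cam_a, cam_b = cameras
        flight = generate_flight(clean_config, rng_seed=2)
        rec = project_to_cameras(flight, cam_a, cam_b, offset=17, rng_seed=1)
        counts_a, _ = decode_counts(rec.view_a.led)
        counts_b, _ = decode_counts(rec.view_b.led)
        assert synchronise(counts_a, counts_b).offset == 17
        assert len(rec.view_b) == len(rec.view_a) + 17

    def test_pixel_noise_gives_subtwo_mm_median_error(self, default_config, cameras):
        cam_a, cam_b = cameras
        flight = generate_flight(default_config, rng_seed=3)
        errs = []
        for seed in range(5):
            rec = project_to_cameras(
                flight, cam_a, cam_b, noise_sd=1.0, offset=0, rng_seed=seed
            )
            pts = triangulate(cam_a, cam_b, rec.view_a.front_px, rec.view_b.front_px).points
            errs.append(np.median(np.linalg.norm(pts - flight.front, axis=1)))
        assert np.mean(errs) < 2.0

    def test_negative_offset_rejected(self, clean_config, cameras):
        flight = generate_flight(clean_config, rng_seed=4)
        with pytest.raises(ValueError):
            project_to_cameras(flight, *cameras, offset=-1)

    def test_behind_camera_flagged(self, clean_config):
        flight = generate_flight(clean_config, rng_seed=5)
        near = sf.make_camera([50.0, 0.0, 40.0], [0.0, 0.0, 30.0])  # inside the flight volume
        far = sf.make_camera([1200.0, 600.0, 500.0], [0.0, 0.0, 30.0])
        with pytest.raises(ValueError, match="behind"):
            project_to_cameras(flight, near, far, offset=0)


class TestSimulateRecording:
    def test_recording_complete_and_consistent(self, default_config):
        flight = generate_flight(default_config, rng_seed=6)
        rec = sf.simulate_recording(flight, rng_seed=7)
        assert rec.true_offset == default_config.inter_camera_offset
        assert rec.calibration_a is not None and rec.calibration_b is not None
        assert rec.observer_azimuth_aligned is not None
        assert len(rec.view_a.led) == len(rec.view_a)
        assert rec.view_a.landmarks_px.shape[0] >= 4
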