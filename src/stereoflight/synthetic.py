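"""Synthetic drinking-on-the-wing flights with known ground truth.

No field recordings ship with the package, so every downstream stage is
exercised against generated flights that reproduce the behavioural sequence
seen in the wild: a slow looping **approach** over the water at low altitude,
interrupted by rapid body saccades; a fast **descent** during which the fly
yaws ~180 degrees (heading reverses while the bearing is retained) and
pitches up; a brief **water contact**; and a straight climbing **departure**.

Phase templates are splines/arc primitives rather than a dynamical flight
model — the analysis concerns kinematics, not aerodynamics.  Per-flight
speeds and altitudes are drawn from log-normal distributions matched to the
published medians and quartiles of each phase, so a cohort of synthetic
flights reproduces the field statistics by construction and the pipeline's
job is to recover them.

The generated world frame has the water surface at z = 0 and the sun azimuth
at ``sun_azimuth`` degrees; :func:`simulate_recording` projects a flight
through two synthetic cameras (with pixel noise, an inter-camera frame offset
and Gray-code LED traces) and hands the pipeline only what a real recording
would provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .stereo import CameraModel, make_camera
from .sync import COUNTER_MODULUS, gray_encode

DEG = np.pi / 180.0


def lognormal_from_quartiles(median: float, quartiles: tuple[float, float]) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and (q1, q3)."""
    q1, q3 = quartiles
    if not 0 < q1 <= median <= q3:
        raise ValueError("need 0 < q1 <= median <= q3")
    z75 = norm.ppf(0.75)
    sigma = np.log(q3 / q1) / (2.0 * z75) if q3 > q1 else 0.0
    return float(np.log(median)), float(sigma)


def sample_lognormal(
    rng: np.random.Generator,
    median: float,
    quartiles: tuple[float, float],
    u: float | None = None,
) -> float:
    """Draw from the matched log-normal; ``u`` fixes the quantile instead.

    Supplying the uniform quantile ``u`` allows stratified cohort sampling:
    a cohort built from a stratified grid of quantiles has exactly the target
    distribution's quantile structure, so its median is the calibration
    median up to 1/n effects rather than a sqrt(n) sampling error.
    """
    mu, sigma = lognormal_from_quartiles(median, quartiles)
    z = rng.standard_normal() if u is None else norm.ppf(u)
    return float(np.exp(mu + sigma * z))


@dataclass
class FlightConfig:
    """Study conditions for one synthetic flight / cohort.

    Kinematic medians and quartiles are per-flight phase means; each flight
    draws its own values from the matched log-normals.  Durations in seconds,
    altitudes/lengths in mm, speeds in m/s.
    """

    frame_rate: float = 250.0
    approach_duration: float = 1.5  # total pre-contact time
    approach_altitude_median: float = 53.52
    approach_altitude_quartiles: tuple[float, float] = (40.12, 65.02)
    approach_speed_median: float = 1.57  # total (3D) speed, held per flight
    approach_speed_quartiles: tuple[float, float] = (1.32, 1.79)
    approach_vertical_speed_median: float = 0.17  # altitude bobbing target
    approach_vertical_speed_quartiles: tuple[float, float] = (0.14, 0.24)
    bob_frequency: float = 2.5  # Hz, altitude oscillation during approach
    departure_altitude_median: float = 70.6
    departure_altitude_quartiles: tuple[float, float] = (53.21, 91.65)
    departure_horizontal_speed_median: float = 1.19
    departure_horizontal_speed_quartiles: tuple[float, float] = (0.94, 1.49)
    departure_vertical_speed_median: float = 0.62
    departure_vertical_speed_quartiles: tuple[float, float] = (0.38, 0.81)
    contact_duration_mean: float = 0.073  # s, time below the landing threshold
    contact_duration_sd: float = 0.011
    contact_altitude: float = 5.0  # mm, CoM height while on the water
    contact_speed: float = 0.3  # m/s, residual horizontal drift on the water
    descent_peak_vertical_velocity: float = -0.45  # m/s (20% of peak = -0.09)
    descent_onset_lead: float = 0.135  # s before contact at which vz crosses 20% of peak
    landing_threshold: float = 10.0  # mm, strict-landing altitude criterion
    saccade_rate: float = 2.0  # events/s during the approach
    saccade_yaw_magnitude: float = 60.0  # deg per saccade
    saccade_turn_radius: float = 30.0  # mm (well below the 210 mm criterion)
    steady_turn_radius: float | None = 800.0  # mm, gentle approach loop; None = straight
    body_length: float = 22.0  # mm front-rear distance (field range 20-25)
    landing_pitch: float = 40.0  # deg head-up at touch-down
    sun_azimuth: float = 137.0  # deg in the generated world frame
    noise_sd_pixels: float = 1.0
    inter_camera_offset: int = 17  # frames, camera B starts earlier than A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.contact_duration_mean <= 0:
            raise ValueError("contact_duration_mean must be positive")
        if self.descent_peak_vertical_velocity >= 0:
            raise ValueError("descent_peak_vertical_velocity must be negative")
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")
        for name in (
            "approach_speed_median",
            "approach_vertical_speed_median",
            "departure_horizontal_speed_median",
            "departure_vertical_speed_median",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.inter_camera_offset < 0:
            raise ValueError("inter_camera_offset must be >= 0")


@dataclass
class GroundTruthFlight:
    """A generated flight with full truth for validating the pipeline."""

    t: np.ndarray  # s, 0 at the first sample below the landing threshold
    front: np.ndarray = field(repr=False)  # (n, 3) mm, world frame (water = z 0)
    rear: np.ndarray = field(repr=False)
    phase_labels: np.ndarray = field(repr=False)  # approach|saccade|descent|contact|departure
    true_descent_onset: float = 0.0  # s (negative)
    true_contact_interval: tuple[float, float] = (0.0, 0.0)
    true_contact_index: tuple[int, int] = (0, 0)  # half-open sample interval
    true_segment_boundaries: list[tuple[int, int]] = field(default_factory=list)
    sun_azimuth: float = 0.0
    fs: float = 250.0
    params: dict = field(default_factory=dict)  # per-flight sampled values
    config: FlightConfig | None = None

    @property
    def com(self) -> np.ndarray:
        return 0.5 * (self.front + self.rear)

    def __len__(self) -> int:
        return self.t.size


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


_DESCENT_TAU_PEAK = 0.75  # fraction of the descent at which |vz| peaks
_DESCENT_TOUCH_FRACTION = 0.55  # |vz| at touch-down as a fraction of the peak
_DESCENT_GRID = np.linspace(0.0, 1.0, 2001)


def _descent_shape(tau: np.ndarray) -> np.ndarray:
    """Unit vertical-speed profile of the plunge: 0 -> 1 at tau_peak -> 0.55.

    The fly accelerates downward, peaks before touch-down and brakes into the
    water, as the field mean vertical-velocity curves show — the peak is
    interior, not at contact, so a 20%-of-peak onset threshold is crossed on
    the clean rising flank.
    """
    tau = np.asarray(tau, dtype=float)
    tp, tf = _DESCENT_TAU_PEAK, _DESCENT_TOUCH_FRACTION
    rising = np.sin(np.pi * tau / (2.0 * tp)) ** 2
    braking = 1.0 - (1.0 - tf) * np.sin(np.pi * (tau - tp) / (2.0 * (1.0 - tp))) ** 2
    return np.where(tau <= tp, rising, braking)


_DESCENT_S = _descent_shape(_DESCENT_GRID)
_DESCENT_F = np.concatenate([[0.0], np.cumsum(0.5 * (_DESCENT_S[1:] + _DESCENT_S[:-1]))]) * (
    _DESCENT_GRID[1] - _DESCENT_GRID[0]
)  # running integral of the shape


def _descent_profile(config: FlightConfig, gap_offset: float = 0.0) -> tuple[float, float, float]:
    """Solve the descent duration so the clean 20%-of-peak vertical-velocity
    crossing leads the landing-threshold crossing by ``descent_onset_lead``.

    Vertical velocity during the plunge is v_pk * s(tau) with the unit shape
    :func:`_descent_shape`; the total drop is v_pk * T * F(1) with F the
    shape's integral.  Returns (T_descent, onset altitude mm, tau at the
    landing-threshold crossing).

    The landing threshold is a *contact-referenced* CoM altitude (the aligned
    analysis frame puts the touch-down point at the origin), so the crossing
    happens at ``contact_altitude + landing_threshold`` above the water.
    """
    v_pk = abs(config.descent_peak_vertical_velocity) * 1000.0  # mm/s
    c_alt = config.contact_altitude
    # contact-referenced threshold altitude; ``gap_offset`` accounts for the
    # altitude still to be lost in the post-touch-down settling blend
    gap = config.landing_threshold - gap_offset
    F1 = float(_DESCENT_F[-1])
    tau20 = float(_DESCENT_GRID[np.searchsorted(_DESCENT_S[: len(_DESCENT_S) * 3 // 4], 0.2)])

    def tau_thr(T: float) -> float:
        drop = v_pk * T * F1
        want = (drop - gap) / (v_pk * T)  # F(tau) at the threshold crossing
        return float(np.interp(want, _DESCENT_F, _DESCENT_GRID))

    T_min = gap / (v_pk * F1)

    def lead_error(T: float) -> float:
        return (tau_thr(T) - tau20) * T - config.descent_onset_lead

    T_hi = max(4.0 * config.descent_onset_lead, 4.0 * T_min)
    T = brentq(lead_error, T_min * 1.0001, T_hi, xtol=1e-10)
    z_onset = c_alt + gap_offset + v_pk * T * F1
    return float(T), float(z_onset), float(tau_thr(T))


def _solve_bob_amplitude(
    target: float, slope: float, env: np.ndarray, phase: np.ndarray, a_max: float
) -> float:
    """Bobbing vz amplitude so that mean |slope + A env sin(phase)| = target."""

    def mean_speed(A: float) -> float:
        return float(np.mean(np.abs(slope + A * env * np.sin(phase))))

    if mean_speed(0.0) >= target or a_max <= 0:
        return 0.0
    if mean_speed(a_max) <= target:
        return a_max
    lo, hi = 0.0, a_max
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_speed(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_flight(
    config: FlightConfig | None = None,
    rng_seed: int | None = None,
    quantiles: dict[str, float] | None = None,
) -> GroundTruthFlight:
    """Generate one ground-truth flight on the camera frame grid.

    All randomness flows through a single generator seeded by ``rng_seed``
    (falling back to ``config.seed``), so identical seeds give identical
    flights.  ``quantiles`` optionally fixes the uniform quantile used for any
    of the per-flight log-normal draws (keys: ``approach_speed``,
    ``approach_vertical_speed``, ``approach_altitude``, ``departure_altitude``,
    ``departure_horizontal_speed``, ``departure_vertical_speed``) — the hook
    stratified cohort sampling uses.
    """
    config = config or FlightConfig()
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    fs = config.frame_rate
    dt = 1.0 / fs
    q = quantiles or {}

    # --- per-flight draws from the phase statistics -------------------------
    v_tot = sample_lognormal(
        rng, config.approach_speed_median, config.approach_speed_quartiles,
        q.get("approach_speed"),
    )
    vs_app = sample_lognormal(
        rng,
        config.approach_vertical_speed_median,
        config.approach_vertical_speed_quartiles,
        q.get("approach_vertical_speed"),
    )
    alt_app = sample_lognormal(
        rng, config.approach_altitude_median, config.approach_altitude_quartiles,
        q.get("approach_altitude"),
    )
    alt_dep = sample_lognormal(
        rng, config.departure_altitude_median, config.departure_altitude_quartiles,
        q.get("departure_altitude"),
    )
    vh_dep = sample_lognormal(
        rng,
        config.departure_horizontal_speed_median,
        config.departure_horizontal_speed_quartiles,
        q.get("departure_horizontal_speed"),
    )
    vz_dep = sample_lognormal(
        rng,
        config.departure_vertical_speed_median,
        config.departure_vertical_speed_quartiles,
        q.get("departure_vertical_speed"),
    )
    strict_duration = max(
        rng.normal(config.contact_duration_mean, config.contact_duration_sd), 0.030
    )
    psi0 = rng.uniform(-np.pi, np.pi)

    # --- descent geometry ----------------------------------------------------
    # after touch-down the vertical velocity blends linearly to zero over a few
    # frames (a fly settles onto the water; a slope discontinuity would ring
    # through the Butterworth filter); the blend still loses a little altitude
    n_blend = max(int(round(0.012 * fs)), 2)
    vz_touch = -abs(config.descent_peak_vertical_velocity) * _DESCENT_TOUCH_FRACTION
    dz_blend = abs(vz_touch) * 1000.0 / fs * (n_blend - 1) / 2.0
    T_desc, z_onset, tau_thr = _descent_profile(config, gap_offset=dz_blend)
    n_d = max(int(round(T_desc * fs)), 4)
    T_desc_grid = n_d * dt
    v_pk = abs(config.descent_peak_vertical_velocity)
    c_alt = config.contact_altitude
    # altitudes in Table-1 terms are contact-referenced (touch-down = 0), so
    # every threshold/target below is offset by the on-water CoM height
    thr = c_alt + config.landing_threshold

    T_app = config.approach_duration - tau_thr * T_desc
    if T_app < 0.3:
        raise ValueError(
            "descent cannot reach contact altitude within approach_duration; "
            "increase approach_duration or the descent steepness"
        )
    n_a = int(round(T_app * fs))

    # --- approach vertical profile -------------------------------------------
    s_app = (np.arange(n_a) - n_a) * dt  # time before descent-ramp start, < 0
    alt_app_z = alt_app + c_alt  # water-referenced target altitude
    # linear base altitude ending at the descent-onset altitude with the mean
    # pinned at the flight's target; the start is clamped clear of the landing
    # threshold so low-altitude draws cannot produce a pre-contact water touch
    z_start = max(2.0 * alt_app_z - z_onset, thr + 6.0)
    slope_mm = (z_onset - z_start) / T_app  # mm/s, base altitude trend
    env = np.ones(n_a)
    n_taper = min(int(round(0.15 * fs)), n_a)
    if n_taper > 1:
        env[-n_taper:] = 0.5 * (1.0 + np.cos(np.linspace(0.0, np.pi, n_taper)))
    phase = 2.0 * np.pi * config.bob_frequency * s_app
    z_base = z_onset + slope_mm * s_app
    clearance = (z_base.min() - (thr + 4.0)) / 1000.0  # m of altitude headroom
    a_alt_cap = max(2.0 * np.pi * config.bob_frequency * clearance, 0.0)
    a_max = min(0.6 * v_tot, a_alt_cap)
    A_bob = _solve_bob_amplitude(vs_app, slope_mm / 1000.0, env, phase, a_max)
    vz_app = slope_mm / 1000.0 + A_bob * env * np.sin(phase)  # m/s
    # integrate backwards so the approach ends exactly at the onset altitude
    z_app = z_onset - 1000.0 * dt * (np.cumsum(vz_app[::-1])[::-1])

    # --- descent samples ------------------------------------------------------
    tau = np.arange(n_d) / n_d  # touch-down lands on the first contact sample
    vz_desc = -v_pk * _descent_shape(tau)
    drop = (v_pk * 1000.0) * T_desc_grid * np.interp(tau, _DESCENT_GRID, _DESCENT_F)
    z_desc = z_onset - drop

    # --- departure vertical profile (to be truncated later) ------------------
    # cosine onset ramp: an abrupt climb-rate kink would ring through the
    # 100 Hz zero-phase filter and bias the altitude reference at take-off
    n_ramp = max(int(round(0.016 * fs)), 2)
    n_dep_max = int(round(3.0 * fs))
    k_dep = np.arange(1, n_dep_max + 1)
    ramp = np.sin(np.pi * np.minimum(k_dep / n_ramp, 1.0) / 2.0) ** 2
    vz_dep_arr = vz_dep * ramp
    z_dep_full = c_alt + 1000.0 * dt * np.cumsum(vz_dep_arr)

    # time from take-off to climbing past the landing threshold
    above = np.flatnonzero(z_dep_full >= thr)
    head_time = (above[0] + 1) * dt if above.size else n_dep_max * dt
    tail_time = (1.0 - tau_thr) * T_desc
    T_flat = max(strict_duration - tail_time - head_time, 0.02)
    n_f = max(int(round(T_flat * fs)), n_blend + 2)

    # truncate the departure where the mean altitude above the threshold
    # reaches the flight's sampled departure-altitude target
    i_above = int(above[0]) if above.size else 0
    running_mean = np.cumsum(z_dep_full[i_above:] - c_alt) / np.arange(1, n_dep_max - i_above + 1)
    hit = np.flatnonzero(running_mean >= alt_dep)
    n_dep = i_above + (int(hit[0]) + 1 if hit.size else n_dep_max - i_above)
    n_dep = max(n_dep, i_above + int(round(0.06 * fs)))
    n_dep = min(n_dep, n_dep_max)
    z_dep = z_dep_full[:n_dep]
    vz_dep_arr = vz_dep_arr[:n_dep]

    # --- contact samples: settling blend, then flat on the water --------------
    j = np.arange(n_f)
    vz_ct = np.where(j < n_blend, vz_touch * (1.0 - (j + 1) / n_blend), 0.0)
    z_ct = (c_alt + dz_blend) + 1000.0 * dt * np.cumsum(vz_ct)

    # --- assemble the vertical track -----------------------------------------
    z = np.concatenate([z_app, z_desc, z_ct, z_dep])
    vz = np.concatenate([vz_app, vz_desc, vz_ct, vz_dep_arr])
    N = z.size
    i_desc0 = n_a
    i_touch = n_a + n_d
    i_dep0 = i_touch + n_f

    # --- horizontal speed and direction --------------------------------------
    vh = np.empty(N)
    vz_capped = np.clip(vz[:n_a], -0.9 * v_tot, 0.9 * v_tot)
    vh[:n_a] = np.sqrt(np.maximum(v_tot**2 - vz_capped**2, 1e-6))
    cs = config.contact_speed
    vh0 = vh[n_a - 1]
    vh[i_desc0:i_touch] = cs + (vh0 - cs) * (1.0 - _smoothstep(tau))
    vh[i_touch:i_dep0] = cs
    vh[i_dep0:] = np.maximum(vh_dep * ramp[:n_dep], cs)

    # saccades: Poisson-placed rapid yaw arcs during the steady approach
    saccade_sign = np.zeros(n_a)
    saccade_intervals: list[tuple[int, int]] = []
    if config.saccade_rate > 0 and n_a > int(0.3 * fs):
        margin = int(round(0.06 * fs))
        dur = config.saccade_yaw_magnitude * DEG * config.saccade_turn_radius / (v_tot * 1000.0)
        n_sacc_samples = max(int(round(dur * fs)), 2)
        window = n_a - 2 * margin - n_sacc_samples
        n_events = rng.poisson(config.saccade_rate * T_app)
        starts = np.sort(rng.integers(margin, margin + max(window, 1), size=n_events))
        last_end = -10**9
        gap = int(round(0.04 * fs))
        for s0 in starts:
            if s0 < last_end + gap:
                continue
            s1 = s0 + n_sacc_samples
            saccade_sign[s0:s1] = rng.choice([-1.0, 1.0])
            saccade_intervals.append((int(s0), int(s1)))
            last_end = s1

    # bearing over the approach: a gentle loop around the tray.  A weak homing
    # term steers the fly back toward the tray so the inspection loops stay
    # inside the filmed volume; its arcs are capped at a 400 mm turn radius,
    # still far above the 210 mm straightness criterion, so only the saccades
    # (30 mm arcs) break the straight-segment classification.  With
    # steady_turn_radius None the approach is a dead-straight line.
    psi = np.full(N, psi0)
    if config.steady_turn_radius is not None:
        turn_dir = float(rng.choice([-1.0, 1.0]))
        r_min_turn = max(400.0, 1.5 * config.saccade_turn_radius)
        r_home = 350.0  # mm, preferred orbit radius
        px_, py_, ps = 0.0, 0.0, psi0
        for i in range(n_a):
            rate = turn_dir * vh[i] * 1000.0 / config.steady_turn_radius
            dist = np.hypot(px_, py_)
            if dist > 1.0:
                err = np.arctan2(-py_, -px_) - ps
                err = (err + np.pi) % (2.0 * np.pi) - np.pi
                rate += 3.0 * min(dist / r_home, 2.0) * err
            cap = vh[i] * 1000.0 / r_min_turn
            rate = float(np.clip(rate, -cap, cap))
            if saccade_sign[i] != 0:
                rate = saccade_sign[i] * vh[i] * 1000.0 / config.saccade_turn_radius
            psi[i] = ps
            px_ += vh[i] * np.cos(ps) * 1000.0 * dt
            py_ += vh[i] * np.sin(ps) * 1000.0 * dt
            ps += rate * dt
        psi[n_a:] = ps
    else:
        sacc = saccade_sign != 0
        yaw_rate = np.zeros(n_a)
        yaw_rate[sacc] = saccade_sign[sacc] * vh[:n_a][sacc] * 1000.0 / config.saccade_turn_radius
        psi[:n_a] = psi0 + np.concatenate([[0.0], np.cumsum(yaw_rate[:-1] * dt)])
        psi[n_a:] = psi[n_a - 1] if n_a > 0 else psi0
    psi[i_desc0:] = psi[i_desc0 - 1] if i_desc0 > 0 else psi0  # bearing retained

    theta = psi.copy()  # direction of travel
    theta[i_dep0:] = psi[i_desc0 - 1] + np.pi  # bearing flips at take-off

    vx = vh * np.cos(theta) * 1000.0  # mm/s
    vy = vh * np.sin(theta) * 1000.0
    x = np.concatenate([[0.0], np.cumsum(vx[:-1] * dt)])
    y = np.concatenate([[0.0], np.cumsum(vy[:-1] * dt)])

    # --- body orientation ------------------------------------------------------
    heading = theta.copy()
    w = _smoothstep(tau)
    heading[i_desc0:i_touch] = psi[i_desc0:i_touch] + np.pi * w
    heading[i_touch:i_dep0] = psi[i_touch:i_dep0] + np.pi

    path_pitch = np.arctan2(vz, vh)
    pitch = path_pitch.copy()
    pitch[i_desc0:i_touch] = (1.0 - w) * path_pitch[i_desc0:i_touch] + w * (
        config.landing_pitch * DEG
    )
    pitch[i_touch:i_dep0] = config.landing_pitch * DEG

    body = np.column_stack(
        [np.cos(heading) * np.cos(pitch), np.sin(heading) * np.cos(pitch), np.sin(pitch)]
    )
    com = np.column_stack([x, y, z])
    half = 0.5 * config.body_length
    front = com + half * body
    rear = com - half * body

    # --- truth bookkeeping, derived with the same defining rules --------------
    below = z < thr
    i0_candidates = np.flatnonzero(below & (vz < 0) & (np.arange(N) >= i_desc0))
    i0 = int(i0_candidates[0])
    run_lo, run_hi = i0, i0 + 1
    while run_hi < N and below[run_hi]:
        run_hi += 1
    t = (np.arange(N) - i0) * dt
    front[:, 0] -= x[i0]
    front[:, 1] -= y[i0]
    rear[:, 0] -= x[i0]
    rear[:, 1] -= y[i0]

    vz_pre = vz[:i0]
    peak = float(vz_pre.min())
    thr_v = 0.2 * peak
    crossings = np.flatnonzero((vz_pre[:-1] > thr_v) & (vz_pre[1:] <= thr_v))
    onset_idx = int(crossings[-1] + 1) if crossings.size else int(np.argmin(vz_pre))

    labels = np.empty(N, dtype=object)
    labels[:onset_idx] = "approach"
    labels[onset_idx:i0] = "descent"
    labels[i0:run_hi] = "contact"
    labels[run_hi:] = "departure"
    for s0, s1 in saccade_intervals:
        if s1 <= onset_idx:
            labels[s0:s1] = "saccade"

    boundaries: list[tuple[int, int]] = []
    prev = 0
    for s0, s1 in saccade_intervals:
        s1 = min(s1, onset_idx)
        if s0 >= onset_idx:
            break
        if s0 > prev:
            boundaries.append((prev, s0))
        prev = s1
    if onset_idx > prev:
        boundaries.append((prev, onset_idx))
    boundaries.append((run_hi, N))

    params = dict(
        total_speed_approach=v_tot,
        vertical_speed_target_approach=vs_app,
        altitude_target_approach=alt_app,
        altitude_target_departure=alt_dep,
        horizontal_speed_departure=vh_dep,
        vertical_speed_departure=vz_dep,
        strict_contact_duration=float(strict_duration),
        bob_amplitude=A_bob,
        descent_duration=T_desc_grid,
        onset_altitude=z_onset,
    )
    return GroundTruthFlight(
        t=t,
        front=front,
        rear=rear,
        phase_labels=labels,
        true_descent_onset=float(t[onset_idx]),
        true_contact_interval=(float(t[i0]), float(t[run_hi]) if run_hi < N else float(t[-1])),
        true_contact_index=(i0, run_hi),
        true_segment_boundaries=boundaries,
        sun_azimuth=config.sun_azimuth,
        fs=fs,
        params=params,
        config=config,
    )


# ---------------------------------------------------------------------------
# two-camera projection
# ---------------------------------------------------------------------------

DEFAULT_LANDMARKS = np.array(
    [
        [150.0, 0.0, 0.0],
        [-150.0, 0.0, 0.0],
        [0.0, 150.0, 0.0],
        [0.0, -150.0, 0.0],
        [110.0, 110.0, 0.0],
    ]
)


def shadow_points(
    sun_azimuth_deg: float,
    base: np.ndarray = (300.0, -200.0, 0.0),
    length: float = 250.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Base and tip of the shadow cast by a vertical beam: tip points away from the sun."""
    base = np.asarray(base, dtype=float)
    az = np.radians(sun_azimuth_deg + 180.0)
    tip = base + length * np.array([np.cos(az), np.sin(az), 0.0])
    return base, tip


@dataclass
class ViewRecording:
    """What one camera delivers: pixel tracks and the LED counter trace."""

    frames: np.ndarray
    front_px: np.ndarray = field(repr=False)
    rear_px: np.ndarray = field(repr=False)
    landmarks_px: np.ndarray = field(repr=False)  # (m, 2), digitised once
    shadow_base_px: np.ndarray = field(repr=False)
    shadow_tip_px: np.ndarray = field(repr=False)
    led: np.ndarray = field(repr=False)  # (n, 8) intensities

    def __len__(self) -> int:
        return self.frames.size


@dataclass
class TwoViewRecording:
    view_a: ViewRecording
    view_b: ViewRecording
    camera_a: CameraModel  # generating truth cameras
    camera_b: CameraModel
    true_offset: int
    fs: float
    counter_rate: float = 25.0
    calibration_a: tuple[np.ndarray, np.ndarray] | None = None  # (world, px)
    calibration_b: tuple[np.ndarray, np.ndarray] | None = None
    observer_azimuth_aligned: float | None = None  # deg, in the sun-aligned frame
    meta: dict = field(default_factory=dict)


def _led_trace(
    counts: np.ndarray,
    levels: tuple[float, float],
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    bits = np.stack([gray_encode(int(c)) for c in counts])
    off, on = levels
    trace = off + bits * (on - off)
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=trace.shape)
    return trace


def project_to_cameras(
    flight: GroundTruthFlight,
    cam_a: CameraModel,
    cam_b: CameraModel,
    noise_sd: float = 0.0,
    offset: int = 0,
    rng_seed: int | None = 0,
    landmarks: np.ndarray | None = None,
    shadow: tuple[np.ndarray, np.ndarray] | None = None,
    counter_rate: float = 25.0,
    led_levels: tuple[float, float] = (20.0, 230.0),
    led_noise_sd: float = 0.0,
    counter_start: int | None = None,
    world_transform: tuple[np.ndarray, np.ndarray] | None = None,
) -> TwoViewRecording:
    """Project a ground-truth flight through two cameras.

    Camera B starts recording ``offset`` frames before camera A; its first
    ``offset`` frames show the scene before the fly moves (the first pose is
    held), so the synchronised overlap covers the whole flight.  Pixel tracks
    receive i.i.d. Gaussian noise of ``noise_sd``; static landmarks and the
    shadow are digitised once per camera.  ``world_transform`` (R, t) is the
    rigid map from the generator frame into the (arbitrary) calibration frame
    and only affects the coordinates reported for calibration targets — the
    pixels are identical either way.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    rng = np.random.default_rng(rng_seed)
    fs = flight.fs
    fpc = max(int(round(fs / counter_rate)), 1)
    N = len(flight)
    if counter_start is None:
        counter_start = int(rng.integers(0, COUNTER_MODULUS))

    if landmarks is None:
        landmarks = DEFAULT_LANDMARKS
    if shadow is None:
        shadow = shadow_points(flight.sun_azimuth)
    shadow_base, shadow_tip = shadow

    pad = offset
    front_ext = np.vstack([np.repeat(flight.front[:1], pad, axis=0), flight.front])
    rear_ext = np.vstack([np.repeat(flight.rear[:1], pad, axis=0), flight.rear])
    scene_counts = (counter_start + np.arange(N + pad) // fpc) % COUNTER_MODULUS

    views = {}
    for name, cam, sl in (("a", cam_a, slice(pad, N + pad)), ("b", cam_b, slice(0, N + pad))):
        pts_f, pts_r = front_ext[sl], rear_ext[sl]
        for pts in (pts_f, pts_r, landmarks):
            if not cam.in_front(pts).all():
                raise ValueError(f"points behind camera {name} (non-positive denominator)")
        n = pts_f.shape[0]

        def digitise(p: np.ndarray, cam=cam) -> np.ndarray:
            px = cam.project(p)
            if noise_sd > 0:
                px = px + rng.normal(0.0, noise_sd, size=px.shape)
            return px

        views[name] = ViewRecording(
            frames=np.arange(n),
            front_px=digitise(pts_f),
            rear_px=digitise(pts_r),
            landmarks_px=digitise(landmarks),
            shadow_base_px=digitise(shadow_base[None, :])[0],
            shadow_tip_px=digitise(shadow_tip[None, :])[0],
            led=_led_trace(scene_counts[sl], led_levels, led_noise_sd, rng),
        )

    meta = {"counter_start": counter_start, "world_transform": world_transform}
    return TwoViewRecording(
        view_a=views["a"],
        view_b=views["b"],
        camera_a=cam_a,
        camera_b=cam_b,
        true_offset=offset,
        fs=fs,
        counter_rate=counter_rate,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# full synthetic recording (cameras + checkerboard calibration + scramble)
# ---------------------------------------------------------------------------


@dataclass
class RecordingSetup:
    """Camera and calibration geometry for a synthetic recording session.

    Cameras sit 0.8-1.2 m from the tray at different azimuths, as in the
    field setup; the exact placement varies per recording through ``jitter``.
    """

    cam_azimuths_deg: tuple[float, float] = (30.0, 120.0)
    cam_distances_m: tuple[float, float] = (1.1, 1.2)  # top of the 0.8-1.2 m field range
    cam_heights_m: tuple[float, float] = (0.55, 0.50)
    focal_px: float = 1200.0
    image_size: tuple[int, int] = (1920, 1080)
    jitter: float = 0.05  # relative placement jitter per recording
    checkerboard_shape: tuple[int, int] = (7, 6)
    checkerboard_spacing_mm: float = 25.0
    checkerboard_noise_px: float = 0.3
    scramble_world: bool = True  # reconstruct in an arbitrary rigid frame


def checkerboard_points(
    shape: tuple[int, int] = (7, 6),
    spacing: float = 40.0,
    rng: np.random.Generator | None = None,
    n_poses: int = 5,
) -> np.ndarray:
    """3D corner positions of a checkerboard filmed at several orientations.

    Poses tilt and shift the board across the whole filmed volume (the flight
    loops extend ~0.5 m around the tray), so the combined cloud is far from
    coplanar and the DLT is interpolating rather than extrapolating wherever
    the fly goes — skimping here reproduces the real failure mode of growing
    reconstruction errors toward the view edges.
    """
    rng = rng or np.random.default_rng(0)
    rows, cols = shape
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    grid = np.column_stack(
        [
            (ii.ravel() - (rows - 1) / 2.0) * spacing,
            (jj.ravel() - (cols - 1) / 2.0) * spacing,
            np.zeros(rows * cols),
        ]
    )
    centres = np.array(
        [
            [0.0, 0.0, 150.0],
            [350.0, 250.0, 300.0],
            [-350.0, 200.0, 120.0],
            [250.0, -320.0, 250.0],
            [-220.0, -300.0, 380.0],
        ]
    )
    pts = []
    for p in range(n_poses):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.35, 1.0)
        K = np.array(
            [
                [0, -axis[2], axis[1]],
                [axis[2], 0, -axis[0]],
                [-axis[1], axis[0], 0],
            ]
        )
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        centre = centres[p % len(centres)] + rng.uniform(-20, 20, size=3)
        pts.append(grid @ R.T + centre)
    return np.vstack(pts)


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniform-ish random proper rotation and a translation up to 0.5 m."""
    M = rng.normal(size=(3, 3))
    Q, Rm = np.linalg.qr(M)
    Q = Q * np.sign(np.diag(Rm))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-500.0, 500.0, size=3)
    return Q, t


def default_cameras(
    setup: RecordingSetup | None = None,
    rng: np.random.Generator | None = None,
    min_distance_mm: float = 0.0,
) -> tuple[CameraModel, CameraModel]:
    """Two pinhole cameras looking at the tray from the configured placements.

    ``min_distance_mm`` backs the cameras off far enough that an unusually
    wide flight stays in front of both — the synthetic stand-in for the
    experimenter framing the scene.
    """
    setup = setup or RecordingSetup()
    rng = rng or np.random.default_rng(0)
    cams = []
    for az, dist, height in zip(
        setup.cam_azimuths_deg, setup.cam_distances_m, setup.cam_heights_m
    ):
        az = az + rng.normal(0.0, 360.0 * setup.jitter / 3.0)
        dist = max(dist * (1.0 + rng.uniform(-setup.jitter, setup.jitter)) * 1000.0,
                   min_distance_mm)
        height = height * (1.0 + rng.uniform(-setup.jitter, setup.jitter)) * 1000.0
        pos = np.array([dist * np.cos(az * DEG), dist * np.sin(az * DEG), height])
        cams.append(
            make_camera(pos, np.array([0.0, 0.0, 30.0]), setup.focal_px, setup.image_size)
        )
    return cams[0], cams[1]


def simulate_recording(
    flight: GroundTruthFlight,
    setup: RecordingSetup | None = None,
    rng_seed: int | None = 0,
) -> TwoViewRecording:
    """Everything a field recording would provide for one drinking event.

    Produces the two pixel/LED streams, checkerboard calibration
    correspondences (expressed in an arbitrary rigid "calibration frame" when
    ``setup.scramble_world`` is set, exactly like a real reconstruction whose
    world frame is fixed by the checkerboard, not by the water), and the
    observer azimuth an experimenter would note down.
    """
    setup = setup or RecordingSetup()
    config = flight.config or FlightConfig()
    rng = np.random.default_rng(rng_seed)
    extent = float(np.linalg.norm(flight.com[:, :2], axis=1).max())
    cam_a, cam_b = default_cameras(setup, rng, min_distance_mm=extent + 300.0)

    rec = project_to_cameras(
        flight,
        cam_a,
        cam_b,
        noise_sd=config.noise_sd_pixels,
        offset=config.inter_camera_offset,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )

    world = checkerboard_points(
        setup.checkerboard_shape, setup.checkerboard_spacing_mm, rng
    )
    if setup.scramble_world:
        R, tvec = random_rigid_transform(rng)
    else:
        R, tvec = np.eye(3), np.zeros(3)
    world_reported = world @ R.T + tvec
    for cam, attr in ((cam_a, "calibration_a"), (cam_b, "calibration_b")):
        px = cam.project(world)
        if setup.checkerboard_noise_px > 0:
            px = px + rng.normal(0.0, setup.checkerboard_noise_px, size=px.shape)
        setattr(rec, attr, (world_reported, px))

    observer_az_world = float(rng.uniform(0.0, 360.0))
    rec.observer_azimuth_aligned = float(
        np.mod(observer_az_world - flight.sun_azimuth + 180.0, 360.0) - 180.0
    )
    rec.meta.update(
        {
            "world_transform": (R, tvec),
            "observer_azimuth_world": observer_az_world,
            "sun_azimuth_world": flight.sun_azimuth,
        }
    )
    return rec


def replace_config(config: FlightConfig, **kwargs) -> FlightConfig:
    """Functional update of a FlightConfig (dataclasses.replace re-export)."""
    return replace(config, **kwargs)
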