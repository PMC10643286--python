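"""Cohort-level statistics and the end-to-end pipeline.

``process_recording`` takes one two-view recording through synchronisation,
calibration, triangulation, world alignment, kinematics and segmentation;
``run_synthetic_cohort`` repeats that for a whole cohort of synthetic drinking
events and assembles the statistics reported for the field data: per-flight
phase means, cohort medians and quartiles, Wilcoxon signed-rank comparisons
of approach vs departure, time-aligned mean curves, and the weighted MMR
directional tests in the sun and observer reference frames.

Every drinking event is treated as a different animal (flights are the
statistical unit); no repeated-measures structure is assumed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .alignment import Trajectory3D, WorldFrame, align_frame
from .circular import MMRResult, axial_transform, mmr_test, rotate_reference
from .kinematics import KinematicsSeries, compute_kinematics
from .segmentation import FlightPhases, FlightSegment, extract_straight_segments, segment_phases
from .stereo import dlt_calibrate, triangulate
from .sync import SyncResult, decode_counts, synchronise
from .synthetic import (
    FlightConfig,
    GroundTruthFlight,
    RecordingSetup,
    TwoViewRecording,
    generate_flight,
    simulate_recording,
)

logger = logging.getLogger(__name__)

PHASE_NAMES = ("approach", "descent", "landing_strict", "departure")
METRICS = ("altitude", "total_speed", "horizontal_speed", "vertical_speed", "vertical_velocity")


@dataclass
class FlightResult:
    """Everything the pipeline produced for one drinking event."""

    flight_id: int
    sync: SyncResult
    trajectory: Trajectory3D
    world: WorldFrame
    kinematics: KinematicsSeries
    phases: FlightPhases
    segments: list[FlightSegment]
    observer_azimuth: float | None = None
    qc: dict = field(default_factory=dict)


def process_recording(
    rec: TwoViewRecording,
    use_calibrated_cameras: bool = True,
    flight_id: int = 0,
    contact_threshold: float = 10.0,
    r_kappa_threshold: float = 210.0,
    cutoff: float = 100.0,
    upsample_factor: int = 3,
) -> FlightResult:
    """Run one recording through the full reconstruction and analysis chain."""
    counts_a, _ = decode_counts(rec.view_a.led)
    counts_b, _ = decode_counts(rec.view_b.led)
    sync = synchronise(counts_a, counts_b)
    off = sync.offset

    n_overlap = min(len(rec.view_a), len(rec.view_b) - off)
    if n_overlap < 10:
        raise ValueError(f"flight {flight_id}: almost no synchronised overlap")
    a = rec.view_a
    b = rec.view_b

    if use_calibrated_cameras:
        if rec.calibration_a is None or rec.calibration_b is None:
            raise ValueError(f"flight {flight_id}: no calibration correspondences supplied")
        cam_a = dlt_calibrate(*rec.calibration_a, image_size=rec.camera_a.image_size)
        cam_b = dlt_calibrate(*rec.calibration_b, image_size=rec.camera_b.image_size)
    else:
        cam_a, cam_b = rec.camera_a, rec.camera_b

    sl_a = slice(0, n_overlap)
    sl_b = slice(off, off + n_overlap)
    front = triangulate(cam_a, cam_b, a.front_px[sl_a], b.front_px[sl_b])
    rear = triangulate(cam_a, cam_b, a.rear_px[sl_a], b.rear_px[sl_b])
    landmarks = triangulate(cam_a, cam_b, a.landmarks_px, b.landmarks_px).points
    sh_base = triangulate(cam_a, cam_b, a.shadow_base_px, b.shadow_base_px).points
    sh_tip = triangulate(cam_a, cam_b, a.shadow_tip_px, b.shadow_tip_px).points

    traj, world = align_frame(
        front.points,
        rear.points,
        landmarks,
        sh_tip - sh_base,
        fs=rec.fs,
        contact_threshold=contact_threshold,
    )
    kin = compute_kinematics(traj, cutoff=cutoff, upsample_factor=upsample_factor)
    phases = segment_phases(kin, contact_threshold=contact_threshold)
    segments = extract_straight_segments(kin, phases, r_kappa_threshold=r_kappa_threshold)

    qc = {
        "sync_confidence": sync.confidence,
        "triangulation_residual_px": float(np.nanmedian(front.residual_px)),
        "plane_fit_rmse_mm": world.plane_fit_rmse,
        "shadow_elevation_deg": world.shadow_elevation_deg,
        "reprojection_rmse_px": (cam_a.reprojection_rmse, cam_b.reprojection_rmse),
    }
    return FlightResult(
        flight_id=flight_id,
        sync=sync,
        trajectory=traj,
        world=world,
        kinematics=kin,
        phases=phases,
        segments=segments,
        observer_azimuth=rec.observer_azimuth_aligned,
        qc=qc,
    )


# ---------------------------------------------------------------------------
# phase statistics
# ---------------------------------------------------------------------------


def phase_means(kin: KinematicsSeries, phases: FlightPhases) -> dict[str, dict[str, float]]:
    """Per-phase arithmetic means of the kinematic quantities for one flight.

    ``descent`` is the flight-analysis landing (descent onset through the end
    of the strict landing); ``landing_strict`` the altitude < 10 mm window.
    Empty phases are reported as None and excluded from paired tests.
    """
    out: dict[str, dict[str, float]] = {}
    values = {
        "altitude": kin.altitude,
        "total_speed": kin.total_speed,
        "horizontal_speed": kin.horizontal_speed,
        "vertical_speed": kin.vertical_speed,
        "vertical_velocity": kin.vertical_velocity,
    }
    for phase in PHASE_NAMES:
        i0, i1 = phases.interval(phase)
        if i1 <= i0:
            logger.warning("empty phase %s; excluded from summaries", phase)
            out[phase] = {m: np.nan for m in METRICS}
            continue
        out[phase] = {m: float(np.nanmean(v[i0:i1])) for m, v in values.items()}
    return out


def paired_phase_test(
    approach_means: np.ndarray, departure_means: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on per-flight phase means.

    Exact null distribution for n <= 25 pairs with no zero or tied
    differences; normal approximation with continuity correction otherwise.
    Degenerate all-zero differences give p = 1.
    """
    x = np.asarray(approach_means, dtype=float)
    y = np.asarray(departure_means, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 6:
        raise ValueError("need at least 6 complete pairs for the signed-rank test")
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    nz = d[d != 0]
    exact_ok = nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size
    res = wilcoxon(x, y, correction=True, method="exact" if exact_ok else "approx")
    return float(res.statistic), float(res.pvalue)


@dataclass
class MeanCurves:
    """Cohort mean time courses on the common t-0-aligned grid."""

    t: np.ndarray
    altitude: np.ndarray = field(repr=False)
    horizontal_speed: np.ndarray = field(repr=False)
    vertical_velocity: np.ndarray = field(repr=False)
    n: np.ndarray = field(repr=False)  # flights contributing per time point

    @property
    def vertical_velocity_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, mean vz) pair consumable by segment_phases' cohort-mean mode."""
        return self.t, self.vertical_velocity


def mean_curves(kins: list[KinematicsSeries], min_flights: int = 2) -> MeanCurves:
    """Pointwise cohort means of t-0-aligned kinematic series.

    Defined only where at least ``min_flights`` flights contribute; flights of
    different lengths simply stop contributing toward the window edges.
    """
    if not kins:
        raise ValueError("no flights supplied")
    dt = kins[0].dt
    starts = [int(round(k.t[0] / dt)) for k in kins]
    stops = [s + len(k) for s, k in zip(starts, kins)]
    lo, hi = min(starts), max(stops)
    size = hi - lo
    acc = {m: np.zeros(size) for m in ("altitude", "horizontal_speed", "vertical_velocity")}
    counts = np.zeros(size, dtype=int)
    for s, k in zip(starts, kins):
        sl = slice(s - lo, s - lo + len(k))
        acc["altitude"][sl] += k.altitude
        acc["horizontal_speed"][sl] += k.horizontal_speed
        acc["vertical_velocity"][sl] += k.vertical_velocity
        counts[sl] += 1
    keep = counts >= min_flights
    if not keep.any():
        raise ValueError("no overlapping support across flights")
    i0, i1 = np.flatnonzero(keep)[[0, -1]]
    sl = slice(i0, i1 + 1)
    n = counts[sl]
    safe = np.maximum(n, 1)
    return MeanCurves(
        t=(np.arange(lo, hi)[sl]) * dt,
        altitude=np.where(n >= min_flights, acc["altitude"][sl] / safe, np.nan),
        horizontal_speed=np.where(n >= min_flights, acc["horizontal_speed"][sl] / safe, np.nan),
        vertical_velocity=np.where(
            n >= min_flights, acc["vertical_velocity"][sl] / safe, np.nan
        ),
        n=n,
    )


def phase_table(results: list[FlightResult]) -> pd.DataFrame:
    """Long-format table of per-flight, per-phase means."""
    rows = []
    for res in results:
        means = phase_means(res.kinematics, res.phases)
        for phase, vals in means.items():
            rows.append({"flight": res.flight_id, "phase": phase, **vals})
    return pd.DataFrame(rows)


def cohort_summary(table: pd.DataFrame) -> dict:
    """Medians and quartiles per phase plus approach-vs-departure paired tests.

    Quartiles use linear interpolation (numpy default), matching the common
    convention for small-sample quartile reporting.
    """
    summary: dict = {"phases": {}, "paired_tests": {}}
    for phase in PHASE_NAMES:
        sub = table[table["phase"] == phase]
        entry = {}
        for m in METRICS:
            v = sub[m].to_numpy(dtype=float)
            v = v[~np.isnan(v)]
            if v.size == 0:
                entry[m] = None
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            entry[m] = {"median": float(med), "q1": float(q1), "q3": float(q3), "n": int(v.size)}
        summary["phases"][phase] = entry
    app = table[table["phase"] == "approach"].set_index("flight")
    dep = table[table["phase"] == "departure"].set_index("flight")
    common = app.index.intersection(dep.index)
    for m in METRICS:
        try:
            stat, p = paired_phase_test(
                app.loc[common, m].to_numpy(), dep.loc[common, m].to_numpy()
            )
            summary["paired_tests"][m] = {"statistic": stat, "p_value": p, "n": int(len(common))}
        except ValueError as exc:
            summary["paired_tests"][m] = {"error": str(exc)}
    return summary


# ---------------------------------------------------------------------------
# directional analysis over a cohort
# ---------------------------------------------------------------------------


def directional_tests(
    results: list[FlightResult],
    reference: str = "sun",
    axial: bool = False,
    n_mc: int = 10_000,
    seed: int = 0,
) -> dict[str, MMRResult]:
    """Weighted MMR test per phase on the pooled straight-segment directions.

    ``reference='sun'`` uses the aligned-frame angles directly (sun at 0);
    ``'observer'`` subtracts each recording's observer azimuth first.  With
    ``axial=True`` segment means are angle-doubled before testing, detecting
    bimodal (axis-aligned) preferences; the unmodified vector lengths remain
    the weights, ranked within each phase's segment set.
    """
    if reference not in ("sun", "observer"):
        raise ValueError("reference must be 'sun' or 'observer'")
    pooled: dict[str, list[tuple[float, float]]] = {"approach": [], "landing": [], "departure": []}
    for res in results:
        for seg in res.segments:
            angle = seg.mean_direction
            if reference == "observer":
                if res.observer_azimuth is None:
                    raise ValueError(f"flight {res.flight_id} has no observer azimuth")
                angle = float(rotate_reference(angle, res.observer_azimuth))
            pooled[seg.phase].append((angle, seg.r))
    out: dict[str, MMRResult] = {}
    for k, (phase, pairs) in enumerate(sorted(pooled.items())):
        if len(pairs) < 3:
            logger.warning("phase %s has %d segments; MMR skipped", phase, len(pairs))
            continue
        angles = np.array([a for a, _ in pairs])
        lengths = np.array([r for _, r in pairs])
        if axial:
            angles = axial_transform(angles)
        out[phase] = mmr_test(angles, lengths, n_mc=n_mc, seed=seed + k)
    return out


# ---------------------------------------------------------------------------
# full synthetic cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortResult:
    results: list[FlightResult]
    flights: list[GroundTruthFlight]
    table: pd.DataFrame
    summary: dict
    curves: MeanCurves
    mmr: dict
    seed: int
    config: FlightConfig


def cohort_mean_descent_onset(
    results: list[FlightResult], curves: MeanCurves, onset_fraction: float = 0.2
) -> float:
    """Descent onset (s) read off the cohort-mean vertical-velocity curve.

    This is the cohort-level analogue of the per-flight rule: the latest
    pre-contact crossing of 20% of the mean curve's peak negative value.
    Only time points where at least half the flights still contribute are
    used — toward the window edges the "mean" is a couple of noisy flights
    and its minima are meaningless.
    """
    t, vz = curves.vertical_velocity_curve
    support = curves.n >= max(2, int(np.ceil(0.5 * curves.n.max())))
    pre = (t < 0) & ~np.isnan(vz) & support
    if not pre.any():
        raise ValueError("mean curve has no pre-contact support")
    tt, vv = t[pre], vz[pre]
    peak = float(vv.min())
    if peak >= 0:
        raise ValueError("cohort mean vertical velocity never negative before contact")
    thr = onset_fraction * peak
    crossings = np.flatnonzero((vv[:-1] > thr) & (vv[1:] <= thr))
    idx = int(crossings[-1] + 1) if crossings.size else int(np.argmin(vv))
    return float(tt[idx])


def run_synthetic_cohort(
    n_flights: int = 66,
    config: FlightConfig | None = None,
    setup: RecordingSetup | None = None,
    seed: int = 0,
    use_calibrated_cameras: bool = True,
    n_mc: int = 10_000,
    r_kappa_threshold: float = 210.0,
) -> CohortResult:
    """Generate, record, reconstruct and analyse a cohort of drinking events.

    The default 66 flights mirror the number of usable field events; all
    randomness derives from ``seed``.
    """
    config = config or FlightConfig()
    setup = setup or RecordingSetup()
    master = np.random.default_rng(seed)
    flight_seeds = master.integers(0, 2**31 - 1, size=(n_flights, 2))

    # stratified quantiles per calibrated quantity: the cohort then carries the
    # target distribution's quantile structure exactly (up to 1/n jitter), so
    # cohort medians estimate the calibration medians without sqrt(n) noise
    strat_keys = (
        "approach_speed",
        "approach_vertical_speed",
        "approach_altitude",
        "departure_altitude",
        "departure_horizontal_speed",
        "departure_vertical_speed",
    )
    strata = (np.arange(n_flights) + 0.5) / n_flights
    quantile_grid = {
        key: strata[master.permutation(n_flights)] for key in strat_keys
    }

    flights: list[GroundTruthFlight] = []
    results: list[FlightResult] = []
    for i in range(n_flights):
        flight = generate_flight(
            config,
            rng_seed=int(flight_seeds[i, 0]),
            quantiles={key: float(quantile_grid[key][i]) for key in strat_keys},
        )
        rec = simulate_recording(flight, setup, rng_seed=int(flight_seeds[i, 1]))
        try:
            res = process_recording(
                rec,
                use_calibrated_cameras=use_calibrated_cameras,
                flight_id=i,
                r_kappa_threshold=r_kappa_threshold,
            )
        except Exception as exc:  # noqa: BLE001 - propagate with the flight id
            raise RuntimeError(f"flight {i} failed in the pipeline: {exc}") from exc
        flights.append(flight)
        results.append(res)

    table = phase_table(results)
    summary = cohort_summary(table)
    curves = mean_curves([r.kinematics for r in results])
    summary["descent_onset"] = {
        "per_flight_mean_s": float(
            np.mean([r.kinematics.t[r.phases.descent[0]] for r in results])
        ),
        "cohort_mean_curve_s": cohort_mean_descent_onset(results, curves),
    }
    summary["strict_landing_duration"] = {
        "mean_s": float(np.mean([r.phases.duration("landing_strict", r.kinematics.dt) for r in results])),
        "sd_s": float(np.std([r.phases.duration("landing_strict", r.kinematics.dt) for r in results])),
    }
    mmr = {
        "sun": directional_tests(results, "sun", n_mc=n_mc, seed=seed),
        "observer": directional_tests(results, "observer", n_mc=n_mc, seed=seed + 100),
        "sun_axial": directional_tests(results, "sun", axial=True, n_mc=n_mc, seed=seed + 200),
    }
    summary["assumptions"] = {"each_event_different_animal": True}
    return CohortResult(
        results=results,
        flights=flights,
        table=table,
        summary=summary,
        curves=curves,
        mmr=mmr,
        seed=seed,
        config=config,
    )


def summary_json(cohort: CohortResult) -> str:
    """Deterministic machine-readable cohort summary."""
    payload = {
        "seed": cohort.seed,
        "n_flights": len(cohort.results),
        "summary": cohort.summary,
        "mmr": {
            frame: {
                phase: {
                    "R_star": r.r_star,
                    "mean_angle_deg": r.mean_angle,
                    "p_value": r.p_value,
                    "n_segments": r.n,
                }
                for phase, r in tests.items()
            }
            for frame, tests in cohort.mmr.items()
        },
        "qc": {
            "median_triangulation_residual_px": float(
                np.median([r.qc["triangulation_residual_px"] for r in cohort.results])
            ),
            "max_shadow_elevation_deg": float(
                np.max([r.qc["shadow_elevation_deg"] for r in cohort.results])
            ),
        },
    }
    return json.dumps(payload, sort_keys=True, indent=2)
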