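"""Flight-phase segmentation and straight-segment isolation.

Phases
------
* **strict landing**: the contiguous window around t = 0 where the CoM
  altitude is below 10 mm (about half a body length) — the actual time on the
  water, used for heading-based directional analysis.
* **descent (+ landing)**: from descent onset to the end of the strict
  landing.  Onset is where the vertical-velocity curve last crosses 20% of its
  peak negative value before contact — evaluated on the per-flight curve by
  default, or on a supplied cohort-mean curve.
* **approach**: everything before descent onset; **departure**: everything
  after the strict landing ends.

Straight segments
-----------------
Fly flight is a chain of straight stretches separated by rapid body saccades.
Straight segments are maximal runs where the 2D CoM radius of curvature
exceeds a threshold (default 210 mm, much larger than the 20-25 mm body),
intersected with the phase windows; runs shorter than 10 ms are excluded.
Approach/departure segments carry bearing-based directions, landing segments
heading-based ones (during the landing reversal the body yaws ~180 degrees
while the bearing is retained, so the bearing stops tracking where the animal
points).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .circular import circular_mean, resultant_length
from .filtering import lowpass_filter
from .kinematics import KinematicsSeries

logger = logging.getLogger(__name__)


class SegmentationError(ValueError):
    pass


@dataclass
class FlightPhases:
    """Half-open sample-index intervals [start, stop) on the up-sampled grid."""

    approach: tuple[int, int]
    descent: tuple[int, int]  # descent onset .. end of strict landing
    landing_strict: tuple[int, int]
    departure: tuple[int, int]
    excluded: list[tuple[int, int]] = field(default_factory=list)

    def interval(self, phase: str) -> tuple[int, int]:
        return getattr(self, phase)

    def duration(self, phase: str, dt: float) -> float:
        i0, i1 = self.interval(phase)
        return (i1 - i0) * dt


@dataclass
class FlightSegment:
    """One saccade-free straight stretch with its mean direction and weight."""

    phase: str  # approach | landing | departure
    start: int
    stop: int  # half-open
    t_start: float
    t_stop: float
    mean_direction: float  # deg
    r: float  # resultant length of summed unit direction vectors (weight)
    n_samples: int


def _contiguous_run(mask: np.ndarray, index: int) -> tuple[int, int] | None:
    """The [start, stop) run of True containing ``index`` (or a neighbour)."""
    for i in (index, index + 1, index - 1):
        if 0 <= i < mask.size and mask[i]:
            lo = i
            while lo > 0 and mask[lo - 1]:
                lo -= 1
            hi = i + 1
            while hi < mask.size and mask[hi]:
                hi += 1
            return lo, hi
    return None


def segment_phases(
    kin: KinematicsSeries,
    contact_threshold: float = 10.0,
    onset_fraction: float = 0.2,
    mean_vertical_velocity_curve: tuple[np.ndarray, np.ndarray] | None = None,
    onset_smooth_cutoff: float | None = 20.0,
) -> FlightPhases:
    """Partition a flight into approach / descent+landing / departure.

    ``mean_vertical_velocity_curve``: optional (t, vz) cohort-mean curve; when
    given, descent onset is read off that curve instead of the flight's own
    (the cohort-mean mode used for the headline onset time).  Per-flight
    curves are additionally smoothed (``onset_smooth_cutoff``) so the 20%
    crossing is not set by differentiation noise.
    """
    alt = kin.altitude
    below = alt < contact_threshold
    i0 = int(np.argmin(np.abs(kin.t)))
    landing = _contiguous_run(below, i0)
    if landing is None:
        raise SegmentationError(
            f"no altitude < {contact_threshold} mm interval around t = 0; not a water contact"
        )
    iL0, iL1 = landing

    if mean_vertical_velocity_curve is not None:
        t_curve, vz_curve = mean_vertical_velocity_curve
        t_curve = np.asarray(t_curve, dtype=float)
        vz_curve = np.asarray(vz_curve, dtype=float)
        vz = np.interp(kin.t, t_curve, vz_curve)
    else:
        vz = kin.vertical_velocity
        if onset_smooth_cutoff is not None:
            vz = lowpass_filter(vz, fs=kin.fs, cutoff=onset_smooth_cutoff)

    pre = np.arange(iL0)
    if pre.size < 3:
        raise SegmentationError("no pre-contact samples to locate descent onset")
    vz_pre = vz[pre]
    peak = float(np.nanmin(vz_pre))
    if peak >= 0:
        raise SegmentationError("vertical velocity never negative before contact")
    thr = onset_fraction * peak
    crossings = np.flatnonzero((vz_pre[:-1] > thr) & (vz_pre[1:] <= thr))
    if crossings.size:
        onset = int(crossings[-1] + 1)
    else:  # already descending faster than the threshold from the first sample
        onset = int(np.flatnonzero(vz_pre <= thr)[0])

    n = len(kin)
    return FlightPhases(
        approach=(0, onset),
        descent=(onset, iL1),
        landing_strict=(iL0, iL1),
        departure=(iL1, n),
    )


def extract_straight_segments(
    kin: KinematicsSeries,
    phases: FlightPhases,
    r_kappa_threshold: float = 210.0,
    min_duration_s: float = 0.010,
) -> list[FlightSegment]:
    """Isolate saccade-free straight segments and their directions.

    Within each directional phase window, straight samples are those whose 2D
    curvature radius exceeds ``r_kappa_threshold`` *and* whose direction is
    defined (bearing exists above the speed floor; heading always does).
    Maximal runs shorter than ``min_duration_s`` are dropped and recorded in
    ``phases.excluded``.  Sensitivity thresholds of 105 and 320 mm bracket the
    210 mm default.
    """
    min_samples = max(int(np.ceil(min_duration_s / kin.dt)), 1)
    straight = kin.curvature_radius > r_kappa_threshold  # NaN-safe: NaN -> False
    segments: list[FlightSegment] = []
    spec = [
        ("approach", phases.approach, kin.bearing),
        ("landing", phases.landing_strict, kin.heading),
        ("departure", phases.departure, kin.bearing),
    ]
    for phase_name, (p0, p1), directions in spec:
        mask = np.zeros(len(kin), dtype=bool)
        mask[p0:p1] = True
        mask &= straight & ~np.isnan(directions)
        padded = np.concatenate([[False], mask, [False]]).astype(int)
        edges = np.diff(padded)
        starts = np.flatnonzero(edges == 1)
        stops = np.flatnonzero(edges == -1)
        for s0, s1 in zip(starts, stops):
            if s1 - s0 < min_samples:
                phases.excluded.append((int(s0), int(s1)))
                continue
            dirs = directions[s0:s1]
            try:
                mean_dir = circular_mean(dirs)
            except ValueError:
                logger.warning(
                    "segment %d:%d in %s has zero resultant; skipped", s0, s1, phase_name
                )
                continue
            segments.append(
                FlightSegment(
                    phase=phase_name,
                    start=int(s0),
                    stop=int(s1),
                    t_start=float(kin.t[s0]),
                    t_stop=float(kin.t[s1 - 1]),
                    mean_direction=mean_dir,
                    r=resultant_length(dirs),
                    n_samples=int(s1 - s0),
                )
            )
    return segments
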