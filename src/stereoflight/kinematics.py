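"""Trajectory filtering, upsampling and flight kinematics.

Aligned front/rear tracks (mm, sampled at the camera frame rate f_s) are
low-pass filtered with a zero-phase second-order Butterworth (cut-off 100 Hz),
up-sampled by a factor F_up = 3 with a cubic spline, and differentiated with
central differences at dt = 1 / (f_s * F_up).  From the centre-of-mass path
(midpoint of front and rear) we derive altitude, horizontal/vertical/total
speed, and the 2D radius of curvature; from the body axis (rear -> front) we
derive heading and pitch; bearing follows the horizontal velocity vector.

Angle conventions: degrees in (-180, 180], measured from the +X axis (the sun
azimuth after world alignment), positive counter-clockwise seen from +Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Trajectory3D
from .filtering import lowpass_filter, upsample

__all__ = [
    "CURVATURE_CAP_MM",
    "KinematicsSeries",
    "centre_of_mass",
    "compute_kinematics",
    "curvature_radius",
    "lowpass_filter",
    "upsample",
    "wrap_angle",
]

CURVATURE_CAP_MM = 1e6  # sentinel radius for locally straight paths


def wrap_angle(angles_deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles in degrees to the interval (-180, 180]."""
    a = np.mod(np.asarray(angles_deg, dtype=float), 360.0)
    a = np.where(a > 180.0, a - 360.0, a)
    return float(a) if np.ndim(angles_deg) == 0 else a


def centre_of_mass(front: np.ndarray, rear: np.ndarray) -> np.ndarray:
    """CoM proxy: elementwise midpoint of the front and rear body points."""
    front = np.asarray(front, dtype=float)
    rear = np.asarray(rear, dtype=float)
    if front.shape != rear.shape:
        raise ValueError("front and rear tracks must have matching shapes")
    return 0.5 * (front + rear)


def curvature_radius(
    xy: np.ndarray, dt: float, smooth_cutoff: float | None = None
) -> np.ndarray:
    """Radius of curvature (mm) of a 2D path sampled at step ``dt``.

    r = (x'^2 + y'^2)^(3/2) / |x' y'' - y' x''| with central differences.
    Straight stretches (vanishing cross term) are capped at the sentinel
    ``CURVATURE_CAP_MM``; zero-speed samples are NaN (undefined direction).

    ``smooth_cutoff`` applies an extra zero-phase Butterworth to the path
    before differentiating: second derivatives of a 100-Hz-bandwidth track are
    noise-dominated, while body saccades are large
    (an order of magnitude below the straightness threshold), so they survive
    smoothing down to ~12 Hz while straight stretches stop dipping below it.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must be (n, 2)")
    if xy.shape[0] < 3:
        raise ValueError("curvature needs at least 3 samples")
    if smooth_cutoff is not None:
        xy = lowpass_filter(xy, fs=1.0 / dt, cutoff=smooth_cutoff)
    d1 = np.gradient(xy, dt, axis=0)
    d2 = np.gradient(d1, dt, axis=0)
    speed2 = np.sum(d1**2, axis=1)
    cross = np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = speed2**1.5 / cross
    r = np.where(cross == 0, CURVATURE_CAP_MM, r)
    r = np.minimum(r, CURVATURE_CAP_MM)
    r[speed2 == 0] = np.nan
    return r


@dataclass
class KinematicsSeries:
    """Per-time-point kinematic quantities on the up-sampled grid."""

    t: np.ndarray  # s, relative to first water contact
    com: np.ndarray = field(repr=False)  # (n, 3) mm
    front: np.ndarray = field(repr=False)  # (n, 3) mm
    rear: np.ndarray = field(repr=False)  # (n, 3) mm
    altitude: np.ndarray = field(repr=False)  # mm
    horizontal_speed: np.ndarray = field(repr=False)  # m/s
    vertical_velocity: np.ndarray = field(repr=False)  # m/s, signed
    total_speed: np.ndarray = field(repr=False)  # m/s
    heading: np.ndarray = field(repr=False)  # deg
    bearing: np.ndarray = field(repr=False)  # deg, NaN below the speed floor
    pitch: np.ndarray = field(repr=False)  # deg, positive head-up
    curvature_radius: np.ndarray = field(repr=False)  # mm
    dt: float = 0.0
    speed_floor: float = 0.05

    @property
    def vertical_speed(self) -> np.ndarray:
        return np.abs(self.vertical_velocity)

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    def __len__(self) -> int:
        return self.t.size


def compute_kinematics(
    traj: Trajectory3D,
    cutoff: float = 100.0,
    upsample_factor: int = 3,
    speed_floor: float = 0.05,
    curvature_smooth_cutoff: float | None = 12.0,
) -> KinematicsSeries:
    """Filter, up-sample and differentiate an aligned trajectory.

    ``speed_floor`` (m/s): below this horizontal speed the bearing is marked
    NaN instead of amplifying noise into a meaningless direction.
    """
    fs = traj.fs
    front = lowpass_filter(traj.front, fs=fs, cutoff=cutoff)
    rear = lowpass_filter(traj.rear, fs=fs, cutoff=cutoff)
    front = upsample(front, upsample_factor)
    rear = upsample(rear, upsample_factor)
    dt = 1.0 / (fs * upsample_factor)
    n = front.shape[0]
    t = traj.t[0] + dt * np.arange(n)

    com = centre_of_mass(front, rear)
    vel = np.gradient(com, dt, axis=0) / 1000.0  # mm/s -> m/s
    horizontal_speed = np.hypot(vel[:, 0], vel[:, 1])
    vertical_velocity = vel[:, 2]
    total_speed = np.sqrt(horizontal_speed**2 + vertical_velocity**2)

    body = front - rear
    heading = wrap_angle(np.degrees(np.arctan2(body[:, 1], body[:, 0])))
    pitch = np.degrees(np.arctan2(body[:, 2], np.hypot(body[:, 0], body[:, 1])))
    bearing = wrap_angle(np.degrees(np.arctan2(vel[:, 1], vel[:, 0])))
    bearing = np.where(horizontal_speed >= speed_floor, bearing, np.nan)

    r_kappa = curvature_radius(com[:, :2], dt, smooth_cutoff=curvature_smooth_cutoff)

    return KinematicsSeries(
        t=t,
        com=com,
        front=front,
        rear=rear,
        altitude=com[:, 2].copy(),
        horizontal_speed=horizontal_speed,
        vertical_velocity=vertical_velocity,
        total_speed=total_speed,
        heading=heading,
        bearing=bearing,
        pitch=pitch,
        curvature_radius=r_kappa,
        dt=dt,
        speed_floor=speed_floor,
    )
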