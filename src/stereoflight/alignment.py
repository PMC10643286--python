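"""Rigid alignment of reconstructed flights into the common analysis frame.

Each two-camera reconstruction lives in the arbitrary coordinate system of its
calibration.  The analysis frame is defined by the scene itself:

* the water-surface plane (total-least-squares fit through >= 4 digitised
  ground landmarks) becomes the XY plane, its normal the +Z axis;
* the sun azimuth becomes the +X axis, fixed by rotating about Z until the
  digitised shadow of a vertical beam points along -X;
* the origin is the water-contact point: the lowest CoM position within
  +/- 20 ms of t = 0, which itself is the first frame with CoM altitude below
  the contact threshold (10 mm, about half a body length) while descending.

The whole transform is rigid (two rotations and one translation), so all
distances, speeds and relative angles are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filtering import lowpass_filter


class AlignmentError(ValueError):
    """Degenerate alignment input (collinear landmarks, vertical shadow...)."""


class NoWaterContactError(AlignmentError):
    """The altitude series never crosses below the contact threshold."""


@dataclass
class WorldFrame:
    """The rigid transform that carried a reconstruction into the analysis frame."""

    rotation: np.ndarray  # (3, 3) orthonormal, det +1
    translation: np.ndarray  # (3,) mm, subtracted after rotation
    t0_index: int
    sun_azimuth_world: float  # deg, sun azimuth in the pre-alignment frame
    plane_fit_rmse: float  # mm
    shadow_elevation_deg: float  # QC: angle between shadow vector and its XY projection


@dataclass
class Trajectory3D:
    """Time-indexed front/rear body points in the aligned analysis frame."""

    t: np.ndarray  # s, 0 at first water contact
    front: np.ndarray = field(repr=False)  # (n, 3) mm
    rear: np.ndarray = field(repr=False)  # (n, 3) mm
    fs: float = 250.0
    world: WorldFrame | None = None

    @property
    def com(self) -> np.ndarray:
        return 0.5 * (self.front + self.rear)

    def __len__(self) -> int:
        return self.t.size


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares plane through >= 4 landmarks.

    Returns (unit normal, centroid, rmse of point-plane distances in mm).
    The normal's sign is arbitrary here; callers orient it toward the flight.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("landmarks must be (n, 3)")
    if pts.shape[0] < 4:
        raise ValueError("plane fit needs at least 4 landmarks")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] <= 1e-10 * max(s[0], 1e-300):
        raise AlignmentError("landmarks are collinear; plane undefined")
    normal = vt[-1]
    rmse = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return normal, centroid, rmse


def _rotation_to_z(normal: np.ndarray) -> np.ndarray:
    """Minimal rotation taking ``normal`` to +Z (axis = n x z; no roll)."""
    n = normal / np.linalg.norm(normal)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(n, z)
    s = np.linalg.norm(axis)
    c = float(n @ z)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 degrees about X
        return np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def _rotation_about_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def assign_t0(
    altitude: np.ndarray,
    vertical_velocity: np.ndarray,
    contact_threshold: float = 10.0,
    t0_frame: int | None = None,
) -> int:
    """First descending sample of the below-threshold window around touch-down.

    The frame of first water contact was assigned manually in field work; this
    automates it with the same threshold that defines the strict landing
    phase, anchored at the global altitude minimum so that spurious dips far
    from the water cannot define t = 0.  ``t0_frame`` overrides the rule
    entirely to preserve a manual workflow.
    """
    if t0_frame is not None:
        return int(t0_frame)
    altitude = np.asarray(altitude, dtype=float)
    vertical_velocity = np.asarray(vertical_velocity, dtype=float)
    below = altitude < contact_threshold
    if not below.any():
        raise NoWaterContactError(
            f"no water contact found: altitude never descends below {contact_threshold} mm"
        )
    # the landing is the sub-threshold excursion containing the global
    # altitude minimum; dips elsewhere (reconstruction tilt far from the
    # calibrated volume, noise) must not define t = 0
    k_min = int(np.argmin(altitude))
    lo = k_min
    while lo > 0 and below[lo - 1]:
        lo -= 1
    descending = np.flatnonzero(vertical_velocity[lo : k_min + 1] < 0)
    if descending.size == 0:
        raise NoWaterContactError(
            "no water contact found: altitude never descends into the contact window"
        )
    return lo + int(descending[0])


def align_frame(
    front: np.ndarray,
    rear: np.ndarray,
    landmarks: np.ndarray,
    shadow_vector: np.ndarray,
    fs: float = 250.0,
    contact_threshold: float = 10.0,
    t0_frame: int | None = None,
    lowpass_cutoff: float = 100.0,
    contact_window_ms: float = 20.0,
) -> tuple[Trajectory3D, WorldFrame]:
    """Carry a raw reconstruction into the water-plane / sun-azimuth frame.

    Rotation 1 maps the landmark-plane normal (oriented toward the flight
    path) onto +Z; rotation 2, about Z, maps the XY projection of the shadow
    vector onto -X so the sun azimuth points along +X; the translation
    subtracts the lowest filtered-CoM point within +/- ``contact_window_ms``
    of t = 0.  t = 0 itself is assigned by :func:`assign_t0` on the filtered
    altitude (or taken from ``t0_frame`` verbatim).

    The t0 search and the lowest-point translation both use the low-pass
    filtered CoM so a single noisy sample cannot define the origin.
    """
    front = np.asarray(front, dtype=float)
    rear = np.asarray(rear, dtype=float)
    if front.shape != rear.shape or front.ndim != 2 or front.shape[1] != 3:
        raise ValueError("front and rear must be matching (n, 3) tracks")
    shadow_vector = np.asarray(shadow_vector, dtype=float)

    normal, centroid, plane_rmse = fit_plane(landmarks)
    com_raw = 0.5 * (front + rear)
    if (com_raw.mean(axis=0) - centroid) @ normal < 0:
        normal = -normal  # orient the plane normal toward the flight path

    R1 = _rotation_to_z(normal)
    sh1 = R1 @ shadow_vector
    horiz = np.hypot(sh1[0], sh1[1])
    if horiz < 1e-9 * np.linalg.norm(shadow_vector):
        raise AlignmentError("shadow vector parallel to the plane normal; azimuth undefined")
    shadow_elevation = float(np.degrees(np.arctan2(abs(sh1[2]), horiz)))
    phi = np.arctan2(sh1[1], sh1[0])
    R2 = _rotation_about_z(np.pi - phi)  # shadow projection -> -X
    R = R2 @ R1

    front_r = front @ R.T
    rear_r = rear @ R.T
    com_r = 0.5 * (front_r + rear_r)

    com_f = lowpass_filter(com_r, fs=fs, cutoff=lowpass_cutoff)
    # altitude for the t0 search is referenced to the lowest filtered CoM
    # position (the eventual origin), matching how the aligned-frame altitude
    # is reported: the water surface sits ~half a body height below the CoM
    # at touch-down, so the plane itself is the wrong zero for a CoM altitude
    altitude_f = com_f[:, 2] - float(np.min(com_f[:, 2]))
    vz_f = np.gradient(altitude_f, 1.0 / fs)
    t0 = assign_t0(altitude_f, vz_f, contact_threshold, t0_frame)

    # translation: the lowest filtered-CoM point of the landing.  The window
    # spans from contact_window_ms before t0 to contact_window_ms past the
    # global altitude minimum: the threshold crossing that defines t0 precedes
    # the actual touch-down, so a window closed at t0 + 20 ms would miss the
    # on-water stretch where the true lowest point lies.
    w = max(int(round(contact_window_ms * 1e-3 * fs)), 0)
    k_min = int(np.argmin(com_f[:, 2]))
    lo = max(0, min(t0, k_min) - w)
    hi = min(len(com_f), max(t0, k_min) + w + 1)
    k = lo + int(np.argmin(com_f[lo:hi, 2]))
    translation = com_f[k].copy()

    shadow_world_az = np.degrees(phi)  # in the rotation-1 frame
    sun_azimuth_world = float(np.mod(shadow_world_az + 180.0 + 180.0, 360.0) - 180.0)

    frame = WorldFrame(
        rotation=R,
        translation=translation,
        t0_index=t0,
        sun_azimuth_world=sun_azimuth_world,
        plane_fit_rmse=plane_rmse,
        shadow_elevation_deg=shadow_elevation,
    )
    t = (np.arange(front.shape[0]) - t0) / fs
    traj = Trajectory3D(
        t=t, front=front_r - translation, rear=rear_r - translation, fs=fs, world=frame
    )
    return traj, frame
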