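"""DLT camera calibration and two-view 3D reconstruction.

The camera model is the classic 11-parameter direct linear transformation
(DLT): a world point X = (x, y, z) in mm maps to pixel coordinates

    u = (L1 x + L2 y + L3 z + L4)  / (L9 x + L10 y + L11 z + 1)
    v = (L5 x + L6 y + L7 z + L8)  / (L9 x + L10 y + L11 z + 1)

Calibration solves the homogeneous linear system from >= 6 non-coplanar
world/pixel correspondences (checkerboard corners filmed at several
orientations); triangulation intersects the two per-camera ray constraints
(4 linear equations, 3 unknowns) in a least-squares sense.  No lens
distortion model is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CalibrationError(ValueError):
    """Degenerate calibration input (coplanar points, rank deficiency)."""


@dataclass
class CameraModel:
    """11 DLT coefficients for one camera placement.

    ``front_sign`` records the sign the projective denominator takes for
    points in front of the camera (the 11-parameter normalisation L12 = 1
    fixes the overall scale but not that sign).
    """

    coeffs: np.ndarray  # (11,)
    image_size: tuple[int, int] = (1920, 1080)
    reprojection_rmse: float | None = None
    front_sign: float = 1.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (11,):
            raise ValueError("DLT model needs exactly 11 coefficients")

    @property
    def projection_matrix(self) -> np.ndarray:
        """The 3x4 projection matrix with P[2, 3] = 1."""
        return np.append(self.coeffs, 1.0).reshape(3, 4)

    def denominators(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        L = self.coeffs
        return points @ L[8:11] + 1.0

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project (n, 3) world points (mm) to (n, 2) pixel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        L = self.coeffs
        den = self.denominators(pts)
        u = (pts @ L[0:3] + L[3]) / den
        v = (pts @ L[4:7] + L[7]) / den
        out = np.column_stack([u, v])
        return out if np.asarray(points).ndim == 2 else out[0]

    def in_front(self, points: np.ndarray) -> np.ndarray:
        """True where the projective denominator has the front-of-camera sign."""
        return self.front_sign * self.denominators(points) > 0


def make_camera(
    position: np.ndarray,
    look_at: np.ndarray,
    focal_px: float = 1200.0,
    image_size: tuple[int, int] = (1920, 1080),
    up: np.ndarray = (0.0, 0.0, 1.0),
) -> CameraModel:
    """Build a DLT camera from a physical pinhole description.

    Used by the synthetic-recording generator and by tests; real recordings
    obtain their model from :func:`dlt_calibrate` instead.
    """
    position = np.asarray(position, dtype=float)
    look_at = np.asarray(look_at, dtype=float)
    fwd = look_at - position
    fwd = fwd / np.linalg.norm(fwd)
    up = np.asarray(up, dtype=float)
    right = np.cross(fwd, up)
    if np.linalg.norm(right) < 1e-9:
        right = np.cross(fwd, (1.0, 0.0, 0.0))
    right = right / np.linalg.norm(right)
    down = np.cross(fwd, right)
    R = np.vstack([right, down, fwd])
    K = np.array(
        [
            [focal_px, 0.0, image_size[0] / 2.0],
            [0.0, focal_px, image_size[1] / 2.0],
            [0.0, 0.0, 1.0],
        ]
    )
    P = K @ np.column_stack([R, -R @ position])
    if abs(P[2, 3]) < 1e-12:
        raise ValueError("camera passes through the world origin; shift the frame")
    P = P / P[2, 3]
    cam = CameraModel(coeffs=P.ravel()[:11], image_size=image_size)
    # points in front of the camera have positive depth; record the sign the
    # normalised denominator takes there
    cam.front_sign = float(np.sign(cam.denominators(look_at[None, :])[0]))
    return cam


def _normalise_points(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre points and scale to unit RMS radius; return (normalised, T)."""
    pts = np.asarray(pts, dtype=float)
    d = pts.shape[1]
    centroid = pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
    scale = np.sqrt(d) / rms if rms > 0 else 1.0
    T = np.eye(d + 1)
    T[:d, :d] *= scale
    T[:d, d] = -scale * centroid
    hom = np.column_stack([pts, np.ones(len(pts))])
    return (hom @ T.T)[:, :d], T


def dlt_calibrate(
    world_points: np.ndarray,
    pixel_points: np.ndarray,
    image_size: tuple[int, int] = (1920, 1080),
    rank_tol: float = 1e-8,
) -> CameraModel:
    """Solve the 11-parameter DLT from world/pixel correspondences.

    World and pixel coordinates are centred and scaled before solving
    (Hartley normalisation) and the projection matrix de-normalised after,
    purely for numerical conditioning.  Coplanar world points leave a
    multi-dimensional solution family and raise :class:`CalibrationError`.
    """
    world = np.asarray(world_points, dtype=float)
    px = np.asarray(pixel_points, dtype=float)
    if world.ndim != 2 or world.shape[1] != 3:
        raise ValueError("world_points must be (n, 3)")
    if px.shape != (world.shape[0], 2):
        raise ValueError("pixel_points must match world_points")
    n = world.shape[0]
    if n < 6:
        raise ValueError("DLT calibration needs at least 6 correspondences")

    wn, Tw = _normalise_points(world)
    pn, Tp = _normalise_points(px)

    A = np.zeros((2 * n, 12))
    X = np.column_stack([wn, np.ones(n)])
    A[0::2, 0:4] = X
    A[0::2, 8:12] = -pn[:, 0:1] * X
    A[1::2, 4:8] = X
    A[1::2, 8:12] = -pn[:, 1:2] * X

    _, s, vt = np.linalg.svd(A)
    # coplanar points: solution family P + a (x) plane, nullspace dim >= 2
    if s[-2] <= rank_tol * s[0]:
        raise CalibrationError(
            "degenerate calibration geometry (world points coplanar or collinear)"
        )
    Pn = vt[-1].reshape(3, 4)
    P = np.linalg.inv(Tp) @ Pn @ Tw
    if abs(P[2, 3]) < 1e-12 * np.abs(P).max():
        raise CalibrationError("DLT normalisation L12 = 1 impossible for this geometry")
    P = P / P[2, 3]

    cam = CameraModel(coeffs=P.ravel()[:11], image_size=image_size)
    den = cam.denominators(world)
    if np.any(den == 0):
        raise CalibrationError("projective denominator vanishes at a calibration point")
    signs = np.sign(den)
    cam.front_sign = float(signs[0]) if np.all(signs == signs[0]) else 1.0
    reproj = cam.project(world)
    # per-coordinate RMSE: comparable to the pixel noise level on one axis
    cam.reprojection_rmse = float(np.sqrt(np.mean((reproj - px) ** 2)))
    return cam


@dataclass
class TriangulationResult:
    points: np.ndarray  # (n, 3) mm
    residual_px: np.ndarray = field(repr=False)  # (n,) rms over the 4 equations
    condition: np.ndarray = field(repr=False)  # (n,) condition number of the system
    ill_conditioned: np.ndarray = field(repr=False)  # (n,) bool


def _ray_system(cam: CameraModel, px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample 2x3 coefficient block and rhs of the DLT ray constraints."""
    L = cam.coeffs
    u, v = px[:, 0], px[:, 1]
    A = np.empty((px.shape[0], 2, 3))
    A[:, 0, :] = L[0:3][None, :] - u[:, None] * L[8:11][None, :]
    A[:, 1, :] = L[4:7][None, :] - v[:, None] * L[8:11][None, :]
    b = np.column_stack([u - L[3], v - L[7]])
    return A, b


def triangulate(
    cam_a: CameraModel,
    cam_b: CameraModel,
    px_a: np.ndarray,
    px_b: np.ndarray,
    condition_threshold: float = 1e8,
) -> TriangulationResult:
    """Least-squares intersection of the two cameras' ray constraints.

    Accepts (n, 2) synchronised pixel tracks (or single points) and returns
    (n, 3) world points with per-sample pixel residuals for quality control.
    Samples with any NaN pixel yield NaN points.  Near-parallel rays are
    flagged through the condition number rather than rejected.
    """
    pa = np.atleast_2d(np.asarray(px_a, dtype=float))
    pb = np.atleast_2d(np.asarray(px_b, dtype=float))
    if pa.shape != pb.shape or pa.shape[1] != 2:
        raise ValueError("pixel tracks must be matching (n, 2) arrays")
    n = pa.shape[0]
    ok = ~(np.isnan(pa).any(axis=1) | np.isnan(pb).any(axis=1))

    A = np.full((n, 4, 3), np.nan)
    b = np.full((n, 4), np.nan)
    Aa, ba = _ray_system(cam_a, np.nan_to_num(pa))
    Ab, bb = _ray_system(cam_b, np.nan_to_num(pb))
    A[:, 0:2, :], A[:, 2:4, :] = Aa, Ab
    b[:, 0:2], b[:, 2:4] = ba, bb

    points = np.full((n, 3), np.nan)
    residual = np.full(n, np.nan)
    condition = np.full(n, np.nan)
    if ok.any():
        Ao, bo = A[ok], b[ok]
        # batched normal equations; systems are tiny and well-scaled
        AtA = np.einsum("nij,nik->njk", Ao, Ao)
        Atb = np.einsum("nij,ni->nj", Ao, bo)
        sol = np.linalg.solve(AtA, Atb[..., None])[..., 0]
        points[ok] = sol
        res = np.einsum("nij,nj->ni", Ao, sol) - bo
        residual[ok] = np.sqrt(np.mean(res**2, axis=1))
        svals = np.linalg.svd(Ao, compute_uv=False)
        condition[ok] = svals[:, 0] / np.maximum(svals[:, -1], 1e-300)
    ill = np.zeros(n, dtype=bool)
    ill[ok] = condition[ok] > condition_threshold
    squeeze = np.asarray(px_a).ndim == 1
    if squeeze:
        return TriangulationResult(points[0], residual[0], condition[0], ill[0])
    return TriangulationResult(points, residual, condition, ill)


def camera_to_dict(cam: CameraModel) -> dict:
    """JSON-ready representation of a calibrated camera."""
    return {
        "coefficients": [float(c) for c in cam.coeffs],
        "image_size": list(cam.image_size),
        "reprojection_rmse_px": cam.reprojection_rmse,
        "front_sign": cam.front_sign,
    }


def camera_from_dict(d: dict) -> CameraModel:
    return CameraModel(
        coeffs=np.asarray(d["coefficients"], dtype=float),
        image_size=tuple(d["image_size"]),
        reprojection_rmse=d.get("reprojection_rmse_px"),
        front_sign=d.get("front_sign", 1.0),
    )
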