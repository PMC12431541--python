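"""Pinhole/DLT camera geometry.

A camera is a single 3x4 projection matrix ``P`` mapping lab coordinates
(millimetres, homogeneous) to pixel coordinates (0-based, origin top-left,
``u`` rightward, ``v`` downward).  This is the classic 11-parameter direct
linear transformation (DLT) form: no explicit intrinsic/extrinsic split and
no lens distortion.  All 3D quantities are in millimetres.

The module provides projection, back-projection of pixels to camera rays,
point-to-ray distances (the per-camera "reconstruction error" of a
triangulated point), least-squares multi-ray triangulation, DLT resection
from known 3D-2D correspondences, and camera-file I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import scipy.linalg


class GeometryError(ValueError):
    """Base class for geometric failures."""


class InvalidCameraError(GeometryError):
    """Projection matrix is rank-deficient or its left 3x3 block is singular."""


class BehindCameraError(GeometryError):
    """A point with non-positive projective depth was projected strictly."""


class DegenerateGeometryError(GeometryError):
    """Triangulation/calibration input does not constrain a unique solution."""


class Pixel(NamedTuple):
    """A 2D image point; may lie outside the image bounds."""

    u: float
    v: float


@dataclass
class Ray:
    """Half-line ``origin + t * direction`` (t >= 0) with a unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0.0:
            raise GeometryError("ray direction must be a finite nonzero vector")
        self.direction = d / n

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


@dataclass
class CameraModel:
    """Finite projective camera: ``x ~ P [X; 1]``.

    Parameters
    ----------
    id : camera identifier (any hashable string).
    P : (3, 4) real projection matrix, defined up to scale.
    image_width, image_height : sensor size in pixels.
    """

    id: str
    P: np.ndarray
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (3, 4):
            raise InvalidCameraError(f"P must be 3x4, got {P.shape}")
        self.P = P

    # -- derived quantities ------------------------------------------------
    @property
    def M(self) -> np.ndarray:
        """Left 3x3 block of P."""
        return self.P[:, :3]

    @property
    def center(self) -> np.ndarray:
        """Camera centre in lab mm (null space of P)."""
        M = self.M
        if abs(np.linalg.det(M)) < 1e-300:
            raise InvalidCameraError("left 3x3 block of P is singular")
        return -np.linalg.solve(M, self.P[:, 3])

    @property
    def _depth_sign(self) -> float:
        """Sign making ``sign * w`` a cheirality indicator (w = third row * Xh)."""
        return 1.0 if np.linalg.det(self.M) > 0 else -1.0

    def validate(self) -> None:
        if np.linalg.matrix_rank(self.P) != 3:
            raise InvalidCameraError("P must have rank 3")
        if abs(np.linalg.det(self.M)) < 1e-12 * np.linalg.norm(self.M, "fro") ** 3:
            raise InvalidCameraError("left 3x3 block of P is singular (non-finite camera)")

    def contains(self, pixel: Sequence[float]) -> bool:
        u, v = float(pixel[0]), float(pixel[1])
        return 0.0 <= u <= self.image_width - 1 and 0.0 <= v <= self.image_height - 1


# ---------------------------------------------------------------------------
# projection and rays
# ---------------------------------------------------------------------------

def projective_depth(camera: CameraModel, point: Sequence[float]) -> float:
    """Signed depth of ``point``; positive iff the point is in front of the camera.

    Invariant to positive rescaling of P and corrected for an overall sign flip.
    """
    Xh = np.append(np.asarray(point, dtype=float).reshape(3), 1.0)
    w = camera.P[2] @ Xh
    return camera._depth_sign * w / np.linalg.norm(camera.M[2])


def project(camera: CameraModel, point: Sequence[float], *, strict: bool = True) -> Pixel:
    """Project a lab-mm point to a pixel.

    Raises :class:`BehindCameraError` for non-positive projective depth when
    ``strict`` (the projection is still mathematically defined for w != 0 and
    returned when ``strict=False``).
    """
    Xh = np.append(np.asarray(point, dtype=float).reshape(3), 1.0)
    x = camera.P @ Xh
    if x[2] == 0.0:
        raise BehindCameraError("point lies in the camera's principal plane")
    if strict and projective_depth(camera, point) <= 0:
        raise BehindCameraError("point is behind the camera")
    return Pixel(x[0] / x[2], x[1] / x[2])


def project_many(camera: CameraModel, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised projection. Returns ``(pixels (n,2), depths (n,))``."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    Xh = np.hstack([pts, np.ones((len(pts), 1))])
    x = Xh @ camera.P.T
    depths = camera._depth_sign * x[:, 2] / np.linalg.norm(camera.M[2])
    with np.errstate(divide="ignore", invalid="ignore"):
        pix = x[:, :2] / x[:, 2:3]
    return pix, depths


def pixel_to_ray(camera: CameraModel, pixel: Sequence[float]) -> Ray:
    """Back-project a pixel to the half-line of points in front of the camera."""
    M = camera.M
    if abs(np.linalg.det(M)) < 1e-300:
        raise InvalidCameraError("left 3x3 block of P is singular")
    xh = np.array([float(pixel[0]), float(pixel[1]), 1.0])
    d = np.linalg.solve(M, xh)
    d *= camera._depth_sign  # orient toward positive depth
    return Ray(origin=camera.center, direction=d)


def point_ray_distance(point: Sequence[float], ray: Ray, *, half_line: bool = True) -> float:
    """Shortest distance from a point to a camera ray.

    With ``half_line`` (the default, matching the half-line definition of a
    camera ray), a point whose perpendicular foot falls behind the origin is
    measured to the origin itself; use ``half_line=False`` for the infinite
    line.  :func:`ray_foot_parameter` exposes the foot parameter ``t`` so
    callers can flag behind-origin points.
    """
    p = np.asarray(point, dtype=float).reshape(3)
    w = p - ray.origin
    t = w @ ray.direction
    if half_line and t < 0.0:
        return float(np.linalg.norm(w))
    return float(np.linalg.norm(w - t * ray.direction))


def ray_foot_parameter(point: Sequence[float], ray: Ray) -> float:
    """Parameter t of the perpendicular foot of ``point`` on the ray's line."""
    p = np.asarray(point, dtype=float).reshape(3)
    return float((p - ray.origin) @ ray.direction)


# ---------------------------------------------------------------------------
# triangulation
# ---------------------------------------------------------------------------

@dataclass
class TriangulationResult:
    """Least-squares intersection of camera rays.

    ``point`` minimises the sum of squared point-to-line distances;
    ``distances`` are the per-ray distances at the optimum and their mean is
    the reconstruction error used to gate correspondences.
    """

    point: np.ndarray
    distances: np.ndarray

    @property
    def mean_ray_distance(self) -> float:
        return float(np.mean(self.distances))


_DEGENERACY_RTOL = 1e-10


def triangulate_rays(rays: Sequence[Ray]) -> TriangulationResult:
    """Closed-form least-squares triangulation from >= 2 rays."""
    if len(rays) < 2:
        raise DegenerateGeometryError("triangulation needs at least 2 rays")
    O = np.array([r.origin for r in rays])
    D = np.array([r.direction for r in rays])
    n = len(rays)
    A = n * np.eye(3) - D.T @ D
    e = np.einsum("ij,ij->i", D, O)
    b = O.sum(axis=0) - D.T @ e
    evals = np.linalg.eigvalsh(A)
    if evals[0] < _DEGENERACY_RTOL * max(evals[-1], 1e-300):
        raise DegenerateGeometryError("rays are (near-)parallel: point not constrained")
    x = np.linalg.solve(A, b)
    distances = np.array([point_ray_distance(x, r) for r in rays])
    return TriangulationResult(point=x, distances=distances)


def triangulate(
    observations: Sequence[tuple[CameraModel, Sequence[float]]],
) -> TriangulationResult:
    """Triangulate a point from ``(camera, pixel)`` observations.

    Requires >= 2 observations from distinct camera centres whose rays are not
    all parallel; raises :class:`DegenerateGeometryError` otherwise.
    """
    if len(observations) < 2:
        raise DegenerateGeometryError("need at least 2 observations")
    rays = [pixel_to_ray(cam, px) for cam, px in observations]
    centers = np.array([r.origin for r in rays])
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.linalg.norm(centers[i] - centers[j]) < 1e-9:
                raise DegenerateGeometryError(
                    "observations share a camera centre; baselines are required"
                )
    return triangulate_rays(rays)


# ---------------------------------------------------------------------------
# DLT resection
# ---------------------------------------------------------------------------

def _normalise_points(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalisation: similarity T s.t. centroid 0, RMS norm sqrt(dim)."""
    pts = np.asarray(pts, dtype=float)
    dim = pts.shape[1]
    centroid = pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
    s = np.sqrt(dim) / max(rms, 1e-300)
    T = np.eye(dim + 1)
    T[:dim, :dim] *= s
    T[:dim, dim] = -s * centroid
    return T, (pts - centroid) * s


def dlt_calibrate(
    points3d: np.ndarray,
    pixels: np.ndarray,
    *,
    camera_id: str = "cam",
    image_width: int = 1920,
    image_height: int = 1080,
) -> CameraModel:
    """Estimate an 11-parameter camera from >= 6 non-coplanar 3D-2D pairs.

    Linear least squares on the normalised DLT system; with noiseless input
    the result reprojects to machine precision.
    """
    X = np.asarray(points3d, dtype=float).reshape(-1, 3)
    x = np.asarray(pixels, dtype=float).reshape(-1, 2)
    if len(X) != len(x):
        raise ValueError("points3d and pixels must have equal length")
    if len(X) < 6:
        raise DegenerateGeometryError("DLT resection needs at least 6 points")
    # coplanarity check on the centred 3D cloud
    sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    if sv[2] < 1e-8 * max(sv[0], 1e-300):
        raise DegenerateGeometryError("3D points are (near-)coplanar")

    T3, Xn = _normalise_points(X)
    T2, xn = _normalise_points(x)
    n = len(X)
    A = np.zeros((2 * n, 12))
    Xh = np.hstack([Xn, np.ones((n, 1))])
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -xn[:, 0:1] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -xn[:, 1:2] * Xh
    _, _, Vt = np.linalg.svd(A)
    Pn = Vt[-1].reshape(3, 4)
    P = np.linalg.solve(T2, Pn) @ T3
    # canonical scale/sign: unit Frobenius norm, positive det of left block
    P /= np.linalg.norm(P)
    if np.linalg.det(P[:, :3]) < 0:
        P = -P
    return CameraModel(id=camera_id, P=P, image_width=image_width, image_height=image_height)


def decompose_projection(P: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Factor P ~ K [R | -R c] with K upper-triangular (positive diagonal).

    Returns ``(K, R, c)`` with ``det(R) = +1`` and K scaled so ``K[2, 2] = 1``.
    """
    P = np.asarray(P, dtype=float)
    M = P[:, :3]
    K, R = scipy.linalg.rq(M)
    # fix signs: K diagonal positive
    signs = np.sign(np.diag(K))
    signs[signs == 0] = 1.0
    S = np.diag(signs)
    K = K @ S
    R = S @ R
    if np.linalg.det(R) < 0:
        # P is defined up to scale: -M = K (-R) keeps K upper-triangular
        # with positive diagonal and makes R a proper rotation.
        R = -R
    c = -np.linalg.solve(M, P[:, 3])
    K = K / K[2, 2]
    return K, R, c


# ---------------------------------------------------------------------------
# rigid / similarity alignment (Umeyama)
# ---------------------------------------------------------------------------

def align_point_sets(
    X: np.ndarray, Y: np.ndarray, *, scale: bool = False
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares similarity/rigid transform mapping X onto Y.

    Returns ``(s, R, t)`` minimising ``||s R X + t - Y||`` (s fixed to 1 for a
    rigid fit).  Proper rotations only.
    """
    X = np.asarray(X, dtype=float).reshape(-1, 3)
    Y = np.asarray(Y, dtype=float).reshape(-1, 3)
    if X.shape != Y.shape or len(X) < 3:
        raise ValueError("need two equally sized point sets with >= 3 points")
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    H = Xc.T @ Yc / len(X)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if scale:
        var = np.mean(np.sum(Xc**2, axis=1))
        s = float(np.trace(np.diag(S) @ D) / var)
    else:
        s = 1.0
    t = my - s * R @ mx
    return s, R, t


def apply_similarity(s: float, R: np.ndarray, t: np.ndarray, X: np.ndarray) -> np.ndarray:
    return s * np.asarray(X, dtype=float) @ np.asarray(R).T + np.asarray(t)


# ---------------------------------------------------------------------------
# camera file I/O (JSON; bit-exact float round trip)
# ---------------------------------------------------------------------------

def save_cameras(path: str | Path, cameras: Iterable[CameraModel]) -> None:
    """Write cameras to JSON: one record per camera, P row-major (12 floats)."""
    records = [
        {
            "id": c.id,
            "P": [float(v) for v in np.asarray(c.P, dtype=float).ravel()],
            "image_width": int(c.image_width),
            "image_height": int(c.image_height),
        }
        for c in cameras
    ]
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def load_cameras(path: str | Path) -> list[CameraModel]:
    records = json.loads(Path(path).read_text())
    cams = []
    for r in records:
        P = np.array(r["P"], dtype=float).reshape(3, 4)
        cams.append(
            CameraModel(
                id=str(r["id"]),
                P=P,
                image_width=int(r["image_width"]),
                image_height=int(r["image_height"]),
            )
        )
    return cams
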