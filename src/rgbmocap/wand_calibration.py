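"""Multi-camera calibration from a two-marker wand of known length.

A rigid wand carrying two distinctly coloured spherical markers is swept
through the measurement volume while all cameras record it.  Given the
synchronized digitized coordinates of the two markers and the known
inter-marker distance, this module estimates an 11-parameter projection
matrix for every camera in a common lab frame.

Pipeline
--------
1. **Initialisation**: nominal intrinsics (principal point at the image
   centre, configurable focal guess); the fundamental matrix between the
   reference camera and its best-overlapping partner via the normalised
   8-point method; essential-matrix decomposition with a cheirality test;
   remaining cameras added by DLT resection against the growing point cloud.
2. **Bundle adjustment** over all camera entries and per-frame marker
   positions, minimising squared reprojection error together with the
   deviation of each frame's inter-marker distance from the known wand
   length.  The distance residuals are what make the solution metric: with
   purely projective cameras, reprojection error alone is invariant to any
   projective warp of the scene.  Robust (Huber) weighting tolerates
   occasional misdetections; frames where a camera misses a marker simply
   contribute no residual.
3. **Gauge fixing**: the first camera's centre is moved to the origin and
   its orientation made canonical; the global scale is set so the mean
   reconstructed inter-marker distance equals the specified wand length.

Quality metrics follow the usual wand-calibration conventions: the mean
absolute error of the reconstructed inter-marker distance, and the mean
point-to-ray distance of the reconstructed wand markers (the reconstruction
error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse

from .geometry import (
    CameraModel,
    DegenerateGeometryError,
    decompose_projection,
    dlt_calibrate,
    pixel_to_ray,
    point_ray_distance,
    triangulate_rays,
)


class ConnectivityError(ValueError):
    """Cameras do not share enough wand observations to be linked."""


class CalibrationError(RuntimeError):
    pass


@dataclass
class WandSpec:
    """The calibration wand: two markers at a known separation (mm)."""

    distance: float

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("wand distance must be positive")


@dataclass
class WandObservation:
    """Digitized wand markers in one camera and frame (either may be missing)."""

    frame: int
    camera: str
    pixel_a: tuple[float, float] | None = None
    pixel_b: tuple[float, float] | None = None


@dataclass
class WandCalibConfig:
    image_width: int = 1920
    image_height: int = 1080
    focal_guess_factor: float = 1.2      # x image_width, nominal intrinsics
    length_weight: float = 1.0           # residual weight, px per mm of length error
    loss: str = "huber"                  # 'huber' or 'linear'
    huber_px: float = 2.0
    max_iterations: int = 150
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-14
    min_pair_frames: int = 15
    init_seed: int = 0
    init_perturbation: float = 0.0       # relative jitter of the initial cameras


@dataclass
class CalibrationResult:
    cameras: list[CameraModel]
    wand_points: np.ndarray              # (n_frames, 2, 3) mm; NaN if unreconstructed
    frames: list[int]
    length_error_mean: float
    length_error_sd: float
    reconstruction_error_mean: float
    reprojection_rms: float
    cost_history: list[float]


# ---------------------------------------------------------------------------
# observation assembly and I/O
# ---------------------------------------------------------------------------

def load_wand_csv(path: str | Path) -> list[WandObservation]:
    """Read a wand table: columns frame, camera, marker (a|b), u, v."""
    df = pd.read_csv(path)
    obs: dict[tuple[int, str], WandObservation] = {}
    for _, r in df.iterrows():
        key = (int(r["frame"]), str(r["camera"]))
        o = obs.setdefault(key, WandObservation(frame=key[0], camera=key[1]))
        pix = (float(r["u"]), float(r["v"]))
        if str(r["marker"]).strip().lower() == "a":
            o.pixel_a = pix
        else:
            o.pixel_b = pix
    return [obs[k] for k in sorted(obs)]


def save_wand_csv(path: str | Path, observations: Sequence[WandObservation]) -> None:
    rows = []
    for o in observations:
        if o.pixel_a is not None:
            rows.append((o.frame, o.camera, "a", o.pixel_a[0], o.pixel_a[1]))
        if o.pixel_b is not None:
            rows.append((o.frame, o.camera, "b", o.pixel_b[0], o.pixel_b[1]))
    pd.DataFrame(rows, columns=["frame", "camera", "marker", "u", "v"]).to_csv(
        path, index=False
    )


def wand_observations_from_track(
    wand_track: np.ndarray,
    cameras: Sequence[CameraModel],
    *,
    noise_sigma_px: float = 0.0,
    dropout_p: float = 0.0,
    seed: int = 0,
) -> list[WandObservation]:
    """Project a simulated wand track into cameras (for fixtures and tests)."""
    from .geometry import project_many

    rng = np.random.default_rng(seed)
    n_frames = wand_track.shape[0]
    obs = []
    for cam in cameras:
        for m in range(2):
            pix, depth = project_many(cam, wand_track[:, m, :])
            if noise_sigma_px > 0:
                pix = pix + rng.normal(0, noise_sigma_px, pix.shape)
            keep = (depth > 0) & (rng.uniform(size=n_frames) >= dropout_p)
            for f in range(n_frames):
                if not keep[f]:
                    continue
                obs.append((f, cam.id, m, pix[f, 0], pix[f, 1]))
    merged: dict[tuple[int, str], WandObservation] = {}
    for f, cid, m, u, v in obs:
        o = merged.setdefault((f, cid), WandObservation(frame=f, camera=cid))
        if m == 0:
            o.pixel_a = (float(u), float(v))
        else:
            o.pixel_b = (float(u), float(v))
    return [merged[k] for k in sorted(merged)]


def _assemble(observations: Sequence[WandObservation]):
    """Pack observations into (cam_ids, frames, uv[n_cams, n_points, 2]).

    Point index convention: point ``2 f`` is marker a of frame ``f``, point
    ``2 f + 1`` is marker b.
    """
    frames = sorted({o.frame for o in observations})
    cam_ids = sorted({o.camera for o in observations})
    fidx = {f: i for i, f in enumerate(frames)}
    cidx = {c: i for i, c in enumerate(cam_ids)}
    uv = np.full((len(cam_ids), 2 * len(frames), 2), np.nan)
    for o in observations:
        ci, fi = cidx[o.camera], fidx[o.frame]
        if o.pixel_a is not None:
            uv[ci, 2 * fi] = o.pixel_a
        if o.pixel_b is not None:
            uv[ci, 2 * fi + 1] = o.pixel_b
    return cam_ids, frames, uv


# ---------------------------------------------------------------------------
# two-view initialisation
# ---------------------------------------------------------------------------

def _normalise_2d(x: np.ndarray):
    c = x.mean(axis=0)
    s = np.sqrt(2.0) / max(np.sqrt(np.mean(np.sum((x - c) ** 2, axis=1))), 1e-300)
    T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])
    return (x - c) * s, T


def _eight_point(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Normalised 8-point fundamental matrix (rank-2 enforced)."""
    if len(x1) < 8:
        raise ConnectivityError("need at least 8 shared points for the 8-point method")
    n1, T1 = _normalise_2d(x1)
    n2, T2 = _normalise_2d(x2)
    A = np.column_stack(
        [
            n2[:, 0] * n1[:, 0], n2[:, 0] * n1[:, 1], n2[:, 0],
            n2[:, 1] * n1[:, 0], n2[:, 1] * n1[:, 1], n2[:, 1],
            n1[:, 0], n1[:, 1], np.ones(len(n1)),
        ]
    )
    _, _, Vt = np.linalg.svd(A)
    F = Vt[-1].reshape(3, 3)
    U, S, Vt = np.linalg.svd(F)
    F = U @ np.diag([S[0], S[1], 0.0]) @ Vt
    return T2.T @ F @ T1


def _decompose_essential(E: np.ndarray):
    U, _, Vt = np.linalg.svd(E)
    if np.linalg.det(U) < 0:
        U = -U
    if np.linalg.det(Vt) < 0:
        Vt = -Vt
    W = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
    R1, R2 = U @ W @ Vt, U @ W.T @ Vt
    t = U[:, 2]
    return [(R1, t), (R1, -t), (R2, t), (R2, -t)]


def _nominal_K(cfg: WandCalibConfig, f: float | None = None) -> np.ndarray:
    f = f if f is not None else cfg.focal_guess_factor * cfg.image_width
    return np.array(
        [
            [f, 0.0, (cfg.image_width - 1) / 2.0],
            [0.0, f, (cfg.image_height - 1) / 2.0],
            [0.0, 0.0, 1.0],
        ]
    )


def _two_view_points(
    K: np.ndarray, R: np.ndarray, t: np.ndarray, x1: np.ndarray, x2: np.ndarray
):
    """Vectorised midpoint triangulation for the pair P1=K[I|0], P2=K[R|t].

    Returns ``(points (n,3), n_in_front)``.
    """
    Kinv = np.linalg.inv(K)
    d1 = (np.hstack([x1, np.ones((len(x1), 1))]) @ Kinv.T)
    d1 /= np.linalg.norm(d1, axis=1, keepdims=True)
    d2 = (np.hstack([x2, np.ones((len(x2), 1))]) @ Kinv.T) @ R  # = R^T K^-1 x2
    d2 /= np.linalg.norm(d2, axis=1, keepdims=True)
    o2 = -R.T @ t
    w = o2[None, :]
    c = np.einsum("ni,ni->n", d1, d2)
    denom = 1.0 - c * c
    denom = np.where(denom < 1e-12, np.nan, denom)
    wd1 = np.einsum("ni,i->n", d1, o2)
    wd2 = np.einsum("ni,i->n", d2, o2)
    t1 = (wd1 - wd2 * c) / denom
    t2 = (wd1 * c - wd2) / denom
    p1 = t1[:, None] * d1
    p2 = o2[None, :] + t2[:, None] * d2
    pts = (p1 + p2) / 2.0
    in_front = int(np.sum((t1 > 0) & (t2 > 0)))
    return pts, in_front


def _pose_and_spread(
    f: float, F: np.ndarray, x1: np.ndarray, x2: np.ndarray,
    pair_idx: np.ndarray, cfg: WandCalibConfig,
):
    """Best cheirality pose for focal ``f`` and the wand-length spread it implies.

    The spread (SD / mean of the two-view reconstructed inter-marker
    distances) is the metric self-consistency of the candidate focal: a
    wrong focal bends the two-view reconstruction projectively, so the
    rigid wand no longer has constant length.
    """
    K = _nominal_K(cfg, f)
    E = K.T @ F @ K
    U, _, Vt = np.linalg.svd(E)
    E = U @ np.diag([1.0, 1.0, 0.0]) @ Vt
    best = None
    for R, t in _decompose_essential(E):
        pts, in_front = _two_view_points(K, R, t, x1, x2)
        if best is None or in_front > best[0]:
            best = (in_front, R, t, pts)
    in_front, R, t, pts = best
    if in_front < max(8, len(x1) // 4):
        return np.inf, None
    lens = np.linalg.norm(pts[pair_idx[:, 0]] - pts[pair_idx[:, 1]], axis=1)
    lens = lens[np.isfinite(lens)]
    if len(lens) < 5 or np.mean(lens) <= 0:
        return np.inf, None
    spread = float(np.std(lens) / np.mean(lens))
    return spread, (K, R, t)


def _estimate_pair_geometry(
    F: np.ndarray, x1: np.ndarray, x2: np.ndarray, pair_idx: np.ndarray,
    cfg: WandCalibConfig,
):
    """Choose the initial pair's focal by wand-length self-consistency.

    Focal estimation from F alone is degenerate when the optical axes
    intersect (typical for converging rigs), so instead each candidate focal
    is scored by how constant the reconstructed wand length is, scanning a
    log grid and refining by golden section.
    """
    grid = list(np.geomspace(0.4 * cfg.image_width, 4.0 * cfg.image_width, 24))
    grid.append(cfg.focal_guess_factor * cfg.image_width)
    scores = [_pose_and_spread(f, F, x1, x2, pair_idx, cfg)[0] for f in grid]
    f0 = grid[int(np.argmin(scores))]
    if not np.isfinite(min(scores)):
        raise CalibrationError("no focal candidate yields a consistent wand length")
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = f0 / 1.25, f0 * 1.25
    c, d = b - phi * (b - a), a + phi * (b - a)
    gc = _pose_and_spread(c, F, x1, x2, pair_idx, cfg)[0]
    gd = _pose_and_spread(d, F, x1, x2, pair_idx, cfg)[0]
    for _ in range(50):
        if gc < gd:
            b, d, gd = d, c, gc
            c = b - phi * (b - a)
            gc = _pose_and_spread(c, F, x1, x2, pair_idx, cfg)[0]
        else:
            a, c, gc = c, d, gd
            d = a + phi * (b - a)
            gd = _pose_and_spread(d, F, x1, x2, pair_idx, cfg)[0]
    f = (a + b) / 2.0
    spread, pose = _pose_and_spread(f, F, x1, x2, pair_idx, cfg)
    if pose is None:
        raise CalibrationError("cheirality test failed for the initial pair")
    return f, pose


def _init_pair(uv1: np.ndarray, uv2: np.ndarray, cfg: WandCalibConfig):
    """Initial camera pair from shared wand points: F -> focal search -> (R, t)."""
    shared = ~np.isnan(uv1[:, 0]) & ~np.isnan(uv2[:, 0])
    idx = np.nonzero(shared)[0]
    x1, x2 = uv1[shared], uv2[shared]
    F = _eight_point(x1, x2)
    pos = {int(j): k for k, j in enumerate(idx)}
    pairs = [
        (pos[j], pos[j + 1]) for j in pos if j % 2 == 0 and (j + 1) in pos
    ]
    if len(pairs) < 5:
        raise ConnectivityError("too few frames with both wand markers in the pair")
    pair_idx = np.array(pairs, dtype=int)
    _, (K, R, t) = _estimate_pair_geometry(F, x1, x2, pair_idx, cfg)
    P1 = K @ np.hstack([np.eye(3), np.zeros((3, 1))])
    P2 = K @ np.hstack([R, t[:, None]])
    return P1, P2


def _initialise(cam_ids, uv, cfg: WandCalibConfig):
    """Incremental structure-from-motion initialisation."""
    n_cams, n_pts, _ = uv.shape
    seen = ~np.isnan(uv[:, :, 0])
    ref = int(np.argmax(seen.sum(axis=1)))
    overlap = (seen & seen[ref]).sum(axis=1)
    overlap[ref] = -1
    partner = int(np.argmax(overlap))
    if overlap[partner] < max(8, cfg.min_pair_frames):
        raise ConnectivityError("reference pair shares too few observations")

    P = [None] * n_cams
    P[ref], P[partner] = _init_pair(uv[ref], uv[partner], cfg)
    X = np.full((n_pts, 3), np.nan)

    def make_cam(i):
        return CameraModel(str(i), P[i], cfg.image_width, cfg.image_height)

    def triangulate_points(active):
        cams = {i: make_cam(i) for i in active}
        for j in range(n_pts):
            rays = [
                pixel_to_ray(cams[i], uv[i, j])
                for i in active
                if seen[i, j]
            ]
            if len(rays) >= 2:
                try:
                    X[j] = triangulate_rays(rays).point
                except DegenerateGeometryError:
                    pass

    active = [ref, partner]
    triangulate_points(active)
    remaining = [i for i in range(n_cams) if i not in active]
    while remaining:
        have = ~np.isnan(X[:, 0])
        scores = [(int((seen[i] & have).sum()), i) for i in remaining]
        scores.sort(reverse=True)
        count, nxt = scores[0]
        if count < 6:
            raise ConnectivityError(
                f"camera {cam_ids[nxt]} shares too few points with the calibrated set"
            )
        mask = seen[nxt] & have
        try:
            cam = dlt_calibrate(
                X[mask], uv[nxt][mask],
                camera_id=str(nxt),
                image_width=cfg.image_width, image_height=cfg.image_height,
            )
        except DegenerateGeometryError as exc:
            raise ConnectivityError(f"resection of camera {cam_ids[nxt]} failed: {exc}")
        P[nxt] = cam.P
        active.append(nxt)
        remaining.remove(nxt)
        triangulate_points(active)

    if cfg.init_perturbation > 0:
        rng = np.random.default_rng(cfg.init_seed)
        for i in range(n_cams):
            # relative per-entry jitter: P entries span orders of magnitude
            P[i] = P[i] * (1.0 + cfg.init_perturbation * rng.standard_normal((3, 4)))
        triangulate_points(list(range(n_cams)))
    return np.stack([p / np.linalg.norm(p) for p in P]), X


# ---------------------------------------------------------------------------
# bundle adjustment
# ---------------------------------------------------------------------------

def _bundle_adjust(P0, X0, uv, wand_distance, cfg: WandCalibConfig):
    n_cams = P0.shape[0]
    seen = ~np.isnan(uv[:, :, 0])
    pt_ok = ~np.isnan(X0[:, 0])
    pt_ids = np.nonzero(pt_ok)[0]
    pt_pos = {j: k for k, j in enumerate(pt_ids)}
    n_pts = len(pt_ids)

    oc, op = np.nonzero(seen[:, pt_ids])
    obs_uv = uv[oc, pt_ids[op]]
    n_obs = len(oc)

    # frames where both wand markers are in the adjustment
    pairs = []
    for j in pt_ids:
        if j % 2 == 0 and (j + 1) in pt_pos:
            pairs.append((pt_pos[j], pt_pos[j + 1]))
    pairs = np.array(pairs, dtype=int)
    w_len = cfg.length_weight

    def unpack(x):
        P = x[: 12 * n_cams].reshape(n_cams, 3, 4)
        X = x[12 * n_cams :].reshape(n_pts, 3)
        return P, X

    def residuals(x):
        P, X = unpack(x)
        Xh = np.hstack([X, np.ones((n_pts, 1))])
        Pc = P[oc]                     # (n_obs, 3, 4)
        proj = np.einsum("nij,nj->ni", Pc, Xh[op])
        r_uv = proj[:, :2] / proj[:, 2:3] - obs_uv
        if len(pairs):
            delta = X[pairs[:, 0]] - X[pairs[:, 1]]
            lens = np.linalg.norm(delta, axis=1)
            r_len = w_len * (lens - wand_distance)
        else:
            r_len = np.zeros(0)
        return np.concatenate([r_uv.ravel(), r_len])

    cost_history: list[float] = []

    def jac(x):
        P, X = unpack(x)
        # record robust cost at accepted iterates (TRF evaluates the
        # jacobian only at accepted points, so this history is monotone)
        f = residuals(x)
        if cfg.loss == "huber":
            a = cfg.huber_px
            z = np.abs(f) / a
            rho = np.where(z <= 1.0, f**2, a**2 * (2 * z - 1.0))
            cost_history.append(0.5 * float(rho.sum()))
        else:
            cost_history.append(0.5 * float(f @ f))

        Xh = np.hstack([X, np.ones((n_pts, 1))])
        Pc = P[oc]
        proj = np.einsum("nij,nj->ni", Pc, Xh[op])
        a_, b_, c_ = proj[:, 0], proj[:, 1], proj[:, 2]
        u, v = a_ / c_, b_ / c_

        rows, cols, vals = [], [], []
        idx = np.arange(n_obs)
        ru = 2 * idx
        rv = 2 * idx + 1
        cambase = 12 * oc
        # d u / d p1 (cols 0..3), d u / d p3 (cols 8..11)
        for j in range(4):
            rows.append(ru); cols.append(cambase + j); vals.append(Xh[op, j] / c_)
            rows.append(ru); cols.append(cambase + 8 + j); vals.append(-u * Xh[op, j] / c_)
            rows.append(rv); cols.append(cambase + 4 + j); vals.append(Xh[op, j] / c_)
            rows.append(rv); cols.append(cambase + 8 + j); vals.append(-v * Xh[op, j] / c_)
        # d / d X
        ptbase = 12 * n_cams + 3 * op
        for j in range(3):
            du = (Pc[:, 0, j] - u * Pc[:, 2, j]) / c_
            dv = (Pc[:, 1, j] - v * Pc[:, 2, j]) / c_
            rows.append(ru); cols.append(ptbase + j); vals.append(du)
            rows.append(rv); cols.append(ptbase + j); vals.append(dv)

        n_res = 2 * n_obs + len(pairs)
        if len(pairs):
            delta = X[pairs[:, 0]] - X[pairs[:, 1]]
            lens = np.linalg.norm(delta, axis=1)
            g = w_len * delta / lens[:, None]
            ridx = 2 * n_obs + np.arange(len(pairs))
            for j in range(3):
                rows.append(ridx); cols.append(12 * n_cams + 3 * pairs[:, 0] + j); vals.append(g[:, j])
                rows.append(ridx); cols.append(12 * n_cams + 3 * pairs[:, 1] + j); vals.append(-g[:, j])

        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        n_par = 12 * n_cams + 3 * n_pts
        return scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(n_res, n_par))

    x0 = np.concatenate([P0.ravel(), X0[pt_ids].ravel()])
    result = scipy.optimize.least_squares(
        residuals,
        x0,
        jac=jac,
        method="trf",
        tr_solver="lsmr",
        x_scale="jac",
        loss=cfg.loss if cfg.loss != "linear" else "linear",
        f_scale=cfg.huber_px,
        ftol=cfg.ftol,
        xtol=cfg.xtol,
        gtol=cfg.gtol,
        max_nfev=cfg.max_iterations,
    )
    P, X = unpack(result.x)
    Xfull = np.full_like(X0, np.nan)
    Xfull[pt_ids] = X
    rms = float(np.sqrt(np.mean(result.fun[: 2 * n_obs] ** 2))) if n_obs else np.nan
    return P, Xfull, rms, cost_history


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def calibrate_from_wand(
    observations: Sequence[WandObservation],
    spec: WandSpec,
    config: WandCalibConfig | None = None,
) -> CalibrationResult:
    """Estimate all camera models from a wand sweep of known length."""
    cfg = config or WandCalibConfig()
    cam_ids, frames, uv = _assemble(observations)
    if len(cam_ids) < 2:
        raise ConnectivityError("need at least 2 cameras")
    both = ~np.isnan(uv[:, 0::2, 0]) & ~np.isnan(uv[:, 1::2, 0])
    frames_multi = int((both.sum(axis=0) >= 2).sum())
    if frames_multi < cfg.min_pair_frames:
        raise ConnectivityError(
            f"only {frames_multi} frames seen by >= 2 cameras "
            f"(need {cfg.min_pair_frames})"
        )

    P0, X0 = _initialise(cam_ids, uv, cfg)
    # pre-scale the initial scene so wand lengths start near the spec value
    lens0 = _pair_lengths(X0)
    if np.isfinite(lens0).any():
        s0 = spec.distance / float(np.nanmean(lens0))
        X0 = X0 * s0
        P0 = P0.copy()
        P0[:, :, 3] *= s0
    good = ~np.isnan(X0[:, 0])
    sv = np.linalg.svd(X0[good] - X0[good].mean(axis=0), compute_uv=False)
    if sv[2] < 1e-6 * sv[0]:
        raise DegenerateGeometryError("wand point cloud is (near-)planar")

    P, X, rms, cost_history = _bundle_adjust(P0, X0, uv, spec.distance, cfg)

    # ---- gauge fix: first camera at origin, canonical orientation --------
    K1, R1, c1 = decompose_projection(P[0])
    H_inv = np.eye(4)
    lens = _pair_lengths(X)
    scale = spec.distance / np.nanmean(lens)
    H_inv[:3, :3] = R1.T / scale
    H_inv[:3, 3] = c1
    P = np.stack([p @ H_inv for p in P])
    P = np.stack([p / np.linalg.norm(p) for p in P])

    cameras = [
        CameraModel(cam_ids[i], P[i], cfg.image_width, cfg.image_height)
        for i in range(len(cam_ids))
    ]

    # ---- re-reconstruct the wand and compute the quality metrics ---------
    seen = ~np.isnan(uv[:, :, 0])
    n_pts = uv.shape[1]
    wand_points = np.full((len(frames), 2, 3), np.nan)
    ray_dists = []
    for j in range(n_pts):
        rays = [
            pixel_to_ray(cameras[i], uv[i, j]) for i in range(len(cameras)) if seen[i, j]
        ]
        if len(rays) < 2:
            continue
        try:
            res = triangulate_rays(rays)
        except DegenerateGeometryError:
            continue
        wand_points[j // 2, j % 2] = res.point
        ray_dists.extend(res.distances.tolist())

    pair_len = np.linalg.norm(wand_points[:, 0] - wand_points[:, 1], axis=1)
    valid = ~np.isnan(pair_len)
    if not valid.any():
        raise CalibrationError("no wand pairs could be reconstructed")
    # final exact rescale on the reconstructed pairs
    s = spec.distance / float(np.mean(pair_len[valid]))
    wand_points *= s
    for cam in cameras:
        Hs = np.diag([1.0 / s, 1.0 / s, 1.0 / s, 1.0])
        cam.P = cam.P @ Hs
        cam.P /= np.linalg.norm(cam.P)
    pair_len = pair_len * s

    err_mean, err_sd = wand_length_error(wand_points[valid], spec)
    return CalibrationResult(
        cameras=cameras,
        wand_points=wand_points,
        frames=frames,
        length_error_mean=err_mean,
        length_error_sd=err_sd,
        reconstruction_error_mean=float(np.mean(ray_dists) * s),
        reprojection_rms=rms,
        cost_history=cost_history,
    )


def _pair_lengths(X: np.ndarray) -> np.ndarray:
    a = X[0::2]
    b = X[1::2]
    return np.linalg.norm(a - b, axis=1)


def wand_length_error(pairs: np.ndarray, spec: WandSpec) -> tuple[float, float]:
    """Mean and SD of the absolute deviation of pair distances from the spec.

    ``pairs`` has shape (n, 2, 3): n reconstructed two-marker poses.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        raise ValueError("no wand pairs")
    d = np.linalg.norm(pairs[:, 0] - pairs[:, 1], axis=1)
    dev = np.abs(d - spec.distance)
    sd = float(np.std(dev, ddof=1)) if len(dev) > 1 else 0.0
    return float(np.mean(dev)), sd
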