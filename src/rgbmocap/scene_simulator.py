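"""Synthetic capture-session generator.

Stands in for a real multi-camera recording: an 8-camera ring around a
2.0 x 4.0 x 2.0 m gait volume, 25 smooth marker trajectories, a two-marker
calibration-wand sweep, exact or noisy projections, and rendered frames with
coloured marker discs.  Everything is deterministic under a seed, so the
calibration, reconstruction and evaluation modules can be tested against
known ground truth without any recorded data.

The gait model is deliberately simple (forward translation plus sinusoidal
limb-like oscillation); it produces plausible multi-target geometry, not
biomechanics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import CameraModel, project_many

MM_PER_M = 1000.0


class RigGeometryError(ValueError):
    """The requested rig cannot view the full measurement volume."""


@dataclass
class RigParams:
    """Camera-ring layout around the measurement volume.

    The volume is axis-aligned with x in [0, vx], y in [0, vy], z in [0, vz]
    (millimetres internally; ``volume_m`` is given in metres).  Cameras sit on
    a ring of radius ``distance_mm`` around the volume centroid at heights in
    ``height_range_mm`` and all point at the centroid.  The default focal
    length makes a 24 mm marker at the volume centre subtend about 8 px at
    native resolution (doubled by the detection-side 2x upscale).
    """

    n_cameras: int = 8
    volume_m: tuple[float, float, float] = (2.0, 4.0, 2.0)
    distance_mm: float = 10000.0
    height_range_mm: tuple[float, float] = (800.0, 1200.0)
    focal_px: float = 3200.0
    image_width: int = 1920
    image_height: int = 1080
    angle_jitter_deg: float = 4.0
    seed: int = 0

    @property
    def volume_mm(self) -> np.ndarray:
        return np.asarray(self.volume_m, dtype=float) * MM_PER_M

    @property
    def center_mm(self) -> np.ndarray:
        return self.volume_mm / 2.0

    def corners_mm(self) -> np.ndarray:
        v = self.volume_mm
        g = np.array(np.meshgrid([0, v[0]], [0, v[1]], [0, v[2]])).T.reshape(-1, 3)
        return g.astype(float)


@dataclass
class GaitParams:
    """Parameters of the sinusoidal 25-marker gait surrogate."""

    n_markers: int = 25
    duration_s: float = 1.0
    fps: float = 240.0
    speed_mm_s: float = 1300.0
    stride_hz: float = 2.0
    amplitude_mm: tuple[float, float] = (10.0, 40.0)


@dataclass
class Scene:
    """Simulator ground truth bundle."""

    cameras: list[CameraModel]
    trajectories: np.ndarray  # (n_markers, n_frames, 3) mm
    wand_track: np.ndarray | None = None  # (n_frames, 2, 3) mm
    frame_rate: float = 240.0
    rig: RigParams = field(default_factory=RigParams)

    @property
    def n_frames(self) -> int:
        return self.trajectories.shape[1]

    @property
    def n_markers(self) -> int:
        return self.trajectories.shape[0]


def _look_at_camera(
    position: np.ndarray,
    target: np.ndarray,
    focal_px: float,
    width: int,
    height: int,
    cam_id: str,
) -> CameraModel:
    forward = target - position
    forward = forward / np.linalg.norm(forward)
    world_up = np.array([0.0, 0.0, 1.0])
    right = np.cross(forward, world_up)
    nr = np.linalg.norm(right)
    if nr < 1e-9:
        raise RigGeometryError("camera optical axis is vertical; undefined roll")
    right /= nr
    down = np.cross(forward, right)  # +v downward in the image
    R = np.vstack([right, down, forward])
    K = np.array(
        [
            [focal_px, 0.0, (width - 1) / 2.0],
            [0.0, focal_px, (height - 1) / 2.0],
            [0.0, 0.0, 1.0],
        ]
    )
    P = K @ np.hstack([R, (-R @ position)[:, None]])
    return CameraModel(id=cam_id, P=P, image_width=width, image_height=height)


def make_rig(params: RigParams | None = None) -> list[CameraModel]:
    """Place cameras on a ring so every camera sees the full volume.

    Raises :class:`RigGeometryError` if any volume corner falls outside any
    camera's image.
    """
    p = params or RigParams()
    if p.n_cameras < 2:
        raise RigGeometryError("need at least 2 cameras")
    rng = np.random.default_rng(p.seed)
    center = p.center_mm
    cameras = []
    for i in range(p.n_cameras):
        theta = 2.0 * np.pi * i / p.n_cameras
        theta += np.deg2rad(rng.uniform(-p.angle_jitter_deg, p.angle_jitter_deg))
        height = rng.uniform(*p.height_range_mm)
        pos = np.array(
            [
                center[0] + p.distance_mm * np.cos(theta),
                center[1] + p.distance_mm * np.sin(theta),
                height,
            ]
        )
        cameras.append(
            _look_at_camera(pos, center, p.focal_px, p.image_width, p.image_height, f"cam{i:02d}")
        )
    corners = p.corners_mm()
    for cam in cameras:
        pix, depth = project_many(cam, corners)
        if np.any(depth <= 0):
            raise RigGeometryError(f"{cam.id}: volume corner behind camera")
        inside = (
            (pix[:, 0] >= 0)
            & (pix[:, 0] <= cam.image_width - 1)
            & (pix[:, 1] >= 0)
            & (pix[:, 1] <= cam.image_height - 1)
        )
        if not np.all(inside):
            raise RigGeometryError(
                f"{cam.id}: volume corners project outside the image; "
                "increase distance_mm or reduce focal_px"
            )
    return cameras


def simulate_gait_markers(
    params: GaitParams | None = None,
    *,
    rig: RigParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Smooth 25-marker walk through the volume.

    Markers start on a well-separated 5x5 grid in the x-z plane, translate
    forward along y at walking speed and oscillate sinusoidally at the stride
    frequency with per-marker amplitude and phase.  Returns an array of shape
    ``(n_markers, n_frames, 3)`` in mm.
    """
    g = params or GaitParams()
    r = rig or RigParams()
    if g.duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(g.duration_s * g.fps))
    t = np.arange(n_frames) / g.fps

    vol = r.volume_mm
    side = int(np.ceil(np.sqrt(g.n_markers)))
    xs = np.linspace(0.30 * vol[0], 0.70 * vol[0], side)
    zs = np.linspace(0.10 * vol[2], 0.90 * vol[2], side)
    base = np.array([(x, z) for z in zs for x in xs])[: g.n_markers]

    y_travel = g.speed_mm_s * g.duration_s
    y0_center = max(0.05 * vol[1], (vol[1] - y_travel) / 2.0 - 200.0)

    traj = np.empty((g.n_markers, n_frames, 3))
    for m in range(g.n_markers):
        amp = rng.uniform(*g.amplitude_mm, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        y0 = y0_center + rng.uniform(-150.0, 150.0)
        osc = amp[:, None] * np.sin(2 * np.pi * g.stride_hz * t[None, :] + phase[:, None])
        traj[m, :, 0] = base[m, 0] + osc[0]
        traj[m, :, 1] = y0 + g.speed_mm_s * t + osc[1]
        traj[m, :, 2] = base[m, 1] + osc[2]
    return traj


def simulate_wand(
    length_mm: float = 500.0,
    n_frames: int = 500,
    seed: int = 0,
    *,
    rig: RigParams | None = None,
) -> np.ndarray:
    """Two-marker wand sweep with exactly constant separation.

    Marker A follows a Lissajous path spanning the volume (margin 20 mm);
    marker B sits at ``length_mm`` from A in the direction of a smoothly
    wandering interior target, which keeps both markers inside the volume
    while the wand orientation varies over the sweep.  Returns
    ``(n_frames, 2, 3)`` mm.
    """
    if length_mm <= 0:
        raise ValueError("wand length must be positive")
    r = rig or RigParams()
    vol = r.volume_mm
    center = r.center_mm
    if length_mm >= 0.8 * min(vol) / 2.0:
        raise ValueError("wand too long for the measurement volume")
    rng = np.random.default_rng(seed)
    s = np.linspace(0.0, 1.0, n_frames)
    margin = 20.0
    amp = vol / 2.0 - margin
    freqs = np.array([2.0, 3.1, 2.6]) + rng.uniform(-0.2, 0.2, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    a = center[None, :] + amp[None, :] * np.sin(
        2 * np.pi * freqs[None, :] * s[:, None] + phases[None, :]
    )
    # interior target: volume centre plus a slow small wobble
    tf = np.array([0.7, 1.1, 0.9]) + rng.uniform(-0.1, 0.1, size=3)
    tp = rng.uniform(0, 2 * np.pi, size=3)
    q = center[None, :] + 100.0 * np.sin(2 * np.pi * tf[None, :] * s[:, None] + tp[None, :])
    d = q - a
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    b = a + length_mm * d
    return np.stack([a, b], axis=1)


def project_scene(
    scene: Scene,
    noise_sigma_px: float = 0.0,
    dropout_p: float = 0.0,
    seed: int = 0,
    *,
    marker_diameter_mm: float = 24.0,
):
    """Project marker trajectories into every camera.

    Returns a :class:`pandas.DataFrame` with columns
    ``camera, frame, u, v, w, h, confidence, class, marker`` — the first
    eight form a detection table (see :mod:`rgbmocap.detection_io`), and
    ``marker`` is the ground-truth correspondence for oracle tests.  Pixel
    noise is isotropic Gaussian; observations are independently dropped with
    probability ``dropout_p``; behind-camera and out-of-frame projections are
    excluded.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    n_markers, n_frames, _ = scene.trajectories.shape
    for cam in scene.cameras:
        pts = scene.trajectories.reshape(-1, 3)
        pix, depth = project_many(cam, pts)
        dists = np.linalg.norm(pts - cam.center[None, :], axis=1)
        size_px = cam_focal_scale(cam) * marker_diameter_mm / np.maximum(dists, 1e-9)
        if noise_sigma_px > 0:
            pix = pix + rng.normal(0.0, noise_sigma_px, size=pix.shape)
        keep = (
            (depth > 0)
            & (pix[:, 0] >= 0)
            & (pix[:, 0] <= cam.image_width - 1)
            & (pix[:, 1] >= 0)
            & (pix[:, 1] <= cam.image_height - 1)
        )
        if dropout_p > 0:
            keep &= rng.uniform(size=len(pts)) >= dropout_p
        idx = np.nonzero(keep)[0]
        for k in idx:
            m, f = divmod(int(k), n_frames)
            rows.append(
                (cam.id, f, float(pix[k, 0]), float(pix[k, 1]), float(size_px[k]),
                 float(size_px[k]), 1.0, 0, m)
            )
    df = pd.DataFrame(
        rows, columns=["camera", "frame", "u", "v", "w", "h", "confidence", "class", "marker"]
    )
    return df.sort_values(["frame", "camera"], kind="stable").reset_index(drop=True)


def cam_focal_scale(cam: CameraModel) -> float:
    """Effective focal length in px (geometric mean of the K diagonal)."""
    from .geometry import decompose_projection

    K, _, _ = decompose_projection(cam.P)
    return float(np.sqrt(abs(K[0, 0] * K[1, 1])))


@dataclass
class RenderStyle:
    """Appearance of rendered frames."""

    background_rgb: tuple[int, int, int] = (96, 96, 96)
    marker_diameter_mm: float = 24.0
    seed: int = 0


def render_frame(
    scene: Scene,
    camera: CameraModel,
    frame: int,
    style: RenderStyle | None = None,
) -> np.ndarray:
    """Rasterise one camera frame: visible markers as filled HSL-coloured discs.

    Disc radii follow perspective (focal * radius / depth); colours are drawn
    per marker from the spherical-marker HSL ranges so the naive colour
    detector can recover them.  Returns an ``(H, W, 3)`` uint8 array.
    """
    from ._color import hsl_to_rgb_u8

    style = style or RenderStyle()
    h, w = camera.image_height, camera.image_width
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[...] = np.array(style.background_rgb, dtype=np.uint8)
    if scene.n_markers == 0:
        return img
    pts = scene.trajectories[:, frame, :]
    pix, depth = project_many(camera, pts)
    dists = np.linalg.norm(pts - camera.center[None, :], axis=1)
    f = cam_focal_scale(camera)
    radii = f * (style.marker_diameter_mm / 2.0) / np.maximum(dists, 1e-9)
    for m in range(scene.n_markers):
        if depth[m] <= 0:
            continue
        u, v, r = pix[m, 0], pix[m, 1], radii[m]
        if u < -r or u > w - 1 + r or v < -r or v > h - 1 + r:
            continue
        mrng = np.random.default_rng(np.random.SeedSequence([style.seed, m]))
        color = hsl_to_rgb_u8(
            int(mrng.integers(140, 161)),
            int(mrng.integers(240, 256)),
            int(mrng.integers(140, 171)),
        )
        x0 = max(int(np.floor(u - r)) - 1, 0)
        x1 = min(int(np.ceil(u + r)) + 2, w)
        y0 = max(int(np.floor(v - r)) - 1, 0)
        y1 = min(int(np.ceil(v + r)) + 2, h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask = (xx - u) ** 2 + (yy - v) ** 2 <= r * r
        img[y0:y1, x0:x1][mask] = color
    return img


def make_scene(
    seed: int = 0,
    *,
    rig_params: RigParams | None = None,
    gait_params: GaitParams | None = None,
    wand_length_mm: float = 500.0,
    wand_frames: int = 500,
) -> Scene:
    """Convenience constructor: rig + gait markers + wand sweep."""
    rp = rig_params or RigParams(seed=seed)
    gp = gait_params or GaitParams()
    cameras = make_rig(rp)
    traj = simulate_gait_markers(gp, rig=rp, seed=seed + 1)
    wand = simulate_wand(wand_length_mm, wand_frames, seed + 2, rig=rp)
    return Scene(cameras=cameras, trajectories=traj, wand_track=wand,
                 frame_rate=gp.fps, rig=rp)
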