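"""Annotated training-image synthesis for spherical-marker detection.

Real spherical markers are imperfect spheres taped to the skin, so the
generator composites two randomized elements onto background frames recorded
without markers:

* a **virtual sphere** — a disc whose nine sub-regions (delimited by four
  boundary lines) are independently resized with nearest-neighbour
  interpolation, one axis then scaled by 80-100%, filled with a uniform
  colour drawn from the marker's HSL ranges (H 140-160, S 240-255,
  L 140-170 on byte scales);
* a **virtual tape** — rendered with probability 0.5, a rotated rectangle
  vertically compressed to an aspect ratio in [0.10, 1.00], filled with a
  near-white HSL colour (H 0-30, S 0-20, L 200-255).

Tape and sphere are combined so the tape centre sits at the anchor
``v1 = v2 * r_aspect + v3 * (1 - r_aspect)`` between the sphere centroid
``v2`` and its bottom edge ``v3``; the composite is resized until the sphere
diameter lies in [8, 24] px, randomly rotated, and inserted (7-12 markers
per image) into a 320x320 crop upscaled bicubically to 640x640.  A Gaussian
blur (sigma in [0.5, 3.0]) smooths each marker's boundary; pixels outside
the (dilated) marker regions are bit-identical to the upscaled background.
Bounding boxes of the sphere masks become normalized object annotations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

from ._color import hsl_to_rgb_u8


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SynthesisConfig:
    """All sampling ranges of the generator (closed intervals).

    HSL ranges are on 0-255 scales.  Geometry ranges whose published source
    is only schematic (boundary-line positions, tape length/width/offset)
    default to values that keep the deformed discs close to circular and the
    tape proportions plausible; all are configurable.
    """

    sphere_base_diameter: int = 96
    sphere_hue: tuple[int, int] = (140, 160)
    sphere_sat: tuple[int, int] = (240, 255)
    sphere_light: tuple[int, int] = (140, 170)
    axis_scale: tuple[float, float] = (0.80, 1.00)
    line_low: tuple[float, float] = (0.25, 0.42)   # first boundary, fraction of diameter
    line_high: tuple[float, float] = (0.58, 0.75)  # second boundary

    tape_probability: float = 0.5
    tape_hue: tuple[int, int] = (0, 30)
    tape_sat: tuple[int, int] = (0, 20)
    tape_light: tuple[int, int] = (200, 255)
    tape_length_rel: tuple[float, float] = (1.5, 3.0)   # x sphere diameter
    tape_width_rel: tuple[float, float] = (0.8, 1.6)    # x sphere diameter
    tape_offset_rel: float = 0.5                        # max centre offset, x diameter
    tape_aspect: tuple[float, float] = (0.10, 1.00)
    tape_rotation: tuple[float, float] = (0.0, 360.0)

    final_diameter: tuple[float, float] = (8.0, 24.0)
    marker_rotation: tuple[float, float] = (0.0, 360.0)
    blur_sigma: tuple[float, float] = (0.5, 3.0)
    n_markers: tuple[int, int] = (7, 12)
    crop_size: int = 320
    out_size: int = 640

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthesisConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in data.items()})
        return cfg

    def sha256(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()


# ---------------------------------------------------------------------------
# sampled specifications
# ---------------------------------------------------------------------------

@dataclass
class SphereSpec:
    base_diameter: int
    line_fractions: tuple[float, float, float, float]  # l1 < l2 (vertical), l3 < l4 (horizontal)
    axis_scale: float
    axis: int  # 0 = vertical (rows), 1 = horizontal (columns)
    hsl: tuple[int, int, int]


@dataclass
class TapeSpec:
    rendered: bool
    length: float = 0.0
    width: float = 0.0
    center_offset: tuple[float, float] = (0.0, 0.0)
    rotation: float = 0.0
    aspect_ratio: float = 1.0
    hsl: tuple[int, int, int] = (0, 0, 0)


@dataclass
class CompositionSpec:
    v1: tuple[float, float]
    v2: tuple[float, float]
    v3: tuple[float, float]
    r_aspect: float
    final_diameter: float
    rotation: float


@dataclass
class ComposedMarker:
    """A rendered virtual marker ready for insertion."""

    image: np.ndarray        # (h, w, 3) uint8
    alpha: np.ndarray        # union of sphere and tape pixels
    sphere_mask: np.ndarray  # sphere pixels only (the annotated object)
    bbox: tuple[int, int, int, int]  # x0, y0, w, h of the sphere mask
    spec: CompositionSpec
    sphere_spec: SphereSpec
    tape_spec: TapeSpec | None


@dataclass
class TrainingSample:
    image: np.ndarray                       # (out, out, 3) uint8
    annotations: list[tuple[int, float, float, float, float]]  # class, cx, cy, w, h
    provenance: dict
    marker_region_mask: np.ndarray          # pixels possibly altered by insertion
    markers: list[ComposedMarker] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sphere
# ---------------------------------------------------------------------------

def sample_sphere_spec(rng: np.random.Generator, config: SynthesisConfig) -> SphereSpec:
    l1 = rng.uniform(*config.line_low)
    l2 = rng.uniform(*config.line_high)
    l3 = rng.uniform(*config.line_low)
    l4 = rng.uniform(*config.line_high)
    axis_scale = rng.uniform(*config.axis_scale)
    axis = int(rng.integers(0, 2))
    hsl = (
        int(rng.integers(config.sphere_hue[0], config.sphere_hue[1] + 1)),
        int(rng.integers(config.sphere_sat[0], config.sphere_sat[1] + 1)),
        int(rng.integers(config.sphere_light[0], config.sphere_light[1] + 1)),
    )
    return SphereSpec(
        base_diameter=config.sphere_base_diameter,
        line_fractions=(l1, l2, l3, l4),
        axis_scale=axis_scale,
        axis=axis,
        hsl=hsl,
    )


def _piecewise_index_map(n_out: int, knots_out: Sequence[float], knots_src: Sequence[float]) -> np.ndarray:
    """Nearest-neighbour source indices for a piecewise-linear coordinate map."""
    centers = (np.arange(n_out) + 0.5) / n_out
    src = np.interp(centers, knots_out, knots_src) * n_out
    return np.clip(np.floor(src).astype(int), 0, n_out - 1)


def render_sphere(spec: SphereSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise a sphere spec to ``(rgb uint8, bool mask)``."""
    d = spec.base_diameter
    c = d / 2.0
    yy, xx = np.mgrid[0:d, 0:d]
    disc = (xx + 0.5 - c) ** 2 + (yy + 0.5 - c) ** 2 <= c * c

    l1, l2, l3, l4 = spec.line_fractions
    col_idx = _piecewise_index_map(d, [0.0, l1, l2, 1.0], [0.0, 1 / 3, 2 / 3, 1.0])
    row_idx = _piecewise_index_map(d, [0.0, l3, l4, 1.0], [0.0, 1 / 3, 2 / 3, 1.0])
    mask = disc[np.ix_(row_idx, col_idx)]

    # squash one axis by axis_scale (nearest neighbour)
    if spec.axis == 0:
        n_new = max(int(round(d * spec.axis_scale)), 1)
        idx = np.clip(np.floor((np.arange(n_new) + 0.5) / spec.axis_scale).astype(int), 0, d - 1)
        mask = mask[idx, :]
    else:
        n_new = max(int(round(d * spec.axis_scale)), 1)
        idx = np.clip(np.floor((np.arange(n_new) + 0.5) / spec.axis_scale).astype(int), 0, d - 1)
        mask = mask[:, idx]

    rgb = np.zeros(mask.shape + (3,), dtype=np.uint8)
    rgb[mask] = hsl_to_rgb_u8(*spec.hsl)
    return rgb, mask


def sample_sphere(
    rng: np.random.Generator, config: SynthesisConfig | None = None
) -> tuple[np.ndarray, np.ndarray, SphereSpec]:
    config = config or SynthesisConfig()
    if config.sphere_base_diameter < 8:
        raise ValueError("sphere base diameter must be at least 8 px")
    spec = sample_sphere_spec(rng, config)
    rgb, mask = render_sphere(spec)
    return rgb, mask, spec


# ---------------------------------------------------------------------------
# tape
# ---------------------------------------------------------------------------

def sample_tape_spec(rng: np.random.Generator, config: SynthesisConfig) -> TapeSpec:
    rendered = bool(rng.uniform() < config.tape_probability)
    d = config.sphere_base_diameter
    length = d * rng.uniform(*config.tape_length_rel)
    width = d * rng.uniform(*config.tape_width_rel)
    r_off = rng.uniform(0.0, config.tape_offset_rel * d)
    th_off = rng.uniform(0.0, 2 * np.pi)
    rotation = rng.uniform(*config.tape_rotation)
    aspect = rng.uniform(*config.tape_aspect)
    hsl = (
        int(rng.integers(config.tape_hue[0], config.tape_hue[1] + 1)),
        int(rng.integers(config.tape_sat[0], config.tape_sat[1] + 1)),
        int(rng.integers(config.tape_light[0], config.tape_light[1] + 1)),
    )
    return TapeSpec(
        rendered=rendered,
        length=length,
        width=width,
        center_offset=(r_off * np.cos(th_off), r_off * np.sin(th_off)),
        rotation=rotation,
        aspect_ratio=aspect,
        hsl=hsl,
    )


def render_tape(spec: TapeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise a tape spec: rotated rectangle, vertically compressed.

    The rectangle (with its sampled centre offset) lives in the tape image;
    the whole image is then compressed vertically by ``aspect_ratio``.  The
    mask is evaluated analytically on pixel centres, so no interpolation
    artefacts occur.
    """
    side = int(np.ceil(spec.length + 2 * abs(spec.center_offset[0]) + 2 * abs(spec.center_offset[1]))) + 4
    cx = cy = side / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    # undo the vertical compression, then the rotation, about the image centre
    xs = xx + 0.5 - cx - spec.center_offset[0]
    ys = (yy + 0.5 - cy) / max(spec.aspect_ratio, 1e-6) - spec.center_offset[1]
    th = np.deg2rad(spec.rotation)
    xr = np.cos(th) * xs + np.sin(th) * ys
    yr = -np.sin(th) * xs + np.cos(th) * ys
    mask = (np.abs(xr) <= spec.length / 2.0) & (np.abs(yr) <= spec.width / 2.0)
    rgb = np.zeros(mask.shape + (3,), dtype=np.uint8)
    rgb[mask] = hsl_to_rgb_u8(*spec.hsl)
    return rgb, mask


def sample_tape(
    rng: np.random.Generator, config: SynthesisConfig | None = None
) -> tuple[np.ndarray, np.ndarray, TapeSpec] | None:
    """Sample a tape; absent (None) with probability 1 - tape_probability."""
    config = config or SynthesisConfig()
    spec = sample_tape_spec(rng, config)
    if not spec.rendered:
        return None
    rgb, mask = render_tape(spec)
    return rgb, mask, spec


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def tape_anchor_point(
    v2: Sequence[float], v3: Sequence[float], r_aspect: float
) -> np.ndarray:
    """Anchor of the tape centre: ``v1 = v2 * r + v3 * (1 - r)``.

    ``v2`` is the sphere centroid, ``v3`` the sphere's bottom-edge point and
    ``r`` the tape aspect ratio, so a face-on tape (r = 1) is centred on the
    sphere and an edge-on tape (r = 0) hugs its bottom edge.
    """
    v2 = np.asarray(v2, dtype=float)
    v3 = np.asarray(v3, dtype=float)
    return v2 * r_aspect + v3 * (1.0 - r_aspect)


def _nn_resize(arr: np.ndarray, scale: float) -> np.ndarray:
    h = max(int(round(arr.shape[0] * scale)), 1)
    w = max(int(round(arr.shape[1] * scale)), 1)
    ri = np.clip(np.floor((np.arange(h) + 0.5) / scale).astype(int), 0, arr.shape[0] - 1)
    ci = np.clip(np.floor((np.arange(w) + 0.5) / scale).astype(int), 0, arr.shape[1] - 1)
    return arr[np.ix_(ri, ci)]


def _mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("empty mask")
    return int(xs.min()), int(ys.min()), int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1)


def _rotate_nn(arr: np.ndarray, angle_deg: float) -> np.ndarray:
    return ndimage.rotate(arr, angle_deg, reshape=True, order=0, prefilter=False)


def compose_marker(
    sphere: tuple[np.ndarray, np.ndarray, SphereSpec],
    tape: tuple[np.ndarray, np.ndarray, TapeSpec] | None,
    rng: np.random.Generator,
    config: SynthesisConfig | None = None,
) -> ComposedMarker:
    """Combine sphere and (optional) tape into one virtual marker.

    The tape is drawn *under* the sphere with its image centre at the anchor
    ``v1``; the composite is resized (nearest neighbour) so the sphere
    diameter lands in the configured [8, 24] px range, then rotated by a
    random angle.  A final corrective resize re-imposes the diameter bound if
    rotation stretched the axis-aligned extent past it.
    """
    config = config or SynthesisConfig()
    s_rgb, s_mask, s_spec = sphere
    if tape is not None:
        t_rgb, t_mask, t_spec = tape
    else:
        t_rgb = t_mask = None
        t_spec = None

    # canvas large enough for both
    sh, sw = s_mask.shape
    th, tw = (t_mask.shape if t_mask is not None else (0, 0))
    pad = int(np.ceil(max(th, tw) / 2)) + 2
    H, W = sh + 2 * pad, sw + 2 * pad
    canvas = np.zeros((H, W, 3), dtype=np.uint8)
    sphere_mask = np.zeros((H, W), dtype=bool)
    tape_mask = np.zeros((H, W), dtype=bool)

    sy, sx = pad, pad
    sphere_mask[sy : sy + sh, sx : sx + sw] = s_mask

    ys, xs = np.nonzero(sphere_mask)
    v2 = np.array([xs.mean() + 0.5, ys.mean() + 0.5])
    v3 = np.array([v2[0], ys.max() + 1.0])  # bottom edge of the sphere
    r_aspect = t_spec.aspect_ratio if t_spec is not None else 1.0
    v1 = tape_anchor_point(v2, v3, r_aspect)

    if t_mask is not None:
        # paste tape image with its centre at v1 (rounded to the pixel grid)
        ty = int(round(v1[1] - th / 2.0))
        tx = int(round(v1[0] - tw / 2.0))
        y0, x0 = max(ty, 0), max(tx, 0)
        y1, x1 = min(ty + th, H), min(tx + tw, W)
        sub = t_mask[y0 - ty : y1 - ty, x0 - tx : x1 - tx]
        tape_mask[y0:y1, x0:x1] = sub
        canvas[y0:y1, x0:x1][sub] = t_rgb[y0 - ty : y1 - ty, x0 - tx : x1 - tx][sub]

    canvas[sphere_mask] = s_rgb[s_mask]
    tape_mask &= ~sphere_mask  # sphere occludes the tape

    # crop to content
    union = sphere_mask | tape_mask
    bx, by, bw, bh = _mask_bbox(union)
    canvas = canvas[by : by + bh, bx : bx + bw]
    sphere_mask = sphere_mask[by : by + bh, bx : bx + bw]
    tape_mask = tape_mask[by : by + bh, bx : bx + bw]

    # resize so the sphere diameter is in the target range
    target = rng.uniform(*config.final_diameter)
    _, _, w0, h0 = _mask_bbox(sphere_mask)
    scale = target / max(w0, h0)
    canvas = _nn_resize(canvas, scale)
    sphere_mask = _nn_resize(sphere_mask, scale)
    tape_mask = _nn_resize(tape_mask, scale)

    # random rotation of the whole composite
    angle = rng.uniform(*config.marker_rotation)
    canvas = _rotate_nn(canvas, angle)
    sphere_mask = _rotate_nn(sphere_mask, angle)
    tape_mask = _rotate_nn(tape_mask, angle)

    # rotation can change the axis-aligned extent slightly; re-impose bounds
    lo, hi = config.final_diameter
    for _ in range(4):
        _, _, w0, h0 = _mask_bbox(sphere_mask)
        dia = max(w0, h0)
        if lo <= dia <= hi:
            break
        corr = np.clip(target, lo + 0.5, hi - 0.5) / dia
        canvas = _nn_resize(canvas, corr)
        sphere_mask = _nn_resize(sphere_mask, corr)
        tape_mask = _nn_resize(tape_mask, corr)

    bbox = _mask_bbox(sphere_mask)
    _, _, w0, h0 = bbox
    spec = CompositionSpec(
        v1=tuple(v1), v2=tuple(v2), v3=tuple(v3), r_aspect=r_aspect,
        final_diameter=float(max(w0, h0)), rotation=float(angle),
    )
    return ComposedMarker(
        image=canvas, alpha=sphere_mask | tape_mask, sphere_mask=sphere_mask,
        bbox=bbox, spec=spec, sphere_spec=s_spec, tape_spec=t_spec,
    )


# ---------------------------------------------------------------------------
# training images
# ---------------------------------------------------------------------------

def _bicubic_resize_u8(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    return np.asarray(Image.fromarray(img).resize(size, Image.BICUBIC))


def make_training_image(
    background: np.ndarray,
    rng: np.random.Generator,
    config: SynthesisConfig | None = None,
    *,
    frame_id: str = "frame",
) -> TrainingSample:
    """Crop, upscale, insert markers, blur their boundaries, annotate.

    A random ``crop_size`` square is cut from ``background``, bicubically
    upscaled to ``out_size``, and 7-12 composed markers are inserted at
    non-overlapping random positions.  Each marker's neighbourhood is
    Gaussian-blurred (sigma in [0.5, 3.0]); the background is restored
    outside the marker mask dilated by ceil(3 sigma), so every pixel outside
    ``marker_region_mask`` is bit-identical to the plain upscaled crop.
    """
    config = config or SynthesisConfig()
    bg = np.asarray(background)
    if bg.ndim == 2:
        bg = np.stack([bg] * 3, axis=-1)
    if bg.shape[0] < config.crop_size or bg.shape[1] < config.crop_size:
        raise ValueError(
            f"background must be at least {config.crop_size}x{config.crop_size}"
        )
    cy = int(rng.integers(0, bg.shape[0] - config.crop_size + 1))
    cx = int(rng.integers(0, bg.shape[1] - config.crop_size + 1))
    crop = bg[cy : cy + config.crop_size, cx : cx + config.crop_size]
    base = _bicubic_resize_u8(crop.astype(np.uint8), (config.out_size, config.out_size))
    out = base.copy()
    S = config.out_size

    n = int(rng.integers(config.n_markers[0], config.n_markers[1] + 1))
    occupied = np.zeros((S, S), dtype=bool)
    region_mask = np.zeros((S, S), dtype=bool)
    annotations: list[tuple[int, float, float, float, float]] = []
    markers: list[ComposedMarker] = []

    for _ in range(n):
        marker = compose_marker(
            sample_sphere(rng, config), sample_tape(rng, config), rng, config
        )
        sigma = float(rng.uniform(*config.blur_sigma))
        dil = int(np.ceil(3.0 * sigma))
        mh, mw = marker.alpha.shape
        # dilated footprint of the marker (computed on a padded canvas so the
        # dilation is not clipped at the marker's own crop boundary)
        footprint = ndimage.binary_dilation(
            np.pad(marker.alpha, dil), structure=_disk_structure(dil)
        )  # shape (mh + 2*dil, mw + 2*dil)

        placed = False
        for _try in range(200):
            py = int(rng.integers(dil + 1, S - mh - dil - 1))
            px = int(rng.integers(dil + 1, S - mw - dil - 1))
            occ = occupied[py - dil : py + mh + dil, px - dil : px + mw + dil]
            if not (occ & footprint).any():
                placed = True
                break
        if not placed:
            continue  # image too crowded; practically unreachable at these sizes

        # composite and blur within a working window padded by the kernel reach
        pad = dil + int(np.ceil(4.0 * sigma)) + 1
        wy0, wy1 = max(py - pad, 0), min(py + mh + pad, S)
        wx0, wx1 = max(px - pad, 0), min(px + mw + pad, S)
        window = out[wy0:wy1, wx0:wx1].astype(float)
        a_y, a_x = py - wy0, px - wx0
        sub = window[a_y : a_y + mh, a_x : a_x + mw]
        sub[marker.alpha] = marker.image[marker.alpha].astype(float)
        blurred = np.stack(
            [ndimage.gaussian_filter(window[..., c], sigma, mode="nearest") for c in range(3)],
            axis=-1,
        )
        win_dil = np.zeros(window.shape[:2], dtype=bool)
        win_dil[a_y - dil : a_y + mh + dil, a_x - dil : a_x + mw + dil] = footprint
        result = out[wy0:wy1, wx0:wx1].copy()
        result[win_dil] = np.clip(np.round(blurred[win_dil]), 0, 255).astype(np.uint8)
        out[wy0:wy1, wx0:wx1] = result

        region = np.zeros((S, S), dtype=bool)
        region[wy0:wy1, wx0:wx1] = win_dil
        region_mask |= region
        occupied |= region

        bx, by_, bw, bh = marker.bbox
        cx_n = (px + bx + bw / 2.0) / S
        cy_n = (py + by_ + bh / 2.0) / S
        annotations.append((0, cx_n, cy_n, bw / S, bh / S))
        markers.append(marker)

    return TrainingSample(
        image=out,
        annotations=annotations,
        provenance={"frame_id": frame_id, "crop_origin": (cx, cy)},
        marker_region_mask=region_mask,
        markers=markers,
    )


def _disk_structure(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return xx * xx + yy * yy <= radius * radius


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------

def write_label_file(path: str | Path, annotations) -> None:
    lines = [
        f"{int(c)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}" for c, cx, cy, w, h in annotations
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def build_dataset(
    frames: Sequence,
    n_images: int,
    seed: int,
    outdir: str | Path,
    config: SynthesisConfig | None = None,
) -> dict:
    """Write a detector-ready dataset: images/, labels/, train.txt, manifest.

    ``frames`` may be image arrays or paths.  Labels use the darknet
    normalized format ``class cx cy w h`` (one object per line).  Each image
    gets an independent child RNG spawned from the master seed, so any single
    sample can be regenerated bit-identically.
    """
    if len(frames) == 0:
        raise ValueError("need at least one background frame")
    config = config or SynthesisConfig()
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "labels").mkdir(parents=True, exist_ok=True)

    loaded = []
    for f in frames:
        if isinstance(f, (str, Path)):
            loaded.append(np.asarray(Image.open(f).convert("RGB")))
        else:
            loaded.append(np.asarray(f))

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_images)
    names = []
    for i in range(n_images):
        rng = np.random.default_rng(children[i])
        fi = int(rng.integers(0, len(loaded)))
        sample = make_training_image(loaded[fi], rng, config, frame_id=str(fi))
        name = f"img_{i:05d}"
        Image.fromarray(sample.image).save(outdir / "images" / f"{name}.png")
        write_label_file(outdir / "labels" / f"{name}.txt", sample.annotations)
        names.append(name)

    (outdir / "train.txt").write_text(
        "\n".join(f"images/{n}.png" for n in names) + "\n"
    )
    config.to_yaml(outdir / "config.yaml")
    manifest = {
        "seed": seed,
        "n_images": n_images,
        "config_sha256": config.sha256(),
        "images": names,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
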