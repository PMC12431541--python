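"""Detector-facing plumbing.

The marker detector itself is a *contract*: any callable taking an RGB image
array and returning a list of :class:`Detection` (e.g. a fine-tuned object
detection network, or the bundled GPU-free colour detector) can be plugged
into the pipeline.  This module provides the pre-detection bicubic upscale
with its coordinate mapping back to native resolution, the square-bbox
occlusion filter, a naive HSL colour-threshold detector used as a reference
in end-to-end tests, and lossless CSV detection tables.

Coordinate convention: detected centres and bbox sizes in the upscaled frame
are divided by the upscale factor (no half-pixel offset) to express them at
the original resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from ._color import hsl_in_range_mask


@dataclass
class Detection:
    """A digitized marker centre + bounding box in one camera/frame."""

    camera: str = ""
    frame: int = 0
    u: float = 0.0
    v: float = 0.0
    w: float = 1.0
    h: float = 1.0
    confidence: float = 1.0
    class_id: int = 0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("bounding box sides must be positive")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        return (self.u, self.v)


@dataclass
class DetectionConfig:
    """Detection thresholds and pre-detection upscaling."""

    confidence_threshold: float = 0.01
    iou_threshold: float = 0.01
    upscale_factor: int = 2

    def __post_init__(self) -> None:
        for t in (self.confidence_threshold, self.iou_threshold):
            if not 0.0 <= t <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")
        if self.upscale_factor < 1:
            raise ValueError("upscale_factor must be >= 1")


Detector = Callable[[np.ndarray], list[Detection]]


class DetectorError(RuntimeError):
    """A plugged-in detector failed; carries the original exception context."""


def detect_with_upscale(
    image: np.ndarray, detector: Detector, cfg: DetectionConfig | None = None
) -> list[Detection]:
    """Upscale bicubically, run the detector, map results to native pixels."""
    cfg = cfg or DetectionConfig()
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    f = cfg.upscale_factor
    if f > 1:
        h, w = img.shape[:2]
        up = np.asarray(
            Image.fromarray(img.astype(np.uint8)).resize((w * f, h * f), Image.BICUBIC)
        )
    else:
        up = img
    try:
        raw = detector(up)
    except Exception as exc:  # noqa: BLE001 - contract boundary
        raise DetectorError(f"detector failed on {up.shape} image: {exc}") from exc
    out = []
    for d in raw:
        if d.confidence < cfg.confidence_threshold:
            continue
        out.append(replace(d, u=d.u / f, v=d.v / f, w=d.w / f, h=d.h / f))
    return out


def squareness_filter(
    detections: Sequence[Detection], tolerance: float
) -> list[Detection]:
    """Drop detections whose bbox deviates from a square by more than ``tolerance``.

    Keeps boxes with ``min(w, h) / max(w, h) >= 1 - tolerance`` (a partially
    occluded marker yields an elongated box and a centre shifted off the true
    marker centre; discarding such boxes protects reconstruction accuracy).
    Order-preserving; output is a subset of the input.
    """
    if not 0.0 <= tolerance < 1.0:
        raise ValueError("tolerance must lie in [0, 1)")
    return [
        d for d in detections if min(d.w, d.h) / max(d.w, d.h) >= 1.0 - tolerance
    ]


def naive_color_detector(
    image: np.ndarray,
    hsl_ranges: dict | None = None,
    *,
    min_area: int = 16,
) -> list[Detection]:
    """Reference detector: HSL threshold + connected components.

    ``hsl_ranges`` maps ``"h"``, ``"s"``, ``"l"`` to (lo, hi) on 0-255
    scales (defaults: the spherical-marker synthesis ranges, widened a
    little to tolerate interpolation at disc edges).  Each connected
    component of in-range pixels becomes one detection: centre of mass plus
    tight bbox, confidence 1.0.
    """
    if hsl_ranges is None:
        hsl_ranges = {"h": (132, 168), "s": (200, 255), "l": (120, 190)}
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image")
    mask = hsl_in_range_mask(
        img, hsl_ranges["h"], hsl_ranges["s"], hsl_ranges["l"]
    )
    labels, n = ndimage.label(mask)
    if n == 0:
        return []
    out = []
    slices = ndimage.find_objects(labels)
    for i, sl in enumerate(slices, start=1):
        comp = labels[sl] == i
        area = int(comp.sum())
        if area < min_area:
            continue
        ys, xs = np.nonzero(comp)
        y0, x0 = sl[0].start, sl[1].start
        out.append(
            Detection(
                u=float(xs.mean() + x0),
                v=float(ys.mean() + y0),
                w=float(xs.max() - xs.min() + 1),
                h=float(ys.max() - ys.min() + 1),
                confidence=1.0,
                class_id=0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# detection tables
# ---------------------------------------------------------------------------

_COLUMNS = ["camera", "frame", "u", "v", "w", "h", "confidence", "class"]


class DetectionTableError(ValueError):
    """Malformed detection table; message names the offending file lines."""


def write_detections(path: str | Path, detections: Sequence[Detection]) -> None:
    df = pd.DataFrame(
        [
            (d.camera, d.frame, d.u, d.v, d.w, d.h, d.confidence, d.class_id)
            for d in detections
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_detections(path: str | Path) -> list[Detection]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise DetectionTableError(f"{path}: missing columns {missing}")
    numeric = {"frame": int, "u": float, "v": float, "w": float, "h": float,
               "confidence": float, "class": int}
    converted = {}
    for col, typ in numeric.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & (df[col] != "")
        bad |= df[col] == ""
        if bad.any():
            lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
            raise DetectionTableError(
                f"{path}: non-numeric value in column '{col}' at line(s) {lines}"
            )
        converted[col] = vals.astype(typ)
    return [
        Detection(
            camera=str(df["camera"].iloc[i]),
            frame=int(converted["frame"].iloc[i]),
            u=float(converted["u"].iloc[i]),
            v=float(converted["v"].iloc[i]),
            w=float(converted["w"].iloc[i]),
            h=float(converted["h"].iloc[i]),
            confidence=float(converted["confidence"].iloc[i]),
            class_id=int(converted["class"].iloc[i]),
        )
        for i in range(len(df))
    ]


def detections_from_dataframe(df: pd.DataFrame) -> list[Detection]:
    """Convert a detection DataFrame (e.g. from the simulator) to objects."""
    conf = df["confidence"] if "confidence" in df.columns else np.ones(len(df))
    cls = df["class"] if "class" in df.columns else np.zeros(len(df), dtype=int)
    return [
        Detection(
            camera=str(c), frame=int(f), u=float(u), v=float(v),
            w=float(w), h=float(h), confidence=float(cf), class_id=int(cl),
        )
        for c, f, u, v, w, h, cf, cl in zip(
            df["camera"], df["frame"], df["u"], df["v"], df["w"], df["h"], conf, cls
        )
    ]
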