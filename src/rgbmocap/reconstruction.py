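"""Multi-view marker correspondence and 3D reconstruction.

Marker identities across cameras are unknown, so correspondences are found
by exploring detection combinations under a hard geometric acceptance rule:
a 3D candidate is valid only if the distance between the triangulated point
and the back-projected camera ray is below the gate (default 5 mm) for
*every* contributing camera, and at least ``min_cameras`` (default 3)
cameras contribute.

Search strategy: iterate over seed camera pairs in decreasing baseline
order; for each pair, triangulate every available detection pair, then
greedily add the best in-gate detection of each remaining camera,
re-triangulating after every addition so the gate is always tested against
the updated point.  Candidates sharing a detection are resolved in favour
of more cameras, then lower mean ray distance; each detection contributes
to at most one reconstructed point, and detections consumed by one seed
pair are unavailable to later (narrower) pairs — so a marker occluded in
one camera is still found from another seed pair.  All orderings and
tie-breaks are deterministic given sorted camera/detection ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detection_io import Detection
from .geometry import (
    CameraModel,
    DegenerateGeometryError,
    Ray,
    pixel_to_ray,
    point_ray_distance,
    triangulate_rays,
)


@dataclass
class ReconstructionConfig:
    """Acceptance rule for a reconstructed marker.

    ``merge_radius_mm`` suppresses duplicate reconstructions of one physical
    marker (a marker's detections can otherwise split into two disjoint
    camera subsets under noise): no two accepted points may be closer than
    this radius.  The default is the spherical marker diameter — two real
    markers cannot have centres closer than that.  Set 0 to disable.
    """

    gate_mm: float = 5.0
    min_cameras: int = 3
    merge_radius_mm: float = 24.0

    def __post_init__(self) -> None:
        if self.gate_mm <= 0:
            raise ValueError("gate_mm must be positive")
        if self.min_cameras < 2:
            raise ValueError("min_cameras must be >= 2")
        if self.merge_radius_mm < 0:
            raise ValueError("merge_radius_mm must be >= 0")


@dataclass
class ReconstructedPoint:
    """A 3D marker with its contributing cameras and per-camera evidence."""

    position: np.ndarray
    frame: int
    cameras_used: frozenset
    mean_ray_distance: float
    observations: dict = field(default_factory=dict)  # camera id -> (u, v)
    label: str | None = None


class UnknownCameraError(KeyError):
    pass


def _ray_pair_midpoint(r1: Ray, r2: Ray) -> tuple[np.ndarray, float] | None:
    """Midpoint of the common perpendicular of two rays and their separation."""
    d1, d2 = r1.direction, r2.direction
    o1, o2 = r1.origin, r2.origin
    c = d1 @ d2
    denom = 1.0 - c * c
    if denom < 1e-12:
        return None
    w = o2 - o1
    t1 = (w @ d1 - (w @ d2) * c) / denom
    t2 = ((w @ d1) * c - w @ d2) / denom
    p1 = o1 + t1 * d1
    p2 = o2 + t2 * d2
    return (p1 + p2) / 2.0, float(np.linalg.norm(p1 - p2))


def match_and_triangulate(
    detections: Sequence[Detection],
    cameras: Mapping[str, CameraModel],
    cfg: ReconstructionConfig | None = None,
) -> list[ReconstructedPoint]:
    """Establish correspondences and triangulate one frame of detections."""
    cfg = cfg or ReconstructionConfig()
    for d in detections:
        if d.camera not in cameras:
            raise UnknownCameraError(f"detection references unknown camera {d.camera!r}")
    if not detections:
        return []
    frame = detections[0].frame

    by_cam: dict[str, list[Detection]] = {}
    for d in sorted(detections, key=lambda d: (d.camera, d.u, d.v)):
        by_cam.setdefault(d.camera, []).append(d)
    cam_ids = sorted(by_cam)
    if len(cam_ids) < 2:
        return []

    rays = {
        cid: [pixel_to_ray(cameras[cid], (d.u, d.v)) for d in by_cam[cid]]
        for cid in cam_ids
    }
    centers = {cid: cameras[cid].center for cid in cam_ids}

    # seed pairs in decreasing baseline order: a marker occluded or merged in
    # one camera can still be seeded from another pair
    pairs = []
    for i, a in enumerate(cam_ids):
        for b in cam_ids[i + 1 :]:
            pairs.append((float(np.linalg.norm(centers[a] - centers[b])), a, b))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))

    # conflict resolution key: most cameras, then lowest mean ray distance
    def sort_key(item):
        used, res = item
        return (-len(used), res.mean_ray_distance, tuple(sorted(used.items())))

    out: list[ReconstructedPoint] = []
    taken: set[tuple[str, int]] = set()
    for _, cam_a, cam_b in pairs:
        others = [c for c in cam_ids if c not in (cam_a, cam_b)]
        candidates = []
        for ia, ra in enumerate(rays[cam_a]):
            if (cam_a, ia) in taken:
                continue
            for ib, rb in enumerate(rays[cam_b]):
                if (cam_b, ib) in taken:
                    continue
                mid = _ray_pair_midpoint(ra, rb)
                if mid is None:
                    continue
                point, sep = mid
                if sep / 2.0 >= cfg.gate_mm:  # each ray is sep/2 from the midpoint
                    continue
                used = {cam_a: ia, cam_b: ib}
                used_rays = [ra, rb]
                try:
                    res = triangulate_rays(used_rays)
                except DegenerateGeometryError:
                    continue
                if np.any(res.distances >= cfg.gate_mm):
                    continue
                point = res.point
                for cid in others:
                    # cheap pre-gate: perpendicular distances to the current point
                    dists = np.array(
                        [point_ray_distance(point, r) for r in rays[cid]]
                    )
                    order = np.argsort(dists, kind="stable")
                    best = None
                    for k in order:
                        if dists[k] >= 2.0 * cfg.gate_mm:
                            break
                        if (cid, int(k)) in taken:
                            continue
                        trial = triangulate_rays(used_rays + [rays[cid][k]])
                        if np.all(trial.distances < cfg.gate_mm):
                            best_mean = trial.mean_ray_distance
                            if best is None or best_mean < best[1]:
                                best = (int(k), best_mean, trial)
                    if best is not None:
                        k, _, trial = best
                        used[cid] = k
                        used_rays.append(rays[cid][k])
                        point = trial.point
                        res = trial
                if len(used) < cfg.min_cameras:
                    continue
                candidates.append((used, res))

        for used, res in sorted(candidates, key=sort_key):
            keys = {(cid, k) for cid, k in used.items()}
            if keys & taken:
                continue
            if cfg.merge_radius_mm > 0 and any(
                np.linalg.norm(res.point - q.position) < cfg.merge_radius_mm
                for q in out
            ):
                continue  # duplicate reconstruction of an accepted marker
            taken |= keys
            obs = {cid: (by_cam[cid][k].u, by_cam[cid][k].v) for cid, k in used.items()}
            out.append(
                ReconstructedPoint(
                    position=res.point,
                    frame=frame,
                    cameras_used=frozenset(used),
                    mean_ray_distance=res.mean_ray_distance,
                    observations=obs,
                )
            )
    return out


def reconstruct_sequence(
    detections: Sequence[Detection] | pd.DataFrame,
    cameras: Mapping[str, CameraModel],
    cfg: ReconstructionConfig | None = None,
    *,
    expected_markers: int | None = None,
) -> tuple[dict[int, list[ReconstructedPoint]], dict]:
    """Apply :func:`match_and_triangulate` frame by frame, with bookkeeping.

    The report counts expected points (``frames x expected_markers`` when the
    marker count is known), reconstructed points, and failures per frame.
    """
    cfg = cfg or ReconstructionConfig()
    if isinstance(detections, pd.DataFrame):
        from .detection_io import detections_from_dataframe

        detections = detections_from_dataframe(detections)
    if len(detections) == 0:
        warnings.warn("empty detection table; nothing to reconstruct", stacklevel=2)
        return {}, {"n_frames": 0, "expected": 0, "reconstructed": 0, "failed": 0,
                    "failures": []}

    frames: dict[int, list[Detection]] = {}
    for d in detections:
        frames.setdefault(d.frame, []).append(d)

    points: dict[int, list[ReconstructedPoint]] = {}
    failures = []
    total = 0
    for f in sorted(frames):
        pts = match_and_triangulate(frames[f], cameras, cfg)
        points[f] = pts
        total += len(pts)
        if expected_markers is not None and len(pts) < expected_markers:
            failures.append({"frame": f, "missing": expected_markers - len(pts)})
    expected = (
        expected_markers * len(frames) if expected_markers is not None else total
    )
    report = {
        "n_frames": len(frames),
        "expected": expected,
        "reconstructed": total,
        "failed": expected - total,
        "failures": failures,
    }
    return points, report


# ---------------------------------------------------------------------------
# temporal association
# ---------------------------------------------------------------------------

@dataclass
class LabeledTrajectories:
    """Per-label tracks with gap and ambiguity bookkeeping."""

    positions: dict  # label -> {frame: ReconstructedPoint}
    ambiguous: list  # (frame, label) where a second candidate was within reach
    gaps: dict       # label -> list of frames with no accepted point


def track_and_label(
    points_by_frame: Mapping[int, Sequence[ReconstructedPoint]],
    initial_labels: Mapping[int, str],
    max_jump_mm: float,
) -> LabeledTrajectories:
    """Propagate frame-0 labels through time by gated nearest-neighbour matching.

    ``initial_labels`` maps point indices in the first frame to label names.
    Jumps above ``max_jump_mm`` (scaled by the number of frames elapsed when
    a label was occluded) are rejected; when two candidate points fall within
    the gate of one label the assignment is flagged ambiguous rather than
    silently swapped.  Points never matched to a label get anonymous ids.
    """
    from scipy.optimize import linear_sum_assignment

    labels = list(initial_labels.values())
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate initial labels")
    frames = sorted(points_by_frame)
    if not frames:
        return LabeledTrajectories({}, [], {})
    f0 = frames[0]

    tracks: dict[str, dict[int, ReconstructedPoint]] = {}
    last_seen: dict[str, tuple[int, np.ndarray]] = {}
    for idx, lab in initial_labels.items():
        pt = points_by_frame[f0][idx]
        pt.label = lab
        tracks[lab] = {f0: pt}
        last_seen[lab] = (f0, pt.position)
    anon_count = 0
    ambiguous: list[tuple[int, str]] = []
    gaps: dict[str, list[int]] = {lab: [] for lab in tracks}

    # anonymous ids for unlabelled frame-0 points
    for i, pt in enumerate(points_by_frame[f0]):
        if i not in initial_labels:
            lab = f"track_{anon_count:03d}"
            anon_count += 1
            pt.label = lab
            tracks[lab] = {f0: pt}
            last_seen[lab] = (f0, pt.position)
            gaps[lab] = []

    for f in frames[1:]:
        pts = list(points_by_frame[f])
        labs = sorted(last_seen)
        if pts and labs:
            cost = np.full((len(labs), len(pts)), np.inf)
            for i, lab in enumerate(labs):
                fprev, pos = last_seen[lab]
                allowed = max_jump_mm * (f - fprev)
                d = np.linalg.norm(
                    np.array([p.position for p in pts]) - pos[None, :], axis=1
                )
                cost[i, np.nonzero(d <= allowed)[0]] = d[d <= allowed]
                if np.sum(d <= allowed) >= 2:
                    ambiguous.append((f, lab))
            # Hungarian on the finite entries (inf replaced by a large constant)
            big = 1e12
            r, c = linear_sum_assignment(np.where(np.isinf(cost), big, cost))
            assigned_pts = set()
            for i, j in zip(r, c):
                if cost[i, j] >= big:
                    continue
                lab = labs[i]
                pts[j].label = lab
                tracks[lab][f] = pts[j]
                last_seen[lab] = (f, pts[j].position)
                assigned_pts.add(j)
            for lab in labs:
                if f not in tracks[lab]:
                    gaps.setdefault(lab, []).append(f)
            for j, p in enumerate(pts):
                if j not in assigned_pts:
                    lab = f"track_{anon_count:03d}"
                    anon_count += 1
                    p.label = lab
                    tracks[lab] = {f: p}
                    last_seen[lab] = (f, p.position)
                    gaps[lab] = []
        else:
            for lab in labs:
                gaps.setdefault(lab, []).append(f)
    return LabeledTrajectories(positions=tracks, ambiguous=ambiguous, gaps=gaps)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def points_to_dataframe(points_by_frame: Mapping[int, Sequence[ReconstructedPoint]]) -> pd.DataFrame:
    rows = []
    for f in sorted(points_by_frame):
        for p in points_by_frame[f]:
            rows.append(
                (p.frame, p.label if p.label is not None else "",
                 p.position[0], p.position[1], p.position[2],
                 len(p.cameras_used), p.mean_ray_distance)
            )
    return pd.DataFrame(
        rows, columns=["frame", "label", "x", "y", "z", "n_cameras", "mean_ray_distance"]
    )


def write_points_csv(path: str | Path, points_by_frame) -> None:
    points_to_dataframe(points_by_frame).to_csv(path, index=False)


def write_trc(
    path: str | Path,
    trajectories: Mapping[str, Mapping[int, ReconstructedPoint]],
    frame_rate: float = 240.0,
) -> None:
    """Minimal TRC (Track Row Column) export for mocap interoperability.

    Positions are written in millimetres; frames missing a marker are left
    blank, as standard TRC allows.
    """
    labels = sorted(trajectories)
    all_frames = sorted({f for t in trajectories.values() for f in t})
    n = len(all_frames)
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{Path(path).name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{frame_rate:g}\t{frame_rate:g}\t{n}\t{len(labels)}\tmm\t{frame_rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t".join(f"{lab}\t\t" for lab in labels),
        "\t\t" + "\t".join(
            f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(labels))
        ),
    ]
    for row_i, f in enumerate(all_frames, start=1):
        cells = [str(row_i), f"{(f / frame_rate):.6f}"]
        for lab in labels:
            pt = trajectories[lab].get(f)
            if pt is None:
                cells.extend(["", "", ""])
            else:
                cells.extend(f"{v:.4f}" for v in pt.position)
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")
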