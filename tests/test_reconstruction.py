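"""Correspondence search, gating, sequence bookkeeping and tracking."""

import numpy as np
import pytest

from rgbmocap.detection_io import detections_from_dataframe
from rgbmocap.geometry import pixel_to_ray, point_ray_distance
from rgbmocap.reconstruction import (
    ReconstructedPoint,
    ReconstructionConfig,
    UnknownCameraError,
    match_and_triangulate,
    points_to_dataframe,
    reconstruct_sequence,
    track_and_label,
    write_trc,
)
from rgbmocap.scene_simulator import project_scene


def frame_detections(scene, frame, **kw):
    df = project_scene(scene, kw.get("noise", 0.0), kw.get("dropout", 0.0),
                       kw.get("seed", 0))
    return detections_from_dataframe(df[df.frame == frame])


class TestMatchAndTriangulate:
    def test_unknown_camera_rejected(self, scene, scene_cameras):
        dets = frame_detections(scene, 0)
        dets[0].camera = "nope"
        with pytest.raises(UnknownCameraError):
            match_and_triangulate(dets, scene_cameras)

    def test_marker_seen_by_two_cameras_excluded(self, scene, scene_cameras):
        """min_cameras=3 rejects markers with only two views."""
        df = project_scene(scene, 0.0, 0.0, 0)
        f0 = df[df.frame == 0]
        # keep marker 0 in only two cameras
        drop = (f0.marker == 0) & ~f0.camera.isin(["cam00", "cam04"])
        dets = detections_from_dataframe(f0[~drop])
        pts = match_and_triangulate(dets, scene_cameras)
        gt0 = scene.trajectories[0, 0, :]
        assert all(np.linalg.norm(p.position - gt0) > 1.0 for p in pts)
        assert len(pts) == 24

    def test_noisy_gate_soundness_and_exclusivity(self, scene, scene_cameras):
        df = project_scene(scene, 1.0, 0.0, 5)
        used_detections = set()
        for f in range(30):
            dets = detections_from_dataframe(df[df.frame == f])
            pts = match_and_triangulate(dets, scene_cameras)
            for p in pts:
                assert len(p.cameras_used) >= 3
                for cid, uv in p.observations.items():
                    ray = pixel_to_ray(scene_cameras[cid], uv)
                    assert point_ray_distance(p.position, ray) < 5.0
                    key = (f, cid, uv)
                    assert key not in used_detections  # one point per detection
                    used_detections.add(key)

    def test_tighter_gate_reconstructs_fewer_points(self, scene, scene_cameras):
        """A gate below the ray-noise scale starves reconstruction; the
        default gate recovers nearly everything.  (Exact count monotonicity
        in the gate is not a theorem for an exclusive greedy matcher: near
        saturation, a larger gate can absorb a neighbour's detection and
        lose a point, so the comparison is made across a wide gap.)"""
        df = project_scene(scene, 1.0, 0.0, 9)
        starved, default = 0, 0
        for f in range(5):
            dets = detections_from_dataframe(df[df.frame == f])
            starved += len(match_and_triangulate(
                dets, scene_cameras, ReconstructionConfig(gate_mm=1.0)))
            default += len(match_and_triangulate(
                dets, scene_cameras, ReconstructionConfig(gate_mm=5.0)))
        assert starved < 0.8 * default

    def test_noiseless_result_stable_across_gates(self, scene, scene_cameras):
        df = project_scene(scene, 0.0, 0.0, 0)
        dets = detections_from_dataframe(df[df.frame == 0])
        for gate in (1.0, 5.0, 20.0):
            pts = match_and_triangulate(dets, scene_cameras,
                                        ReconstructionConfig(gate_mm=gate))
            assert len(pts) == 25


class TestReconstructSequence:
    def test_dropout_bookkeeping(self, scene, scene_cameras):
        df = project_scene(scene, 0.0, 0.1, 7)
        sub = df[df.frame < 10]
        points, report = reconstruct_sequence(sub, scene_cameras,
                                              expected_markers=25)
        assert report["expected"] == 10 * 25
        assert report["reconstructed"] + report["failed"] == report["expected"]
        assert report["n_frames"] == 10

    def test_zero_dropout_has_no_failures(self, scene, scene_cameras):
        df = project_scene(scene, 0.0, 0.0, 0)
        _, report = reconstruct_sequence(df[df.frame < 5], scene_cameras,
                                         expected_markers=25)
        assert report["failed"] == 0

    def test_single_camera_reconstructs_nothing(self, scene, scene_cameras):
        df = project_scene(scene, 0.0, 0.0, 0)
        sub = df[(df.frame < 5) & (df.camera == "cam00")]
        _, report = reconstruct_sequence(sub, scene_cameras, expected_markers=25)
        assert report["reconstructed"] == 0

    def test_empty_table_warns(self, scene_cameras):
        with pytest.warns(UserWarning):
            points, report = reconstruct_sequence([], scene_cameras)
        assert points == {}


def _pt(pos, f):
    return ReconstructedPoint(
        position=np.asarray(pos, float), frame=f,
        cameras_used=frozenset({"a", "b", "c"}), mean_ray_distance=0.1,
        observations={"a": (0, 0), "b": (0, 0), "c": (0, 0)},
    )


class TestTrackAndLabel:
    def test_static_points_keep_labels(self):
        pbf = {f: [_pt([0, 0, 0], f), _pt([1000, 0, 0], f)] for f in range(5)}
        tr = track_and_label(pbf, {0: "LHEE", 1: "RHEE"}, 30.0)
        assert set(tr.positions) == {"LHEE", "RHEE"}
        assert all(len(t) == 5 for t in tr.positions.values())
        assert tr.ambiguous == []

    def test_crossing_trajectories_flagged_ambiguous(self):
        pbf = {}
        for f in range(11):
            x = 10.0 * f
            pbf[f] = [_pt([x, 0, 0], f), _pt([100 - x, 5, 0], f)]
        tr = track_and_label(pbf, {0: "A", 1: "B"}, 30.0)
        assert len(tr.ambiguous) > 0

    def test_gap_recorded_and_label_resumes(self):
        pbf = {0: [_pt([0, 0, 0], 0)], 1: [], 2: [_pt([5, 0, 0], 2)]}
        tr = track_and_label(pbf, {0: "X"}, 30.0)
        assert tr.gaps["X"] == [1]
        assert 2 in tr.positions["X"]

    def test_duplicate_initial_labels_rejected(self):
        pbf = {0: [_pt([0, 0, 0], 0), _pt([9, 9, 9], 0)]}
        with pytest.raises(ValueError):
            track_and_label(pbf, {0: "A", 1: "A"}, 30.0)

    def test_jump_beyond_limit_not_associated(self):
        pbf = {0: [_pt([0, 0, 0], 0)], 1: [_pt([500, 0, 0], 1)]}
        tr = track_and_label(pbf, {0: "A"}, 30.0)
        assert 1 not in tr.positions["A"]
        assert tr.gaps["A"] == [1]


class TestExport:
    def test_points_dataframe_columns(self, scene, scene_cameras):
        df = project_scene(scene, 0.0, 0.0, 0)
        pts, _ = reconstruct_sequence(df[df.frame < 2], scene_cameras)
        out = points_to_dataframe(pts)
        assert list(out.columns) == [
            "frame", "label", "x", "y", "z", "n_cameras", "mean_ray_distance",
        ]
        assert len(out) == 50

    def test_trc_export_parses(self, tmp_path):
        pbf = {f: [_pt([f, 0, 0], f), _pt([100, 100, 100], f)] for f in range(3)}
        tr = track_and_label(pbf, {0: "A", 1: "B"}, 30.0)
        path = tmp_path / "out.trc"
        write_trc(path, tr.positions, frame_rate=240.0)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("PathFileType")
        assert len(lines) == 5 + 3  # header + data rows
        first = lines[5].split("\t")
        assert first[0] == "1"
        assert len(first) == 2 + 3 * 2
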