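"""Virtual marker synthesis: sampling ranges, composition, training images."""

import numpy as np
import pytest
from scipy import ndimage

from rgbmocap.marker_synthesis import (
    SphereSpec,
    SynthesisConfig,
    TapeSpec,
    build_dataset,
    compose_marker,
    make_training_image,
    render_sphere,
    render_tape,
    sample_sphere,
    sample_sphere_spec,
    sample_tape,
    sample_tape_spec,
    tape_anchor_point,
)

CFG = SynthesisConfig()


class TestSphere:
    def test_identity_deformation_is_plain_disc(self):
        spec = SphereSpec(96, (1 / 3, 2 / 3, 1 / 3, 2 / 3), 1.0, 0, (150, 250, 150))
        _, mask = render_sphere(spec)
        assert mask.sum() == pytest.approx(np.pi * 48**2, rel=0.02)

    def test_sampled_hsl_within_printed_ranges(self):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            s = sample_sphere_spec(rng, CFG)
            h, sat, lig = s.hsl
            assert 140 <= h <= 160
            assert 240 <= sat <= 255
            assert 140 <= lig <= 170
            assert 0.80 <= s.axis_scale <= 1.00
            l1, l2, l3, l4 = s.line_fractions
            assert l1 < l2 and l3 < l4

    def test_mask_connected_and_area_bounded_by_extremes(self):
        """Any sampled deformation's area lies between the extreme line settings."""
        rng = np.random.default_rng(1)
        lo, hi = CFG.line_low, CFG.line_high
        extreme_areas = []
        for l1 in lo:
            for l2 in hi:
                for l3 in lo:
                    for l4 in hi:
                        spec = SphereSpec(96, (l1, l2, l3, l4), 1.0, 0, (150, 250, 150))
                        extreme_areas.append(render_sphere(spec)[1].sum())
        amin, amax = min(extreme_areas), max(extreme_areas)
        for _ in range(50):
            s = sample_sphere_spec(rng, CFG)
            s = SphereSpec(96, s.line_fractions, 1.0, 0, s.hsl)  # isolate the lines
            _, mask = render_sphere(s)
            _, n = ndimage.label(mask)
            assert n == 1
            assert amin * 0.98 <= mask.sum() <= amax * 1.02


class TestTape:
    def test_render_probability_is_one_half(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        n = 10_000
        rendered = sum(sample_tape_spec(rng, CFG).rendered for _ in range(n))
        lo, hi = stats.binom.interval(0.99, n, 0.5)
        assert lo <= rendered <= hi

    def test_aspect_ratios_within_range(self):
        rng = np.random.default_rng(3)
        for _ in range(10_000):
            s = sample_tape_spec(rng, CFG)
            assert 0.10 <= s.aspect_ratio <= 1.00
            h, sat, lig = s.hsl
            assert 0 <= h <= 30 and 0 <= sat <= 20 and 200 <= lig <= 255

    def test_unit_aspect_keeps_nominal_height(self):
        spec = TapeSpec(True, length=60.0, width=20.0, center_offset=(0, 0),
                        rotation=0.0, aspect_ratio=1.0, hsl=(10, 10, 220))
        _, mask = render_tape(spec)
        ys = np.nonzero(mask.any(axis=1))[0]
        assert ys.max() - ys.min() + 1 == pytest.approx(20, abs=1)

    def test_compressed_aspect_shrinks_height(self):
        spec = TapeSpec(True, length=60.0, width=20.0, center_offset=(0, 0),
                        rotation=0.0, aspect_ratio=0.5, hsl=(10, 10, 220))
        _, mask = render_tape(spec)
        ys = np.nonzero(mask.any(axis=1))[0]
        assert ys.max() - ys.min() + 1 == pytest.approx(10, abs=1)


class TestComposition:
    @pytest.mark.parametrize(
        "r,expected",
        [(1.0, (10.0, 10.0)), (0.0, (10.0, 20.0)), (0.5, (10.0, 15.0))],
    )
    def test_anchor_interpolates_centroid_and_bottom_edge(self, r, expected):
        assert tuple(tape_anchor_point((10, 10), (10, 20), r)) == expected

    def test_composed_anchor_matches_formula(self):
        rng = np.random.default_rng(4)
        sphere = sample_sphere(rng, CFG)
        spec = TapeSpec(True, length=150.0, width=90.0, center_offset=(0, 0),
                        rotation=30.0, aspect_ratio=0.37, hsl=(10, 10, 220))
        tape = (*render_tape(spec), spec)
        m = compose_marker(sphere, tape, rng, CFG)
        v1 = np.array(m.spec.v2) * m.spec.r_aspect + np.array(m.spec.v3) * (
            1 - m.spec.r_aspect
        )
        assert m.spec.v1 == pytest.approx(tuple(v1), abs=1e-12)

    def test_final_sphere_diameter_in_range(self):
        for i in range(300):
            rng = np.random.default_rng(100 + i)
            m = compose_marker(sample_sphere(rng, CFG), sample_tape(rng, CFG), rng, CFG)
            d = max(m.bbox[2], m.bbox[3])
            assert 8 <= d <= 24

    def test_bbox_is_tight_box_of_sphere_mask(self):
        rng = np.random.default_rng(5)
        m = compose_marker(sample_sphere(rng, CFG), sample_tape(rng, CFG), rng, CFG)
        ys, xs = np.nonzero(m.sphere_mask)
        assert m.bbox == (xs.min(), ys.min(), xs.max() - xs.min() + 1,
                          ys.max() - ys.min() + 1)

    def test_bbox_disc_covers_sphere_mask(self):
        """The inscribed disc reproduces the bulk of each sphere mask."""
        fracs = []
        for i in range(150):
            rng = np.random.default_rng(1000 + i)
            m = compose_marker(sample_sphere(rng, CFG), sample_tape(rng, CFG), rng, CFG)
            x0, y0, w, h = m.bbox
            yy, xx = np.mgrid[0 : m.sphere_mask.shape[0], 0 : m.sphere_mask.shape[1]]
            cx, cy = x0 + (w - 1) / 2, y0 + (h - 1) / 2
            ell = ((xx - cx) / (w / 2)) ** 2 + ((yy - cy) / (h / 2)) ** 2 <= 1.0
            fracs.append((m.sphere_mask & ell).sum() / m.sphere_mask.sum())
        assert np.mean(fracs) >= 0.95
        assert min(fracs) >= 0.75  # strongly deformed 8 px blobs rasterise coarsely


class TestTrainingImage:
    def test_size_and_annotation_count(self, background):
        for seed in range(20):
            s = make_training_image(background, np.random.default_rng(seed), CFG)
            assert s.image.shape == (640, 640, 3)
            assert 7 <= len(s.annotations) <= 12
            for c, cx, cy, w, h in s.annotations:
                assert c == 0
                assert 0 <= cx <= 1 and 0 <= cy <= 1 and 0 < w <= 1 and 0 < h <= 1

    def test_background_retained_outside_marker_regions(self, background):
        from PIL import Image

        rng = np.random.default_rng(9)
        s = make_training_image(background, rng, CFG)
        cx, cy = s.provenance["crop_origin"]
        crop = background[cy : cy + 320, cx : cx + 320]
        base = np.asarray(Image.fromarray(crop).resize((640, 640), Image.BICUBIC))
        outside = ~s.marker_region_mask
        assert (s.image[outside] == base[outside]).all()

    def test_rerun_with_same_seed_is_bit_identical(self, background):
        a = make_training_image(background, np.random.default_rng(77), CFG)
        b = make_training_image(background, np.random.default_rng(77), CFG)
        assert (a.image == b.image).all()
        assert a.annotations == b.annotations

    def test_small_background_rejected(self):
        with pytest.raises(ValueError):
            make_training_image(np.zeros((100, 100, 3), np.uint8),
                                np.random.default_rng(0), CFG)


class TestDatasetWriter:
    def test_dataset_layout_and_formats(self, tmp_path, background):
        manifest = build_dataset([background], 12, 31, tmp_path / "ds")
        images = sorted((tmp_path / "ds" / "images").glob("*.png"))
        labels = sorted((tmp_path / "ds" / "labels").glob("*.txt"))
        assert len(images) == len(labels) == 12
        assert manifest["n_images"] == 12 and manifest["seed"] == 31
        for lab in labels:
            for line in lab.read_text().splitlines():
                fields = line.split()
                assert len(fields) == 5
                assert fields[0] == "0"
                assert all(0.0 <= float(v) <= 1.0 for v in fields[1:])
        assert (tmp_path / "ds" / "train.txt").exists()
        assert (tmp_path / "ds" / "config.yaml").exists()

    def test_different_seeds_give_different_images(self, tmp_path, background):
        build_dataset([background], 3, 1, tmp_path / "a")
        build_dataset([background], 3, 2, tmp_path / "b")
        pa = sorted((tmp_path / "a" / "images").glob("*.png"))
        pb = sorted((tmp_path / "b" / "images").glob("*.png"))
        for f1 in pa:
            for f2 in pb:
                assert f1.read_bytes() != f2.read_bytes()

    def test_config_yaml_roundtrip(self, tmp_path):
        CFG.to_yaml(tmp_path / "c.yaml")
        back = SynthesisConfig.from_yaml(tmp_path / "c.yaml")
        assert back == CFG
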