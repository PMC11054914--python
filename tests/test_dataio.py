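"""Preprocessing and the row-major position-class encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pupilgrid as pg
from pupilgrid.dataio import PupilAnnotation
from pupilgrid.errors import (
    ConsistencyError,
    FormatError,
    RangeError,
    SizeError,
)


class TestToGrayscale:
    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((255, 255, 255), 1.0),
            ((0, 0, 0), 0.0),
            # hand arithmetic with the BT.601 weights
            ((100, 150, 200),
             0.299 * 100 / 255 + 0.587 * 150 / 255 + 0.114 * 200 / 255),
        ],
    )
    def test_constant_images(self, rgb, expected):
        img = np.full((4, 6, 3), rgb, dtype=np.uint8)
        out = pg.to_grayscale(img)
        assert out.shape == (4, 6)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(FormatError):
            pg.to_grayscale(np.zeros((4, 6, 4), dtype=np.uint8))
        with pytest.raises(FormatError):
            pg.to_grayscale(np.zeros((4, 6)))


class TestResize:
    def test_identity_resize_is_exact(self):
        img = np.random.default_rng(0).random((15, 20))
        out = pg.resize(img, 20, 15)
        assert np.array_equal(out, img)

    def test_constant_image_stays_constant(self):
        out = pg.resize(np.full((48, 64), 0.37), 20, 15)
        np.testing.assert_allclose(out, 0.37, atol=1e-12)

    def test_output_in_unit_interval(self):
        img = np.random.default_rng(1).random((48, 64))
        out = pg.resize(img, 320, 240)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_rescaled_annotation_lands_in_rescaled_pupil(self):
        # render at 640x480, downscale to 320x240; the scaled ground truth
        # must still sit on a dark (pupil) pixel
        scene = pg.sample_scene(3, "easy", 640, 480)
        scene.noise_sd = 0.0
        img, ann = pg.render_eye(scene, 640, 480)
        small = pg.resize(img, 320, 240)
        sann = pg.scale_annotation(ann, (640, 480), (320, 240))
        assert small[sann.cy, sann.cx] < scene.iris_intensity

    def test_nonpositive_target_rejected(self):
        with pytest.raises(SizeError):
            pg.resize(np.zeros((4, 4)), 0, 4)


class TestScaleAnnotation:
    @pytest.mark.parametrize(
        "ann, in_size, out_size, expected",
        [
            ((100, 50), (320, 240), (320, 240), (100, 50)),
            ((100, 50), (640, 480), (320, 240), (50, 25)),
            # ratios 320/620 and 240/460, then round
            ((310, 230), (620, 460), (320, 240), (160, 120)),
        ],
    )
    def test_examples(self, ann, in_size, out_size, expected):
        out = pg.scale_annotation(PupilAnnotation(*ann), in_size, out_size)
        assert out == expected

    def test_result_clipped_into_bounds(self):
        out = pg.scale_annotation(PupilAnnotation(639, 479), (640, 480),
                                  (320, 240))
        assert 0 <= out.cx < 320 and 0 <= out.cy < 240


class TestCropCenter:
    def test_even_margins(self):
        img = np.random.default_rng(0).random((288, 384))
        out, off = pg.crop_center(img, 320, 240)
        assert off == (32, 24)
        assert out.shape == (240, 320)
        assert np.array_equal(out, img[24:264, 32:352])

    def test_same_size_crop_is_identity(self):
        img = np.random.default_rng(0).random((240, 320))
        out, off = pg.crop_center(img, 320, 240)
        assert off == (0, 0)
        assert np.array_equal(out, img)

    def test_odd_margin_ties_toward_top_left(self):
        img = np.random.default_rng(0).random((240, 321))
        _, off = pg.crop_center(img, 320, 240)
        assert off == (0, 0)

    def test_oversized_target_rejected(self):
        with pytest.raises(SizeError):
            pg.crop_center(np.zeros((240, 320)), 321, 240)


class TestClassEncoding:
    @pytest.mark.parametrize(
        "coord, cls", [((0, 0), 1), ((1, 0), 2), ((9, 7), 150), ((19, 14), 300)]
    )
    def test_corner_and_center_classes(self, coord, cls):
        assert pg.coord_to_class(PupilAnnotation(*coord), 20) == cls
        assert pg.class_to_coord(cls, 20) == coord

    def test_bijection_over_all_300_cells(self):
        seen = set()
        for cy in range(15):
            for cx in range(20):
                c = pg.coord_to_class(PupilAnnotation(cx, cy), 20, 15)
                assert pg.class_to_coord(c, 20, 15) == (cx, cy)
                seen.add(c)
        assert seen == set(range(1, 301))

    def test_out_of_range_rejected(self):
        with pytest.raises(RangeError):
            pg.coord_to_class(PupilAnnotation(20, 0), 20)
        with pytest.raises(RangeError):
            pg.class_to_coord(0, 20)
        with pytest.raises(RangeError):
            pg.class_to_coord(301, 20, 15)


class TestDatasetRoundTrip:
    def test_save_load_preserves_annotations_and_8bit_intensities(
        self, tmp_path, easy_lowres_samples
    ):
        samples = easy_lowres_samples[:10]
        pg.save_dataset(samples, tmp_path, seed=7)
        loaded = pg.load_dataset(tmp_path)
        assert len(loaded) == 10
        for orig, back in zip(samples, loaded):
            assert back.annotation == orig.annotation
            assert np.abs(back.image - orig.image).max() <= 1.0 / 255.0

    def test_missing_image_file_is_a_consistency_error(
        self, tmp_path, easy_lowres_samples
    ):
        pg.save_dataset(easy_lowres_samples[:3], tmp_path)
        (tmp_path / "img_00001.png").unlink()
        with pytest.raises(ConsistencyError, match="img_00001.png"):
            pg.load_dataset(tmp_path)

    def test_unlabeled_image_is_a_consistency_error(
        self, tmp_path, easy_lowres_samples
    ):
        pg.save_dataset(easy_lowres_samples[:3], tmp_path)
        import shutil

        shutil.copy(tmp_path / "img_00000.png", tmp_path / "img_00099.png")
        with pytest.raises(ConsistencyError, match="img_00099.png"):
            pg.load_dataset(tmp_path)


@settings(max_examples=50, derandomize=True)
@given(
    cx=st.integers(0, 19), cy=st.integers(0, 14),
    in_w=st.integers(20, 800), in_h=st.integers(15, 600),
    out_w=st.integers(20, 800), out_h=st.integers(15, 600),
)
def test_scaled_annotation_always_in_bounds(cx, cy, in_w, in_h, out_w, out_h):
    ann = pg.scale_annotation(
        PupilAnnotation(cx * in_w // 20, cy * in_h // 15),
        (in_w, in_h), (out_w, out_h),
    )
    assert 0 <= ann.cx < out_w and 0 <= ann.cy < out_h
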