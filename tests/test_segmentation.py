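"""Segmentation: thresholding, deblurring, line integration, TV denoising."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as sk_disk
from skimage.measure import euler_number, label

from skelopod.errors import NoCellFound
from skelopod.segmentation import (MovieStack, denoise_tv, gaussian_psf,
                                   integrate_dic, segment_dic,
                                   segment_fluorescence,
                                   segment_phase_contrast)


def _block_image(value=200.0):
    img = np.zeros((100, 100))
    img[40:60, 40:60] = value
    return img


class TestFluorescence:
    def test_bimodal_block_recovered_exactly(self):
        img = _block_image()
        seg = segment_fluorescence(img)
        expect = img > 0
        assert np.array_equal(seg.mask, expect)

    def test_min_area_drops_speck(self):
        img = _block_image()
        img[5:8, 5:8] = 200.0
        seg = segment_fluorescence(img, min_area=50)
        assert np.array_equal(seg.mask, _block_image() > 0)

    def test_constant_image_raises(self):
        with pytest.raises(NoCellFound):
            segment_fluorescence(np.full((50, 50), 7.0))

    def test_affine_intensity_invariance(self):
        img = _block_image() + np.random.default_rng(0).normal(0, 5, (100, 100))
        m1 = segment_fluorescence(img).mask
        m2 = segment_fluorescence(3.5 * img + 100.0).mask
        assert np.array_equal(m1, m2)

    def test_single_component_no_holes(self):
        rng = np.random.default_rng(1)
        img = np.zeros((120, 120))
        rr, cc = sk_disk((60, 60), 30)
        img[rr, cc] = 150
        img[55:60, 55:60] = 0  # interior hole must be filled
        img += rng.normal(0, 10, img.shape)
        seg = segment_fluorescence(img)
        assert label(seg.mask).max() == 1
        assert euler_number(seg.mask) == 1  # one component, zero holes


class TestPhaseContrast:
    @pytest.fixture()
    def forward_model(self):
        rng = np.random.default_rng(0)
        truth = np.zeros((120, 120), bool)
        rr, cc = sk_disk((60, 60), 25)
        truth[rr, cc] = True
        tex = truth * (1 + 0.4 * rng.normal(size=truth.shape))
        blurred = gaussian_filter(tex, 2) + 0.01 * rng.normal(size=truth.shape)
        return blurred, truth

    def test_area_within_10pct(self, forward_model):
        blurred, truth = forward_model
        seg = segment_phase_contrast(blurred, psf=gaussian_psf(2.0), n_iter=10)
        assert abs(seg.area / truth.sum() - 1.0) < 0.10

    def test_delta_psf_skips_deblurring(self, forward_model):
        blurred, _ = forward_model
        delta = np.zeros((5, 5))
        delta[2, 2] = 1.0
        seg = segment_phase_contrast(blurred, psf=delta, n_iter=10)
        # identity convolution: same result as the pipeline minus RL
        assert seg.area > 0

    def test_uniform_background_raises(self):
        with pytest.raises(NoCellFound):
            segment_phase_contrast(np.zeros((50, 50)))


def _smooth_blob(shape=(80, 80), r=20):
    img = np.zeros(shape)
    rr, cc = sk_disk((shape[0] // 2, shape[1] // 2), r)
    img[rr, cc] = 100.0
    return gaussian_filter(img, 3)


class TestLineIntegratedDIC:
    def test_inverts_forward_difference(self):
        blob = _smooth_blob()
        deriv = np.diff(blob, axis=1, prepend=0.0)
        rec = integrate_dic(deriv, (1.0, 0.0))
        # recovery up to a per-line additive constant
        target = blob - np.median(blob, axis=1, keepdims=True)
        assert np.abs(rec - target).max() < 1e-9

    def test_zero_image_maps_to_zero(self):
        out = integrate_dic(np.zeros((40, 40)), (1.0, 0.0))
        assert np.abs(out).max() == 0.0

    def test_rotation_symmetry(self):
        blob = _smooth_blob()
        deriv = np.diff(blob, axis=1, prepend=0.0)
        r1 = integrate_dic(deriv, (1.0, 0.0))
        r2 = integrate_dic(np.rot90(deriv), (0.0, -1.0))
        assert np.allclose(np.rot90(r1), r2, atol=1e-9)

    def test_non_unit_shear_rejected(self):
        with pytest.raises(ValueError):
            integrate_dic(np.zeros((10, 10)), (2.0, 0.0))


class TestTVDenoise:
    def test_reduces_error_on_piecewise_constant(self):
        rng = np.random.default_rng(2)
        clean = np.zeros((60, 60))
        clean[20:40, 20:40] = 1.0
        noisy = clean + rng.normal(0, 0.2, clean.shape)
        out = denoise_tv(noisy, weight=0.2)
        assert np.abs(out - clean).mean() < np.abs(noisy - clean).mean()

    def test_small_weight_is_near_identity(self):
        rng = np.random.default_rng(3)
        img = rng.normal(0, 1, (30, 30))
        out = denoise_tv(img, weight=1e-4)
        assert np.abs(out - img).max() < 0.05

    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 3.0)
        assert np.array_equal(denoise_tv(img, 0.1), img)

    def test_total_variation_never_increases(self):
        rng = np.random.default_rng(4)
        img = rng.normal(0, 1, (40, 40))

        def tv(a):
            return (np.abs(np.diff(a, axis=0)).sum()
                    + np.abs(np.diff(a, axis=1)).sum())

        assert tv(denoise_tv(img, 0.3)) <= tv(img) + 1e-9


class TestDIC:
    @pytest.fixture()
    def dic_blob(self):
        rng = np.random.default_rng(5)
        blob = _smooth_blob(shape=(120, 120), r=20)
        truth = blob > 0.5 * blob.max()
        deriv = np.diff(blob, axis=1, prepend=0.0)
        noisy = deriv + rng.normal(0, 0.3, deriv.shape)
        return noisy, deriv, truth

    @staticmethod
    def _jaccard(a, b):
        return (a & b).sum() / (a | b).sum()

    def test_both_variants_close_to_truth_and_each_other(self, dic_blob):
        noisy, _, truth = dic_blob
        masks = {}
        for var in ("denoise_first", "texture_after"):
            masks[var] = segment_dic(noisy, (1, 0), var).mask
            assert self._jaccard(masks[var], truth) >= 0.8
        assert self._jaccard(masks["denoise_first"],
                             masks["texture_after"]) >= 0.8

    def test_noise_free_jaccard(self, dic_blob):
        _, clean, truth = dic_blob
        seg = segment_dic(clean, (1, 0), "denoise_first")
        assert self._jaccard(seg.mask, truth) >= 0.95

    def test_uniform_image_raises(self):
        with pytest.raises(NoCellFound):
            segment_dic(np.zeros((50, 50)), (1, 0), "denoise_first")

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            segment_dic(np.ones((20, 20)), (1, 0), "bogus")


class TestMovieStack:
    def test_tiff_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 255, (4, 32, 32)).astype(np.uint16)
        m = MovieStack(frames, frame_interval=10.0, pixel_size=0.2)
        path = tmp_path / "m.tif"
        m.to_tiff(path)
        back = MovieStack.from_tiff(path, 10.0, 0.2)
        assert np.array_equal(back.frames, frames)
        assert back.n_frames == 4

    def test_invalid_metadata_rejected(self):
        frames = np.zeros((2, 8, 8))
        with pytest.raises(ValueError):
            MovieStack(frames, frame_interval=0.0, pixel_size=0.2)
        with pytest.raises(ValueError):
            MovieStack(frames, frame_interval=1.0, pixel_size=-1.0)
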