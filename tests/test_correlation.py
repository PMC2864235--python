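"""Angular matrices, normalised cross-correlation and site intensities."""

import numpy as np
import pytest

from skelopod.activity import Activity
from skelopod.correlation import (AngularActivityMatrix,
                                  AngularIntensityMatrix,
                                  activity_site_intensity,
                                  build_activity_matrix, cross_correlate,
                                  length_vs_intensity_profile,
                                  sample_membrane_intensity,
                                  site_intensity_summary)
from skelopod.errors import DegenerateInput


def _zero_rowmean_matrix(seed=0, n=100, m=90):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n, m))
    return a - a.mean(axis=1, keepdims=True)


class TestCrossCorrelate:
    def test_output_shape_formula(self):
        a = _zero_rowmean_matrix(n=100, m=90)
        C = cross_correlate(AngularActivityMatrix(a, 4.0),
                            AngularIntensityMatrix(a.copy(), 4.0))
        assert C.values.shape == (90, 199)  # (360/4, 2*100-1)
        assert C.angle_shifts[0] == pytest.approx(-176.0)
        assert C.angle_shifts[-1] == pytest.approx(180.0)
        assert C.time_shifts[0] == -99 and C.time_shifts[-1] == 99

    def test_autocorrelation_peak_is_one_at_origin(self):
        a = _zero_rowmean_matrix(seed=1)
        C = cross_correlate(AngularActivityMatrix(a, 4.0),
                            AngularIntensityMatrix(a.copy(), 4.0))
        dk, dth, v = C.peak()
        assert (dk, dth) == (0.0, 0.0)
        assert v == pytest.approx(1.0)

    def test_planted_shift_recovered(self):
        a = _zero_rowmean_matrix(seed=2)
        shifted = np.roll(np.roll(a, 3, axis=0), 5, axis=1)  # +3 fr, +20 deg
        C = cross_correlate(AngularActivityMatrix(a, 4.0),
                            AngularIntensityMatrix(shifted, 4.0))
        dk, dth, v = C.peak()
        assert (dk, dth) == (-3.0, -20.0)
        assert v > 0.9

    def test_bounded_and_affine_invariant(self):
        a = _zero_rowmean_matrix(seed=3, n=40, m=30)
        b = _zero_rowmean_matrix(seed=4, n=40, m=30)
        C1 = cross_correlate(AngularActivityMatrix(a, 12.0),
                             AngularIntensityMatrix(b, 12.0))
        assert np.abs(C1.values).max() <= 1.0 + 1e-12
        C2 = cross_correlate(AngularActivityMatrix(2.5 * a + 1.0, 12.0),
                             AngularIntensityMatrix(0.5 * b - 3.0, 12.0))
        assert np.allclose(C1.values, C2.values, atol=1e-9)

    def test_circular_shift_property(self):
        a = _zero_rowmean_matrix(seed=5, n=30, m=36)
        C0 = cross_correlate(AngularActivityMatrix(a, 10.0),
                             AngularIntensityMatrix(a.copy(), 10.0))
        Cs = cross_correlate(AngularActivityMatrix(a, 10.0),
                             AngularIntensityMatrix(np.roll(a, 2, axis=1),
                                                    10.0))
        _, dth0, _ = C0.peak()
        _, dths, _ = Cs.peak()
        assert dths - dth0 == pytest.approx(-20.0)  # -2 bins of 10 deg

    def test_zero_variance_rejected(self):
        a = np.zeros((10, 12))
        with pytest.raises(DegenerateInput):
            cross_correlate(AngularActivityMatrix(a, 30.0),
                            AngularIntensityMatrix(a, 30.0))


class TestActivityMatrix:
    def test_empty(self):
        A = build_activity_matrix([], 4.0, 10)
        assert A.values.shape == (10, 90)
        assert not A.values.any()

    def test_sign_convention(self):
        pro = Activity("protrusion", 0, 0, 0.0, 30, 7.0, frame_index=3)
        ret = Activity("retraction", 0, 0, 0.0, 30, 7.0, frame_index=3)
        Ap = build_activity_matrix([pro], 4.0, 10)
        Ar = build_activity_matrix([ret], 4.0, 10)
        assert Ap.values.sum() == 7.0 and (Ap.values != 0).sum() == 1
        assert Ar.values.sum() == -7.0

    def test_collision_keeps_larger(self):
        a1 = Activity("protrusion", 0, 0, 1.0, 30, 3.0, frame_index=3)
        a2 = Activity("retraction", 0, 0, 1.0, 30, 9.0, frame_index=3)
        A = build_activity_matrix([a1, a2], 4.0, 10)
        assert A.values.sum() == -9.0


class TestSampleMembrane:
    def _ring_setup(self, intensity_fn, r=25):
        from skelopod.boundary import extract_boundary, fit_bspline
        side = 2 * (r + 15)
        yy, xx = np.mgrid[0:side, 0:side]
        c = side // 2
        mask = (yy - c) ** 2 + (xx - c) ** 2 <= r ** 2
        curve = fit_bspline(extract_boundary(mask))
        img = np.zeros((side, side))
        band = mask & ((yy - c) ** 2 + (xx - c) ** 2 >= (r - 4) ** 2)
        theta = np.degrees(np.arctan2(-(yy - c), xx - c))
        img[band] = intensity_fn(theta[band])
        return img, curve

    def test_uniform_ring_flat_profile(self):
        img, curve = self._ring_setup(lambda th: 5.0)
        prof = sample_membrane_intensity(img, curve, delta_theta=10.0)
        assert prof.shape == (36,)
        assert np.allclose(prof, prof[0], atol=0.8)

    def test_cosine_pattern_recovered(self):
        img, curve = self._ring_setup(lambda th: np.cos(np.radians(th)))
        prof = sample_membrane_intensity(img, curve, delta_theta=10.0)
        centers = -180 + 10.0 * np.arange(36) + 5.0
        expect = np.cos(np.radians(centers))
        r = np.corrcoef(prof, expect)[0, 1]
        assert r > 0.97

    def test_delta_theta_must_divide_360(self):
        img, curve = self._ring_setup(lambda th: 1.0)
        with pytest.raises(ValueError):
            sample_membrane_intensity(img, curve, delta_theta=7.0)


class TestNormalization:
    def test_minmax_and_zscore(self):
        rng = np.random.default_rng(0)
        I = AngularIntensityMatrix(rng.normal(5, 2, (20, 36)), 10.0)
        mm = I.normalized("minmax")
        assert mm.values.min() == pytest.approx(0.0)
        assert mm.values.max() == pytest.approx(1.0)
        z = I.normalized("zscore")
        assert np.allclose(z.values.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.values.std(axis=1), 1.0, atol=1e-9)


class TestSiteIntensity:
    def _acts(self, rng, n=200, coupling=2.0, noise=0.1):
        acts, intens = [], np.zeros((n, 36))
        for k in range(n):
            theta = float(rng.uniform(-179, 179))
            ln = float(rng.uniform(1, 8))
            kind = "protrusion" if rng.random() < 0.7 else "retraction"
            signed = ln if kind == "protrusion" else -ln
            b = int((theta + 180) // 10) % 36
            intens[k, b] = coupling * signed + rng.normal(0, noise)
            acts.append(Activity(kind, 0, 0, theta, 10.0 * k, ln,
                                 frame_index=k))
        return acts, AngularIntensityMatrix(intens, 10.0, "zscore")

    def test_linear_coupling_recovered(self):
        rng = np.random.default_rng(6)
        acts, I = self._acts(rng)
        pairs = activity_site_intensity(acts, I, offset_deg=0.0)
        summ = site_intensity_summary(pairs)
        assert summ["correlation"] > 0.8
        assert (summ["mean_intensity_protrusion"]
                > summ["mean_intensity_retraction"])

    def test_constant_intensity_flagged(self):
        rng = np.random.default_rng(8)
        acts, _ = self._acts(rng)
        I0 = AngularIntensityMatrix(np.zeros((len(acts), 36)), 10.0, "zscore")
        pairs = activity_site_intensity(acts, I0)
        summ = site_intensity_summary(pairs)
        assert summ["degenerate"]
        assert (pairs["intensity"] == 0).all()

    def test_offset_must_align_with_bins(self):
        I = AngularIntensityMatrix(np.zeros((5, 36)), 10.0)
        with pytest.raises(ValueError):
            activity_site_intensity([], I, offset_deg=7.0)


class TestLengthProfile:
    def test_monotone_negative_coupling(self):
        rng = np.random.default_rng(9)
        intens = rng.uniform(-2, 2, 400)
        signed = -3.0 * intens + rng.normal(0, 0.2, 400)
        import pandas as pd
        pairs = pd.DataFrame({"intensity": intens, "signed_length": signed,
                              "kind": "protrusion", "frame": 0})
        prof = length_vs_intensity_profile(pairs, n_bins=6)
        assert (np.diff(prof["mean_length"]) < 0).all()

    def test_single_bin_equals_overall_mean(self):
        import pandas as pd
        pairs = pd.DataFrame({"intensity": [0.1, 0.5, 0.9],
                              "signed_length": [1.0, 2.0, 6.0],
                              "kind": "protrusion", "frame": 0})
        prof = length_vs_intensity_profile(pairs, n_bins=1)
        assert prof["mean_length"].iloc[0] == pytest.approx(3.0)

    def test_no_coupling_flat_within_sem(self):
        rng = np.random.default_rng(10)
        import pandas as pd
        pairs = pd.DataFrame({"intensity": rng.uniform(-2, 2, 600),
                              "signed_length": rng.normal(0, 1, 600),
                              "kind": "protrusion", "frame": 0})
        prof = length_vs_intensity_profile(pairs, n_bins=5)
        grand = prof["mean_length"].mean()
        assert (np.abs(prof["mean_length"] - grand)
                <= 2.5 * prof["sem"] + 1e-9).all()
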