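"""Trace construction, profile sampling, quartic fit and laminar subdivision."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from laminarct import (BoundaryPair, RibbonSpec, Trace, build_traces,
                       fit_quartic, generate_ribbon, inflections,
                       laminar_split, mean_profile, sample_trace,
                       subject_laminar_ct, total_ct)
from laminarct.errors import (BoundsError, GeometryError,
                              NoAdmissibleSplitError)
from laminarct.laminar import DepthProfile


class TestBuildTraces:
    def test_parallel_contours_perpendicular_equal_lengths(self, parallel_boundaries):
        traces = build_traces(parallel_boundaries)
        # 20 candidates collapse onto the 10 shared endpoint pairs
        assert len(traces) == 10
        for t in traces:
            assert t.length_px == pytest.approx(13.0)
            assert t.start[0] == pytest.approx(t.end[0])  # vertical

    def test_single_point_contours_deduplicate_to_one(self):
        b = BoundaryPair(np.array([[0.0, 0.0]]), np.array([[0.0, 13.0]]),
                         pixel_mm=0.1875)
        traces = build_traces(b)
        assert len(traces) == 1
        assert traces[0].length_px == pytest.approx(13.0)

    def test_identical_contours_degenerate(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5)])
        with pytest.raises(GeometryError):
            build_traces(BoundaryPair(pts, pts, pixel_mm=0.1875))

    def test_all_pairs_rule(self):
        sup = np.column_stack([np.arange(3.0), np.zeros(3)])
        deep = np.column_stack([np.arange(3.0), np.full(3, 10.0)])
        traces = build_traces(BoundaryPair(sup, deep, 1.0), "all_pairs")
        assert len(traces) == 9  # 2*9 directed pairs, deduplicated

    def test_curved_phantom_mean_length_matches_truth(self, curved_ribbon):
        b = curved_ribbon.truth["boundaries"]
        assert total_ct(b) == pytest.approx(2.4375, rel=0.02)


class TestSampleTrace:
    def _image(self, raster):
        class _Img:
            pass
        img = _Img()
        img.raster = np.asarray(raster, dtype=float)
        return img

    def test_constant_field(self):
        img = self._image(np.full((20, 20), 7.0))
        t = Trace(np.array([2.0, 2.0]), np.array([2.0, 15.0]), "sup2deep", 13.0)
        assert np.allclose(sample_trace(img, t, 51).intensities, 7.0)

    def test_linear_ramp_sampled_exactly(self):
        """Bilinear interpolation reproduces a linear field exactly."""
        yy = np.arange(30, dtype=float)[:, None]
        img = self._image(np.broadcast_to(3.0 * yy + 1.0, (30, 20)).copy())
        t = Trace(np.array([5.0, 2.0]), np.array([5.0, 27.0]), "sup2deep", 25.0)
        got = sample_trace(img, t, 101).intensities
        expect = 3.0 * np.linspace(2.0, 27.0, 101) + 1.0
        assert np.allclose(got, expect, atol=1e-12)

    def test_depth_reversal_for_deep_to_superficial(self):
        yy = np.arange(30, dtype=float)[:, None]
        img = self._image(np.broadcast_to(yy, (30, 20)).copy())
        fwd = Trace(np.array([5.0, 2.0]), np.array([5.0, 27.0]), "sup2deep", 25.0)
        rev = Trace(np.array([5.0, 27.0]), np.array([5.0, 2.0]), "deep2sup", 25.0)
        assert np.allclose(sample_trace(img, fwd, 51).intensities,
                           sample_trace(img, rev, 51).intensities)

    def test_endpoint_outside_raster(self):
        img = self._image(np.zeros((10, 10)))
        t = Trace(np.array([0.0, 0.0]), np.array([0.0, 12.0]), "sup2deep", 12.0)
        with pytest.raises(BoundsError):
            sample_trace(img, t)


class TestMeanProfile:
    def _trace(self, vals):
        t = Trace(np.zeros(2), np.ones(2), "sup2deep", 1.0)
        t.intensities = np.asarray(vals, dtype=float)
        return t

    def test_identity_and_symmetry(self):
        v = np.linspace(1, 5, 11)
        assert np.allclose(mean_profile([self._trace(v)]).mean_intensity, v)
        p = mean_profile([self._trace(v), self._trace(-v)])
        assert np.allclose(p.mean_intensity, 0.0)

    def test_noisy_copies_average_to_template(self):
        rng = np.random.default_rng(0)
        template = np.sin(np.linspace(0, 3, 101)) * 10
        noise_sd = 1.0
        traces = [self._trace(template + rng.normal(0, noise_sd, 101))
                  for _ in range(100)]
        p = mean_profile(traces)
        assert np.max(np.abs(p.mean_intensity - template)) < noise_sd / 10 * 4

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            mean_profile([])


class TestQuarticFit:
    def test_exact_quartic_recovered(self):
        c_true = np.array([0.2, -1.0, 3.0, -2.0, 0.5])
        d = np.linspace(0, 1, 101)
        y = np.polynomial.polynomial.polyval(d, c_true)
        prof = fit_quartic(DepthProfile(d, y))
        assert np.allclose(prof.coeffs, c_true, atol=1e-9)
        assert prof.rss < 1e-18

    def test_matches_normal_equations_oracle(self, clean_ribbon):
        """OLS fit agrees with a direct normal-equations solve."""
        b = clean_ribbon.truth["boundaries"]
        traces = [sample_trace(clean_ribbon, t) for t in build_traces(b)]
        prof = fit_quartic(mean_profile(traces))
        V = np.polynomial.polynomial.polyvander(prof.depths, 4)
        oracle = np.linalg.solve(V.T @ V, V.T @ prof.mean_intensity)
        assert np.allclose(prof.coeffs, oracle, atol=1e-9)

    def test_constant_profile(self):
        prof = fit_quartic(DepthProfile(np.linspace(0, 1, 51), np.full(51, 5.0)))
        assert np.allclose(prof.coeffs, [5, 0, 0, 0, 0], atol=1e-9)

    def test_noisy_quartic_coefficients_unbiased(self):
        """Coefficient estimates stay within 3 SEs of truth across seeds."""
        c_true = np.array([0.2, -1.0, 3.0, -2.0, 0.5])
        d = np.linspace(0, 1, 101)
        V = np.polynomial.polynomial.polyvander(d, 4)
        cov = 0.01 ** 2 * np.linalg.inv(V.T @ V)
        se = np.sqrt(np.diag(cov))
        ests = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = V @ c_true + rng.normal(0, 0.01, len(d))
            ests.append(fit_quartic(DepthProfile(d, y)).coeffs)
        mean_err = np.mean(ests, axis=0) - c_true
        assert np.all(np.abs(mean_err) < 3 * se / np.sqrt(50))

    def test_too_few_points_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_quartic(DepthProfile(np.linspace(0, 1, 4), np.zeros(4)))


class TestInflections:
    def test_constructed_roots(self):
        # p''(x) proportional to (x - 0.35)(x - 0.68)
        d1, d2 = inflections([0.0, 0.0, 0.238 / 2, -1.03 / 6, 1.0 / 12])
        assert (d1, d2) == (pytest.approx(0.35), pytest.approx(0.68))

    def test_single_interior_root_rejected(self):
        # x^4 - x^2: inflections at +/- 1/sqrt(6), only one inside (0,1)
        with pytest.raises(NoAdmissibleSplitError) as exc:
            inflections([0.0, 0.0, -1.0, 0.0, 1.0])
        assert exc.value.roots is not None
        assert np.allclose(np.sort(np.abs(exc.value.roots)), 1 / np.sqrt(6))

    def test_degenerate_c4_rejected(self):
        with pytest.raises(NoAdmissibleSplitError):
            inflections([1.0, 1.0, 1.0, 1.0, 1e-13])


class TestThickness:
    def test_parallel_contours_arithmetic(self, parallel_boundaries):
        assert total_ct(parallel_boundaries) == pytest.approx(13 * 0.1875)

    def test_thirds_split(self):
        lam = laminar_split(3.0, 1 / 3, 2 / 3)
        assert (lam.superficial_mm, lam.middle_mm, lam.deep_mm) == (
            pytest.approx(1.0), pytest.approx(1.0), pytest.approx(1.0))

    def test_published_like_fraction_pattern(self):
        lam = laminar_split(2.4, 0.38, 0.68)
        assert np.allclose((lam.superficial_mm, lam.middle_mm, lam.deep_mm),
                           (0.912, 0.720, 0.768))
        assert np.allclose(lam.fractions, (0.38, 0.30, 0.32))

    @pytest.mark.parametrize("d1,d2", [(0.5, 0.5), (0.7, 0.3), (0.0, 0.5),
                                       (0.5, 1.0)])
    def test_degenerate_depths_rejected(self, d1, d2):
        with pytest.raises(ValueError):
            laminar_split(2.0, d1, d2)

    @given(total=st.floats(0.5, 5.0),
           d1=st.floats(0.05, 0.45), gap=st.floats(0.05, 0.45))
    def test_partition_identity(self, total, d1, gap):
        lam = laminar_split(total, d1, d1 + gap)
        assert lam.superficial_mm + lam.middle_mm + lam.deep_mm == lam.total_mm
        assert min(lam.superficial_mm, lam.middle_mm, lam.deep_mm) >= 0


class TestSubjectPipeline:
    def test_single_slice_identity_and_pooling_invariance(self, clean_ribbon):
        b = clean_ribbon.truth["boundaries"]
        one, _ = subject_laminar_ct([(clean_ribbon, b)])
        four, _ = subject_laminar_ct([(clean_ribbon, b)] * 4)
        for attr in ("total_mm", "superficial_mm", "middle_mm", "deep_mm"):
            assert getattr(four, attr) == pytest.approx(getattr(one, attr),
                                                        rel=1e-12)

    def test_multi_slice_jittered_thickness(self):
        slices, truths = [], []
        for i, t in enumerate((2.30, 2.36, 2.44, 2.50, 2.58)):
            img = generate_ribbon(RibbonSpec(thickness_mm=t, seed=i))
            slices.append((img, img.truth["boundaries"]))
            truths.append(t)
        lam, _ = subject_laminar_ct(slices)
        assert lam.total_mm == pytest.approx(np.mean(truths), rel=0.02)

    def test_roi_mask_restricts_and_empty_mask_errors(self, clean_ribbon):
        b = clean_ribbon.truth["boundaries"]
        lam_all, _ = subject_laminar_ct([(clean_ribbon, b)])
        lam_roi, _ = subject_laminar_ct([(clean_ribbon, b)],
                                        roi_mask=(10, -1e9, 50, 1e9))
        assert lam_roi.total_mm == pytest.approx(lam_all.total_mm, rel=0.01)
        with pytest.raises(GeometryError):
            subject_laminar_ct([(clean_ribbon, b)],
                               roi_mask=(-10, -10, -5, -5))

    def test_orientation_invariance(self, clean_ribbon):
        """Swapping which contour is traced first leaves results unchanged:
        deep-to-superficial traces are depth-reversed before pooling."""
        b = clean_ribbon.truth["boundaries"]
        traces = build_traces(b)
        fwd = [sample_trace(clean_ribbon, t) for t in traces]
        rev = []
        for t in traces:
            r = Trace(t.end.copy(), t.start.copy(),
                      "deep2sup" if t.direction == "sup2deep" else "sup2deep",
                      t.length_px)
            rev.append(sample_trace(clean_ribbon, r))
        p1, p2 = mean_profile(fwd), mean_profile(rev)
        assert np.allclose(p1.mean_intensity, p2.mean_intensity, atol=1e-9)

    def test_scale_equivariance(self, clean_ribbon):
        """Scaling pixel_mm by k scales thicknesses by k, fractions unchanged."""
        b = clean_ribbon.truth["boundaries"]
        lam1, _ = subject_laminar_ct([(clean_ribbon, b)])
        b2 = BoundaryPair(b.superficial, b.deep, pixel_mm=b.pixel_mm * 2.0)
        lam2, _ = subject_laminar_ct([(clean_ribbon, b2)])
        assert lam2.total_mm == pytest.approx(2.0 * lam1.total_mm)
        assert np.allclose(lam2.fractions, lam1.fractions)

    def test_intensity_affine_invariance(self, clean_ribbon):
        """a*I + b changes the fitted quartic equivariantly, leaving the
        inflection depths untouched."""
        b = clean_ribbon.truth["boundaries"]
        _, prof1 = subject_laminar_ct([(clean_ribbon, b)])

        class _Img:
            pass
        img2 = _Img()
        img2.raster = 3.5 * clean_ribbon.raster - 40.0
        _, prof2 = subject_laminar_ct([(img2, b)])
        assert np.allclose(prof1.inflection_depths, prof2.inflection_depths,
                           atol=1e-8)
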