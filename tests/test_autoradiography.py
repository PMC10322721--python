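"""Densitometry: standard conversion, calibration curve, linearization,
laminar profiles and CoV quality control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexgrad import autoradiography as ar
from cortexgrad.exceptions import DataError, ParameterError

PARAMS = ar.LigandParams(E=0.5, B=10.0, S_a=5.0, K_D=1.0, L=1.0)


class TestStandardConcentration:
    def test_zero_radioactivity_gives_zero(self):
        assert ar.standard_concentration(0.0, 2.0, PARAMS) == 0.0

    def test_hand_computed_value(self):
        # 100 / (0.5 * 10 * 2 * 5) * (1 + 1) / 1 = 4
        assert ar.standard_concentration(100.0, 2.0, PARAMS) == pytest.approx(4.0)

    def test_saturation_limit(self):
        p = ar.LigandParams(E=0.5, B=10.0, S_a=5.0, K_D=1e-9, L=100.0)
        cb = ar.standard_concentration(100.0, 2.0, p)
        assert cb == pytest.approx(100.0 / (0.5 * 10 * 2 * 5), rel=1e-8)

    @settings(deadline=None, max_examples=50)
    @given(R=st.floats(0.1, 1e5), c=st.floats(0.1, 100.0))
    def test_homogeneity_in_R_and_inverse_in_denominator_terms(self, R, c):
        base = ar.standard_concentration(R, 2.0, PARAMS)
        assert ar.standard_concentration(c * R, 2.0, PARAMS) == pytest.approx(c * base, rel=1e-12)
        assert ar.standard_concentration(R, c * 2.0, PARAMS) == pytest.approx(base / c, rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            ar.LigandParams(E=0.5, B=10.0, S_a=5.0, K_D=1.0, L=0.0)
        with pytest.raises(ParameterError):
            ar.LigandParams(E=1.5, B=10.0, S_a=5.0, K_D=1.0, L=1.0)


def _linear_standards(n=6):
    grays = np.linspace(20, 220, n)
    # choose R so C_b is linear in gray: C_b = gray * k
    k = 0.1
    factor = PARAMS.E * PARAMS.B * 2.0 * PARAMS.S_a * PARAMS.L / (PARAMS.K_D + PARAMS.L)
    return [ar.Standard(R=g * k * factor, W_b=2.0, gray=g) for g in grays]


class TestCalibrationCurve:
    def test_interpolates_standards_exactly(self):
        stds = _linear_standards()
        curve = ar.fit_calibration_curve(stds, PARAMS)
        for s in stds:
            expect = ar.standard_concentration(s.R, s.W_b, PARAMS)
            assert curve(s.gray) == pytest.approx(expect, abs=1e-12)

    def test_linear_standards_reproduce_line_at_midpoints(self):
        stds = _linear_standards()
        curve = ar.fit_calibration_curve(stds, PARAMS)
        mids = np.linspace(25, 215, 40)
        assert np.allclose(curve(mids), mids * 0.1, atol=1e-9)

    def test_concave_curve_monotone_and_bounded_between_knots(self):
        grays = np.array([10, 60, 110, 160, 210, 250], dtype=float)
        cbs = np.sqrt(grays)  # concave, increasing
        factor = PARAMS.E * PARAMS.B * 2.0 * PARAMS.S_a * PARAMS.L / (PARAMS.K_D + PARAMS.L)
        stds = [ar.Standard(R=c * factor, W_b=2.0, gray=g) for g, c in zip(grays, cbs)]
        curve = ar.fit_calibration_curve(stds, PARAMS)
        dense = np.linspace(10, 250, 100_000)
        vals = curve(dense)
        assert (np.diff(vals) >= -1e-9).all()  # monotone everywhere
        for lo, hi, clo, chi in zip(grays[:-1], grays[1:], cbs[:-1], cbs[1:]):
            seg = vals[(dense >= lo) & (dense <= hi)]
            assert (seg >= clo - 1e-9).all() and (seg <= chi + 1e-9).all()

    def test_out_of_range_clamps_with_warning(self):
        curve = ar.fit_calibration_curve(_linear_standards(), PARAMS)
        with pytest.warns(UserWarning, match="clamped"):
            v = curve(np.array([0.0, 255.0]))
        assert v[0] == pytest.approx(curve(20.0))
        assert v[1] == pytest.approx(curve(220.0))

    def test_non_monotone_standards_rejected_naming_pair(self):
        stds = _linear_standards()
        bad = stds[:2] + [ar.Standard(R=stds[0].R, W_b=2.0, gray=150.0)] + stds[3:]
        with pytest.raises(DataError, match="not jointly monotone"):
            ar.fit_calibration_curve(bad, PARAMS)

    def test_duplicate_gray_rejected(self):
        stds = _linear_standards()
        dup = stds + [ar.Standard(R=stds[-1].R * 1.1, W_b=2.0, gray=stds[-1].gray)]
        with pytest.raises(DataError, match="duplicate gray"):
            ar.fit_calibration_curve(dup, PARAMS)

    def test_too_few_standards_rejected(self):
        with pytest.raises(DataError, match="at least 4"):
            ar.fit_calibration_curve(_linear_standards()[:3], PARAMS)


class TestLinearizeImage:
    def test_constant_image_at_knot(self):
        stds = _linear_standards()
        curve = ar.fit_calibration_curve(stds, PARAMS)
        img = np.full((5, 7), stds[2].gray)
        out = ar.linearize_image(img, curve)
        expect = ar.standard_concentration(stds[2].R, stds[2].W_b, PARAMS)
        assert out.shape == (5, 7)
        assert np.allclose(out, expect)

    def test_pixel_ordering_preserved(self, rng):
        curve = ar.fit_calibration_curve(_linear_standards(), PARAMS)
        img = rng.uniform(20, 220, (16, 16))
        out = ar.linearize_image(img, curve)
        flat_in, flat_out = img.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert (np.diff(flat_out[order]) >= -1e-12).all()

    def test_roundtrip_through_inverted_curve(self, rng):
        """A gray image built by inverting the curve on a known
        concentration field linearizes back to that field."""
        grays = np.array([10, 60, 110, 160, 210, 250], dtype=float)
        cbs = np.sqrt(grays)
        factor = PARAMS.E * PARAMS.B * 2.0 * PARAMS.S_a * PARAMS.L / (PARAMS.K_D + PARAMS.L)
        stds = [ar.Standard(R=c * factor, W_b=2.0, gray=g) for g, c in zip(grays, cbs)]
        curve = ar.fit_calibration_curve(stds, PARAMS)
        field = rng.uniform(cbs[0] + 0.1, cbs[-1] - 0.1, (20, 20))
        dense = np.linspace(10, 250, 200_001)
        gray_img = np.interp(field, curve(dense), dense)
        recovered = ar.linearize_image(gray_img, curve)
        assert np.allclose(recovered, field, atol=1e-6)


class TestLaminarProfile:
    def test_uniform_image_gives_flat_profile(self):
        img = np.full((40, 12), 7.0)
        prof = ar.laminar_profile(img, 0, 40, slice(None), n_bins=10)
        assert np.allclose(prof.density, 7.0)
        assert prof.depth_percent[0] == pytest.approx(5.0)
        assert prof.depth_percent[-1] == pytest.approx(95.0)

    def test_piecewise_constant_halves(self):
        img = np.vstack([np.full((10, 6), 10.0), np.full((10, 6), 2.0)])
        prof = ar.laminar_profile(img, 0, 20, slice(None), n_bins=10)
        assert np.allclose(prof.density[:5], 10.0)
        assert np.allclose(prof.density[5:], 2.0)

    def test_matches_bruteforce_band_means(self, rng):
        img = rng.uniform(0, 50, (30, 9))
        prof = ar.laminar_profile(img, 2, 28, slice(1, 8), n_bins=13)
        rows = img[2:28, 1:8].mean(axis=1)
        expect = [chunk.mean() for chunk in np.array_split(rows, 13)]
        assert np.allclose(prof.density, expect)

    def test_bad_geometry_rejected(self):
        img = np.ones((10, 4))
        with pytest.raises(ParameterError):
            ar.laminar_profile(img, 8, 3, slice(None), 10)
        with pytest.raises(ParameterError):
            ar.laminar_profile(img, 0, 10, slice(2, 2), 10)


def _profile(value, n_bins=10):
    return ar.LaminarProfile(depth_percent=(np.arange(n_bins) + 0.5) * 10,
                             density=np.full(n_bins, float(value)), n_columns=5)


class TestAreaMeanDensity:
    def test_identical_sections_have_zero_cov(self):
        mean, cov = ar.area_mean_density([_profile(10)] * 3)
        assert mean == 10.0
        assert cov == 0.0

    def test_hand_computed_mean_and_cov(self):
        mean, cov = ar.area_mean_density([_profile(8), _profile(10), _profile(12)])
        assert mean == pytest.approx(10.0)
        assert cov == pytest.approx(np.std([8, 10, 12], ddof=1) / 10.0)

    def test_single_section_warns_and_reports_missing_cov(self):
        with pytest.warns(UserWarning, match="sections"):
            mean, cov = ar.area_mean_density([_profile(5)])
        assert mean == 5.0
        assert np.isnan(cov)

    def test_zero_mean_is_error(self):
        with pytest.raises(DataError, match="CoV undefined"):
            ar.area_mean_density([_profile(0)] * 3)


class TestCohortCov:
    def test_zero_noise_cohort_has_zero_median_cov(self, rng):
        base = pd.DataFrame(rng.uniform(1, 10, (6, 4)))
        med, skipped = ar.cohort_cov_summary([base.copy() for _ in range(3)])
        assert med == 0.0
        assert skipped == 0

    def test_planted_multiplicative_noise_recovers_cov(self):
        """CoV of multiplicative noise with SD 0.1 is ~0.1 (50-seed MC)."""
        meds = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            base = pd.DataFrame(r.uniform(5, 50, (8, 5)))
            reps = [base * (1 + 0.1 * r.standard_normal(base.shape)) for _ in range(5)]
            meds.append(ar.cohort_cov_summary(reps)[0])
        assert np.mean(meds) == pytest.approx(0.1, abs=0.015)

    def test_scale_invariance(self, rng):
        reps = [pd.DataFrame(rng.uniform(1, 10, (5, 3))) for _ in range(4)]
        med1, _ = ar.cohort_cov_summary(reps)
        med2, _ = ar.cohort_cov_summary([7.3 * r for r in reps])
        assert med1 == pytest.approx(med2, rel=1e-12)

    def test_single_replicate_is_error(self, rng):
        with pytest.raises(DataError):
            ar.cohort_cov_summary([pd.DataFrame(rng.uniform(1, 10, (5, 3)))])

    def test_missing_cells_skipped_and_counted(self, rng):
        reps = [pd.DataFrame(rng.uniform(1, 10, (4, 3))) for _ in range(3)]
        for r in reps:
            r.iloc[0, 0] = np.nan
        med, skipped = ar.cohort_cov_summary(reps)
        assert skipped == 1
        assert np.isfinite(med)
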