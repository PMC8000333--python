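import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromaqc.io import Chromatogram
from chromaqc.peaks import (
    FittedPeakSet,
    GaussianPeak,
    auto_add_peaks,
    doe_responses,
    fit_peaks,
    gaussian_area,
    gaussian_profile,
    match_peaks,
)

SQRT_PI_LN2 = np.sqrt(np.pi / np.log(2.0))


class TestGaussianArea:
    def test_unit_peak_closed_form(self):
        assert gaussian_area(GaussianPeak(1.0, 0.0, 1.0)) == pytest.approx(
            SQRT_PI_LN2, abs=1e-12
        )

    def test_matches_quadrature(self, rng):
        for _ in range(5):
            h, c, w = rng.uniform(0.1, 5), rng.uniform(0, 30), rng.uniform(0.01, 0.5)
            t = np.linspace(c - 10 * w, c + 10 * w, 10_000)
            quad = np.trapezoid(gaussian_profile(t, h, c, w), t)
            assert abs(gaussian_area(GaussianPeak(h, c, w)) - quad) / quad < 1e-6

    @given(h=st.floats(0.1, 10), w=st.floats(0.01, 1.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_linearity_in_height_and_width(self, h, w):
        a = gaussian_area(GaussianPeak(h, 5.0, w))
        assert gaussian_area(GaussianPeak(2 * h, 5.0, w)) == pytest.approx(2 * a)
        assert gaussian_area(GaussianPeak(h, 5.0, 2 * w)) == pytest.approx(2 * a)

    def test_invalid_peak_rejected(self):
        with pytest.raises(ValueError):
            GaussianPeak(0.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            GaussianPeak(1.0, 1.0, -0.1)


def _trace(peaks, t, noise=0.0, rng=None):
    y = np.zeros_like(t)
    for h, c, w in peaks:
        y += gaussian_profile(t, h, c, w)
    if noise and rng is not None:
        y = y + noise * rng.standard_normal(t.size)
    return Chromatogram("x", t, y)


class TestFitPeaks:
    def test_noiseless_recovery_from_perturbed_start(self):
        t = np.arange(9.0, 11.0, 0.002)
        chrom = _trace([(1.0, 10.0, 0.1)], t)
        init = FittedPeakSet([GaussianPeak(1.1, 10.01, 0.11)])
        fit = fit_peaks(chrom, init)
        p = fit.peaks[0]
        assert abs(p.height - 1.0) < 1e-6
        assert abs(p.center - 10.0) < 1e-6
        assert abs(p.hwhm - 0.1) < 1e-6
        assert fit.converged

    def test_optimum_is_fixed_point(self):
        t = np.arange(9.0, 11.0, 0.002)
        chrom = _trace([(1.0, 10.0, 0.1)], t)
        fit = fit_peaks(chrom, FittedPeakSet([GaussianPeak(1.0, 10.0, 0.1)]))
        assert fit.sum_squared_residuals <= 1e-20
        assert fit.converged

    def test_ssr_never_increases(self, rng):
        t = np.arange(0.0, 5.0, 0.005)
        chrom = _trace([(1.0, 2.0, 0.1), (0.5, 3.0, 0.08)], t, 0.02, rng)
        init = FittedPeakSet([GaussianPeak(0.8, 2.05, 0.12), GaussianPeak(0.6, 2.95, 0.07)])
        ssr0 = float(np.sum((chrom.intensity - init.model(t)) ** 2))
        fit = fit_peaks(chrom, init)
        assert fit.sum_squared_residuals <= ssr0

    def test_close_doublet_areas_within_3pct(self, rng):
        t = np.arange(9.0, 11.0, 0.002)
        truth = [(1.0, 9.9, 0.08), (0.7, 10.1, 0.08)]
        chrom = _trace(truth, t, 0.01, rng)
        init = FittedPeakSet([GaussianPeak(0.9, 9.88, 0.07), GaussianPeak(0.75, 10.12, 0.09)])
        fit = fit_peaks(chrom, init)
        for p, (h, c, w) in zip(fit.peaks, truth):
            true_area = gaussian_area(GaussianPeak(h, c, w))
            assert abs(gaussian_area(p) - true_area) / true_area < 0.03

    def test_too_few_points_rejected(self):
        t = np.linspace(0, 1, 5)
        chrom = Chromatogram("x", t, np.zeros(5))
        with pytest.raises(ValueError):
            fit_peaks(chrom, FittedPeakSet([GaussianPeak(1, 0.5, 0.1), GaussianPeak(1, 0.6, 0.1)]))


class TestAutoAdd:
    def test_quiet_residual_returns_input(self):
        t = np.arange(0.0, 5.0, 0.01)
        chrom = Chromatogram("x", t, np.full_like(t, 1e-5))
        out = auto_add_peaks(chrom, max_peaks=10, min_height=1e-3)
        assert len(out) == 0

    def test_max_peaks_cap(self):
        t = np.arange(0.0, 22.0, 0.005)
        truth = [(1.0, 2.0 * k + 1.0, 0.08) for k in range(10)]
        chrom = _trace(truth, t)
        out = auto_add_peaks(chrom, max_peaks=5, min_height=1e-3)
        assert len(out) == 5

    def test_all_resolvable_peaks_found(self):
        t = np.arange(0.0, 11.0, 0.005)
        truth = [(0.5 + 0.1 * k, 2.0 + 2.0 * k, 0.06) for k in range(5)]
        chrom = _trace(truth, t)
        out = auto_add_peaks(chrom, max_peaks=10, min_height=1e-2)
        assert len(out) == 5
        np.testing.assert_allclose(
            [p.center for p in out.peaks], [c for _, c, _ in truth], atol=1e-4
        )


class TestMatchPeaks:
    def _set(self, centers, heights=None):
        heights = heights or [1.0] * len(centers)
        return FittedPeakSet([GaussianPeak(h, c, 0.08) for h, c in zip(heights, centers)])

    def test_identical_sets_identical_rows(self):
        s = self._set([5.0, 10.0, 15.0])
        table = match_peaks([s, s], 0.15, ["a", "b"])
        np.testing.assert_array_equal(table.areas[0], table.areas[1])
        assert table.peak_names == ["peak_5.00", "peak_10.00", "peak_15.00"]

    def test_small_shift_within_tolerance(self):
        ref = self._set([5.0, 10.0, 15.0])
        shifted = self._set([5.05, 10.05, 15.05])
        table = match_peaks([ref, shifted], 0.15, ["ref", "s"])
        assert np.all(table.areas[1] > 0)

    def test_large_shift_unmatched_with_warning(self):
        ref = self._set([5.0, 10.0])
        shifted = self._set([5.0, 10.30])
        with pytest.warns(UserWarning, match="unmatched"):
            table = match_peaks([ref, shifted], 0.15, ["ref", "s"])
        assert table.areas[1, 0] > 0
        assert table.areas[1, 1] == 0.0

    def test_two_candidates_nearest_wins(self):
        ref = self._set([10.0])
        other = self._set([9.95, 10.10], heights=[2.0, 3.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = match_peaks([ref, other], 0.15, ["ref", "o"])
        # 9.95 is nearer to 10.0 than 10.10
        assert table.areas[1, 0] == pytest.approx(gaussian_area(GaussianPeak(2.0, 9.95, 0.08)))


class TestDoeResponses:
    def test_hand_computed_resolution(self):
        pset = FittedPeakSet([GaussianPeak(1, 10.0, 0.25), GaussianPeak(1, 11.0, 0.25)])
        rs, _ = doe_responses(pset)
        assert rs == pytest.approx(1.18 * 1.0 / (0.5 + 0.5))

    def test_near_coincident_centers_near_zero(self):
        pset = FittedPeakSet([GaussianPeak(1, 10.0, 0.25), GaussianPeak(1, 10.0 + 1e-12, 0.25)])
        rs, _ = doe_responses(pset)
        assert rs == pytest.approx(0.0, abs=1e-9)

    def test_three_peaks_sum_over_adjacent_pairs(self):
        pset = FittedPeakSet(
            [GaussianPeak(1, 10.0, 0.25), GaussianPeak(1, 11.0, 0.25), GaussianPeak(1, 12.0, 0.25)]
        )
        rs, area = doe_responses(pset)
        assert rs == pytest.approx(2 * 1.18)
        assert area == pytest.approx(3 * gaussian_area(GaussianPeak(1, 0, 0.25)))

    def test_single_peak_zero_resolution(self):
        rs, area = doe_responses(FittedPeakSet([GaussianPeak(1, 10.0, 0.25)]))
        assert rs == 0.0 and area > 0
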