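"""Numerical checks of the nine peak-quality features against hand-computed
and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peakvote import IsotopeTrace, PeakFeatures, PrecursorPeakGroup, extract_features
from peakvote._domain import FEATURE_NAMES
from peakvote.features import (
    boundary_intensity,
    coelution,
    compute_fwhm,
    jagging_score,
    shape_similarity,
    snr,
)
from conftest import gaussian_trace

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = 2*sqrt(2 ln2) * sigma


class TestFwhm:
    def test_hand_interpolated_triangle(self):
        tr = IsotopeTrace(0, [0, 1, 2, 3, 4], [0, 50, 100, 50, 0], 0, 4)
        fwhm, left, right = compute_fwhm(tr)
        assert (fwhm, left, right) == (2.0, 1.0, 3.0)

    def test_sampled_gaussian_matches_closed_form(self):
        sigma = 2.0
        tr = gaussian_trace(sigma=sigma, dt=0.02, boundary_sigmas=4.0)
        fwhm, _, _ = compute_fwhm(tr)
        assert fwhm == pytest.approx(GAUSS_FWHM * sigma, abs=0.01)

    def test_error_halves_with_sampling_density(self):
        sigma = 0.1
        errs = []
        for dt in (0.02, 0.005):
            fwhm, _, _ = compute_fwhm(gaussian_trace(sigma=sigma, dt=dt))
            errs.append(abs(fwhm - GAUSS_FWHM * sigma))
        assert errs[1] <= errs[0] / 2 + 1e-12

    def test_crossing_clamped_to_boundary(self):
        # trace never falls to half-max on the right inside the window
        tr = IsotopeTrace(0, [0, 1, 2], [0, 60, 100], 0, 2)
        fwhm, left, right = compute_fwhm(tr)
        assert right == 2.0 and left == pytest.approx(50 / 60)

    def test_degenerate_traces_missing(self):
        assert compute_fwhm(IsotopeTrace(0, [0, 1, 2], [0, 0, 0], 0, 2)) is None
        assert compute_fwhm(IsotopeTrace(0, [0, 1, 2], [1, 5, 9], 1.9, 2.0)) is None


class TestJagging:
    @pytest.mark.parametrize(
        "intensities, expected",
        [
            ([0, 100, 40, 100, 0], 1),  # dip below half inside the crossings
            ([0, 50, 100, 50, 0], 0),  # no point strictly below half in-window
        ],
    )
    def test_hand_counts(self, intensities, expected):
        tr = IsotopeTrace(0, np.arange(len(intensities)), intensities, 0, len(intensities) - 1)
        assert jagging_score(tr) == expected

    def test_fine_sampled_gaussian_is_zero(self):
        assert jagging_score(gaussian_trace(dt=0.005)) == 0

    def test_missing_when_fwhm_missing(self):
        assert jagging_score(IsotopeTrace(0, [0, 1], [0, 0], 0, 1)) is None

    @given(
        n_left=st.integers(2, 10),
        n_right=st.integers(2, 10),
        apex=st.floats(10.0, 1e6),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_unimodal_traces_score_zero(self, n_left, n_right, apex, data):
        """Any strictly unimodal in-window trace has jagging 0."""
        up = sorted(
            data.draw(
                st.lists(st.floats(0.0, 0.999), min_size=n_left, max_size=n_left, unique=True)
            )
        )
        down = sorted(
            data.draw(
                st.lists(st.floats(0.0, 0.999), min_size=n_right, max_size=n_right, unique=True)
            ),
            reverse=True,
        )
        y = np.array(up + [1.0] + down) * apex
        t = np.arange(y.size, dtype=float)
        assert jagging_score(IsotopeTrace(0, t, y, 0, t[-1])) == 0


class TestShapeSimilarity:
    def test_identical_traces(self):
        trs = [gaussian_trace(isotope_index=i, scale=s) for i, s in enumerate((1, 0.5, 0.1))]
        assert shape_similarity(trs) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = IsotopeTrace(0, [0, 1, 2], [1, 2, 3], 0, 2)
        b = IsotopeTrace(1, [0, 1, 2], [3, 2, 1], 0, 2)
        assert shape_similarity([a, b]) == pytest.approx(-1.0)

    def test_constant_trace_pair_scores_zero(self):
        a = IsotopeTrace(0, [0, 1, 2], [1, 2, 3], 0, 2)
        c = IsotopeTrace(1, [0, 1, 2], [5, 5, 5], 0, 2)
        assert shape_similarity([a, c]) == 0.0

    def test_single_trace_missing(self):
        assert shape_similarity([gaussian_trace()]) is None

    def test_mismatched_grids_interpolated(self):
        a = gaussian_trace(isotope_index=0, dt=0.02)
        b = gaussian_trace(isotope_index=1, dt=0.03, scale=0.4)
        assert shape_similarity([a, b]) == pytest.approx(1.0, abs=1e-3)


class TestCoelution:
    def test_identical_triple(self):
        trs = [gaussian_trace(isotope_index=i, scale=s) for i, s in enumerate((1, 0.5, 0.1))]
        score, count = coelution(trs)
        assert score == 0.0 and count == 3

    def test_three_sample_shift_on_005_grid(self):
        dt = 0.05
        m0 = gaussian_trace(0, sigma=0.15, dt=dt, boundary_sigmas=3)
        m1 = gaussian_trace(1, sigma=0.15, dt=dt, boundary_sigmas=3, center=10.0 + 3 * dt)
        m1 = IsotopeTrace(1, m0.times, np.interp(m0.times, m1.times, m1.intensities),
                          m0.boundary_start, m0.boundary_end)
        m2 = gaussian_trace(2, sigma=0.15, dt=dt, boundary_sigmas=3)
        score, count = coelution([m0, m1, m2])
        # pairs (M,M+1) and (M+1,M+2) shifted 3 samples, (M,M+2) aligned
        assert score == pytest.approx((0.15 + 0.15 + 0.0) / 3, abs=1e-9)
        assert count == 1

    @pytest.mark.parametrize("shift", [1, 2, 3, 4, 5])
    def test_injected_integer_lag_recovered_exactly(self, shift):
        dt = 0.05
        a = gaussian_trace(0, sigma=0.2, dt=dt, boundary_sigmas=3)
        shifted = gaussian_trace(1, sigma=0.2, dt=dt, boundary_sigmas=3,
                                 center=10.0 + shift * dt)
        b = IsotopeTrace(1, a.times, np.interp(a.times, shifted.times, shifted.intensities),
                         a.boundary_start, a.boundary_end)
        score, count = coelution([a, b])
        assert score == pytest.approx(shift * dt, abs=1e-9)
        assert count == 0

    def test_single_trace_missing(self):
        assert coelution([gaussian_trace()]) == (None, None)


class TestSnr:
    def test_apex_over_outside_median(self):
        t = np.arange(21.0)
        y = np.full(21, 10.0)
        y[10] = 1000.0
        assert snr(IsotopeTrace(0, t, y, 8, 12)) == pytest.approx(100.0)

    def test_all_zero_missing(self):
        assert snr(IsotopeTrace(0, [0, 1, 2], [0, 0, 0], 0, 2)) is None

    def test_fallback_min_positive_inside(self):
        # no outside points; floor falls back to min positive = apex
        t = np.array([0.0, 1.0])
        assert snr(IsotopeTrace(0, t, [0.0, 500.0], 0, 1)) == pytest.approx(1.0)


class TestBoundaryIntensity:
    def test_gaussian_at_three_sigma(self):
        tr = gaussian_trace(boundary_sigmas=3.0, dt=0.001)
        assert boundary_intensity([tr]) == pytest.approx(np.exp(-4.5), rel=1e-2)

    def test_boundaries_collapsed_on_apex(self):
        t = np.arange(-4, 4.01, 0.02) + 10
        y = 1e4 * np.exp(-0.5 * (t - 10) ** 2)
        tr = IsotopeTrace(0, t, y, 10, 10)
        assert boundary_intensity([tr]) == pytest.approx(1.0)

    def test_all_zero_missing(self):
        assert boundary_intensity([IsotopeTrace(0, [0, 1, 2], [0, 0, 0], 0, 2)]) is None


class TestExtractFeatures:
    def test_missing_report_values_become_zero(self):
        group = PrecursorPeakGroup("PEPK", 2, traces=[gaussian_trace()])
        feats = extract_features(group)
        assert feats.idotp == 0.0 and feats.avg_mass_error_ppm == 0.0

    def test_identical_aligned_triple(self):
        trs = [gaussian_trace(isotope_index=i, scale=s) for i, s in enumerate((1, 0.5, 0.25))]
        feats = extract_features(PrecursorPeakGroup("PEPK", 2, traces=trs, idotp=0.99))
        assert feats.fwhm_sd == pytest.approx(0.0, abs=1e-9)
        assert feats.shape_similarity == pytest.approx(1.0)
        assert feats.coelution_score == 0.0 and feats.coelution_count == 3

    def test_per_isotope_mass_errors_averaged(self):
        group = PrecursorPeakGroup(
            "PEPK", 2, traces=[gaussian_trace()],
            mass_error_ppm={0: 2.0, 1: -1.0, 2: 5.0},
        )
        assert extract_features(group).avg_mass_error_ppm == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "traces",
        [
            [IsotopeTrace(0, [0.0], [0.0], 0, 0)],  # single all-zero sample
            [IsotopeTrace(i, [0, 1, 2], [0, 0, 0], 0, 2) for i in range(3)],  # all-zero triple
            [IsotopeTrace(0, [0, 1], [5, 5], 0, 1)],  # constant
        ],
        ids=["single-point", "all-zero-triple", "constant"],
    )
    def test_total_contract_on_adversarial_groups(self, traces):
        feats = extract_features(PrecursorPeakGroup("PEPK", 2, traces=traces))
        assert np.all(np.isfinite(feats.to_array()))

    def test_invariance_to_uniform_intensity_rescaling(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 2.0, 0.05) + 9
        traces = []
        for i, frac in enumerate((0.6, 0.3, 0.1)):
            y = frac * 1e5 * np.exp(-0.5 * ((t - 10) / 0.2) ** 2)
            y *= 1 + 0.05 * rng.standard_normal(t.size)
            traces.append(IsotopeTrace(i, t, np.clip(y, 0, None), 9.5, 10.5))
        g1 = PrecursorPeakGroup("PEPK", 2, traces=traces, idotp=0.95, mass_error_ppm=1.0)
        scaled = [
            IsotopeTrace(tr.isotope_index, tr.times, tr.intensities * 137.0,
                         tr.boundary_start, tr.boundary_end)
            for tr in traces
        ]
        g2 = PrecursorPeakGroup("PEPK", 2, traces=scaled, idotp=0.95, mass_error_ppm=1.0)
        np.testing.assert_allclose(
            extract_features(g1).to_array(), extract_features(g2).to_array(), rtol=1e-9
        )

    def test_output_ranges(self, small_dataset):
        examples, _ = small_dataset
        for ex in examples:
            f = ex.features
            assert -1.0 <= f.shape_similarity <= 1.0
            assert f.coelution_count in (0.0, 1.0, 2.0, 3.0)
            assert np.all(np.isfinite(f.to_array()))

    def test_feature_order_is_documented_nine(self):
        feats = PeakFeatures.from_array(np.arange(9.0))
        assert feats.to_array().tolist() == list(range(9))
        assert len(FEATURE_NAMES) == 9
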