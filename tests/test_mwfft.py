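import numpy as np
import pytest

from ramansync.crosscorr import estimate_lag
from ramansync.mwfft import (
    ShiftMatrix,
    ShiftProfile,
    WindowConfig,
    build_shift_matrix,
    deflicker,
    find_change_points,
    merge_short_regions,
    mwfft_correct,
    profile_from_matrix,
    relocate_change_points,
    synchronize,
)
from ramansync.preprocess import smooth_savgol
from ramansync.spectra_io import Spectrum, SpectrumPair
from ramansync.synthgen import fixture, make_pair, piecewise_shift

from .conftest import peak_rich


def smoothed_pair(spec):
    pair, truth = make_pair(spec)
    return SpectrumPair(
        smooth_savgol(pair.primary), smooth_savgol(pair.secondary)
    ), truth


class TestWindowConfig:
    def test_default_lag_bound(self):
        assert WindowConfig().lag_bound == 70 // 3

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"window": 3},
            {"hop": 0},
            {"hop": 71},
            {"max_lag": 70},
            {"min_vote_corr": 1.0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WindowConfig(**kwargs)


class TestShiftMatrix:
    def test_identical_pair_votes_all_zero(self, axis2048):
        y = peak_rich(axis2048, seed=5)
        pair = SpectrumPair(Spectrum(axis2048, y), Spectrum(axis2048, y))
        m = build_shift_matrix(pair, WindowConfig(hop=4))
        voted = np.flatnonzero(m.counts.sum(axis=1))
        assert list(voted) == [m.max_lag]  # only the zero-lag row

    def test_global_shift_unanimous_columns(self, axis2048):
        y = peak_rich(axis2048, seed=6, n_peaks=20)
        qry = y[np.clip(np.arange(2048) - 5, 0, 2047)]
        pair = SpectrumPair(Spectrum(axis2048, y), Spectrum(axis2048, qry))
        m = build_shift_matrix(pair, WindowConfig())
        interior = slice(200, 1848)
        col_lags = m.counts[:, interior]
        nonzero_rows = np.flatnonzero(col_lags.sum(axis=1))
        assert list(nonzero_rows) == [5 + m.max_lag]

    def test_two_regime_unanimity_away_from_boundary(self):
        spec = fixture("two-regime", seed=11)
        pair, truth = smoothed_pair(spec)
        m = build_shift_matrix(pair, WindowConfig(min_vote_corr=0.7, hop=2))
        cp = truth.change_points[0]
        for col in (cp - 300, cp + 300):
            votes = m.column(col)
            if votes:
                assert max(votes, key=votes.get) == truth.shift[col]

    def test_too_short_spectrum_rejected(self):
        s = Spectrum(np.arange(10.0), np.sin(np.arange(10.0)))
        with pytest.raises(ValueError):
            build_shift_matrix(SpectrumPair(s, s), WindowConfig(window=70))


def matrix_from_columns(columns, max_lag, window=4):
    counts = np.zeros((2 * max_lag + 1, len(columns)), dtype=np.int32)
    for i, col in enumerate(columns):
        for lag, k in col.items():
            counts[lag + max_lag, i] = k
    return ShiftMatrix(counts, max_lag, window)


class TestProfileFromMatrix:
    def test_unanimous_mode(self):
        m = matrix_from_columns([{5: 3}] * 6, max_lag=10)
        p = profile_from_matrix(m, min_support=1)
        assert set(p.shift) == {5}

    def test_majority_mode(self):
        m = matrix_from_columns([{2: 2, 8: 1}] * 6, max_lag=10)
        assert set(profile_from_matrix(m, min_support=1).shift) == {2}

    def test_tie_prefers_left_neighbor_value(self):
        cols = [{7: 3}] * 3 + [{7: 2, 3: 2}] * 3
        p = profile_from_matrix(matrix_from_columns(cols, 10), min_support=1)
        assert set(p.shift) == {7}

    def test_tie_without_neighbor_prefers_smallest_abs(self):
        m = matrix_from_columns([{9: 2, -3: 2}] * 6, max_lag=10)
        assert set(profile_from_matrix(m, min_support=1).shift) == {-3}

    def test_unvoted_columns_inherit_nearest(self):
        cols = [{4: 5}] * 3 + [{}] * 4 + [{6: 5}] * 3
        p = profile_from_matrix(matrix_from_columns(cols, 10), min_support=1)
        np.testing.assert_array_equal(p.shift[:5], 4)
        np.testing.assert_array_equal(p.shift[-5:], 6)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            profile_from_matrix(matrix_from_columns([{}] * 5, 10), min_support=1)


class TestChangePoints:
    def test_constant_profile_has_none(self):
        assert find_change_points(ShiftProfile(np.full(50, 3))) == []

    def test_single_discontinuity(self):
        p = ShiftProfile(np.array([2, 2, 2, 8, 8]))
        assert find_change_points(p) == [3]

    def test_flicker_suppressed(self):
        p = ShiftProfile(np.array([2, 2, 8, 2, 2]))
        assert find_change_points(p) == []

    def test_deflicker_keeps_length(self):
        p = ShiftProfile(np.array([2, 2, 8, 2, 2, 9, 9, 9, 9, 9]))
        assert deflicker(p).n == 10

    def test_merge_short_regions(self):
        shift = piecewise_shift(300, [100, 120, 200], [2, 9, 2, 5])
        merged = merge_short_regions(ShiftProfile(shift), 50)
        assert merged.regions() == [(0, 200, 2), (200, 300, 5)]


class TestRelocate:
    def _valley_spectrum(self, n=400):
        # peak apex at 200, valleys at 190 and 210
        x = np.arange(float(n))
        y = np.exp(-0.5 * ((x - 200) / 4) ** 2) + 0.2 * np.sin(x / 3.2)
        return Spectrum(x, y)

    def test_change_point_on_apex_moves_to_valley(self):
        s = self._valley_spectrum()
        p = ShiftProfile(piecewise_shift(400, [200], [2, 8]))
        out = relocate_change_points(p, s, search=30)
        (new_cp,) = out.change_points
        assert new_cp != 200
        y = s.intensity
        assert y[new_cp] <= y[new_cp - 1] and y[new_cp] <= y[new_cp + 1]

    def test_change_point_at_valley_unchanged(self):
        s = self._valley_spectrum()
        y = s.intensity
        valleys = [
            i for i in range(150, 250)
            if y[i] <= y[i - 1] and y[i] <= y[i + 1] and (y[i] < y[i - 1] or y[i] < y[i + 1])
        ]
        cp = valleys[0]
        p = ShiftProfile(piecewise_shift(400, [cp], [2, 8]))
        assert relocate_change_points(p, s, search=30).change_points == [cp]

    def test_flat_spectrum_flagged(self):
        s = Spectrum(np.arange(400.0), np.zeros(400))
        p = ShiftProfile(piecewise_shift(400, [200], [2, 8]))
        out = relocate_change_points(p, s, search=30)
        assert out.change_points == [200]
        assert out.diagnostics["unrelocated_change_points"] == [200]


class TestSynchronize:
    def test_zero_profile_identity(self, axis2048):
        y = peak_rich(axis2048, seed=8)
        pair = SpectrumPair(Spectrum(axis2048, y), Spectrum(axis2048, y + 0.1))
        out = synchronize(pair, ShiftProfile(np.zeros(2048, dtype=int)))
        np.testing.assert_array_equal(out.intensity, y + 0.1)

    def test_global_shift_recovers_truth_except_edges(self, axis2048):
        y = peak_rich(axis2048, seed=9)
        warped = y[np.clip(np.arange(2048) - 5, 0, 2047)]
        pair = SpectrumPair(Spectrum(axis2048, y), Spectrum(axis2048, warped))
        out = synchronize(pair, ShiftProfile(np.full(2048, 5)))
        np.testing.assert_array_equal(out.intensity[:-5], y[:-5])

    def test_region_values_bit_identical(self):
        spec = fixture("two-regime", seed=12)
        pair, truth = make_pair(spec)
        out = synchronize(pair, truth)
        sec = pair.secondary.intensity
        for start, stop, v in truth.regions():
            a, b = max(start - v, 0) + 30, min(stop - v, 2048) - 30
            np.testing.assert_array_equal(out.intensity[a:b], sec[a + v : b + v])

    def test_excessive_shift_rejected(self):
        x = np.arange(200.0)
        s = Spectrum(x, np.sin(x / 5))
        pair = SpectrumPair(s, s)
        shift = piecewise_shift(200, [150], [0, 60])  # |60| >= region length 50
        with pytest.raises(ValueError, match="region"):
            synchronize(pair, ShiftProfile(shift))


class TestEndToEnd:
    def test_identical_pair_is_noop(self, axis2048):
        y = peak_rich(axis2048, seed=10)
        s = Spectrum(axis2048, y)
        corrected, profile, report = mwfft_correct(SpectrumPair(s, s))
        np.testing.assert_array_equal(corrected.intensity, y)
        assert profile.change_points == []
        assert report.r == pytest.approx(1.0) and report.R == pytest.approx(1.0)

    def test_two_regime_improves_similarity(self):
        pair, truth = smoothed_pair(fixture("two-regime", seed=13))
        corrected, profile, report = mwfft_correct(pair, WindowConfig(min_vote_corr=0.7))
        assert report.R > report.r
        assert report.d_mean_after < report.d_mean_before
        assert np.mean(profile.shift == truth.shift) >= 0.95

    def test_global_ninety_point_profile(self):
        pair, truth = smoothed_pair(fixture("global-90", seed=14))
        cfg = WindowConfig(window=512, hop=4, max_lag=128, min_vote_corr=0.7)
        _, profile, _ = mwfft_correct(pair, cfg)
        assert set(profile.shift) == {90}

    def test_reduces_to_global_estimate_when_window_spans_spectrum(self):
        pair, _ = make_pair(fixture("global-small", seed=15))
        n = pair.n
        cfg = WindowConfig(window=n, hop=n, max_lag=100, min_vote_corr=0.0)
        profile = profile_from_matrix(build_shift_matrix(pair, cfg))
        global_lag = estimate_lag(
            pair.primary.intensity, pair.secondary.intensity, 100
        )
        assert set(profile.shift) == {global_lag}
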