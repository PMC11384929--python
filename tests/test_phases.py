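"""Segmentation, normalization, rates, peaks, dose comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmpkit.kinetics import GompertzParams, gompertz_bmp
from bmpkit.phases import (
    GasSeries,
    find_peaks,
    normalize_per_vs,
    production_rate,
    relative_increase,
    relative_increase_matrix,
    segment,
)
from conftest import BMP_PHASE4_BY_DOSE, BMY_60D_BY_DOSE


def _linear_series(ml_per_day=24.0, days=4.0, dt=1 / 96, **kw):
    t = np.arange(1, int(days / dt) + 1) * dt
    kw.setdefault("feed_events", ((0.0, 1.0),))
    return GasSeries(times=t, cumulative_ml=ml_per_day * t, **kw)


class TestGasSeries:
    def test_decreasing_cumulative_rejected(self):
        with pytest.raises(ValueError, match="decreases"):
            GasSeries(times=[0, 1, 2], cumulative_ml=[0, 5, 4])

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            GasSeries(times=[0, 2, 1], cumulative_ml=[0, 1, 2])


class TestSegment:
    def test_reference_windows(self, clean_reactor):
        """Feeds at 0/8/21/44 with a 60-day horizon give the four standard
        windows, each re-zeroed at its feed."""
        _, s = clean_reactor
        segs = segment(s, horizon=60.0)
        assert len(segs) == 4
        starts = [p.times[0] for p in segs]
        assert starts == pytest.approx([1 / 96, 8.0, 21.0, 44.0], abs=1 / 96)
        for p in segs:
            assert p.cumulative_ml.min() >= 0.0

    def test_volume_conservation(self, small_experiment):
        """Per-phase finals sum to the whole-series final for every reactor."""
        _, series = small_experiment
        for s in series:
            segs = segment(s, horizon=60.0)
            assert sum(p.final_ml for p in segs) == pytest.approx(s.final_ml, rel=1e-9)

    def test_single_feed_single_window_closed_at_horizon(self):
        s = _linear_series(days=3.0)
        (only,) = segment(s, horizon=3.0)
        assert only.times[-1] == pytest.approx(3.0)
        # re-zeroed at the feed instant: negligible volume at the phase start
        assert only.cumulative_ml[0] == pytest.approx(0.0, abs=s.cumulative_ml[1])

    def test_feed_beyond_horizon_rejected(self):
        s = _linear_series(days=3.0, feed_events=((0.0, 1.0), (5.0, 1.0)))
        with pytest.raises(ValueError, match="horizon"):
            segment(s, horizon=3.0)

    def test_no_feeds_rejected(self):
        s = _linear_series(feed_events=())
        with pytest.raises(ValueError, match="feed"):
            segment(s, horizon=4.0)


class TestNormalize:
    def test_worked_glucose_numbers(self):
        # 982.6 mL final over 2.6 g VS -> 377.9 mL/g-VS
        t = np.linspace(0.01, 14, 50)
        phase = GasSeries(times=t, cumulative_ml=np.linspace(0, 982.6, 50))
        curve = normalize_per_vs(phase, vs_fed=2.6)
        assert curve.iloc[-1] == pytest.approx(377.9, abs=0.05)

    def test_identity_and_linearity(self):
        phase = _linear_series()
        one = normalize_per_vs(phase, 1.0)
        two = normalize_per_vs(phase, 2.0)
        np.testing.assert_allclose(one.to_numpy(), phase.cumulative_ml)
        np.testing.assert_allclose(two.to_numpy() * 2, phase.cumulative_ml)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            normalize_per_vs(_linear_series(), 0.0)


class TestProductionRate:
    def test_linear_cumulative_constant_rate(self):
        # 24 mL/day -> 1 mL/hr everywhere
        rate = production_rate(_linear_series(ml_per_day=24.0))
        np.testing.assert_allclose(rate.to_numpy(), 1.0, rtol=1e-9)

    def test_flat_cumulative_zero_rate(self):
        s = GasSeries(times=np.arange(1, 100) / 96, cumulative_ml=np.full(99, 7.0))
        assert production_rate(s).abs().max() == 0.0

    def test_gompertz_peak_rate_matches_rmax(self):
        """Smoothed max rate of a Gompertz phase ~ Rmax/24 mL/hr."""
        p = GompertzParams(bbmp=394.16, rmax=90.97, lag_days=0.10)
        t = np.arange(1, 14 * 96 + 1) / 96
        s = GasSeries(times=t, cumulative_ml=gompertz_bmp(p, t))
        rate = production_rate(s, window_hr=1.0)
        assert rate.max() == pytest.approx(90.97 / 24.0, rel=0.01)

    def test_single_point_rejected(self):
        s = GasSeries(times=[1.0], cumulative_ml=[0.0])
        with pytest.raises(ValueError):
            production_rate(s)


class TestFindPeaks:
    def test_single_hump(self):
        t = np.linspace(0, 10, 961)
        rate = pd.Series(5 * np.exp(-((t - 4) ** 2)), index=t)
        peaks = find_peaks(rate, min_prominence=0.5)
        assert len(peaks) == 1
        assert peaks[0].day == pytest.approx(4.0, abs=0.02)
        assert peaks[0].rate_ml_per_hr == pytest.approx(5.0, rel=1e-3)

    def test_two_gompertz_pulses_ten_days_apart(self):
        # lag long enough that each pulse starts from ~zero (the Gompertz
        # form has a small nonzero value at its onset for short lags)
        p = GompertzParams(bbmp=200.0, rmax=60.0, lag_days=2.0)
        t = np.arange(1, 20 * 96 + 1) / 96
        c = gompertz_bmp(p, t) + np.where(t > 10, gompertz_bmp(p, np.maximum(t - 10, 0)), 0)
        s = GasSeries(times=t, cumulative_ml=c)
        peaks = find_peaks(production_rate(s), min_prominence=0.5, min_separation_days=2)
        assert len(peaks) == 2
        assert peaks[1].day - peaks[0].day == pytest.approx(10.0, abs=0.2)

    def test_all_zero_rate_empty(self):
        rate = pd.Series(np.zeros(50), index=np.arange(50.0))
        assert find_peaks(rate) == []

    def test_monotone_rate_no_interior_peak(self):
        rate = pd.Series(np.linspace(0, 10, 100), index=np.arange(100.0))
        assert find_peaks(rate) == []


class TestRelativeIncrease:
    def test_exact_printed_cell(self):
        assert relative_increase(334.71, 390.33) == pytest.approx(14.25, abs=0.005)

    def test_unrounded_input_cell(self):
        # recomputation gives 65.40; the printed 65.39 came from unrounded inputs
        assert relative_increase(135.06, 390.33) == pytest.approx(65.40, abs=0.005)

    def test_equal_values_zero(self):
        assert relative_increase(7.7, 7.7) == 0.0

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            relative_increase(1.0, 0.0)

    @given(st.floats(0.1, 1e4), st.floats(0.1, 1e4), st.floats(0.01, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_algebraic_identity_and_scale_invariance(self, a, b, c):
        # RI(a, b) = 100 (1 - a/b), invariant under common scaling
        assert relative_increase(a, b) == pytest.approx(100 * (1 - a / b), rel=1e-12)
        assert relative_increase(c * a, c * b) == pytest.approx(
            relative_increase(a, b), rel=1e-9, abs=1e-9
        )


class TestRelativeIncreaseMatrix:
    def test_final_phase_bmp_panel(self):
        m = relative_increase_matrix(BMP_PHASE4_BY_DOSE, basis="phase4_bmp")
        assert m.at(4.0, 2.0) == pytest.approx(24.06, abs=0.005)
        assert m.at(8.0, 6.0) == pytest.approx(14.25, abs=0.005)

    def test_sixty_day_bmy_panel(self):
        m = relative_increase_matrix(BMY_60D_BY_DOSE, basis="total_bmy")
        assert m.at(8.0, 6.0) == pytest.approx(3.24, abs=0.005)
        assert m.at(6.0, 2.0) == pytest.approx(8.87, abs=0.005)

    def test_diagonal_zero_and_upper_triangle_empty(self):
        m = relative_increase_matrix({0.0: 10.0, 2.0: 20.0, 4.0: 30.0})
        assert all(m.values.loc[d, d] == 0.0 for d in m.doses)
        assert np.isnan(m.values.loc[0.0, 4.0])

    def test_equal_values_give_zero_entry(self):
        m = relative_increase_matrix({0.0: 5.0, 2.0: 5.0})
        assert m.at(2.0, 0.0) == 0.0

    def test_single_dose_rejected(self):
        with pytest.raises(ValueError):
            relative_increase_matrix({0.0: 5.0})
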