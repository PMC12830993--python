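"""Event recognition, QC, lock-mass correction and binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirlms.preprocess import (
    QC_GOOD,
    QC_LOW_TIC,
    QC_NO_LOCKMASS,
    QC_SHORT,
    EventRecognitionParams,
    Scan,
    SamplingEvent,
    bin_and_normalize,
    detect_events,
    lockmass_correct,
    qc_check,
    rebin_1da,
)

from .conftest import make_event


def _scan(index, tic):
    """Single-peak scan with the given TIC."""
    return Scan(index, np.array([500.0]), np.array([float(tic)]))


class TestDetectEvents:
    def test_thirteen_scans_above_trigger_form_one_full_event(self):
        stream = [_scan(i, 1e5) for i in range(13)]
        events = detect_events(stream)
        assert len(events) == 1
        assert events[0].duration_s == 13.0

    def test_all_scans_below_trigger_yield_no_events(self):
        stream = [_scan(i, 100.0) for i in range(20)]
        assert detect_events(stream) == []

    def test_empty_stream(self):
        assert detect_events([]) == []

    def test_timeout_closes_partial_event(self):
        # 5 scans above trigger then silence: the event opens at scan 0,
        # accumulates scans 0-4, and no qualifying scan arrives before the
        # 13 s timeout (reached at scan 13), so it closes with 5 scans.
        stream = [_scan(i, 1e5) for i in range(5)] + [
            _scan(i, 10.0) for i in range(5, 18)
        ]
        events = detect_events(stream)
        assert len(events) == 1
        assert events[0].duration_s == 5.0

    def test_scans_never_shared_between_events(self):
        stream = [_scan(i, 1e5) for i in range(30)]
        events = detect_events(stream)
        indices = [s.index for ev in events for s in ev.scans]
        assert len(indices) == len(set(indices))
        # 30 qualifying scans: two full 13-scan events plus a 4-scan tail
        assert [ev.duration_s for ev in events] == [13.0, 13.0, 4.0]

    def test_event_reopens_after_timeout(self):
        # burst of 4, long silence, burst of 4 — two separate events
        stream = (
            [_scan(i, 1e5) for i in range(4)]
            + [_scan(i, 10.0) for i in range(4, 20)]
            + [_scan(i, 1e5) for i in range(20, 24)]
        )
        events = detect_events(stream)
        assert [ev.duration_s for ev in events] == [4.0, 4.0]


class TestQcCheck:
    def test_good_event(self, toy_event):
        assert qc_check(toy_event) == QC_GOOD

    def test_three_second_event_is_short(self):
        # 3 s is not "more than 3 seconds"
        ev = make_event([(717.5070, 1e4)], n_scans=3)
        assert qc_check(ev) == QC_SHORT

    def test_four_second_event_passes_duration(self):
        ev = make_event([(717.5070, 1e4)], n_scans=4)
        assert qc_check(ev) == QC_GOOD

    def test_missing_lockmass(self):
        ev = make_event([(500.0, 1e6)])
        assert qc_check(ev) == QC_NO_LOCKMASS

    def test_low_tic(self):
        ev = make_event([(717.5070, 10.0)], n_scans=13)  # TIC 130 <= 1e3
        assert qc_check(ev) == QC_LOW_TIC

    def test_criteria_checked_in_order(self):
        # violates all three criteria; lock-mass absence wins
        ev = make_event([(500.0, 10.0)], n_scans=2)
        assert qc_check(ev) == QC_NO_LOCKMASS

    def test_qc_is_pure(self, toy_event):
        assert qc_check(toy_event) == qc_check(toy_event)


class TestLockmassCorrect:
    def test_observed_drift_shifts_all_mz(self):
        ev = make_event([(717.6070, 5e4), (500.05, 2e4)])
        corrected = lockmass_correct(ev)
        assert corrected.lockmass_observed == pytest.approx(717.6070)
        # all m/z shifted by -0.1000
        shifted = ev.mz - 0.1000
        shifted[np.abs(ev.mz - 717.6070) < 1e-12] = 717.5070
        np.testing.assert_allclose(corrected.mz, shifted, atol=1e-12)
        assert (corrected.mz == 717.5070).any()

    def test_zero_drift_is_identity(self, toy_event):
        corrected = lockmass_correct(toy_event)
        np.testing.assert_array_equal(corrected.mz, toy_event.mz)

    def test_more_intense_candidate_defines_shift(self):
        # two peaks inside the window: the stronger one (717.45) is the
        # lock-mass, so the shift is +0.057
        ev = make_event([(717.45, 9e4), (717.60, 1e4), (300.0, 1e4)], n_scans=5)
        corrected = lockmass_correct(ev)
        assert corrected.lockmass_observed == pytest.approx(717.45)
        assert corrected.mz[np.abs(ev.mz - 300.0) < 1e-9][0] == pytest.approx(
            300.0 + (717.5070 - 717.45)
        )

    def test_refuses_event_without_lockmass(self):
        from dataclasses import replace

        ev = make_event([(500.0, 1e6)])
        ev = replace(ev, qc_status=QC_NO_LOCKMASS)
        with pytest.raises(ValueError):
            lockmass_correct(ev)


class TestBinAndNormalize:
    def test_single_peak_lands_in_expected_bin(self):
        ev = make_event([(500.05, 123.0)], n_scans=1)
        mat = bin_and_normalize([ev])
        assert mat.values.shape == (1, 9000)
        assert mat.values[0, 4000] == pytest.approx(1.0)
        assert mat.values[0].sum() == pytest.approx(1.0, abs=1e-9)

    def test_peak_on_upper_boundary_discarded(self):
        ev = make_event([(1000.0, 50.0), (500.0, 50.0)], n_scans=1)
        mat = bin_and_normalize([ev])
        assert mat.values[0].sum() == pytest.approx(1.0)
        assert mat.values[0, 4000] == pytest.approx(1.0)  # only the 500 peak

    def test_normalization_arithmetic(self):
        ev = make_event([(200.0, 300.0), (600.0, 100.0)], n_scans=1)
        mat = bin_and_normalize([ev])
        assert mat.values[0, 1000] == pytest.approx(0.75)
        assert mat.values[0, 5000] == pytest.approx(0.25)

    def test_exact_bin_edge_goes_to_own_bin(self):
        ev = make_event([(500.0, 1.0)], n_scans=1)
        mat = bin_and_normalize([ev])
        assert mat.values[0, 4000] == pytest.approx(1.0)

    def test_empty_row_flagged_not_divided(self):
        ev = make_event([(50.0, 10.0)], n_scans=1)  # below range
        mat = bin_and_normalize([ev])
        assert mat.annotations["empty_row"].iloc[0]
        assert mat.values[0].sum() == 0.0

    def test_invalid_grid_rejected(self, toy_event):
        with pytest.raises(ValueError):
            bin_and_normalize([toy_event], lo=1000.0, hi=100.0)
        with pytest.raises(ValueError):
            bin_and_normalize([toy_event], width=-0.1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(100.0, 999.95),
                st.floats(0.1, 1e6),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_in_range_mass_conserved_before_normalization(self, peaks):
        """Binning neither loses nor creates in-range intensity."""
        ev = make_event(peaks, n_scans=1)
        mat = bin_and_normalize([ev])
        in_range = sum(i for mz, i in peaks if 100.0 <= mz < 1000.0)
        if in_range > 0:
            # rows are normalised, so conservation shows as a unit sum
            assert mat.values[0].sum() == pytest.approx(1.0, abs=1e-9)


class TestRebin1Da:
    def test_row_sum_preserved(self, toy_event):
        mat = bin_and_normalize([toy_event])
        coarse = rebin_1da(mat)
        assert coarse.values.shape == (1, 900)
        assert coarse.values[0].sum() == pytest.approx(mat.values[0].sum())

    def test_index_arithmetic(self):
        ev = make_event([(500.05, 7.0)], n_scans=1)
        coarse = rebin_1da(bin_and_normalize([ev]))
        assert coarse.values[0, 400] == pytest.approx(1.0)

    def test_zero_row_stays_zero(self):
        ev = make_event([(50.0, 1.0)], n_scans=1)
        coarse = rebin_1da(bin_and_normalize([ev]))
        assert not coarse.values[0].any()

    def test_wrong_width_rejected(self, toy_event):
        mat = bin_and_normalize([toy_event], width=1.0)
        with pytest.raises(ValueError):
            rebin_1da(mat)


def test_drift_invariance_of_corrected_features():
    """Correct-then-bin is invariant to injected mass drift inside the
    search window: drifted and undrifted copies bin identically."""
    peaks = [(717.5070, 5e4), (620.30, 2e4), (885.50, 1e4), (300.10, 5e3)]
    base = make_event(peaks)
    for drift in (-0.2, -0.05, 0.04, 0.19):
        from dataclasses import replace

        drifted = replace(base, mz=base.mz + drift)
        m0 = bin_and_normalize([lockmass_correct(base)])
        m1 = bin_and_normalize([lockmass_correct(drifted)])
        np.testing.assert_allclose(m0.values, m1.values, atol=1e-12)
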