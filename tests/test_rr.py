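"""RR series I/O, artifact correction, RMSSD and windowed summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import affectdyn as ad
from affectdyn.errors import (
    InsufficientBeatsError,
    ParseError,
    SparseWindowError,
    UncorrectableSeriesError,
)
from affectdyn.rr import CORRECTION_THRESHOLDS_MS


def naive_rmssd(x):
    """Independent two-pass loop oracle for the RMSSD formula."""
    total = 0.0
    n = 0
    for a, b in zip(x, x[1:]):
        total += (b - a) ** 2
        n += 1
    return (total / n) ** 0.5


class TestReadRR:
    def test_plain_format(self, tmp_path):
        path = tmp_path / "rr.txt"
        path.write_text("800\n810\n790\n")
        rr = ad.read_rr(path)
        assert rr.intervals_ms.tolist() == [800.0, 810.0, 790.0]
        assert np.allclose(rr.beat_times_s, [0.8, 1.61, 2.4])

    def test_timed_csv_format(self, tmp_path):
        path = tmp_path / "rr.csv"
        path.write_text("beat_time_s,rr_ms\n0.8,800\n1.61,810\n")
        rr = ad.read_rr(path, format="timed_csv")
        assert rr.intervals_ms.tolist() == [800.0, 810.0]

    @pytest.mark.parametrize("content", ["", "800\n-5\n800\n", "800\nabc\n"])
    def test_parse_errors(self, tmp_path, content):
        path = tmp_path / "bad.txt"
        path.write_text(content)
        with pytest.raises(ParseError):
            ad.read_rr(path)

    def test_parse_error_carries_line_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("800\n-5\n")
        with pytest.raises(ParseError) as exc:
            ad.read_rr(path)
        assert exc.value.line == 2


class TestRMSSD:
    def test_worked_example(self):
        assert ad.rmssd([800, 810, 790]) == pytest.approx(np.sqrt(250), abs=1e-9)

    def test_single_difference(self):
        assert ad.rmssd([1000, 900]) == pytest.approx(100.0)

    def test_constant_series_is_zero(self):
        assert ad.rmssd([720.0] * 50) == 0.0

    def test_too_short(self):
        with pytest.raises(InsufficientBeatsError):
            ad.rmssd([800])

    def test_oracle_equivalence_random_series(self):
        """Matches a naive loop implementation to 1e-9 relative tolerance."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = rng.integers(2, 60)
            x = rng.uniform(300, 1500, size=n)
            assert ad.rmssd(x) == pytest.approx(naive_rmssd(x), rel=1e-9)

    @given(
        st.lists(st.floats(300, 1500), min_size=2, max_size=40),
        st.floats(-100, 100),
        st.floats(0.1, 5),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_shift_invariance_and_scaling(self, x, shift, scale):
        base = ad.rmssd(x)
        shifted = ad.rmssd([v + shift for v in x])
        scaled = ad.rmssd([v * scale for v in x])
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert scaled == pytest.approx(scale * base, rel=1e-9, abs=1e-9)


class TestMeanHR:
    @pytest.mark.parametrize(
        "intervals,hr,rr_mean",
        [([800.0] * 10, 75.0, 800.0), ([1000.0] * 3, 60.0, 1000.0), ([600, 1000], 75.0, 800.0)],
    )
    def test_reciprocal_relation(self, intervals, hr, rr_mean):
        got_hr, got_rr = ad.mean_hr(intervals)
        assert got_hr == pytest.approx(hr)
        assert got_rr == pytest.approx(rr_mean)
        assert got_hr * got_rr == pytest.approx(60000.0)

    def test_empty(self):
        with pytest.raises(InsufficientBeatsError):
            ad.mean_hr([])


class TestCorrectArtifacts:
    def test_clean_series_untouched(self):
        rr = ad.RRSeries(np.full(50, 800.0))
        corrected, report = ad.correct_artifacts(rr, "medium")
        assert report.n_flagged == 0
        assert np.array_equal(corrected.intervals_ms, rr.intervals_ms)

    def test_level_none_is_identity(self):
        x = np.array([800.0, 1600.0, 800.0, 790.0, 805.0])
        corrected, report = ad.correct_artifacts(ad.RRSeries(x), "none")
        assert report.n_flagged == 0
        assert np.array_equal(corrected.intervals_ms, x)

    def test_missed_beat_repaired(self):
        x = np.full(20, 800.0)
        x[10] = 1600.0  # missed detection: double interval
        corrected, report = ad.correct_artifacts(ad.RRSeries(x), "medium")
        assert report.flagged_indices == [10]
        assert np.allclose(corrected.intervals_ms, 800.0)
        assert corrected.duration_s == pytest.approx(x.sum() / 1000, abs=1e-12)

    def test_ectopic_pair_repaired(self):
        x = np.concatenate([np.full(8, 800.0), [320.0, 480.0], np.full(8, 800.0)])
        corrected, report = ad.correct_artifacts(ad.RRSeries(x), "medium")
        assert report.n_flagged == 2
        assert np.allclose(corrected.intervals_ms, 800.0)
        assert corrected.duration_s == pytest.approx(x.sum() / 1000, abs=1e-12)

    def test_unflagged_intervals_bit_identical(self):
        rng = np.random.default_rng(5)
        x = rng.normal(800, 20, size=100)
        x[[20, 60]] = [1600.0, 300.0]
        corrected, report = ad.correct_artifacts(ad.RRSeries(x), "medium")
        good = np.setdiff1d(np.arange(100), report.flagged_indices)
        # unflagged values survive verbatim (correction may change beat count)
        remaining = corrected.intervals_ms
        for v in x[good]:
            assert v in remaining

    def test_level_sensitivity(self):
        x = np.full(30, 800.0)
        x[15] = 1000.0  # deviation 200 ms
        _, rep_medium = ad.correct_artifacts(ad.RRSeries(x), "medium")
        _, rep_strong = ad.correct_artifacts(ad.RRSeries(x), "strong")
        assert rep_medium.n_flagged == 0  # 200 < 250
        assert rep_strong.n_flagged == 1  # 200 > 150

    def test_idempotent(self, simulated_rr):
        noisy = ad.inject_artifacts(simulated_rr, "ectopic_split", 0.05, seed=11)
        once, _ = ad.correct_artifacts(noisy, "medium")
        twice, report = ad.correct_artifacts(once, "medium")
        assert report.n_flagged == 0
        assert np.array_equal(once.intervals_ms, twice.intervals_ms)

    def test_all_flagged_uncorrectable(self):
        x = np.array([100.0, 1900.0] * 5)  # alternating extremes
        with pytest.raises((UncorrectableSeriesError, InsufficientBeatsError)):
            ad.correct_artifacts(ad.RRSeries(x), "very_strong")


class TestWindowedRMSSD:
    def test_constant_recording_all_zero(self, schedule, windows):
        rr = ad.RRSeries(np.full(2000, 800.0))
        matrix = ad.windowed_rmssd(rr, windows)
        assert matrix.values.shape == (4, 4)
        assert np.allclose(matrix.values, 0.0)

    def test_single_window_populated(self, schedule, windows):
        """Variability planted in exactly one window lands in exactly one cell,
        with the value the plain RMSSD formula gives for those intervals."""
        target = sorted(windows.by_kind("transition"), key=lambda w: w.t_start_s)[3]
        intervals = []
        t = 0.0
        alternate = [780.0, 820.0]
        while t < 1560:
            v = 800.0
            if target.t_start_s <= t + 0.8 < target.t_end_s:
                v = alternate[len(intervals) % 2]
            intervals.append(v)
            t += v / 1000.0
        rr = ad.RRSeries(np.array(intervals))
        # independent selection: loop over cumulative times
        selected, cum = [], 0.0
        for v in intervals:
            cum += v / 1000.0
            if target.t_start_s <= cum < target.t_end_s:
                selected.append(v)
        matrix = ad.windowed_rmssd(rr, windows)
        cell = matrix[target.from_state + target.to_state]
        assert cell == pytest.approx(naive_rmssd(selected), rel=1e-9)
        assert cell > 10.0
        others = matrix.values.copy()
        i, j = "ABCD".index(target.from_state), "ABCD".index(target.to_state)
        others[i, j] = 0.0
        assert np.allclose(others, 0.0)

    def test_cells_finite_nonnegative(self, simulated_rr, windows):
        matrix = ad.windowed_rmssd(simulated_rr, windows)
        assert np.all(np.isfinite(matrix.values))
        assert np.all(matrix.values >= 0)
        assert matrix.values.size == 16

    def test_sparse_window_error(self, windows):
        short = ad.RRSeries(np.full(100, 800.0))  # recording ends at 80 s
        with pytest.raises(SparseWindowError):
            ad.windowed_rmssd(short, windows)

    def test_origin_offset_shifts_membership(self, schedule, windows):
        """Shifting the origin by a window width changes which beats count."""
        rng = np.random.default_rng(0)
        x = rng.normal(800, 20, size=2200)
        a = ad.windowed_rmssd(ad.RRSeries(x, origin_offset_s=0.0), windows)
        b = ad.windowed_rmssd(ad.RRSeries(x, origin_offset_s=-30.0), windows)
        assert not np.allclose(a.values, b.values)
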