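"""Actigraphy reading, cleaning, scaling, smoothing and segmentation."""

import numpy as np
import pandas as pd
import pytest

from actimotif.preprocess import (
    MINUTES_PER_DAY,
    DayRecord,
    InvalidConfigError,
    aggregate_minutes,
    read_actigraphy,
    read_segments,
    scale_counts,
    segment_days,
    smooth_day,
    write_days,
    write_segments,
)


def _single_axis_csv(path, days_minutes):
    """days_minutes: {date: number of minutes to emit}."""
    rows = []
    for date, n_min in days_minutes.items():
        for m in range(n_min):
            ts = f"{date} {m // 60:02d}:{m % 60:02d}:00"
            rows.append({"timestamp": ts, "date": date, "activity": float(m % 7)})
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


class TestReadActigraphy:
    def test_completeness_filter_keeps_full_days(self, tmp_path):
        p = _single_axis_csv(
            tmp_path / "subj1.csv",
            {"2020-01-01": 1440, "2020-01-02": 1440, "2020-01-03": 900},
        )
        days, report = read_actigraphy(p, dialect="single")
        assert len(days) == 2
        assert report.n_days_complete == 2
        assert report.n_days_dropped == 1
        assert days[0].subject_id == "subj1"

    def test_duplicate_minutes_keep_first(self, tmp_path):
        p = tmp_path / "dup.csv"
        rows = [
            {"timestamp": f"2020-01-01 {m // 60:02d}:{m % 60:02d}:00", "date": "2020-01-01", "activity": 1.0}
            for m in range(1440)
        ]
        rows.insert(5, {"timestamp": "2020-01-01 00:03:00", "date": "2020-01-01", "activity": 99.0})
        pd.DataFrame(rows).to_csv(p, index=False)
        days, report = read_actigraphy(p)
        assert report.n_rows_duplicate == 1
        assert len(days) == 1
        assert days[0].values[0, 3] == 1.0  # first occurrence kept

    def test_malformed_timestamps_rejected_and_counted(self, tmp_path):
        p = tmp_path / "bad.csv"
        rows = [
            {"timestamp": f"2020-01-01 {m // 60:02d}:{m % 60:02d}:00", "date": "2020-01-01", "activity": 1.0}
            for m in range(1440)
        ]
        rows[10]["timestamp"] = "not-a-time"
        pd.DataFrame(rows).to_csv(p, index=False)
        days, report = read_actigraphy(p)
        assert report.n_rows_malformed == 1
        assert len(days) == 0  # day now incomplete

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.csv"
        pd.DataFrame(columns=["timestamp", "date", "activity"]).to_csv(p, index=False)
        with pytest.raises(ValueError):
            read_actigraphy(p)

    def test_triaxial_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        day = DayRecord(
            subject_id="t1",
            date="2020-03-05",
            values=rng.uniform(0, 2, (3, MINUTES_PER_DAY)),
            axis_names=("x", "y", "z"),
        )
        p = tmp_path / "tri.csv"
        write_days([day], p, dialect="triaxial")
        days, _ = read_actigraphy(p, dialect="triaxial")
        assert len(days) == 1
        assert np.allclose(days[0].values, day.values, atol=1e-9)
        # writing again yields byte-identical files
        p2 = tmp_path / "tri2.csv"
        write_days(days, p2, dialect="triaxial")
        assert p.read_bytes() == p2.read_bytes()


class TestAggregateMinutes:
    def test_median_of_minute(self):
        frame = pd.DataFrame(
            {
                "timestamp": ["2020-01-01 00:00:01", "2020-01-01 00:00:20", "2020-01-01 00:00:59"],
                "value": [1.0, 2.0, 100.0],
            }
        )
        out = aggregate_minutes(frame)
        assert out["value"].tolist() == [2.0]

    def test_single_sample_identity(self):
        frame = pd.DataFrame({"timestamp": ["2020-01-01 10:30:05"], "value": [7.0]})
        assert aggregate_minutes(frame)["value"].tolist() == [7.0]

    def test_even_count_midpoint_convention(self):
        frame = pd.DataFrame(
            {
                "timestamp": ["2020-01-01 00:00:%02d" % s for s in (1, 2, 3, 4)],
                "value": [1.0, 2.0, 3.0, 4.0],
            }
        )
        assert aggregate_minutes(frame)["value"].tolist() == [2.5]


class TestScaleCounts:
    def _day(self, fill=3000.0):
        return DayRecord("s", "2020-01-01", np.full((1, MINUTES_PER_DAY), fill))

    def test_default_divisor(self):
        out = scale_counts(self._day())
        assert np.all(out.values == 3.0)
        assert out.divisor == 1000.0

    def test_unit_divisor_is_identity(self):
        out = scale_counts(self._day(), divisor=1.0)
        assert np.array_equal(out.values, self._day().values)

    def test_composition_of_divisors(self):
        once = scale_counts(self._day(), 1000.0)
        twice = scale_counts(scale_counts(self._day(), 10.0), 100.0)
        assert np.allclose(once.values, twice.values, atol=1e-12)
        assert twice.divisor == 1000.0

    def test_nonpositive_divisor_rejected(self):
        with pytest.raises(InvalidConfigError):
            scale_counts(self._day(), 0.0)


class TestSmoothDay:
    def test_constant_day_unchanged(self):
        day = DayRecord("s", "2020-01-01", np.full((1, MINUTES_PER_DAY), 1.7))
        out = smooth_day(day)
        assert np.max(np.abs(out.values - 1.7)) < 1e-8

    def test_reduces_second_difference_roughness(self):
        rng = np.random.default_rng(1)
        t = np.arange(MINUTES_PER_DAY)
        clean = 1.0 + np.sin(2 * np.pi * t / MINUTES_PER_DAY)
        noisy = clean + rng.normal(0, 0.3, MINUTES_PER_DAY)
        day = DayRecord("s", "2020-01-01", np.maximum(noisy, 0)[None, :])
        out = smooth_day(day)
        rough = lambda v: np.sum(np.diff(v, 2) ** 2)
        assert rough(out.values[0]) < 0.01 * rough(day.values[0])

    def test_large_basis_near_interpolates_smooth_signal(self):
        t = np.arange(MINUTES_PER_DAY)
        clean = 1.0 + np.sin(2 * np.pi * t / MINUTES_PER_DAY)
        day = DayRecord("s", "2020-01-01", clean[None, :])
        out = smooth_day(day, basis_size=300, lam=0.01)
        assert np.max(np.abs(out.values[0] - clean)) < 1e-3

    def test_tiny_basis_rejected(self):
        day = DayRecord("s", "2020-01-01", np.zeros((1, MINUTES_PER_DAY)))
        with pytest.raises(InvalidConfigError):
            smooth_day(day, basis_size=3)


class TestSegmentDays:
    def _days(self, n=1):
        rng = np.random.default_rng(0)
        return [
            DayRecord(f"s", f"2020-01-{d + 1:02d}", rng.uniform(0, 2, (1, MINUTES_PER_DAY)))
            for d in range(n)
        ]

    @pytest.mark.parametrize("window_min,n_expected", [(15, 96), (30, 48), (60, 24)])
    def test_segment_counts(self, window_min, n_expected):
        segs = segment_days(self._days(), window_min)
        assert len(segs) == n_expected

    def test_partition_reconstructs_day_exactly(self):
        days = self._days()
        segs = segment_days(days, 30)
        rebuilt = np.concatenate([s.axes[0].values for s in sorted(segs, key=lambda s: s.window_index)])
        assert np.array_equal(rebuilt, days[0].values[0])

    def test_window_grid_normalized_to_unit_interval(self):
        seg = segment_days(self._days(), 30)[0]
        assert seg.grid[0] == 0.0 and seg.grid[-1] == 1.0
        assert seg.axes[0].n_points == 30

    def test_day_indices_chronological_per_subject(self):
        segs = segment_days(self._days(3), 60)
        assert {s.day_index for s in segs} == {1, 2, 3}

    def test_non_divisor_window_rejected(self):
        with pytest.raises(InvalidConfigError):
            segment_days(self._days(), 25)

    def test_segment_store_round_trip(self, tmp_path):
        segs = segment_days(self._days(2), 30)
        p = tmp_path / "segments.csv"
        write_segments(segs, p)
        back = read_segments(p)
        assert len(back) == len(segs)
        key = {(s.subject_id, s.day_index, s.window_index): s for s in segs}
        for s in back:
            orig = key[(s.subject_id, s.day_index, s.window_index)]
            assert np.allclose(s.axes[0].values, orig.axes[0].values, atol=1e-9)
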