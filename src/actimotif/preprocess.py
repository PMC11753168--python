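"""Reading, cleaning and segmenting per-minute actigraphy.

Input dialects
--------------
``single``   one activity-count column per minute: ``timestamp, date,
             activity`` (one file per subject, Depresjon/PSYKOSE style).
``triaxial`` minute-level triaxial values: ``subject, timestamp, x, y, z``.

A retained day is a calendar day (local midnight to midnight, from the
file's own dates) with exactly 1,440 nonnegative, non-missing minute
values per axis.  Counts are divided by 1,000 by default to keep
amplitudes manageable; an optional penalized B-spline smoother reduces
minute-to-minute measurement noise.  Days are cut into non-overlapping
fixed windows (15/30/60 min), each rescaled to the unit interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .cluster import ActivitySegment
from .curves import FunctionalCurve

__all__ = [
    "DayRecord",
    "ReadReport",
    "read_actigraphy",
    "aggregate_minutes",
    "scale_counts",
    "smooth_day",
    "segment_days",
    "write_days",
    "write_segments",
    "read_segments",
    "MINUTES_PER_DAY",
]

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440


class InvalidConfigError(ValueError):
    """Raised for unusable preprocessing parameters."""


@dataclass(frozen=True)
class DayRecord:
    """One complete calendar day of minute-level activity for one subject."""

    subject_id: str
    date: str  # ISO calendar date
    values: np.ndarray  # (H, 1440), nonnegative
    axis_names: tuple[str, ...] = ("activity",)
    divisor: float = 1.0  # scaling already applied to values

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.shape[1] != MINUTES_PER_DAY:
            raise ValueError(f"a day must have {MINUTES_PER_DAY} minutes, got {values.shape[1]}")
        if not np.all(np.isfinite(values)):
            raise ValueError("day values must be finite")
        object.__setattr__(self, "values", values)
        if len(self.axis_names) != values.shape[0]:
            raise ValueError("axis_names must match the number of axes")

    @property
    def n_axes(self) -> int:
        return self.values.shape[0]


@dataclass
class ReadReport:
    """Row-level accounting from reading one actigraphy source."""

    n_days_complete: int = 0
    n_days_dropped: int = 0
    n_rows_malformed: int = 0
    n_rows_duplicate: int = 0
    n_rows_negative: int = 0
    dropped_days: list[tuple[str, str]] = field(default_factory=list)


def _minutes_of_day(ts: pd.Series) -> np.ndarray:
    return (ts.dt.hour * 60 + ts.dt.minute).to_numpy()


def _collect_days(
    df: pd.DataFrame,
    subject: str,
    value_cols: list[str],
    axis_names: tuple[str, ...],
    report: ReadReport,
) -> list[DayRecord]:
    days = []
    for date, day_df in df.groupby("date_key", sort=True):
        dup = day_df.duplicated(subset="minute", keep="first")
        if dup.any():
            report.n_rows_duplicate += int(dup.sum())
            logger.info("%s %s: %d duplicate minutes dropped", subject, date, int(dup.sum()))
            day_df = day_df[~dup]
        neg = (day_df[value_cols] < 0).any(axis=1)
        if neg.any():
            report.n_rows_negative += int(neg.sum())
            day_df = day_df[~neg]
        if len(day_df) != MINUTES_PER_DAY:
            report.n_days_dropped += 1
            report.dropped_days.append((subject, str(date)))
            continue
        values = np.empty((len(value_cols), MINUTES_PER_DAY))
        order = np.argsort(day_df["minute"].to_numpy())
        for h, col in enumerate(value_cols):
            values[h] = day_df[col].to_numpy()[order]
        days.append(DayRecord(subject_id=subject, date=str(date), values=values, axis_names=axis_names))
        report.n_days_complete += 1
    return days


def read_actigraphy(
    path: str | Path,
    dialect: str = "single",
    subject_id: str | None = None,
) -> tuple[list[DayRecord], ReadReport]:
    """Read a per-minute comma-separated actigraphy file into complete days.

    Rows with unparseable timestamps or negative values are rejected and
    counted; duplicate minutes keep the first occurrence.  Only days
    with all 1,440 minutes present are retained.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty actigraphy file: {path}")
    report = ReadReport()
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = ts.isna()
    if bad.any():
        report.n_rows_malformed += int(bad.sum())
        logger.info("%s: %d malformed rows rejected", path.name, int(bad.sum()))
        df = df[~bad]
        ts = ts[~bad]
    df = df.assign(minute=_minutes_of_day(ts))
    days: list[DayRecord] = []
    if dialect == "single":
        subject = subject_id if subject_id is not None else path.stem
        if "date" in df.columns:
            df = df.assign(date_key=pd.to_datetime(df["date"]).dt.date.astype(str))
        else:
            df = df.assign(date_key=ts.dt.date.astype(str))
        bad_val = pd.to_numeric(df["activity"], errors="coerce").isna()
        if bad_val.any():
            report.n_rows_malformed += int(bad_val.sum())
            df = df[~bad_val]
        df["activity"] = df["activity"].astype(float)
        days = _collect_days(df, subject, ["activity"], ("activity",), report)
    elif dialect == "triaxial":
        df = df.assign(date_key=ts.dt.date.astype(str))
        for subject, sub_df in df.groupby("subject", sort=True):
            days.extend(
                _collect_days(sub_df, str(subject), ["x", "y", "z"], ("x", "y", "z"), report)
            )
    else:
        raise InvalidConfigError(f"unknown dialect {dialect!r}")
    return days, report


def aggregate_minutes(frame: pd.DataFrame, value_cols: list[str] | None = None) -> pd.DataFrame:
    """Median-aggregate sub-minute samples to the minute level.

    Expects a ``timestamp`` column; all points within each minute are
    reduced to their median (the even-count convention is the midpoint
    average).  Minutes with no samples are simply absent, so the
    enclosing day later fails the completeness filter.
    """
    ts = pd.to_datetime(frame["timestamp"])
    if value_cols is None:
        value_cols = [c for c in frame.columns if c != "timestamp"]
    out = (
        frame.assign(timestamp=ts.dt.floor("min"))
        .groupby("timestamp", as_index=False)[value_cols]
        .median()
    )
    return out


def scale_counts(day: DayRecord, divisor: float = 1000.0) -> DayRecord:
    """Divide counts elementwise; the applied divisor is recorded."""
    if divisor <= 0:
        raise InvalidConfigError("divisor must be positive")
    return replace(day, values=day.values / divisor, divisor=day.divisor * divisor)


def _penalized_bspline(y: np.ndarray, basis_size: int, lam: float) -> np.ndarray:
    """P-spline fit: cubic B-spline basis, second-difference coefficient penalty."""
    n = y.size
    x = np.arange(n, dtype=float)
    degree = 3
    n_knots = basis_size - degree + 1
    interior = np.linspace(0, n - 1, n_knots)
    knots = np.concatenate(
        [np.full(degree, interior[0]), interior, np.full(degree, interior[-1])]
    )
    design = BSpline.design_matrix(x, knots, degree).toarray()
    D2 = np.diff(np.eye(design.shape[1]), n=2, axis=0)
    lhs = design.T @ design + lam * D2.T @ D2
    coef = np.linalg.solve(lhs, design.T @ y)
    return design @ coef


def smooth_day(day: DayRecord, basis_size: int = 50, lam: float = 10.0) -> DayRecord:
    """Penalized B-spline smoothing per axis.

    ``basis_size`` cubic B-splines span the day; a second-difference
    penalty with weight ``lam`` controls roughness.  Constant days pass
    through unchanged (constants lie in the penalty null space), and
    smoothed values are clipped at zero to respect the count domain.
    """
    if basis_size < 4:
        raise InvalidConfigError("basis_size must be >= 4")
    out = np.vstack(
        [_penalized_bspline(day.values[h], basis_size, lam) for h in range(day.n_axes)]
    )
    return replace(day, values=np.maximum(out, 0.0))


def segment_days(days: list[DayRecord], window_min: int) -> list[ActivitySegment]:
    """Cut each day into consecutive non-overlapping fixed windows.

    The window length must divide 1,440; each window's time axis is
    rescaled to [0, 1].  Days are numbered per subject in chronological
    order starting at 1.
    """
    if MINUTES_PER_DAY % window_min != 0:
        raise InvalidConfigError(f"window_min={window_min} must divide {MINUTES_PER_DAY}")
    if window_min < 8:
        raise InvalidConfigError("window_min must be >= 8 samples")
    grid = np.linspace(0.0, 1.0, window_min)
    n_windows = MINUTES_PER_DAY // window_min
    segments = []
    day_counter: dict[str, int] = {}
    for day in sorted(days, key=lambda d: (d.subject_id, d.date)):
        day_counter[day.subject_id] = day_counter.get(day.subject_id, 0) + 1
        d_idx = day_counter[day.subject_id]
        for j in range(n_windows):
            sl = slice(j * window_min, (j + 1) * window_min)
            axes = tuple(
                FunctionalCurve(grid, day.values[h, sl]) for h in range(day.n_axes)
            )
            segments.append(
                ActivitySegment(
                    subject_id=day.subject_id,
                    day_index=d_idx,
                    window_index=j,
                    axes=axes,
                    window_min=window_min,
                )
            )
    return segments


def write_days(days: list[DayRecord], path: str | Path, dialect: str = "single") -> None:
    """Write day records back to a per-minute file in a supported dialect."""
    path = Path(path)
    rows = []
    for day in days:
        base = pd.Timestamp(day.date)
        stamps = base + pd.to_timedelta(np.arange(MINUTES_PER_DAY), unit="min")
        if dialect == "single":
            rows.append(
                pd.DataFrame(
                    {
                        "timestamp": stamps.strftime("%Y-%m-%d %H:%M:%S"),
                        "date": day.date,
                        "activity": day.values[0],
                    }
                )
            )
        elif dialect == "triaxial":
            rows.append(
                pd.DataFrame(
                    {
                        "subject": day.subject_id,
                        "timestamp": stamps.strftime("%Y-%m-%d %H:%M:%S"),
                        "x": day.values[0],
                        "y": day.values[1],
                        "z": day.values[2],
                    }
                )
            )
        else:
            raise InvalidConfigError(f"unknown dialect {dialect!r}")
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def write_segments(segments: list[ActivitySegment], path: str | Path) -> None:
    """Long-format segment store: subject, day, window, axis, minute, value."""
    rows = []
    for seg in segments:
        for h, ax in enumerate(seg.axes):
            rows.append(
                pd.DataFrame(
                    {
                        "subject": seg.subject_id,
                        "day": seg.day_index,
                        "window": seg.window_index,
                        "axis": h,
                        "minute": np.arange(ax.n_points),
                        "value": ax.values,
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_segments(path: str | Path) -> list[ActivitySegment]:
    """Inverse of :func:`write_segments`."""
    df = pd.read_csv(path)
    segments = []
    for (subject, day, window), g in df.groupby(["subject", "day", "window"], sort=True):
        axes = []
        n_axes = g["axis"].nunique()
        for h in range(n_axes):
            vals = g[g["axis"] == h].sort_values("minute")["value"].to_numpy()
            axes.append(FunctionalCurve(np.linspace(0.0, 1.0, vals.size), vals))
        segments.append(
            ActivitySegment(
                subject_id=str(subject),
                day_index=int(day),
                window_index=int(window),
                axes=tuple(axes),
                window_min=axes[0].n_points,
            )
        )
    return segments
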