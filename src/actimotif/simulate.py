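"""Seeded synthetic actigraphy with planted motifs and group structure.

The generator emulates the structure of free-living activity data:
1,440 nonnegative samples per day per axis, built from a small library
of short-window motif templates (sleep-like flat-low, flat-high, single
bump, double bump, ramp).  Each window draws a template according to
time-of-day placement probabilities over four 6-hour blocks, then
applies a random boundary-preserving phase warp, multiplicative
amplitude jitter, a case-group amplitude effect and additive noise.
Ground truth (template per window, group per subject) is recorded for
recovery experiments; the emitted per-minute files are valid inputs to
the preprocessing dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .biomarkers import BiomarkerTable, score_column
from .preprocess import MINUTES_PER_DAY, DayRecord, write_days

__all__ = [
    "SimulationConfig",
    "TEMPLATES",
    "generate",
    "generate_to_dir",
    "generate_biomarker_table",
    "generate_classification_table",
    "random_warp",
]


def _flat_low(t):
    return 0.05 + 0.02 * np.sin(np.pi * t)


def _flat_high(t):
    return 1.2 + 0.05 * np.sin(np.pi * t)


def _single_bump(t):
    return 0.2 + 1.8 * np.exp(-0.5 * ((t - 0.5) / 0.15) ** 2)


def _double_bump(t):
    return 0.2 + 1.2 * (
        np.exp(-0.5 * ((t - 0.3) / 0.09) ** 2) + np.exp(-0.5 * ((t - 0.7) / 0.09) ** 2)
    )


def _ramp(t):
    return 0.1 + 1.6 * t


#: named motif templates on [0, 1]
TEMPLATES = {
    "flat_low": _flat_low,
    "flat_high": _flat_high,
    "single_bump": _single_bump,
    "double_bump": _double_bump,
    "ramp": _ramp,
}


def _default_block_probs(templates: tuple[str, ...]) -> np.ndarray:
    """Circadian placement: sleep-like template dominates the night block."""
    T = len(templates)
    probs = np.full((4, T), 1.0 / T)
    if "flat_low" in templates and T > 1:
        i = templates.index("flat_low")
        night = np.full(T, 0.3 / (T - 1))
        night[i] = 0.7
        day = np.full(T, 0.85 / (T - 1))
        day[i] = 0.15
        probs[0] = night  # 00:00-05:59
        probs[1:] = day
    return probs


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults give a two-group cohort with clearly shaped motifs, mild
    phase warping and amplitude jitter, a sleep-dominated night block,
    and a lower-amplitude case group.
    """

    n_subjects_per_group: int = 10
    days_per_subject: int = 7
    window_min: int = 30
    n_axes: int = 1
    templates: tuple[str, ...] = ("flat_low", "single_bump", "double_bump")
    amplitude_jitter_sd: float = 0.1
    warp_intensity: float = 0.1  # max deviation of gamma from identity
    block_probs: np.ndarray | None = None  # (4, T), rows sum to 1
    group_effect: float = 0.7  # case-group amplitude multiplier on active templates
    noise_sd: float = 0.02  # additive, in scaled-count units (counts/1000)
    seed: int = 0

    def __post_init__(self) -> None:
        if MINUTES_PER_DAY % self.window_min != 0:
            raise ValueError("window_min must divide 1440")
        unknown = [t for t in self.templates if t not in TEMPLATES]
        if unknown:
            raise ValueError(f"unknown templates: {unknown}")
        if self.amplitude_jitter_sd < 0 or self.noise_sd < 0 or not 0 <= self.warp_intensity < 1:
            raise ValueError("jitter/noise sds must be >= 0 and warp intensity in [0, 1)")
        probs = self.block_probs if self.block_probs is not None else _default_block_probs(self.templates)
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (4, len(self.templates)) or not np.allclose(probs.sum(axis=1), 1.0):
            raise ValueError("block_probs must be (4, T) with rows summing to 1")
        object.__setattr__(self, "block_probs", probs)


def random_warp(rng: np.random.Generator, n_points: int, intensity: float) -> np.ndarray:
    """Boundary-preserving monotone warp with max deviation <= intensity.

    Built as the normalized cumulative sum of positive Dirichlet-style
    increments, then shrunk toward the identity so the largest deviation
    equals ``intensity`` times a uniform draw.
    """
    grid = np.linspace(0.0, 1.0, n_points)
    if intensity == 0.0:
        return grid.copy()
    inc = rng.gamma(4.0, size=n_points - 1)
    raw = np.concatenate(([0.0], np.cumsum(inc)))
    raw /= raw[-1]
    delta = raw - grid
    peak = np.max(np.abs(delta))
    if peak < 1e-12:
        return grid.copy()
    scale = intensity * rng.uniform(0.5, 1.0) / peak
    return grid + delta * min(scale, 1.0)


def _windows_per_day(window_min: int) -> int:
    return MINUTES_PER_DAY // window_min


def generate(config: SimulationConfig) -> tuple[list[DayRecord], pd.DataFrame, pd.DataFrame]:
    """Synthesize the cohort.

    Returns ``(days, truth_segments, truth_subjects)``:
    day records in scaled units (as if counts had been divided by
    1,000), the per-window template assignments, and per-subject group
    and covariates.  Fully deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    n_windows = _windows_per_day(config.window_min)
    t = np.linspace(0.0, 1.0, config.window_min)
    active = {name: not name.startswith("flat_low") for name in config.templates}

    days: list[DayRecord] = []
    seg_rows = []
    subj_rows = []
    for group_id, group in enumerate(["control", "case"]):
        for s in range(config.n_subjects_per_group):
            subject = f"{group}_{s:02d}"
            subj_rows.append(
                {
                    "subject": subject,
                    "group": group,
                    "y": group_id,
                    "age_40_69": int(rng.random() < 0.5),
                    "male": int(rng.random() < 0.5),
                }
            )
            for d in range(config.days_per_subject):
                values = np.empty((config.n_axes, MINUTES_PER_DAY))
                date = str(pd.Timestamp("2020-01-01") + pd.Timedelta(days=d))[:10]
                for j in range(n_windows):
                    block = (j * config.window_min) // 360  # 6-hour block
                    tmpl_idx = rng.choice(len(config.templates), p=config.block_probs[block])
                    name = config.templates[tmpl_idx]
                    gamma = random_warp(rng, config.window_min, config.warp_intensity)
                    amp = max(1.0 + rng.normal(0.0, config.amplitude_jitter_sd), 0.05)
                    if group == "case" and active[name]:
                        amp *= config.group_effect
                    base = TEMPLATES[name](gamma)
                    for h in range(config.n_axes):
                        axis_scale = 1.0 if h == 0 else 0.8 + 0.4 * h / config.n_axes
                        vals = amp * axis_scale * base
                        if config.noise_sd > 0:
                            vals = vals + rng.normal(0.0, config.noise_sd, config.window_min)
                        values[h, j * config.window_min : (j + 1) * config.window_min] = np.maximum(
                            vals, 0.0
                        )
                    seg_rows.append(
                        {
                            "subject": subject,
                            "day": d + 1,
                            "window": j,
                            "template": name,
                            "group": group,
                        }
                    )
                axis_names = ("activity",) if config.n_axes == 1 else ("x", "y", "z")[: config.n_axes]
                days.append(
                    DayRecord(subject_id=subject, date=date, values=values, axis_names=axis_names)
                )
    return days, pd.DataFrame(seg_rows), pd.DataFrame(subj_rows)


def generate_to_dir(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit per-minute files (one per subject, raw-count units) + ground truth.

    Values are multiplied back to raw counts (x 1,000) so the files
    round-trip through preprocessing with the default divisor.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    days, truth_seg, truth_subj = generate(config)
    paths = {}
    dialect = "single" if config.n_axes == 1 else "triaxial"
    if dialect == "single":
        by_subject: dict[str, list[DayRecord]] = {}
        for day in days:
            by_subject.setdefault(day.subject_id, []).append(day)
        for subject, sdays in sorted(by_subject.items()):
            p = out_dir / f"{subject}.csv"
            write_days(
                [replace(d, values=d.values * 1000.0) for d in sdays], p, dialect="single"
            )
            paths[subject] = p
    else:
        p = out_dir / "cohort_triaxial.csv"
        write_days([replace(d, values=d.values * 1000.0) for d in days], p, dialect="triaxial")
        paths["cohort"] = p
    truth_seg.to_csv(out_dir / "truth_segments.csv", index=False)
    truth_subj.to_csv(out_dir / "truth_subjects.csv", index=False)
    paths["truth_segments"] = out_dir / "truth_segments.csv"
    paths["truth_subjects"] = out_dir / "truth_subjects.csv"
    return paths


def generate_biomarker_table(
    n_subjects: int = 60,
    days_per_subject: int = 10,
    K: int = 6,
    P: int = 2,
    beta: dict[str, float] | None = None,
    beta0: float = 0.0,
    score_sd: float = 1.0,
    subject_level_outcome: bool = False,
    covariates: bool = False,
    seed: int = 0,
) -> BiomarkerTable:
    """Synthetic FPC-score table with planted logistic effects.

    Scores are centered normal with sd ``score_sd``; outcomes follow a
    logistic model with log-odds ``beta`` on the named score columns.
    With ``subject_level_outcome`` the linear predictor uses the
    subject's mean scores so the outcome is constant within subject (as
    in a case/control study); otherwise each day-row draws its own
    outcome.  Ground truth is stored in ``frame.attrs["beta"]``.
    """
    rng = np.random.default_rng(seed)
    beta = dict(beta or {})
    cols = [score_column(k, p + 1) for k in range(K) for p in range(P)]
    unknown = [c for c in beta if c not in cols]
    if unknown:
        raise ValueError(f"planted beta names not in score columns: {unknown}")
    rows = []
    for i in range(n_subjects):
        subject = f"s{i:03d}"
        subj_scores = rng.normal(0.0, score_sd, size=len(cols))
        for d in range(days_per_subject):
            if subject_level_outcome:
                day_scores = subj_scores + rng.normal(0.0, 0.3 * score_sd, size=len(cols))
            else:
                day_scores = rng.normal(0.0, score_sd, size=len(cols))
            rows.append({"subject": subject, "day": d + 1, **dict(zip(cols, day_scores))})
    frame = pd.DataFrame(rows)
    b = np.array([beta.get(c, 0.0) for c in cols])
    cov_cols: list[str] = []
    if covariates:
        subj = frame["subject"].unique()
        age = {s: int(rng.random() < 0.5) for s in subj}
        male = {s: int(rng.random() < 0.5) for s in subj}
        frame["age_40_69"] = frame["subject"].map(age)
        frame["male"] = frame["subject"].map(male)
        cov_cols = ["age_40_69", "male"]
    if subject_level_outcome:
        subj_mean = frame.groupby("subject")[cols].transform("mean")
        eta = beta0 + subj_mean.to_numpy() @ b
        prob = 1.0 / (1.0 + np.exp(-eta))
        y_subj: dict[str, int] = {}
        for s, g in frame.groupby("subject"):
            y_subj[s] = int(rng.random() < prob[g.index[0]])
        frame["y"] = frame["subject"].map(y_subj)
    else:
        eta = beta0 + frame[cols].to_numpy() @ b
        prob = 1.0 / (1.0 + np.exp(-eta))
        frame["y"] = (rng.random(len(frame)) < prob).astype(int)
    frame.attrs["beta"] = beta
    return BiomarkerTable(frame, cols, cov_cols, "y")


def generate_classification_table(
    n_subjects_per_group: int = 10,
    days_per_subject: int = 5,
    n_features: int = 4,
    separation: float = 6.0,
    noise_sd: float = 1.0,
    covariates: bool = False,
    seed: int = 0,
) -> BiomarkerTable:
    """Two-class day-row feature table for classifier protocol tests.

    Case and control feature means sit ``separation`` noise-sds apart,
    so large values give a perfectly separable problem and 0 gives pure
    chance.
    """
    rng = np.random.default_rng(seed)
    cols = [f"f{j + 1}" for j in range(n_features)]
    rows = []
    for group_id, group in enumerate(["control", "case"]):
        mean = group_id * separation * noise_sd
        for i in range(n_subjects_per_group):
            subject = f"{group}_{i:02d}"
            for d in range(days_per_subject):
                feats = rng.normal(mean, noise_sd, n_features)
                rows.append(
                    {"subject": subject, "day": d + 1, "y": group_id, **dict(zip(cols, feats))}
                )
    frame = pd.DataFrame(rows)
    cov_cols: list[str] = []
    if covariates:
        subj = frame["subject"].unique()
        age = {s: int(rng.random() < 0.5) for s in subj}
        frame["age_40_69"] = frame["subject"].map(age)
        cov_cols = ["age_40_69"]
    return BiomarkerTable(frame, cols, cov_cols, "y")
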