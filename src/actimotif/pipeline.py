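"""End-to-end orchestration: simulate -> preprocess -> cluster ->
biomarkers -> associate/classify, with a run manifest.

A single structured config drives all stages.  All randomness funnels
through one root seed, expanded deterministically per stage; every
output directory carries exactly one manifest recording the tool
version, stage parameters, derived seeds and SHA-256 digests of all
written files, so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import daily_cluster_means, extract_scores, fit_fpca
from .cluster import fit_motifs
from .curves import DistanceWeights
from .models import baseline_classify, fit_association, loso_classify
from .preprocess import read_actigraphy, scale_counts, segment_days, smooth_day, write_segments
from .simulate import SimulationConfig, generate_to_dir

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (detected before any stage runs)."""


class StageError(RuntimeError):
    """A pipeline stage failed; a partial manifest has been written."""


_KNOWN_KEYS = {
    "simulate": {
        "n_subjects_per_group",
        "days_per_subject",
        "window_min",
        "n_axes",
        "templates",
        "amplitude_jitter_sd",
        "warp_intensity",
        "group_effect",
        "noise_sd",
    },
    "preprocess": {"window_min", "divisor", "smooth", "basis_size"},
    "cluster": {"k", "wp", "wa", "max_iter", "tol", "n_restarts"},
    "biomarkers": {"variance_target", "fixed_p"},
    "models": {"features", "run_association", "run_classification"},
}


@dataclass
class PipelineConfig:
    """Parameters for every stage, plus the root seed."""

    seed: int = 0
    simulate: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    biomarkers: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for stage, known in _KNOWN_KEYS.items():
            given = getattr(self, stage)
            unknown = set(given) - known
            if unknown:
                raise ConfigError(f"unknown keys in [{stage}]: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - {"seed", *_KNOWN_KEYS}
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        return cls(**raw)


def _stage_seeds(root_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(root_seed)
    names = ["simulate", "cluster", "biomarkers", "models"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31)) for n, c in zip(names, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path, force: bool = False) -> dict:
    """Execute all stages in order and write outputs plus a manifest.

    Refuses to run into a non-empty output directory unless ``force``;
    raises :class:`StageError` (after writing a partial manifest) if a
    stage fails.  Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise ConfigError(f"output directory {out_dir} is not empty (use force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "tool": "actimotif",
        "version": __version__,
        "root_seed": config.seed,
        "stage_seeds": seeds,
        "config": asdict(config),
        "stages": [],
        "files": {},
    }

    def _record(stage: str, outputs: dict[str, Path]) -> None:
        manifest["stages"].append(stage)
        for name, p in outputs.items():
            if isinstance(p, Path) and p.is_file():
                manifest["files"][str(p.relative_to(out_dir))] = _sha256(p)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    try:
        # --- simulate -------------------------------------------------
        sim_cfg = SimulationConfig(seed=seeds["simulate"], **config.simulate)
        sim_dir = out_dir / "data"
        paths = generate_to_dir(sim_cfg, sim_dir)
        _record("simulate", paths)

        # --- preprocess -----------------------------------------------
        pp = config.preprocess
        window_min = pp.get("window_min", sim_cfg.window_min)
        divisor = pp.get("divisor", 1000.0)
        do_smooth = pp.get("smooth", True)
        days = []
        data_files = sorted(sim_dir.glob("*.csv"))
        data_files = [p for p in data_files if not p.name.startswith("truth_")]
        dialect = "single" if sim_cfg.n_axes == 1 else "triaxial"
        for p in data_files:
            d, _report = read_actigraphy(p, dialect=dialect)
            days.extend(d)
        if not days:
            raise StageError("preprocess produced no complete days")
        days = [scale_counts(d, divisor) for d in days]
        if do_smooth:
            days = [smooth_day(d, pp.get("basis_size", 50)) for d in days]
        segments = segment_days(days, window_min)
        seg_path = out_dir / "segments.csv"
        write_segments(segments, seg_path)
        _record("preprocess", {"segments": seg_path})

        # --- cluster --------------------------------------------------
        cc = config.cluster
        K = cc.get("k", 3)
        H = segments[0].n_axes
        if "wp" in cc or "wa" in cc:
            weights = DistanceWeights(np.atleast_1d(cc["wp"]), np.atleast_1d(cc["wa"]))
        else:
            weights = DistanceWeights.equal(H)
        model = fit_motifs(
            segments,
            K,
            weights,
            seed=seeds["cluster"],
            max_iter=cc.get("max_iter", 50),
            tol=cc.get("tol", 0.0),
            n_restarts=cc.get("n_restarts", 1),
        )
        labels_path = out_dir / "labels.csv"
        pd.DataFrame(
            {
                "subject": [s.subject_id for s in segments],
                "day": [s.day_index for s in segments],
                "window": [s.window_index for s in segments],
                "label": model.labels,
            }
        ).to_csv(labels_path, index=False)
        centers_path = out_dir / "centers.csv"
        rows = []
        for k, cen in enumerate(model.centers):
            for h, ax in enumerate(cen):
                rows.append(
                    pd.DataFrame(
                        {
                            "cluster": k,
                            "axis": h,
                            "minute": np.arange(ax.n_points),
                            "value": ax.values,
                        }
                    )
                )
        pd.concat(rows, ignore_index=True).to_csv(centers_path, index=False, float_format="%.10g")
        _record("cluster", {"labels": labels_path, "centers": centers_path})

        # --- biomarkers -----------------------------------------------
        bc = config.biomarkers
        means = daily_cluster_means(segments, model.labels, K)
        fpca_models = {}
        for k in range(K):
            cluster_means = [m for m in means if m.cluster_id == k]
            fpca_models[k] = fit_fpca(
                cluster_means,
                variance_target=bc.get("variance_target", 0.80),
                n_components=bc.get("fixed_p"),
            )
        table = extract_scores(means, fpca_models)
        truth_subjects = pd.read_csv(sim_dir / "truth_subjects.csv")
        table = table.with_covariates(truth_subjects[["subject", "age_40_69", "male"]])
        table = table.with_outcome(dict(zip(truth_subjects["subject"], truth_subjects["y"])))
        scores_path = out_dir / "biomarkers.csv"
        table.frame.to_csv(scores_path, index=False, float_format="%.10g")
        _record("biomarkers", {"scores": scores_path})

        # --- models ---------------------------------------------------
        mc = config.models
        outputs = {}
        if mc.get("run_association", True):
            assoc = fit_association(table, seed=seeds["models"])
            assoc_path = out_dir / "association.csv"
            pd.DataFrame(
                {
                    "term": assoc.odds_ratios.index,
                    "odds_ratio": assoc.odds_ratios.to_numpy(),
                    "ci_lower": assoc.conf_int["lower"].to_numpy(),
                    "ci_upper": assoc.conf_int["upper"].to_numpy(),
                    "p_value": assoc.p_values.to_numpy(),
                }
            ).to_csv(assoc_path, index=False, float_format="%.6g")
            outputs["association"] = assoc_path
        if mc.get("run_classification", True):
            feats = mc.get("features", "biomarkers+demographics")
            if feats == "baseline":
                report = baseline_classify(table, seed=seeds["models"])
            else:
                report = loso_classify(
                    table,
                    seed=seeds["models"],
                    include_covariates=(feats == "biomarkers+demographics"),
                )
            cls_path = out_dir / "classification.csv"
            report.metrics.reset_index().to_csv(cls_path, index=False, float_format="%.6g")
            outputs["classification"] = cls_path
        _record("models", outputs)
    except (ConfigError, StageError):
        raise
    except Exception as exc:  # short-circuit with a partial manifest
        manifest["error"] = str(exc)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise StageError(f"pipeline stage failed: {exc}") from exc
    return manifest
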