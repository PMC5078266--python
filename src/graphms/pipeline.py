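"""End-to-end orchestration: cohort -> threshold -> metrics -> stats -> SVM.

``run_pipeline`` ties the stages together and writes a run directory:
the per-subject metric table, the CV-versus-tau scan with the chosen
threshold (when tau="auto"), the group-comparison grid, the
classification report, and a machine-readable run manifest (config,
seeds, package version).  All randomness flows from one master seed
through named child streams, so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import TASKS, GridSpec, default_grid, run_task, task_report_table
from .matrices import read_manifest
from .metrics import metrics_table
from .selection import ThresholdScan, metric_cv_curve, select_threshold
from .simulate import CohortConfig, GroupProfile, preset_profiles, sample_cohort
from .stats import compare_all, comparison_grid

logger = logging.getLogger(__name__)

_STREAMS = ("simulation", "folds", "solver")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    ``manifest``: path to a cohort manifest CSV, or None to simulate.
    ``tau``: binarization threshold in [0, 1], or "auto" to run the
    CV-stability selection on the HC group.
    """

    manifest: str | None = None
    simulate: CohortConfig | None = None
    tau: float | str = "auto"
    tasks: tuple[str, ...] = tuple(TASKS)
    feature_sets: tuple = ("all",)
    grid: GridSpec = field(default_factory=default_grid)
    seed: int = 0
    out_dir: str = "graphms_run"

    def __post_init__(self) -> None:
        if self.tau != "auto" and not 0.0 <= float(self.tau) <= 1.0:
            raise ValueError(f"tau must be 'auto' or in [0, 1], got {self.tau}")
        bad = [t for t in self.tasks if t not in TASKS]
        if bad:
            raise ValueError(f"unknown tasks {bad}; valid: {sorted(TASKS)}")


def _child_seeds(seed: int) -> dict[str, int]:
    """Named child streams derived from the master seed (all < 2**31)."""
    root = np.random.SeedSequence(seed)
    return {
        name: int(ss.generate_state(1)[0] % (2**31))
        for name, ss in zip(_STREAMS, root.spawn(len(_STREAMS)))
    }


@dataclass(frozen=True)
class PipelineResult:
    run_dir: Path
    tau: float
    metric_table: pd.DataFrame
    scan: ThresholdScan | None
    comparisons: pd.DataFrame
    reports: pd.DataFrame


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and write its artifacts.

    Returns the in-memory results alongside the run directory, which
    contains metrics.csv, threshold_scan.csv (auto mode),
    group_comparisons.csv, classification.csv, and run_manifest.yaml.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed)

    if config.manifest is not None:
        records = read_manifest(config.manifest)
    else:
        sim = config.simulate or CohortConfig(seed=seeds["simulation"])
        if config.simulate is None:
            logger.info("no cohort given: simulating the preset five-group cohort")
        records = sample_cohort(sim)

    scan = None
    if config.tau == "auto":
        hc = [r.matrix for r in records if r.group == "HC"]
        if len(hc) < 2:
            raise ValueError("tau='auto' needs >= 2 HC subjects for the CV scan")
        scan = metric_cv_curve(hc, seed=seeds["solver"])
        tau = select_threshold(scan)
        scan_df = scan.cv_curves.copy()
        scan_df["mean_cv"] = scan.mean_cv()
        scan_df.to_csv(out / "threshold_scan.csv")
        (out / "chosen_tau.json").write_text(
            json.dumps({"tau": tau, "mean_density": scan.mean_density}) + "\n"
        )
    else:
        tau = float(config.tau)

    table = metrics_table(records, tau, seed=seeds["solver"])
    table.to_csv(out / "metrics.csv", index=False, na_rep="NA")

    comparisons = compare_all(table)
    comparisons.to_csv(out / "group_comparisons.csv", index=False)
    comparison_grid(comparisons).to_csv(out / "group_comparison_grid.csv", na_rep="-")

    reports = []
    present = set(table["group"])
    for task in config.tasks:
        if not set(TASKS[task]) <= present:
            logger.warning("skipping task %s: groups missing from cohort", task)
            continue
        for fs in config.feature_sets:
            reports.append(run_task(table, task, fs, config.grid, seed=seeds["folds"]))
    report_df = task_report_table(reports)
    report_df.to_csv(out / "classification.csv", float_format="%.4f")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "child_seeds": seeds,
        "tau": tau,
        "tasks": list(config.tasks),
        "feature_sets": [list(f) if not isinstance(f, str) else f for f in config.feature_sets],
        "n_subjects": len(records),
        "groups": {g: int((table["group"] == g).sum()) for g in sorted(present)},
    }
    (out / "run_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return PipelineResult(out, tau, table, scan, comparisons, report_df)


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig (and optional simulation block) from YAML."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = None
    if "simulate" in raw:
        s = dict(raw.pop("simulate") or {})
        profiles = preset_profiles()
        for label, overrides in (s.pop("profiles", None) or {}).items():
            base = profiles.get(label) or GroupProfile(label)
            profiles[label] = dataclasses.replace(base, **overrides)
        sim = CohortConfig(profiles=profiles, **{**s})
    grid = default_grid(raw.pop("folds", 10))
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown config keys {sorted(bad)}")
    if "tasks" in raw:
        raw["tasks"] = tuple(raw["tasks"])
    if "feature_sets" in raw:
        raw["feature_sets"] = tuple(
            fs if isinstance(fs, str) else tuple(fs) for fs in raw["feature_sets"]
        )
    return PipelineConfig(simulate=sim, grid=grid, **raw)
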