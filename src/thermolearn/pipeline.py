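"""Pipeline orchestration: simulate -> filter -> fit -> compare -> metrics.

One configured, seeded run writes datasets and belief trajectories as
CSV, fits and group BMS as JSON, a metrics report as JSON, and a run
report (config echo, per-stage seeds, file manifest with SHA-256
checksums) as JSON plus a short human-readable summary.  Every stage
seed is derived from the master seed through a documented splitting
scheme (:func:`thermolearn.synthetic_data.child_seed`), so a fixed
master seed makes the whole run byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior_metrics as bm
from . import inversion as inv
from . import model_comparison as mc
from .learning_models import run_filter
from .synthetic_data import (
    DATASET_COLUMNS,
    AgentSpec,
    BehavioralDataset,
    TaskConfig,
    child_seed,
    default_param_priors,
    generate_cohort,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "read_dataset", "write_dataset"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["trial", "cue", "stimulus", "u", "rated", "prediction"]


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""

    task: TaskConfig = field(default_factory=TaskConfig)
    n_subjects: int = 6
    generating_model: str = "hgf2"
    models: tuple[str, ...] = ("hgf2", "rw")
    out_dir: str = "thermolearn-run"
    seed: int = 0
    n_restarts: int = 4
    bms_samples: int = 10**6
    hgf_mode: str = "canonical"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("model list must be non-empty")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return d


@dataclass
class RunReport:
    """Run manifest: config echo, stage timings/seeds, file checksums,
    and headline tables."""

    config: dict
    stages: dict
    manifest: dict
    headline: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "stages": self.stages,
                 "manifest": self.manifest, "headline": self.headline},
                fh, indent=1, sort_keys=True,
            )


def write_dataset(data: BehavioralDataset, path) -> None:
    """Write a behavioral dataset as CSV (UTF-8, '.' decimal, empty
    field = missing) with a JSON ground-truth sidecar when present."""
    data.to_csv(path)


def read_dataset(path, subject_id: str | None = None) -> BehavioralDataset:
    """Read a behavioral dataset CSV written by :func:`write_dataset`.

    Unknown columns trigger a warning; missing required columns raise an
    error naming them; an empty file is an error.  The ground-truth
    sidecar ``<path>.agent.json`` is restored when present.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path} is empty or not a CSV") from exc
    if df.empty:
        raise ValueError(f"{path} contains no trials")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing required columns: {missing}")
    unknown = [c for c in df.columns if c not in DATASET_COLUMNS]
    if unknown:
        import warnings

        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    for col in DATASET_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[DATASET_COLUMNS]
    df["rated"] = df["rated"].astype(bool)

    agent = None
    sid = subject_id
    sidecar = Path(f"{path}.agent.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        agent = AgentSpec.from_dict(meta["agent"])
        sid = sid or meta.get("subject_id")
    ds = BehavioralDataset(df=df, subject_id=sid or path.stem, agent=agent)
    if not ds.passes_exclusion():
        logger.warning(
            "%s: %.1f%% of choices missing exceeds the 10%% exclusion threshold",
            ds.subject_id, 100 * ds.missing_fraction,
        )
    return ds


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline and write all artifacts to
    ``config.out_dir``; idempotent for a fixed master seed."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    manifest: dict = {}
    headline: dict = {}
    master = config.seed

    def record(path: Path) -> None:
        manifest[str(path.relative_to(out))] = _sha256(path)

    def stage(name):
        stages[name] = {"seed": child_seed(master, name)}
        return time.perf_counter()

    try:
        # --- simulate -----------------------------------------------------
        t0 = stage("simulate")
        cohort = generate_cohort(
            config.n_subjects,
            default_param_priors(config.generating_model),
            config.task,
            seed=stages["simulate"]["seed"],
            model=config.generating_model,
        )
        data_dir = out / "datasets"
        data_dir.mkdir(exist_ok=True)
        for ds in cohort:
            p = data_dir / f"{ds.subject_id}.csv"
            write_dataset(ds, p)
            record(p)
            record(Path(f"{p}.agent.json"))
        stages["simulate"]["elapsed_s"] = time.perf_counter() - t0

        # --- filter -------------------------------------------------------
        t0 = stage("filter")
        traj_dir = out / "trajectories"
        traj_dir.mkdir(exist_ok=True)
        trajectories = []
        for ds in cohort:
            traj = run_filter("hgf2", ds.u,
                              {"mode": config.hgf_mode,
                               **({} if ds.agent is None or ds.agent.model != "hgf2"
                                  else ds.agent.params)})
            trajectories.append(traj)
            p = traj_dir / f"{ds.subject_id}.csv"
            traj.to_csv(p)
            record(p)
        stages["filter"]["elapsed_s"] = time.perf_counter() - t0

        # --- fit ----------------------------------------------------------
        t0 = stage("fit")
        fit_dir = out / "fits"
        fit_dir.mkdir(exist_ok=True)
        fits = {m: [] for m in config.models}
        for i, ds in enumerate(cohort):
            for m in config.models:
                fit = inv.fit_map(
                    ds, m, n_restarts=config.n_restarts,
                    seed=child_seed(stages["fit"]["seed"], f"{i}-{m}"),
                    allow_excluded=True,
                )
                fits[m].append(fit)
                p = fit_dir / f"{ds.subject_id}-{m}.json"
                fit.to_json(p)
                record(p)
        ev = inv.evidence_matrix(fits)
        p = out / "evidence.csv"
        ev.to_csv(p)
        record(p)
        stages["fit"]["elapsed_s"] = time.perf_counter() - t0

        # --- compare ------------------------------------------------------
        t0 = stage("compare")
        bms = mc.rfx_bms(ev, n_samples=config.bms_samples,
                         seed=stages["compare"]["seed"])
        p = out / "bms.json"
        bms.to_json(p)
        record(p)
        headline["bms_expected_frequencies"] = dict(
            zip(bms.model_names, [float(x) for x in bms.expected_frequencies]))
        headline["bms_exceedance"] = dict(
            zip(bms.model_names, [float(x) for x in bms.exceedance]))
        headline["bms_winner"] = bms.winner
        stages["compare"]["elapsed_s"] = time.perf_counter() - t0

        # --- metrics ------------------------------------------------------
        t0 = stage("metrics")
        report = bm.compute_metrics(cohort, trajectories)
        p = out / "metrics.json"
        report.to_json(p)
        record(p)
        headline["group_metrics"] = report.group
        stages["metrics"]["elapsed_s"] = time.perf_counter() - t0
    except Exception as exc:
        partial = RunReport(config=config.to_dict(), stages=stages,
                            manifest=manifest, headline={"aborted": repr(exc)})
        partial.to_json(out / "report.partial.json")
        raise RuntimeError(
            f"pipeline aborted during stage {list(stages)[-1]!r}; partial "
            f"outputs preserved in {out}"
        ) from exc

    run_report = RunReport(config=config.to_dict(), stages=stages,
                           manifest=manifest, headline=headline)
    run_report.to_json(out / "report.json")
    with open(out / "report.txt", "w") as fh:
        fh.write(_format_report(run_report))
    return run_report


def _format_report(r: RunReport) -> str:
    lines = ["thermolearn run report", "======================", ""]
    lines.append(f"subjects: {r.config['n_subjects']}  "
                 f"models: {', '.join(r.config['models'])}  "
                 f"seed: {r.config['seed']}")
    for name, s in r.stages.items():
        lines.append(f"  stage {name:<9} seed={s['seed']:<11} "
                     f"elapsed={s.get('elapsed_s', float('nan')):.2f}s")
    if "bms_exceedance" in r.headline:
        lines.append("")
        lines.append("group BMS exceedance probabilities:")
        for m, x in r.headline["bms_exceedance"].items():
            lines.append(f"  {m:<6} {x:.3f}")
        lines.append(f"winning model: {r.headline['bms_winner']}")
    if "group_metrics" in r.headline:
        lines.append("")
        lines.append("group metrics (means):")
        for k, v in sorted(r.headline["group_metrics"].items()):
            if isinstance(v, float):
                lines.append(f"  {k:<32} {v: .4f}")
    lines.append("")
    lines.append(f"{len(r.manifest)} files written (SHA-256 in report.json)")
    return "\n".join(lines) + "\n"
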