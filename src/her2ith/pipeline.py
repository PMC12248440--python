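"""End-to-end orchestration: simulate/load -> fit -> classify -> report.

A run is described by a :class:`RunConfig` with exactly one input mode:

* ``preset`` — a named built-in cohort (``"paper97"`` for the assigned
  97-tumor reference cohort, ``"synthetic"`` for a sampled cohort with
  the configured size/prevalence);
* ``cohort_csv`` — a cohort CSV (with a ``her2_counts_file`` column of
  per-tumor cell TSVs, resolved relative to the CSV);
* ``histogram_dir`` — a directory of histogram TSVs (classification only,
  no covariates, so no association report).

Every run writes, under ``out_dir``: the labeled cohort CSV, per-tumor fit
and decision JSONs, the association report (JSON), a run log, and an echo
of the fully defaulted configuration including seed and package version —
re-running with the same configuration reproduces the outputs byte for
byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import CohortClassification, ITHOptions, classify_cohort
from .gmm import FitOptions
from .histogram import histogram_from_cells, read_cells_tsv, read_histogram_tsv
from .presets import paper97
from .stats import Table2Report, build_table2, pcr_rate
from .synth import CohortSpec, CohortTable, simulate_cohort

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline",
           "PipelineResult"]

logger = logging.getLogger("her2ith")


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


@dataclass
class RunConfig:
    """Fully defaulted pipeline configuration (one input mode only)."""

    # input modes
    preset: str | None = None
    cohort_csv: str | None = None
    histogram_dir: str | None = None
    # synthetic-cohort parameters (preset == "synthetic")
    n_tumors: int = 97
    prevalence_hh: float = 18 / 97
    n_cells: int = 60
    # fitting / classification
    sigma_floor: float = 0.25
    tol: float = 1e-8
    max_iter: int = 500
    n_starts: int = 5
    tau_low: float = 2.0
    tau_pos: float = 2.0
    pi_min: float = 0.10
    # run plumbing
    seed: int = 0
    out_dir: str = "her2ith_run"
    log_level: str = "INFO"

    def fit_options(self) -> FitOptions:
        return FitOptions(sigma_floor=self.sigma_floor, tol=self.tol,
                          max_iter=self.max_iter, n_starts=self.n_starts,
                          seed=self.seed)

    def ith_options(self) -> ITHOptions:
        return ITHOptions(tau_low=self.tau_low, tau_pos=self.tau_pos,
                          pi_min=self.pi_min)


_KNOWN_PRESETS = ("paper97", "synthetic")


def validate_config(mapping: dict) -> RunConfig:
    """Type- and range-check a raw config mapping; fill and echo defaults."""
    errors: list[str] = []
    known = {f.name: f for f in dataclasses.fields(RunConfig)}
    for key in mapping:
        if key not in known:
            errors.append(f"unknown key {key!r}")
    cfg = RunConfig(**{k: v for k, v in mapping.items() if k in known})

    modes = [m for m in ("preset", "cohort_csv", "histogram_dir")
             if getattr(cfg, m) is not None]
    if len(modes) != 1:
        errors.append(
            "exactly one input mode required (preset | cohort_csv | "
            f"histogram_dir), got {modes or 'none'}"
        )
    if cfg.preset is not None and cfg.preset not in _KNOWN_PRESETS:
        errors.append(f"unknown preset {cfg.preset!r}; choose from {_KNOWN_PRESETS}")
    if cfg.cohort_csv is not None and not Path(cfg.cohort_csv).is_file():
        errors.append(f"cohort_csv not found: {cfg.cohort_csv}")
    if cfg.histogram_dir is not None and not Path(cfg.histogram_dir).is_dir():
        errors.append(f"histogram_dir not found: {cfg.histogram_dir}")
    if cfg.n_tumors < 1:
        errors.append("n_tumors must be >= 1")
    if not 0.0 <= cfg.prevalence_hh <= 1.0:
        errors.append("prevalence_hh must lie in [0, 1]")
    if cfg.n_cells < 20:
        errors.append("n_cells must be >= 20")
    if cfg.sigma_floor <= 0:
        errors.append("sigma_floor must be positive")
    if cfg.tol <= 0:
        errors.append("tol must be positive")
    if cfg.max_iter < 1 or cfg.n_starts < 1:
        errors.append("max_iter and n_starts must be >= 1")
    if cfg.tau_low <= 0 or cfg.tau_pos <= 0:
        errors.append("tau_low and tau_pos must be positive")
    if not 0.0 < cfg.pi_min <= 0.5:
        errors.append("pi_min must lie in (0, 0.5]")
    if cfg.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
        errors.append(f"unknown log_level {cfg.log_level!r}")
    if int(cfg.seed) != cfg.seed:
        errors.append("seed must be an integer")
    if errors:
        raise ConfigError(errors)
    return cfg


@dataclass
class PipelineResult:
    """Paths and objects produced by one run."""

    config: RunConfig
    out_dir: Path
    classification: CohortClassification
    report: Table2Report | None
    report_path: Path | None
    labeled_csv: Path


def _load_cohort_csv(path: str) -> CohortTable:
    csv_path = Path(path)
    table = pd.read_csv(csv_path, dtype={"grade": str})
    if "tumor_id" not in table.columns:
        raise ValueError(f"{path}: missing tumor_id column")
    cells = {}
    if "her2_counts_file" in table.columns:
        for _, row in table.iterrows():
            cells[row["tumor_id"]] = read_cells_tsv(
                csv_path.parent / row["her2_counts_file"]
            )
        table = table.drop(columns=["her2_counts_file"])
    return CohortTable(table=table, cells=cells, specs={})


def _load_histogram_dir(path: str) -> dict:
    """Histogram-only input: tumor id (file stem) -> SignalHistogram."""
    files = sorted(Path(path).glob("*.tsv"))
    if not files:
        raise ValueError(f"no .tsv histograms in {path}")
    return {f.stem: read_histogram_tsv(f) for f in files}


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> PipelineResult:
    echo = dataclasses.asdict(config)
    echo["package_version"] = __version__
    (out / "config_echo.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))

    stage = "input"
    try:
        hist_only = None
        if config.preset == "paper97":
            logger.info("building paper97 preset cohort (seed=%d)", config.seed)
            cohort = paper97(seed=config.seed, n_cells=config.n_cells)
        elif config.preset == "synthetic":
            logger.info("simulating cohort n=%d (seed=%d)",
                        config.n_tumors, config.seed)
            cohort = simulate_cohort(CohortSpec(
                n_tumors=config.n_tumors, prevalence_hh=config.prevalence_hh,
                seed=config.seed, n_cells=config.n_cells))
        elif config.cohort_csv is not None:
            logger.info("loading cohort CSV %s", config.cohort_csv)
            cohort = _load_cohort_csv(config.cohort_csv)
        else:
            logger.info("loading histogram directory %s", config.histogram_dir)
            cohort = None
            hist_only = _load_histogram_dir(config.histogram_dir)

        stage = "classify"
        fit_opts, ith_opts = config.fit_options(), config.ith_options()
        if hist_only is not None:
            from .classify import classify_ith

            rows, results = [], {}
            for tid, hist in hist_only.items():
                res = classify_ith(hist, fit_opts, ith_opts)
                results[tid] = res
                rows.append({
                    "tumor_id": tid, "ith_label": res.label,
                    "chosen_k": res.chosen_k, "overall_mean": res.overall_mean,
                })
            table = pd.DataFrame(rows)
            classification = CohortClassification(
                table=table, results=results,
                prevalence=float((table["ith_label"] == "HH").mean()),
                group_mean_fish_ratio={}, excluded=[])
        else:
            classification = classify_cohort(cohort, fit_opts, ith_opts)
        for tid, reason in classification.excluded:
            logger.warning("tumor %s excluded: %s", tid, reason)
        logger.info("classified %d tumors, HH prevalence %.3f",
                    len(classification.table), classification.prevalence)

        stage = "persist-fits"
        fits_dir = out / "fits"
        fits_dir.mkdir(exist_ok=True)
        for tid, res in classification.results.items():
            payload = res.to_dict()
            payload["fit_k1"] = res.selection.fit_k1.to_dict()
            payload["fit_k2"] = res.selection.fit_k2.to_dict()
            (fits_dir / f"{tid}.json").write_text(json.dumps(payload, indent=2))

        stage = "stats"
        labeled_csv = out / "labeled_cohort.csv"
        classification.table.to_csv(labeled_csv, index=False)
        report = None
        report_path = None
        if "pcr" in classification.table.columns:
            report = build_table2(classification.table)
            report_path = out / "report.json"
            payload = json.loads(report.to_json())
            payload["prevalence_hh"] = classification.prevalence
            payload["group_mean_fish_ratio"] = classification.group_mean_fish_ratio
            payload["pcr_rate_by_label"] = {
                label: pcr_rate(int(sub["pcr"].sum()), len(sub)).percent
                for label, sub in classification.table.groupby("ith_label")
            }
            payload["seed"] = config.seed
            payload["package_version"] = __version__
            report_path.write_text(json.dumps(payload, indent=2))
            (out / "report.txt").write_text(report.summary() + "\n")
        else:
            logger.info("no outcome column; skipping association report")
    except Exception:
        logger.exception("pipeline failed in stage %r", stage)
        raise

    return PipelineResult(config=config, out_dir=out,
                          classification=classification, report=report,
                          report_path=report_path, labeled_csv=labeled_csv)
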