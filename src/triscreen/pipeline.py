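"""End-to-end orchestration: simulate/ingest -> normalize -> score -> report.

Each stage consumes and produces plain CSV, so stages compose through
files exactly as the monolithic :func:`run` executes them in memory;
all randomness flows from config seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import mom as mom_mod
from . import risk as risk_mod
from .evaluation import evaluate_all, group_comparison
from .markers import PANEL, mom_column
from .synthetic import CohortSpec, default_cohort_spec, generate_cohort

logger = logging.getLogger(__name__)

#: Schema version written as a comment line at the top of cohort CSVs.
SCHEMA_VERSION = "triscreen-cohort-v1"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a run needs; serializable and replayable.

    ``cohort_csv`` takes precedence over ``cohort_spec``; when both are
    unset the reference 40+40 synthetic spec is used.  ``median_models``
    selects ``"default"`` (published AFP-L2 GA curve + weight
    hyperbola), ``"identity"`` (no adjustment; appropriate when the
    input is already adjusted MoM) or a per-marker mapping
    ``{marker: {ga_coefficients: [...], weight_a: ..., weight_b: ...}}``.
    """

    cohort_csv: str | None = None
    cohort_spec: dict | None = None
    seed: int = 0
    emit_raw: bool = False
    median_models: str | dict = "identity"
    convention: str = "product"
    markers: list[str] | None = None
    log_transform: bool = True
    ridge_factor: float = 1e-8
    cv: int | None = None
    age_params: dict = field(default_factory=dict)
    n_bootstrap: int = 2000
    nri_categories: list[float] | None = None
    score_on_adjusted: bool = False
    outdir: str = "triscreen_run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def resolve_median_models(spec: str | dict):
    if spec == "default":
        return mom_mod.default_median_models()
    if spec == "identity":
        return mom_mod.identity_median_models()
    if isinstance(spec, dict):
        models = mom_mod.identity_median_models()
        for marker, cfg in spec.items():
            if marker not in PANEL:
                raise ValueError(f"median model for unknown marker {marker!r}")
            ga = mom_mod.GAMedianModel(tuple(cfg.get("ga_coefficients", (0,) * 5)))
            wt = mom_mod.WeightMedianModel(
                a=cfg.get("weight_a", 1.0), b=cfg.get("weight_b", 0.0)
            )
            models[marker] = (ga, wt)
        return models
    raise ValueError(f"median_models must be 'default', 'identity' or a mapping")


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    """Write a cohort CSV with the schema-version comment header."""
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        frame.to_csv(fh, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    if frame.empty:
        raise ValueError(f"cohort file {path} contains no records")
    required = {"subject_id", "group"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"cohort file {path} missing columns: {sorted(missing)}")
    return frame


# -- stages -----------------------------------------------------------


def simulate_stage(config: RunConfig) -> pd.DataFrame:
    try:
        if config.cohort_spec is not None:
            spec = CohortSpec.from_dict(config.cohort_spec)
        else:
            spec = default_cohort_spec()
        cohort = generate_cohort(spec, seed=config.seed, emit_raw=config.emit_raw)
    except ValueError as exc:
        raise PipelineError("simulate", str(exc)) from exc
    logger.info("simulate: %d records", len(cohort))
    return cohort


def ingest_stage(config: RunConfig) -> pd.DataFrame:
    try:
        cohort = read_cohort_csv(config.cohort_csv)
    except (ValueError, OSError, pd.errors.EmptyDataError) as exc:
        raise PipelineError("ingest", str(exc)) from exc
    logger.info("ingest: %d records from %s", len(cohort), config.cohort_csv)
    return cohort


def normalize_stage(cohort: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    try:
        transformer = mom_mod.MoMTransformer(
            median_models=resolve_median_models(config.median_models),
            convention=config.convention,
        ).fit(cohort)
        out = transformer.transform(cohort)
    except ValueError as exc:
        raise PipelineError("normalize", str(exc)) from exc
    logger.info("normalize: %d records", len(out))
    return out


def score_stage(cohort: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    try:
        models = None
        if config.markers is not None:
            models = risk_mod.enumerate_models(config.markers)
        scores = risk_mod.score_cohort(
            cohort,
            models=models,
            age_params=risk_mod.AgeRiskParams(**config.age_params),
            log_transform=config.log_transform,
            use_adjusted=config.score_on_adjusted,
            ridge_factor=config.ridge_factor,
            cv=config.cv,
            random_state=config.seed,
        )
    except (ValueError, KeyError) as exc:
        raise PipelineError("score", str(exc)) from exc
    logger.info(
        "score: %d records x %d models", cohort.shape[0],
        scores["model_id"].nunique(),
    )
    return scores


def evaluate_stage(scores: pd.DataFrame, cohort: pd.DataFrame, config: RunConfig):
    try:
        labels = dict(zip(cohort["subject_id"], cohort["group"]))
        report = evaluate_all(
            scores,
            labels,
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
            nri_categories=config.nri_categories,
        )
        report.group_comparison = group_comparison(cohort)
    except (ValueError, KeyError) as exc:
        raise PipelineError("evaluate", str(exc)) from exc
    report.config = {**report.config, **config.to_dict()}
    logger.info(
        "evaluate: %d models, %d improvement pairs",
        len(report.discrimination), len(report.improvement),
    )
    return report


def run(config: RunConfig):
    """Execute the full pipeline and write all artifacts under outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.cohort_csv is not None:
        cohort = ingest_stage(config)
    else:
        cohort = simulate_stage(config)
        write_cohort_csv(cohort, outdir / "cohort.csv")

    cohort = normalize_stage(cohort, config)
    write_cohort_csv(cohort, outdir / "cohort_mom.csv")

    scores = score_stage(cohort, config)
    scores.to_csv(outdir / "scores.csv", index=False)

    report = evaluate_stage(scores, cohort, config)
    report.write(outdir / "report")
    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return report
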