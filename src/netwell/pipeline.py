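"""End-to-end orchestration: config, staged pipeline, reports, CLI.

A run directory is populated stage by stage
(simulate? -> ingest -> networks -> features -> correlate -> predict);
every stage reads only the artifacts of earlier stages from the run
directory, so any stage can be re-run without recomputing its predecessors.
All randomness flows from the single root seed in the config.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior_features import (
    BEHAVIOR_FEATURES,
    daily_table_from_minutes,
    weekly_behavior_table,
)
from .correlation_analysis import (
    cohort_pair_matrix,
    count_pairs,
    high_low_tests,
    matrix_as_table,
    per_person_counts,
)
from .data_model import (
    ORDINAL_RANGES,
    StudyConfig,
    WELLNESS_ATTRIBUTES,
    minutes_frame,
    read_events,
    read_minutes,
    read_survey,
    survey_frame,
    write_events,
    write_minutes,
    write_survey,
)
from .network_builder import structural_feature_table, structure_wide
from .synthetic_cohort import (
    GeneratorConfig,
    generate_cohort,
    generate_comm_log,
    generate_daily_table,
    generate_wearable_stream,
    write_ground_truth,
)
from .wellness_prediction import (
    F1Report,
    relative_improvement,
    random_baseline,
    run_prediction,
)

logger = logging.getLogger("netwell")

_DAILY_COLUMNS = [
    "participant", "date", "week", "worn_minutes", "daily_steps",
    "sedentary", "lightly", "fairly", "very", "hr_sum", "hr_sumsq", "hr_count",
]


@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one of ``simulate`` or the
    three input paths must be present."""

    out_dir: Path
    seed: int = 0
    simulate: GeneratorConfig | None = None
    events_path: Path | None = None
    minutes_path: Path | None = None
    survey_path: Path | None = None
    study: StudyConfig | None = None
    taus: tuple = (0.5, 0.7)
    central_stat: str = "mean"
    correction: str = "fdr_bh"
    grid: str = "small"
    weight_mode: str = "scalar"
    split_unit: str = "participant"
    attributes: tuple = WELLNESS_ATTRIBUTES
    feature_sets: tuple = ("baseline", "network_only", "full")

    def __post_init__(self) -> None:
        paths = (self.events_path, self.minutes_path, self.survey_path)
        have_paths = all(p is not None for p in paths)
        if self.simulate is None and not have_paths:
            raise ValueError("config needs either a simulate block or all three input paths")
        if self.simulate is not None and any(p is not None for p in paths):
            raise ValueError("config must not mix a simulate block with input paths")
        if self.simulate is None and self.study is None:
            raise ValueError("a study block (study_start, n_weeks, roster) is required "
                             "when reading real inputs")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        if sim is not None:
            if "study_start" in sim:
                sim["study_start"] = dt.date.fromisoformat(str(sim["study_start"]))
            sim = GeneratorConfig(**sim)
        study = raw.pop("study", None)
        if study is not None:
            study["study_start"] = dt.date.fromisoformat(str(study["study_start"]))
            study["roster"] = frozenset(study.get("roster", ()))
            study = StudyConfig(**study)
        for key in ("events_path", "minutes_path", "survey_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        for key in ("taus", "attributes", "feature_sets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulate=sim, study=study, **raw)

    def study_config(self) -> StudyConfig:
        return self.simulate.study_config() if self.simulate is not None else self.study


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> None:
    """Write the synthetic study's CSVs and ground truth into the run dir.

    The minute-level CSV is only materialised for small cohorts (the daily
    aggregate table carries the same information for the pipeline).
    """
    gen = config.simulate
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    profiles, surveys = generate_cohort(gen)
    events = generate_comm_log(profiles, gen)
    daily = generate_daily_table(profiles, gen)
    write_events(events, out / "comm_events.csv")
    write_survey(surveys, out / "survey.csv")
    d = daily.copy()
    d["date"] = d["date"].astype(str)
    d[_DAILY_COLUMNS].to_csv(out / "daily_wearable.csv", index=False)
    write_ground_truth(profiles, gen, out / "ground_truth.json")
    if gen.n_participants * gen.n_weeks <= 100:
        write_minutes(generate_wearable_stream(profiles, gen), out / "wearable_minutes.csv")
    logger.info("simulate: %d participants, %d events, %d participant-days",
                len(profiles), len(events), len(daily))


def stage_ingest(config: RunConfig) -> None:
    """Normalise external inputs into the run-dir artifact formats."""
    study = config.study_config()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    if config.simulate is not None:
        return  # simulate already wrote canonical artifacts
    events = read_events(config.events_path, study)
    write_events(events, out / "comm_events.csv")
    minutes = read_minutes(config.minutes_path, study)
    daily = daily_table_from_minutes(minutes_frame(minutes), study)
    d = daily.copy()
    d["date"] = d["date"].astype(str)
    d[_DAILY_COLUMNS].to_csv(out / "daily_wearable.csv", index=False)
    write_survey(read_survey(config.survey_path), out / "survey.csv")


def _read_stage_events(config: RunConfig):
    return read_events(config.out_dir / "comm_events.csv", config.study_config())


def _read_stage_daily(config: RunConfig) -> pd.DataFrame:
    daily = pd.read_csv(config.out_dir / "daily_wearable.csv",
                        dtype={"participant": str})
    daily["date"] = pd.to_datetime(daily["date"]).dt.date
    return daily


def stage_networks(config: RunConfig) -> pd.DataFrame:
    study = config.study_config()
    features = structural_feature_table(_read_stage_events(config), study)
    features.to_csv(config.out_dir / "structure_features.csv", index=False)
    return features


def stage_features(config: RunConfig) -> pd.DataFrame:
    """Merge weekly behavior, weekly structure, gender and labels into the
    participant-week feature table."""
    study = config.study_config()
    out = config.out_dir
    weekly = weekly_behavior_table(_read_stage_daily(config), study)
    weekly.to_csv(out / "weekly_behavior.csv", index=False)
    structure = structure_wide(pd.read_csv(out / "structure_features.csv",
                                           dtype={"participant": str}))
    survey = pd.read_csv(out / "survey.csv", dtype={"participant": str})
    table = weekly.merge(structure, on=["participant", "week"], how="outer")
    table = table.merge(survey, on="participant", how="left")
    table = table.sort_values(["participant", "week"]).reset_index(drop=True)
    table.to_csv(out / "feature_table.csv", index=False)
    return table


def _read_feature_table(config: RunConfig) -> pd.DataFrame:
    return pd.read_csv(config.out_dir / "feature_table.csv", dtype={"participant": str})


def stage_correlate(config: RunConfig) -> dict:
    out = config.out_dir
    table = _read_feature_table(config)
    matrix = cohort_pair_matrix(table, stat=config.central_stat)
    matrix.to_csv(out / "correlation_matrix.csv", index=False)
    matrix_as_table(matrix).to_csv(out / "table_cohort_ncc.csv")

    counts = per_person_counts(table, tau=config.taus[0])
    pair_rows = [
        {"structure_feature": s, "behavior_feature": b, "n_participants": c}
        for (s, b), c in counts.pair_counts.items()
    ]
    pd.DataFrame(pair_rows).to_csv(out / "table_person_pair_counts.csv", index=False)
    pct = counts.percentages()
    summary_rows = [
        {
            "behavior_feature": b,
            **{f"{k}_count": v for k, v in counts.behavior_counts[b].items()},
            **{f"{k}_pct": v for k, v in pct[b].items()},
        }
        for b in counts.behavior_counts
    ]
    pd.DataFrame(summary_rows).to_csv(out / "table_person_summary.csv", index=False)

    tests = high_low_tests(table, stat=config.central_stat, method=config.correction)
    pd.DataFrame([dataclasses.asdict(t) for t in tests]).to_csv(
        out / "highlow_tests.csv", index=False
    )
    summary = {
        "pair_counts": {str(tau): count_pairs(matrix, tau) for tau in config.taus},
        "n_significant_highlow": int(sum(t.significant for t in tests)),
        "n_person_counted": counts.denominator,
    }
    (out / "correlation_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def make_prediction_table(reports: dict[str, F1Report], random_report: F1Report, K: int) -> pd.DataFrame:
    """Assemble the prediction report table for one attribute.

    Rows in fixed order: random baseline, behavior baseline, network-only,
    full, improvement.  The improvement row is recomputed from the display-precision
    (2-decimal) baseline and full rows, so the table is internally consistent
    at its own display precision.
    """
    for fs in ("baseline", "network_only", "full"):
        if fs not in reports:
            raise ValueError(f"missing feature-set report {fs!r}")
    level_cols = [f"Level{j}" for j in range(1, K + 1)]
    rows = {
        "random generation baseline": random_report.as_row(),
        "gender + health behavior data": reports["baseline"].as_row(),
        "social network structure": reports["network_only"].as_row(),
        "gender + health behavior data + social network": reports["full"].as_row(),
    }
    table = pd.DataFrame(rows).T.reindex(columns=["F1", *level_cols]).round(2)
    improvement = {}
    for col in table.columns:
        base = table.loc["gender + health behavior data", col]
        full = table.loc["gender + health behavior data + social network", col]
        improvement[col] = (
            float(relative_improvement(base, full)) if base > 0 else np.nan
        )
    table.loc["improvement"] = improvement
    return table


def stage_predict(config: RunConfig) -> dict:
    out = config.out_dir
    table = _read_feature_table(config)
    results: dict[str, dict] = {}
    card: dict[str, dict] = {}
    for attribute in config.attributes:
        K = ORDINAL_RANGES[attribute][1]
        reports: dict[str, F1Report] = {}
        attr_card: dict[str, dict] = {}
        y_test_ref = None
        for fs in config.feature_sets:
            res = run_prediction(
                table, attribute, fs,
                seed=config.seed, grid=config.grid,
                weight_mode=config.weight_mode, split_unit=config.split_unit,
            )
            reports[fs] = res.report
            attr_card[fs] = {
                "selected": [t.name for t in res.model.classifiers],
                "cv_accuracy": res.cv_accuracy,
                "weights": res.model.weights.tolist(),
                "hyperparameters": {t.name: t.best_params for t in res.model.classifiers},
            }
            y_test_ref = res.report.support
        y_pseudo = np.repeat(
            list(y_test_ref.keys()), list(y_test_ref.values())
        )
        _, random_report = random_baseline(y_pseudo, K, seed=config.seed)
        t6 = make_prediction_table(reports, random_report, K)
        t6.to_csv(out / f"prediction_report_{attribute}.csv")
        results[attribute] = {
            fs: {"macro_f1": r.overall, "per_level": r.per_level}
            for fs, r in reports.items()
        }
        card[attribute] = attr_card
    (out / "model_card.json").write_text(json.dumps(card, indent=1))
    (out / "prediction_summary.json").write_text(json.dumps(results, indent=1))
    return results


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage in order and write run metadata; returns the run
    directory."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    if config.simulate is not None:
        stage_simulate(config)
    else:
        stage_ingest(config)
    stage_networks(config)
    stage_features(config)
    corr = stage_correlate(config)
    pred = stage_predict(config)
    meta = {
        "netwell_version": __version__,
        "seed": config.seed,
        "config": {
            k: str(v) for k, v in dataclasses.asdict(config).items() if v is not None
        },
        "correlation_summary": corr,
        "prediction_summary": pred,
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=1))
    return out


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

_STAGES = {
    "simulate": stage_simulate,
    "ingest": stage_ingest,
    "networks": stage_networks,
    "features": stage_features,
    "correlate": stage_correlate,
    "predict": stage_predict,
}


@click.group()
@click.version_option(__version__)
def cli() -> None:
    """Weekly communication networks, wearable behavior features and
    network-driven wellness prediction."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")


def _stage_command(name: str):
    @cli.command(name=name)
    @click.option("--config", "config_path", required=True,
                  type=click.Path(exists=True), help="Run config YAML.")
    def _cmd(config_path: str) -> None:
        config = RunConfig.from_yaml(config_path)
        try:
            _STAGES[name](config)
        except Exception as err:  # noqa: BLE001 - stage name in exit message
            raise click.ClickException(f"stage {name!r} failed: {err}") from err

    _cmd.__doc__ = f"Run the {name} stage against the configured run directory."
    return _cmd


for _name in _STAGES:
    _stage_command(_name)


@cli.command(name="run-all")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
def run_all(config_path: str) -> None:
    """Run every stage in order."""
    config = RunConfig.from_yaml(config_path)
    out = run_pipeline(config)
    click.echo(f"run complete: {out}")


@cli.command(name="report")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
def report(config_path: str) -> None:
    """Print the run's summary JSONs."""
    config = RunConfig.from_yaml(config_path)
    for name in ("correlation_summary.json", "prediction_summary.json"):
        path = config.out_dir / name
        if path.exists():
            click.echo(path.read_text())
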