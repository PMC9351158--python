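"""Full-factorial simulation driver.

Builds the scenario grid (family x sample size x dispersion x zero
proportion), runs the replication loop with per-replication derived
seeds, fits the model roster to every generated dataset, aggregates the
convergence/AIC/BIC/MAE metrics, and renders result tables.  Runs are
fully reproducible from the base seed and resumable: a cell whose
record file already exists in the output directory is loaded, not
recomputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datagen import (
    DEFAULT_BETA,
    DISPERSIONS,
    SAMPLE_SIZES,
    ZERO_PROPS,
    ScenarioSpec,
    generate_scenario_dataset,
    replication_seed,
)
from .evaluation import ReplicationRecord, ScenarioSummary, mae, summarize
from .fitting import ModelSpec, fit, predict_mean
from .likelihoods import FAMILIES

__all__ = ["StudyConfig", "build_grid", "run_study", "render_tables", "summaries_frame"]

_RECORD_COLS = [
    "scenario_id", "replication", "model", "converged",
    "aic", "bic", "mae", "seed", "failure_reason",
]


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce one simulation study."""

    families: tuple = FAMILIES
    sample_sizes: tuple = SAMPLE_SIZES
    dispersions: tuple = DISPERSIONS
    zero_props: tuple = ZERO_PROPS
    replications: int = 1000
    base_seed: int = 20220804
    beta: tuple = DEFAULT_BETA
    models: tuple = FAMILIES  # fitted-model roster
    zero_covariates: str = "intercept_only"  # zero-part policy for zi fits
    mae_reference: str = "true_mean"  # or "observed"
    output_dir: str | None = None

    def __post_init__(self):
        for fam in tuple(self.families) + tuple(self.models):
            if fam not in FAMILIES:
                raise ValueError(f"unknown family {fam!r}")
        for name, vals in (
            ("families", self.families), ("sample_sizes", self.sample_sizes),
            ("dispersions", self.dispersions), ("zero_props", self.zero_props),
            ("models", self.models),
        ):
            if not tuple(vals):
                raise ValueError(f"empty factor list: {name}")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if self.mae_reference not in ("true_mean", "observed"):
            raise ValueError("mae_reference must be 'true_mean' or 'observed'")

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("families", "sample_sizes", "dispersions", "zero_props", "models", "beta"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def build_grid(config: StudyConfig) -> list[ScenarioSpec]:
    """Cross-product of factors per family, in deterministic order.

    poisson: sizes only; nb: sizes x dispersions; zip: sizes x zero
    proportions; zinb: sizes x dispersions x zero proportions.
    """
    grid = []
    for fam in config.families:
        disps = tuple(config.dispersions) if fam in ("nb", "zinb") else (None,)
        zeros = tuple(config.zero_props) if fam in ("zip", "zinb") else (None,)
        for n in config.sample_sizes:
            for d in disps:
                for z in zeros:
                    grid.append(
                        ScenarioSpec(
                            family=fam, n=int(n), dispersion=d, zero_prop=z,
                            replications=config.replications,
                            base_seed=config.base_seed,
                        )
                    )
    return grid


def _roster(config: StudyConfig) -> list[ModelSpec]:
    specs = []
    for fam in config.models:
        if fam in ("zip", "zinb"):
            specs.append(ModelSpec(family=fam, zero_covariates=config.zero_covariates))
        else:
            specs.append(ModelSpec(family=fam))
    return specs


def _run_cell(scenario: ScenarioSpec, config: StudyConfig, roster) -> list[ReplicationRecord]:
    records = []
    for r in range(scenario.replications):
        data = generate_scenario_dataset(scenario, r, beta=config.beta)
        seed = replication_seed(scenario.base_seed, scenario.scenario_id, r)
        for spec in roster:
            try:
                result = fit(spec, data)
            except Exception as exc:  # fitting contract: capture, never abort
                records.append(
                    ReplicationRecord(
                        scenario_id=scenario.scenario_id, replication=r,
                        model=spec.family, converged=False, seed=seed,
                        failure_reason=f"error:{type(exc).__name__}",
                    )
                )
                continue
            if result.converged:
                ref = data.true_mean if config.mae_reference == "true_mean" else data.y
                err = mae(ref, predict_mean(result))
                records.append(
                    ReplicationRecord(
                        scenario_id=scenario.scenario_id, replication=r,
                        model=spec.family, converged=True,
                        aic=result.aic, bic=result.bic, mae=err, seed=seed,
                    )
                )
            else:
                records.append(
                    ReplicationRecord(
                        scenario_id=scenario.scenario_id, replication=r,
                        model=spec.family, converged=False, seed=seed,
                        failure_reason=result.failure_reason,
                    )
                )
    return records


def _records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=_RECORD_COLS)


def _frame_to_records(df: pd.DataFrame) -> list[ReplicationRecord]:
    out = []
    for row in df.itertuples(index=False):
        conv = bool(row.converged)
        out.append(
            ReplicationRecord(
                scenario_id=row.scenario_id, replication=int(row.replication),
                model=row.model, converged=conv,
                aic=float(row.aic) if conv else None,
                bic=float(row.bic) if conv else None,
                mae=float(row.mae) if conv else None,
                seed=int(row.seed) if not pd.isna(row.seed) else None,
                failure_reason=None if pd.isna(row.failure_reason) else row.failure_reason,
            )
        )
    return out


def run_study(config: StudyConfig, progress: bool = False):
    """Run the full study; returns (summaries, records).

    With `config.output_dir` set, per-cell record CSVs and a combined
    summary CSV are written; completed cells are skipped on rerun.
    Individual fit failures become non-converged records and never
    abort the study.
    """
    out = Path(config.output_dir) if config.output_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    roster = _roster(config)
    grid = build_grid(config)
    all_records: list[ReplicationRecord] = []
    summaries: list[ScenarioSummary] = []
    log_path = out / "study_log.jsonl" if out is not None else None

    for i, scenario in enumerate(grid):
        cell_path = out / f"records_{scenario.scenario_id}.csv" if out is not None else None
        if cell_path is not None and cell_path.exists():
            records = _frame_to_records(
                pd.read_csv(cell_path, float_precision="round_trip")
            )
        else:
            records = _run_cell(scenario, config, roster)
            if cell_path is not None:
                # %.17g keeps the metrics bit-exact across a resume round-trip
                _records_to_frame(records).to_csv(cell_path, index=False, float_format="%.17g")
        all_records.extend(records)
        for spec in roster:
            group = [r for r in records if r.model == spec.family]
            summaries.append(summarize(group))
        if progress:
            print(f"[{i + 1}/{len(grid)}] {scenario.scenario_id} done", flush=True)
        if log_path is not None:
            failures = [r for r in records if not r.converged]
            with log_path.open("a") as fh:
                fh.write(
                    json.dumps(
                        {
                            "scenario_id": scenario.scenario_id,
                            "n_records": len(records),
                            "n_failed": len(failures),
                            "failure_reasons": sorted({r.failure_reason for r in failures if r.failure_reason}),
                        }
                    )
                    + "\n"
                )

    if out is not None:
        summaries_frame(summaries).to_csv(out / "summaries.csv", index=False, float_format="%.17g")
    return summaries, all_records


def summaries_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def _parse_scenario_id(sid: str) -> dict:
    parts = sid.split("_")
    out = {"family": parts[0], "n": None, "dispersion": None, "zero_prop": None}
    for tok in parts[1:]:
        if tok.startswith("n"):
            out["n"] = int(tok[1:])
        elif tok.startswith("d"):
            out["dispersion"] = float(tok[1:])
        elif tok.startswith("z"):
            out["zero_prop"] = float(tok[1:])
    return out


def render_tables(summaries, outdir) -> list[Path]:
    """Write per-family convergence / AIC / BIC / MAE tables as CSV.

    Rows are keyed by sample size (and dispersion / zero proportion
    where the family has them), one column per fitted model; the
    four-factor zinb family is split into one file per sample size.
    Missing cells are rendered as 'NA'.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = summaries_frame(summaries)
    meta = pd.DataFrame([_parse_scenario_id(s) for s in df["scenario_id"]])
    df = pd.concat([meta, df], axis=1)
    metric_cols = {
        "convergence": "convergence_rate",
        "aic": "mean_aic",
        "bic": "mean_bic",
        "mae": "mean_mae",
    }
    written = []
    all_models = sorted(df["model"].unique())
    for family, fam_df in df.groupby("family", sort=False):
        keys = ["n"]
        if family in ("nb", "zinb"):
            keys.append("dispersion")
        if family in ("zip", "zinb"):
            keys.append("zero_prop")
        splits = (
            [(f"_n{n}", g) for n, g in fam_df.groupby("n", sort=True)]
            if family == "zinb"
            else [("", fam_df)]
        )
        for suffix, part in splits:
            row_keys = [k for k in keys if not (family == "zinb" and k == "n")] or ["n"]
            for metric, col in metric_cols.items():
                wide = part.pivot_table(index=row_keys, columns="model", values=col, sort=True)
                wide = wide.reindex(columns=all_models)  # absent cells -> NA markers
                path = outdir / f"{metric}_{family}{suffix}.csv"
                wide.to_csv(path, na_rep="NA")
                written.append(path)
    return written
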