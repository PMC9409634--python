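"""End-to-end orchestration of the analysis workflow.

``simulate_study`` writes a complete synthetic study to disk (RR files
per subject and posture, a manifest, the cohort covariate table and its
ground truth).  ``run_pipeline`` consumes such a study directory — or
any directory with the same layout built from real recordings — and
produces, deterministically under a fixed config and seed:

* per-subject HRV index pairs and supine-minus-standing deltas,
* group-comparison tables for covariates, valve/ventricular parameters
  and the Δ indices,
* per-Δ stepwise pre-selections (one per variable category),
* one hierarchical-partitioning row per Δ index that retained at least
  one predictor,
* a run log echoing every parameter so each number is traceable.

Subjects failing a quality gate in either posture are excluded from the
Δ analyses (with a named reason) but remain in the covariate tables,
mirroring per-variable n reporting.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DataQualityError, HrvPartError, ParameterError
from .indices import INDEX_NAMES, delta, hrv_indices
from .io import read_cohort, read_rr, write_cohort, write_results, write_rr
from .partition import MAX_PREDICTORS, partition_cohort
from .preprocess import clean_rr, select_segment
from .selection import CATEGORIES, assemble_predictors, stepwise_by_category
from .stats import group_comparison_table
from .synth import CohortGenParams, generate_cohort, subject_rr_pair

__all__ = ["PipelineConfig", "simulate_study", "run_pipeline"]

DELTA_COLUMNS = [f"d_{name}" for name in INDEX_NAMES]
CATEGORICAL_VARS = {"female", "medication", "smoking", "hypertension", "diabetes"}

TABLE_VARIABLES = {
    "table1_clinical": ["age", "female", "bmi", "dbp", "sbp", "mbf",
                        "medication", "hypertension", "smoking", "diabetes"],
    "table2_valve": ["vmax", "pgmean", "pgmax", "ava", "avai"],
    "table3_ventricular": ["lvef", "lvm", "lvmi", "rwt"],
    "table4_deltas": DELTA_COLUMNS,
}


@dataclass
class PipelineConfig:
    """Every stage parameter in one (serializable) place."""

    input_dir: str = "study"
    output_dir: str = "results"
    seed: int = 0
    # segment selection
    n_beats: int = 300
    skip_beats: int = 0
    # cleaning
    clean_lo_ms: float = 300.0
    clean_hi_ms: float = 2000.0
    clean_rel_tol: float = 0.20
    clean_max_removed_frac: float = 0.20
    # spectral
    resample_rate: float = 3.0
    welch_nperseg: int = 256
    # nonlinear
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    dfa_corrected: bool = True
    # stepwise
    p_enter: float = 0.05
    p_remove: float = 0.10
    # partitioning
    partition_repeats: int = 10

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def simulate_study(
    outdir: str | Path,
    n_per_group: tuple[int, int, int] = (22, 73, 32),
    seed: int = 0,
    missing_rate: float = 0.0,
) -> Path:
    """Write a full synthetic study (cohort + RR files) to ``outdir``."""
    outdir = Path(outdir)
    (outdir / "rr").mkdir(parents=True, exist_ok=True)
    params = CohortGenParams(
        n_per_group=tuple(n_per_group), missing_rate=missing_rate, seed=seed
    )
    cohort, truth = generate_cohort(params)
    write_cohort(cohort, outdir / "cohort.csv")
    write_results(truth, outdir / "ground_truth.json")

    seeds = np.random.SeedSequence(seed).generate_state(len(cohort)) % (2**31)
    manifest_rows = []
    for row, subj_seed in zip(cohort.itertuples(), seeds):
        sup, sta = subject_rr_pair(row.group, int(subj_seed), row.subject_id)
        sup_path = outdir / "rr" / f"{row.subject_id}_supine.txt"
        sta_path = outdir / "rr" / f"{row.subject_id}_standing.txt"
        write_rr(sup_path, sup.intervals)
        write_rr(sta_path, sta.intervals)
        manifest_rows.append(
            {
                "subject_id": row.subject_id,
                "group": row.group,
                "supine_file": f"rr/{row.subject_id}_supine.txt",
                "standing_file": f"rr/{row.subject_id}_standing.txt",
            }
        )
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.csv", index=False)
    return outdir


def _subject_delta(cfg: PipelineConfig, indir: Path, row) -> dict:
    """Read, clean, segment and index one subject's posture pair."""
    out = {"subject_id": row.subject_id}
    sets = {}
    for posture, col in (("supine", "supine_file"), ("standing", "standing_file")):
        raw = read_rr(indir / getattr(row, col))
        nn = clean_rr(
            raw,
            lo_ms=cfg.clean_lo_ms,
            hi_ms=cfg.clean_hi_ms,
            rel_tol=cfg.clean_rel_tol,
            max_removed_frac=cfg.clean_max_removed_frac,
            subject_id=row.subject_id,
            posture=posture,
        )
        nn = select_segment(nn, n=cfg.n_beats, skip=cfg.skip_beats)
        sets[posture] = hrv_indices(
            nn,
            sampen_m=cfg.sampen_m,
            sampen_r_factor=cfg.sampen_r_factor,
            dfa_corrected=cfg.dfa_corrected,
            rate=cfg.resample_rate,
            nperseg=cfg.welch_nperseg,
        )
    d = delta(sets["supine"], sets["standing"])
    out.update(d.as_dict())
    # the ΔmeanNN covariate is conventionally reported in seconds
    out["d_mean_nn"] = d.d_mean_nn_s
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow; returns the result bundle it also writes."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(indir / "manifest.csv")
    cohort = read_cohort(indir / "cohort.csv")

    deltas = []
    exclusions = []
    for row in manifest.itertuples():
        try:
            deltas.append(_subject_delta(config, indir, row))
        except HrvPartError as exc:
            exclusions.append({"subject_id": row.subject_id, "reason": str(exc)})
    if not deltas:
        raise DataQualityError("no usable subjects after quality gates")
    delta_df = pd.DataFrame(deltas)

    # RR-derived deltas replace any same-named generator columns
    covars = cohort.drop(
        columns=[c for c in cohort.columns if c in set(delta_df.columns) - {"subject_id"}],
        errors="ignore",
    )
    merged = covars.merge(delta_df, on="subject_id", how="inner")

    tables = {}
    for name, variables in TABLE_VARIABLES.items():
        rows = group_comparison_table(
            merged, [v for v in variables if v in merged.columns],
            group_col="group", categorical=CATEGORICAL_VARS,
            group_order=["NAV", "AVSc", "AVSt"],
        )
        tables[name] = [dataclasses.asdict(r) for r in rows]

    selections = {}
    partition_rows = []
    for dep in DELTA_COLUMNS:
        dep_col = "d_mean_nn" if dep == "d_mean_nn" else dep
        sels = stepwise_by_category(
            merged, dep_col, p_enter=config.p_enter, p_remove=config.p_remove
        )
        selections[dep_col] = [dataclasses.asdict(s) for s in sels]
        trimmed = False
        try:
            predictors = assemble_predictors(sels)
        except ParameterError:
            # over the 2^k budget: keep the valve and ΔmeanNN selections
            # (the scientifically indispensable ones) and fill the budget
            # in category order
            full = assemble_predictors(sels, max_combined=10**9)
            priority = [
                p for s in sels if s.category in ("valve", "d_mean_nn")
                for p in sorted(s.selected)
            ]
            ordered = priority + [p for p in full if p not in priority]
            predictors = ordered[:MAX_PREDICTORS]
            trimmed = True
            warnings.warn(
                f"{dep_col}: {len(full)} pre-selected predictors trimmed to "
                f"{MAX_PREDICTORS}", stacklevel=2,
            )
        if not predictors:
            partition_rows.append(
                {"delta": dep_col, "valve_parameter": None, "covariables": [],
                 "r2_combined": None, "n": 0, "repeats": 0,
                 "valve_i_pct_absolute": None, "valve_i_pct_of_r2": None,
                 "reason": "no predictors pre-selected"}
            )
            continue
        n_complete = len(merged[[dep_col] + predictors].dropna())
        if n_complete <= len(predictors) + 2:
            partition_rows.append(
                {"delta": dep_col, "valve_parameter": None,
                 "covariables": predictors, "r2_combined": None,
                 "n": n_complete, "repeats": 0,
                 "valve_i_pct_absolute": None, "valve_i_pct_of_r2": None,
                 "reason": "insufficient complete cases for partitioning"}
            )
            continue
        row = partition_cohort(
            merged, dep_col, predictors,
            repeats=config.partition_repeats, seed=config.seed,
        )
        row["trimmed"] = trimmed
        partition_rows.append(row)

    run_log = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_subjects": int(len(manifest)),
        "n_usable": int(len(delta_df)),
        "exclusions": exclusions,
    }
    results = {
        "tables": tables,
        "selections": selections,
        "partition_rows": partition_rows,
        "run_log": run_log,
    }

    delta_df.to_csv(outdir / "deltas.csv", index=False)
    write_results(tables, outdir / "tables.json")
    write_results(selections, outdir / "selections.json")
    write_results(partition_rows, outdir / "partition.json")
    write_results(run_log, outdir / "run_log.json")
    return results
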