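"""Plain-text serialization of cohorts, index series and configs.

Per-patient signal CSVs have columns ``t_min, value_mmHg, agg_min``; index
CSVs have ``t_min, lprx, window_min``.  Missing values serialize as empty
fields.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .synthetic import (
    GroundTruth,
    LogisticOutcome,
    ReactivityDist,
    SimParams,
    StepOutcome,
)
from .types import IndexSeries, PatientRecord, PhysioSeries

COHORT_FILE = "cohort.csv"
TRUTH_FILE = "ground_truth.json"


def write_series_csv(path: Path, series: PhysioSeries) -> None:
    df = pd.DataFrame(
        {"t_min": series.t, "value_mmHg": series.v, "agg_min": series.agg}
    )
    df.to_csv(path, index=False)


def read_series_csv(path: Path) -> PhysioSeries:
    df = pd.read_csv(path)
    return PhysioSeries(
        df["t_min"].to_numpy(float),
        df["value_mmHg"].to_numpy(float),
        df["agg_min"].to_numpy(float),
    )


def write_index_csv(path: Path, index: IndexSeries) -> None:
    df = pd.DataFrame(
        {
            "t_min": index.t,
            "lprx": index.lprx,
            "window_min": np.full(len(index), index.window_minutes, dtype=int),
        }
    )
    df.to_csv(path, index=False)


def read_index_csv(path: Path) -> IndexSeries:
    df = pd.read_csv(path)
    window = int(df["window_min"].iloc[0]) if len(df) else 0
    return IndexSeries(window, df["t_min"].to_numpy(float), df["lprx"].to_numpy(float))


def write_cohort(
    out_dir: Path,
    records: Iterable[PatientRecord],
    truths: Optional[Iterable[GroundTruth]] = None,
) -> None:
    """Write one CSV per patient signal plus cohort CSV and truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        write_series_csv(out_dir / f"{rec.patient_id}_icp.csv", rec.icp)
        write_series_csv(out_dir / f"{rec.patient_id}_map.csv", rec.map)
        row = {
            "patient_id": rec.patient_id,
            "monitor_type": rec.monitor_type,
            "gos": rec.gos,
            "drainage_intervals": json.dumps(
                [[s, e] for s, e in rec.drainage_intervals]
            ),
            "meta": json.dumps(rec.meta, sort_keys=True),
        }
        row.update(rec.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / COHORT_FILE, index=False)
    if truths is not None:
        payload = [asdict(t) for t in truths]
        (out_dir / TRUTH_FILE).write_text(json.dumps(payload, indent=1))


def read_cohort(in_dir: Path) -> list[PatientRecord]:
    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / COHORT_FILE)
    base_cols = {"patient_id", "monitor_type", "gos", "drainage_intervals", "meta"}
    records = []
    for _, row in table.iterrows():
        pid = str(row["patient_id"])
        covariates = {
            k: row[k] for k in table.columns if k not in base_cols
        }
        records.append(
            PatientRecord(
                patient_id=pid,
                monitor_type=str(row["monitor_type"]),
                icp=read_series_csv(in_dir / f"{pid}_icp.csv"),
                map=read_series_csv(in_dir / f"{pid}_map.csv"),
                drainage_intervals=[
                    (float(s), float(e))
                    for s, e in json.loads(row["drainage_intervals"])
                ],
                gos=int(row["gos"]),
                covariates=covariates,
                meta=json.loads(row["meta"]) if isinstance(row["meta"], str) else {},
            )
        )
    return records


def read_ground_truth(in_dir: Path) -> list[GroundTruth]:
    payload = json.loads((Path(in_dir) / TRUTH_FILE).read_text())
    return [GroundTruth(**item) for item in payload]


def sim_params_from_dict(raw: dict) -> SimParams:
    """Build SimParams from a plain config mapping (YAML/JSON friendly)."""
    raw = dict(raw)
    if "reactivity_distribution" in raw and isinstance(
        raw["reactivity_distribution"], dict
    ):
        raw["reactivity_distribution"] = ReactivityDist(
            **raw["reactivity_distribution"]
        )
    if "outcome_model" in raw and isinstance(raw["outcome_model"], dict):
        om = dict(raw["outcome_model"])
        kind = om.pop("kind", "step")
        raw["outcome_model"] = (
            StepOutcome(**om) if kind == "step" else LogisticOutcome(**om)
        )
    for key in ("stay_range_days", "slow_wave_period_range", "sampling_interval_range"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return SimParams(**raw)


def load_config_file(path: Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
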