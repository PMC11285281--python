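"""Pipeline orchestration: cohort table, scan battery, plots, manifest."""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__, burden, io, scan, signal, synthetic
from .types import LPRX_WINDOWS, IndexSeries, PatientRecord

log = logging.getLogger(__name__)


def percent(count: float, total: float, ndigits: int = 1) -> float:
    """Percentage of ``count`` in ``total`` rounded to ``ndigits`` decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


class ConfigError(ValueError):
    """Invalid analysis configuration."""


@dataclass
class AnalysisConfig:
    sim: Optional[synthetic.SimParams] = None
    input_dir: Optional[str] = None
    windows: Sequence[int] = (10, 30, 120)
    segments: Sequence[str] = ("full", "first_24h")
    pct_thresholds: Sequence[float] = (0.0, 0.2, 0.3)
    schemes: Sequence[str] = scan.OUTCOME_SCHEMES
    subgroups: Sequence[str] = ("all", "evd", "ipd")
    use_imputation: bool = False
    tie_rule: str = "lowest"
    min_coverage: float = 0.25
    out_dir: str = "lprx_out"
    seed: int = 0
    make_plots: bool = False
    write_signals: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        bad = set(self.windows) - set(LPRX_WINDOWS)
        if bad:
            raise ConfigError(f"windows {sorted(bad)} not in {LPRX_WINDOWS}")
        for seg in self.segments:
            burden.make_segment(seg)  # raises on unknown labels
        if self.sim is None and self.input_dir is None:
            raise ConfigError("config needs either 'sim' params or 'input_dir'")

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        raw = dict(raw)
        if raw.get("sim") is not None:
            try:
                raw["sim"] = io.sim_params_from_dict(raw["sim"])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"bad sim params: {exc}") from exc
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_manifest_dict(self) -> dict:
        d = asdict(self)
        for key in ("windows", "segments", "pct_thresholds", "schemes", "subgroups"):
            d[key] = list(d[key])
        return d


def build_table1(
    cohort: pd.DataFrame,
    continuous: Optional[Sequence[str]] = None,
    categorical: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Demographic/physiologic comparison table for both outcome schemes.

    Continuous variables get median (IQR) per group and a Mann-Whitney U
    p-value; binary variables get n (%) per group and the rank-test p-value
    (see :func:`lprx.scan.binary_mann_whitney`).  Missing variables are
    flagged, not fatal.
    """
    if continuous is None:
        continuous = [
            c for c in cohort.columns
            if c == "age" or c == "icu_days" or c.startswith("mean_")
        ]
    if categorical is None:
        categorical = [
            c for c in (
                "sex_male", "hypoxia", "hypotension", "epidural_hematoma",
                "surgical_evacuation", "dc_primary", "dc_secondary",
            ) if c in cohort.columns
        ]
    rows = []
    for scheme in scan.OUTCOME_SCHEMES:
        classes = cohort["gos"].map(lambda g: scan.dichotomize_gos(g, scheme))
        adverse = cohort[classes == 1]
        good = cohort[classes == 0]
        rows.append(
            {
                "scheme": scheme, "variable": "n_patients", "kind": "count",
                "adverse": float(len(adverse)), "good": float(len(good)),
                "adverse_pct": percent(len(adverse), len(cohort)) if len(cohort) else np.nan,
                "good_pct": percent(len(good), len(cohort)) if len(cohort) else np.nan,
                "p": np.nan, "flag": "",
            }
        )
        for var in continuous:
            va = adverse[var].to_numpy(dtype=float)
            vg = good[var].to_numpy(dtype=float)
            va, vg = va[np.isfinite(va)], vg[np.isfinite(vg)]
            if va.size == 0 or vg.size == 0:
                rows.append({"scheme": scheme, "variable": var, "kind": "continuous",
                             "flag": "missing", "p": np.nan})
                continue
            _, p = scan.mann_whitney_compare(va, vg)
            rows.append(
                {
                    "scheme": scheme, "variable": var, "kind": "continuous",
                    "adverse": float(np.median(va)),
                    "adverse_q1": float(np.quantile(va, 0.25)),
                    "adverse_q3": float(np.quantile(va, 0.75)),
                    "good": float(np.median(vg)),
                    "good_q1": float(np.quantile(vg, 0.25)),
                    "good_q3": float(np.quantile(vg, 0.75)),
                    "p": p, "flag": "",
                }
            )
        for var in categorical:
            ka = int(adverse[var].astype(bool).sum())
            kg = int(good[var].astype(bool).sum())
            na, ng = len(adverse), len(good)
            if na == 0 or ng == 0:
                rows.append({"scheme": scheme, "variable": var, "kind": "categorical",
                             "flag": "empty group", "p": np.nan})
                continue
            rows.append(
                {
                    "scheme": scheme, "variable": var, "kind": "categorical",
                    "adverse": float(ka), "good": float(kg),
                    "adverse_pct": percent(ka, na, 2),
                    "good_pct": percent(kg, ng, 2),
                    "p": scan.binary_mann_whitney(ka, na, kg, ng),
                    "flag": "",
                }
            )
    return pd.DataFrame(rows)


def _patient_summaries(
    record: PatientRecord,
    indices: dict[int, IndexSeries],
    icp_minutes,
    config: AnalysisConfig,
) -> list[burden.SegmentSummary]:
    out = []
    for seg_label in config.segments:
        seg = burden.make_segment(seg_label)
        out.append(
            burden.segment_mean(
                icp_minutes, seg, record.patient_id,
                min_coverage=config.min_coverage, metric="mean_icp",
            )
        )
        for w, idx in indices.items():
            out.append(
                burden.segment_mean(
                    idx, seg, record.patient_id,
                    min_coverage=config.min_coverage, metric="mean_lprx",
                )
            )
            for thr in config.pct_thresholds:
                out.append(
                    burden.pct_time_above(idx, thr, seg, record.patient_id)
                )
    return out


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full pipeline and write the report bundle to ``out_dir``.

    Deterministic for a fixed config + seed.  Returns a dict with the main
    in-memory artifacts (cohort table, summaries, battery results, manifest).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.sim is not None:
        sim = synthetic.SimParams(**{**asdict_simsafe(config.sim), "seed": config.seed})
        records, truths = synthetic.generate_cohort(sim)
    else:
        records = io.read_cohort(Path(config.input_dir))
        truths = None

    kept: list[PatientRecord] = []
    loss_rows = []
    excluded = []
    for rec in records:
        if rec.monitored_minutes <= 360:
            excluded.append(rec.patient_id)
            log.info("excluding %s: monitored span <= 6 h", rec.patient_id)
            continue
        cleaned, counts = signal.clean_record(rec)
        loss_rows.append({"patient_id": rec.patient_id, **counts, **rec.meta})
        kept.append(cleaned)

    cohort_rows = []
    all_summaries: list[burden.SegmentSummary] = []
    for rec in kept:
        indices = {
            w: signal.compute_lprx(rec, w, use_imputation=config.use_imputation)
            for w in config.windows
        }
        icp_minutes = signal.to_minute_grid(rec.icp)
        map_minutes = signal.to_minute_grid(rec.map)
        all_summaries.extend(_patient_summaries(rec, indices, icp_minutes, config))
        row = {
            "patient_id": rec.patient_id,
            "monitor_type": rec.monitor_type,
            "gos": rec.gos,
            "icu_days": rec.monitored_minutes / 1440.0,
            "mean_icp": float(np.nanmean(icp_minutes.v)) if icp_minutes.n_present else np.nan,
            "mean_map": float(np.nanmean(map_minutes.v)) if map_minutes.n_present else np.nan,
        }
        for w, idx in indices.items():
            vals = idx.lprx[np.isfinite(idx.lprx)] if len(idx) else np.array([])
            row[f"mean_lprx_{w}"] = float(vals.mean()) if vals.size else np.nan
        row.update(rec.covariates)
        cohort_rows.append(row)
    cohort_df = pd.DataFrame(cohort_rows)
    summaries_df = burden.summaries_to_frame(all_summaries)

    table1 = build_table1(cohort_df)
    results = scan.run_scan_battery(
        summaries_df, cohort_df,
        schemes=config.schemes, subgroups=config.subgroups,
        tie_rule=config.tie_rule,
    )
    battery = scan.battery_table(results)

    cohort_df.to_csv(out_dir / "cohort_summary.csv", index=False)
    summaries_df.to_csv(out_dir / "segment_summaries.csv", index=False)
    table1.to_csv(out_dir / "table1.csv", index=False)
    battery.to_csv(out_dir / "scan_battery.csv", index=False)
    traces = pd.concat(
        [r.table.assign(**{k: r.stratum.get(k) for k in r.stratum}) for r in results],
        ignore_index=True,
    )
    traces.to_csv(out_dir / "scan_traces.csv", index=False)
    best = [
        {**r.stratum, "best_threshold": r.best_threshold,
         "best_chi2": r.best_chi2, "best_p": r.best_p, "usable": r.usable}
        for r in results
    ]
    (out_dir / "best_thresholds.json").write_text(
        json.dumps(best, indent=1, default=_json_default)
    )
    if config.write_signals and config.sim is not None:
        io.write_cohort(out_dir / "cohort", records, truths)

    manifest = {
        "config": config.to_manifest_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_manifest_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "lprx_version": __version__,
        "n_patients_input": len(records),
        "n_patients_analyzed": len(kept),
        "excluded_patients": excluded,
        "data_loss": loss_rows,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=_json_default)
    )

    if config.make_plots:
        plot_battery(results, out_dir / "plots")

    return {
        "cohort": cohort_df,
        "summaries": summaries_df,
        "table1": table1,
        "results": results,
        "battery": battery,
        "manifest": manifest,
    }


def asdict_simsafe(sim: synthetic.SimParams) -> dict:
    """SimParams as a kwargs dict preserving nested dataclasses."""
    return {f: getattr(sim, f) for f in sim.__dataclass_fields__}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return str(obj)


def plot_scan(result: scan.ThresholdScanResult, path: Path) -> None:
    """Chi-square-versus-threshold curve for one stratum."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    tab = result.table
    ax.plot(tab["threshold"], tab["chi2"], lw=1.2)
    if result.best_threshold is not None:
        ax.axvline(result.best_threshold, color="crimson", ls="--", lw=0.8)
    ax.set_xlabel("threshold")
    ax.set_ylabel("chi-square")
    ax.set_title(
        ", ".join(f"{k}={v}" for k, v in result.stratum.items() if pd.notna(v)),
        fontsize=7,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_battery(results: Sequence[scan.ThresholdScanResult], out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, r in enumerate(results):
        if not r.usable:
            continue
        name = "_".join(
            str(r.stratum.get(k, "")) for k in
            ("scheme", "subgroup", "metric", "window_minutes", "segment")
        )
        plot_scan(r, out_dir / f"scan_{i:03d}_{name}.png")
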