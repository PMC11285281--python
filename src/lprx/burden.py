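"""Per-patient segment summaries: grand means and % time above threshold.

Segments follow the half-open minute convention: ``day_k`` covers
``[(k-1)*1440, k*1440)``, ``first_Nh`` covers ``[0, N*60)`` and ``full`` the
entire monitored span.  Quantiles in cohort tables use linear interpolation
between order statistics (numpy default) for bit-reproducibility.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .types import IndexSeries, PhysioSeries

SEGMENT_LABELS = (
    "full", "first_24h", "first_48h", "first_96h", "first_144h",
    "day_1", "day_2", "day_3", "day_4", "day_5", "day_6", "day_7",
)


@dataclass(frozen=True)
class Segment:
    label: str
    start_minute: float
    end_minute: float  # half-open; math.inf for "full"

    @property
    def duration(self) -> float:
        return self.end_minute - self.start_minute


def make_segment(label: str, span_minutes: Optional[float] = None) -> Segment:
    """Resolve a segment label to its half-open minute interval."""
    if label == "full":
        end = math.inf if span_minutes is None else float(span_minutes)
        return Segment("full", 0.0, end)
    if label.startswith("first_") and label.endswith("h"):
        hours = int(label[len("first_"):-1])
        return Segment(label, 0.0, hours * 60.0)
    if label.startswith("day_"):
        k = int(label[len("day_"):])
        return Segment(label, (k - 1) * 1440.0, k * 1440.0)
    raise ValueError(f"unknown segment label {label!r}")


@dataclass
class SegmentSummary:
    patient_id: str
    segment: Segment
    metric: str  # "mean_lprx" | "mean_icp" | "pct_above"
    value: float  # NaN when below the minimum-coverage rule
    n_valid: int
    window_minutes: Optional[int] = None
    threshold: Optional[float] = None


def _extract(series: Union[IndexSeries, PhysioSeries]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, IndexSeries):
        return series.t, series.lprx
    return series.t, series.v


def segment_mean(
    series: Union[IndexSeries, PhysioSeries],
    segment: Segment,
    patient_id: str = "",
    min_coverage: float = 0.25,
    metric: str = "mean_lprx",
) -> SegmentSummary:
    """Arithmetic mean of present minute values inside the segment.

    Missing (NaN) when the valid-minute coverage of the segment is below
    ``min_coverage`` or the patient has no data in the segment.  For the
    ``full`` segment coverage is taken relative to the monitored span.
    """
    t, v = _extract(series)
    in_seg = (t >= segment.start_minute) & (t < segment.end_minute)
    vals = v[in_seg]
    vals = vals[np.isfinite(vals)]
    n_valid = int(vals.size)
    if math.isinf(segment.duration):
        denom = float(t.max() - segment.start_minute) if t.size else 0.0
    else:
        denom = segment.duration
    value = float(vals.mean()) if n_valid and n_valid >= min_coverage * denom else float("nan")
    win = series.window_minutes if isinstance(series, IndexSeries) else None
    return SegmentSummary(patient_id, segment, metric, value, n_valid, win)


def pct_time_above(
    series: IndexSeries,
    threshold: float,
    segment: Segment,
    patient_id: str = "",
    min_coverage: float = 0.0,
) -> SegmentSummary:
    """Fraction of present minutes in the segment strictly above ``threshold``.

    Missing when no minutes are present (or coverage is below an optional
    ``min_coverage`` floor).
    """
    if not -1 <= threshold <= 1:
        raise ValueError("threshold must be in [-1, 1]")
    t, v = _extract(series)
    in_seg = (t >= segment.start_minute) & (t < segment.end_minute)
    vals = v[in_seg]
    vals = vals[np.isfinite(vals)]
    n_valid = int(vals.size)
    denom = segment.duration if not math.isinf(segment.duration) else (
        float(t.max() - segment.start_minute) if t.size else 0.0
    )
    ok = n_valid > 0 and (min_coverage <= 0 or n_valid >= min_coverage * denom)
    value = float((vals > threshold).mean()) if ok else float("nan")
    return SegmentSummary(
        patient_id, segment, "pct_above", value, n_valid,
        series.window_minutes, threshold,
    )


def summaries_to_frame(summaries: Iterable[SegmentSummary]) -> pd.DataFrame:
    """Long-format table of segment summaries."""
    rows = [
        {
            "patient_id": s.patient_id,
            "segment": s.segment.label,
            "metric": s.metric,
            "window_minutes": s.window_minutes,
            "threshold": s.threshold,
            "value": s.value,
            "n_valid": s.n_valid,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "segment", "metric", "window_minutes",
            "threshold", "value", "n_valid",
        ],
    )


def cohort_summary_table(
    summaries: pd.DataFrame,
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Median (IQR) of per-patient grand means, per group and metric.

    ``groups`` maps patient_id to a group label (e.g. alive/dead).  Returns
    one row per (metric, window, threshold, segment, group) with columns
    median, q1, q3, n.  Empty groups yield rows of NaN.
    """
    df = summaries.copy()
    df["group"] = df["patient_id"].map(dict(groups))
    keys = ["metric", "window_minutes", "threshold", "segment", "group"]
    out = []
    for key, sub in df.groupby(keys, dropna=False):
        vals = sub["value"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        row = dict(zip(keys, key))
        if vals.size:
            row.update(
                median=float(np.median(vals)),
                q1=float(np.quantile(vals, 0.25)),
                q3=float(np.quantile(vals, 0.75)),
                n=int(vals.size),
            )
        else:
            row.update(median=np.nan, q1=np.nan, q3=np.nan, n=0)
        out.append(row)
    return pd.DataFrame(out, columns=keys + ["median", "q1", "q3", "n"])
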