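"""Core data containers for minute-resolution ICP/MAP monitoring data.

Time convention: minutes since monitoring start, intervals half-open
``[start, end)``. Missing samples are ``NaN`` in the value arrays; the
timestamp of a removed sample is retained so data-loss is auditable.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

LPRX_WINDOWS = (10, 15, 20, 30, 60, 90, 120)

MonitorType = str  # "EVD" | "IPD"


@dataclass
class PhysioSeries:
    """One patient's sporadically sampled pressure signal.

    Parameters
    ----------
    t
        Sample timestamps, minutes since monitoring start, strictly increasing.
    v
        Sample values in mmHg; ``NaN`` marks a missing/removed sample.
    agg
        Per-sample aggregation duration in minutes (each stored value is the
        median of the raw signal over ``(t - agg, t]``).
    """

    t: np.ndarray
    v: np.ndarray
    agg: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.agg = np.asarray(self.agg, dtype=float)
        if not (self.t.shape == self.v.shape == self.agg.shape):
            raise ValueError("t, v and agg must have identical shapes")
        if self.t.ndim != 1:
            raise ValueError("PhysioSeries arrays must be one-dimensional")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.t.size and not np.all(self.agg > 0):
            raise ValueError("aggregation durations must be positive")

    def __len__(self) -> int:
        return self.t.size

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of non-missing samples."""
        return np.isfinite(self.v)

    @property
    def n_present(self) -> int:
        return int(self.present.sum())

    @property
    def span(self) -> float:
        """Monitored span in minutes (time of the last sample)."""
        return float(self.t[-1]) if self.t.size else 0.0

    def with_values(self, v: np.ndarray) -> "PhysioSeries":
        return replace(self, v=np.asarray(v, dtype=float))

    def copy(self) -> "PhysioSeries":
        return PhysioSeries(self.t.copy(), self.v.copy(), self.agg.copy())


@dataclass
class PatientRecord:
    """ICP + MAP series with monitor metadata and outcome."""

    patient_id: str
    monitor_type: MonitorType
    icp: PhysioSeries
    map: PhysioSeries
    drainage_intervals: list[tuple[float, float]] = field(default_factory=list)
    gos: int = 5
    covariates: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.monitor_type not in ("EVD", "IPD"):
            raise ValueError(f"unknown monitor type {self.monitor_type!r}")
        if self.drainage_intervals and self.monitor_type != "EVD":
            raise ValueError("drainage intervals are only valid for EVD monitors")
        if not 1 <= int(self.gos) <= 5:
            raise ValueError(f"GOS must be in 1..5, got {self.gos}")

    @property
    def monitored_minutes(self) -> float:
        return max(self.icp.span, self.map.span)


@dataclass
class IndexSeries:
    """Minute-indexed moving-correlation index for one patient/window.

    ``t[i]`` is the minute at which the window *ends*; the value at minute
    ``t`` summarizes samples in ``(t - window_minutes, t]``.  The first
    defined value therefore occurs no earlier than minute ``window_minutes``.
    """

    window_minutes: int
    t: np.ndarray
    lprx: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.lprx = np.asarray(self.lprx, dtype=float)
        if self.t.shape != self.lprx.shape:
            raise ValueError("t and lprx must have identical shapes")
        finite = np.isfinite(self.lprx)
        if finite.any():
            vals = self.lprx[finite]
            if vals.size and (vals.min() < -1 - 1e-9 or vals.max() > 1 + 1e-9):
                raise ValueError("index values must lie in [-1, 1]")
            if float(self.t[finite].min()) < self.window_minutes:
                raise ValueError(
                    "index defined before one full window has elapsed"
                )

    def __len__(self) -> int:
        return self.t.size

    @property
    def present(self) -> np.ndarray:
        return np.isfinite(self.lprx)


def merge_intervals(
    intervals: Sequence[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Merge overlapping/touching half-open ``[start, end)`` intervals."""
    cleaned = [(float(s), float(e)) for s, e in intervals if e > s]
    if not cleaned:
        return []
    cleaned.sort()
    merged = [cleaned[0]]
    for s, e in cleaned[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged
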