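"""Cleaning and moving-correlation computation for sporadic ICP/MAP series.

The index is a moving Pearson correlation of consecutive minute-by-minute
ICP and MAP samples, evaluated every minute with a right-aligned window
(the value reported at minute ``t`` covers ``(t - n, t]``).
"""
from __future__ import annotations

import logging
import warnings

import numpy as np

from .types import IndexSeries, PatientRecord, PhysioSeries, merge_intervals

log = logging.getLogger(__name__)

#: Strict validity limits; samples at or beyond a limit are artifacts.
VALIDITY_LIMITS = {"ICP": (0.0, 80.0), "MAP": (0.0, 400.0)}


def filter_artifacts(
    series: PhysioSeries, signal_kind: str
) -> tuple[PhysioSeries, int]:
    """Mark out-of-range samples missing (strict inequalities).

    ICP is valid on ``(0, 80)`` mmHg and MAP on ``(0, 400)`` mmHg; a value
    exactly at a limit is removed.  Returns the cleaned series and the number
    of samples removed.
    """
    try:
        lo, hi = VALIDITY_LIMITS[signal_kind]
    except KeyError:
        raise ValueError(
            f"unknown signal kind {signal_kind!r}; expected 'ICP' or 'MAP'"
        ) from None
    bad = series.present & ((series.v <= lo) | (series.v >= hi))
    n_removed = int(bad.sum())
    if n_removed:
        v = series.v.copy()
        v[bad] = np.nan
        series = series.with_values(v)
        log.debug("filter_artifacts(%s): removed %d samples", signal_kind, n_removed)
    return series, n_removed


def remove_drainage(
    series: PhysioSeries, intervals: list[tuple[float, float]]
) -> tuple[PhysioSeries, int]:
    """Mark samples inside open-drain intervals missing.

    Intervals are half-open ``[start, end)``; overlapping intervals are
    merged.  Returns the cleaned series and the number of samples removed.
    """
    merged = merge_intervals(intervals)
    if not merged or not len(series):
        return series, 0
    bad = np.zeros(len(series), dtype=bool)
    for s, e in merged:
        bad |= (series.t >= s) & (series.t < e)
    bad &= series.present
    n_removed = int(bad.sum())
    if n_removed:
        v = series.v.copy()
        v[bad] = np.nan
        series = series.with_values(v)
    return series, n_removed


def to_minute_grid(series: PhysioSeries, grid_minutes: float = 1.0) -> PhysioSeries:
    """Project sporadic aggregated samples onto a uniform minute grid.

    Grid minute ``k`` represents the interval ``(k-1, k]`` (minute-ending
    stamps).  Each stored sample is the median of the raw signal over
    ``(t - agg, t]``, so its value populates every grid minute that interval
    overlaps; minutes covered by several samples take their median, minutes
    covered by none (or only by missing samples) are ``NaN``.  A series
    already on the 1-min grid with unit aggregation comes back
    value-identical.
    """
    if grid_minutes <= 0:
        raise ValueError("grid_minutes must be positive")
    if not len(series):
        return PhysioSeries(np.array([]), np.array([]), np.array([]))
    g = grid_minutes
    n_bins = int(np.ceil(series.t[-1] / g)) + 1
    grid_t = np.arange(n_bins) * g
    grid_v = np.full(n_bins, np.nan)
    ok = series.present
    if ok.any():
        t, v, agg = series.t[ok], series.v[ok], series.agg[ok]
        # bins k with k*g > t-agg and (k-1)*g < t
        k_min = np.maximum(np.floor((t - agg) / g).astype(int) + 1, 0)
        k_max = np.minimum(np.ceil(t / g).astype(int), n_bins - 1)
        counts = np.maximum(k_max - k_min + 1, 0)
        total = int(counts.sum())
        if total:
            offsets = np.arange(total) - np.repeat(
                np.cumsum(counts) - counts, counts
            )
            bins = np.repeat(k_min, counts) + offsets
            vals = np.repeat(v, counts)
            order = np.argsort(bins, kind="stable")
            bins, vals = bins[order], vals[order]
            starts = np.flatnonzero(np.r_[True, np.diff(bins) != 0])
            stops = np.r_[starts[1:], bins.size]
            runs = stops - starts
            one = runs == 1
            grid_v[bins[starts[one]]] = vals[starts[one]]
            two = runs == 2
            s2 = starts[two]
            grid_v[bins[s2]] = 0.5 * (vals[s2] + vals[s2 + 1])
            for start, stop in zip(starts[runs > 2], stops[runs > 2]):
                grid_v[bins[start]] = np.median(vals[start:stop])
    return PhysioSeries(grid_t, grid_v, np.full(n_bins, float(g)))


def regularize(
    series: PhysioSeries,
    grid_minutes: float = 1.0,
    max_gap_minutes: float = 5.0,
) -> PhysioSeries:
    """Impute a sporadic series onto a uniform grid.

    Stand-in imputation: samples are median-binned onto the grid, then gaps
    of at most ``max_gap_minutes`` between present grid values are filled by
    linear interpolation; longer gaps stay missing.  A series already on the
    grid comes back value-identical (imputation is the identity on regular
    data).
    """
    gridded = to_minute_grid(series, grid_minutes)
    v = gridded.v
    idx = np.flatnonzero(np.isfinite(v))
    if idx.size >= 2:
        v = v.copy()
        gaps = np.diff(idx)
        max_steps = int(round(max_gap_minutes / grid_minutes))
        for j in np.flatnonzero((gaps > 1) & (gaps <= max_steps)):
            a, b = idx[j], idx[j + 1]
            inner = np.arange(a + 1, b)
            v[inner] = v[a] + (v[b] - v[a]) * (inner - a) / (b - a)
        gridded = gridded.with_values(v)
    return gridded


def moving_pearson(
    x: np.ndarray,
    y: np.ndarray,
    n: int,
    min_valid_fraction: float = 0.8,
    _chunk: int = 4096,
) -> np.ndarray:
    """Right-aligned moving Pearson correlation over ``n`` consecutive samples.

    ``x`` and ``y`` share a common uniform grid.  The output has the same
    length; position ``i`` holds the pairwise-complete correlation of the
    window ``[i-n+1, i]``, and is ``NaN`` when fewer than
    ``ceil(min_valid_fraction * n)`` pairs are present, when either signal is
    constant within the window, or before one full window has elapsed.
    """
    if n < 3:
        raise ValueError("window must contain at least 3 samples")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    T = x.size
    out = np.full(T, np.nan)
    if T < n:
        return out
    min_pairs = max(3, int(np.ceil(min_valid_fraction * n)))
    win_x = np.lib.stride_tricks.sliding_window_view(x, n)
    win_y = np.lib.stride_tricks.sliding_window_view(y, n)
    n_win = win_x.shape[0]
    for lo in range(0, n_win, _chunk):
        hi = min(lo + _chunk, n_win)
        X = win_x[lo:hi]
        Y = win_y[lo:hi]
        valid = np.isfinite(X) & np.isfinite(Y)
        cnt = valid.sum(axis=1)
        ok = cnt >= min_pairs
        if not ok.any():
            continue
        Xv = np.where(valid, X, 0.0)
        Yv = np.where(valid, Y, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mx = Xv.sum(axis=1) / cnt
            my = Yv.sum(axis=1) / cnt
            dx = np.where(valid, X - mx[:, None], 0.0)
            dy = np.where(valid, Y - my[:, None], 0.0)
            cov = (dx * dy).sum(axis=1)
            vx = (dx * dx).sum(axis=1)
            vy = (dy * dy).sum(axis=1)
            # exact constant detection: an undefined correlation stays NaN
            xmax = np.where(valid, X, -np.inf).max(axis=1)
            xmin = np.where(valid, X, np.inf).min(axis=1)
            ymax = np.where(valid, Y, -np.inf).max(axis=1)
            ymin = np.where(valid, Y, np.inf).min(axis=1)
            const = (xmax == xmin) | (ymax == ymin)
            ok &= ~const & (vx > 0) & (vy > 0)
            r = cov / np.sqrt(vx * vy)
        r = np.clip(r, -1.0, 1.0)
        block = out[lo + n - 1 : hi + n - 1]
        block[ok] = r[ok]
    return out


def compute_lprx(
    record: PatientRecord,
    window_minutes: int,
    use_imputation: bool = False,
    min_valid_fraction: float = 0.8,
    max_gap_minutes: float = 5.0,
) -> IndexSeries:
    """Compute the moving ICP/MAP correlation index for one patient.

    The record is expected to have passed :func:`filter_artifacts` and
    :func:`remove_drainage` already.  Pipeline: minute binning (or
    :func:`regularize` when ``use_imputation``) of both signals onto a shared
    1-min grid, then :func:`moving_pearson` with ``n = window_minutes``.
    """
    prep = regularize if use_imputation else to_minute_grid
    kwargs = {"max_gap_minutes": max_gap_minutes} if use_imputation else {}
    icp = prep(record.icp, 1.0, **kwargs)
    map_ = prep(record.map, 1.0, **kwargs)
    T = max(len(icp), len(map_))
    if record.monitored_minutes < window_minutes or T < window_minutes:
        warnings.warn(
            f"patient {record.patient_id}: monitored span shorter than the "
            f"{window_minutes}-min window; returning an empty index series",
            stacklevel=2,
        )
        return IndexSeries(window_minutes, np.array([]), np.array([]))

    def pad(s: PhysioSeries) -> np.ndarray:
        v = np.full(T, np.nan)
        v[: len(s)] = s.v
        return v

    r = moving_pearson(pad(map_), pad(icp), window_minutes, min_valid_fraction)
    # grid stamps are minute-ending; the window terminating at stamp n-1
    # reaches back before monitoring start, so the index starts at minute n
    r[:window_minutes] = np.nan
    return IndexSeries(window_minutes, np.arange(T, dtype=float), r)


def clean_record(record: PatientRecord) -> tuple[PatientRecord, dict]:
    """Apply artifact limits to both signals and drainage removal to ICP.

    MAP minutes paired with removed ICP minutes drop out of correlation
    windows automatically (pairwise-complete windows), so drainage removal is
    applied to the ICP series only.  Returns the cleaned record and a
    per-signal removal count dict.
    """
    icp, n_icp = filter_artifacts(record.icp, "ICP")
    map_, n_map = filter_artifacts(record.map, "MAP")
    icp, n_drain = remove_drainage(icp, record.drainage_intervals)
    cleaned = PatientRecord(
        patient_id=record.patient_id,
        monitor_type=record.monitor_type,
        icp=icp,
        map=map_,
        drainage_intervals=list(record.drainage_intervals),
        gos=record.gos,
        covariates=dict(record.covariates),
        meta=dict(record.meta),
    )
    counts = {
        "icp_artifacts_removed": n_icp,
        "map_artifacts_removed": n_map,
        "drainage_samples_removed": n_drain,
    }
    return cleaned, counts
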