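"""Sequential chi-square critical-threshold scanning.

Per-patient summary values (grand-mean index, mean ICP, or % time above a
key index threshold) are dichotomized at every grid point (strictly
``value > threshold``); an uncorrected Pearson chi-square (df=1) against the
dichotomized outcome is evaluated at each point, and the threshold with the
highest statistic is the critical threshold.  P-values are unadjusted for
multiple comparisons; the tidy result table carries the number of grid
points so users can apply their own correction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

OUTCOME_SCHEMES = ("survival", "favorable")

#: Grid dialects. The %-time grid (0..1 in 0.05 steps) is a repo choice; the
#: index and ICP grids follow the published scanning convention.
LPRX_GRID = ("lprx", -0.5, 0.7, 0.05)
ICP_GRID = ("icp", 0.0, 40.0, 0.5)
PCT_TIME_GRID = ("pct_time", 0.0, 1.0, 0.05)


@dataclass(frozen=True)
class ThresholdGrid:
    metric_kind: str  # "lprx" | "icp" | "pct_time"
    lo: float
    hi: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0 or self.hi < self.lo:
            raise ValueError("grid must have positive step and hi >= lo")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step))
        return np.round(self.lo + self.step * np.arange(n + 1), 10)

    @classmethod
    def for_kind(cls, metric_kind: str) -> "ThresholdGrid":
        for kind, lo, hi, step in (LPRX_GRID, ICP_GRID, PCT_TIME_GRID):
            if kind == metric_kind:
                return cls(kind, lo, hi, step)
        raise ValueError(f"unknown metric kind {metric_kind!r}")


def dichotomize_gos(gos: int, scheme: str) -> int:
    """Binary outcome class: 1 = adverse (dead / unfavorable), 0 otherwise.

    survival: GOS 1 (dead) vs GOS 2-5 (alive);
    favorable: GOS 1-3 (unfavorable) vs GOS 4-5 (favorable).
    """
    gos = int(gos)
    if not 1 <= gos <= 5:
        raise ValueError(f"GOS must be in 1..5, got {gos}")
    if scheme == "survival":
        return 1 if gos == 1 else 0
    if scheme == "favorable":
        return 1 if gos <= 3 else 0
    raise ValueError(f"unknown outcome scheme {scheme!r}")


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Uncorrected Pearson chi-square for a 2x2 table, df=1.

    Cells: rows are (above, below) threshold, columns (adverse, good) outcome
    — but the statistic is symmetric in any row/column relabeling.  Returns
    ``(chi2, p, valid)``; a zero marginal makes the result invalid (NaN
    statistic) rather than raising.
    """
    a, b, c, d = (float(x) for x in (a, b, c, d))
    n = a + b + c + d
    if n <= 0:
        raise ValueError("table must contain at least one observation")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return float("nan"), float("nan"), False
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, True


@dataclass
class ThresholdScanResult:
    grid: ThresholdGrid
    table: pd.DataFrame  # threshold, a, b, c, d, chi2, p, valid
    n_patients: int
    usable: bool
    stratum: dict = field(default_factory=dict)
    best_threshold: Optional[float] = None
    best_chi2: Optional[float] = None
    best_p: Optional[float] = None


def scan_thresholds(
    values: Sequence[float],
    classes: Sequence[int],
    grid: ThresholdGrid,
    tie_rule: str = "lowest",
    stratum: Optional[dict] = None,
) -> ThresholdScanResult:
    """Sweep the grid, computing a 2x2 chi-square at each threshold.

    ``values`` and ``classes`` are index-aligned per patient; patients with a
    missing (NaN) summary are excluded.  At each grid point patients split by
    ``value > threshold`` (strict) vs ``<= threshold``.  A scan with fewer
    than 2 patients in either outcome class is marked unusable (its trace is
    still produced).
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(classes, dtype=int)
    if v.shape != c.shape:
        raise ValueError("values and classes must be index-aligned")
    keep = np.isfinite(v)
    v, c = v[keep], c[keep]
    n = int(v.size)
    usable = int((c == 1).sum()) >= 2 and int((c == 0).sum()) >= 2

    adverse = c == 1
    rows = []
    for thr in grid.values:
        above = v > thr
        a = int((above & adverse).sum())
        b = int((above & ~adverse).sum())
        cc = int((~above & adverse).sum())
        d = int((~above & ~adverse).sum())
        if n:
            chi2, p, valid = chi2_2x2(a, b, cc, d)
        else:
            chi2, p, valid = float("nan"), float("nan"), False
        rows.append(
            {"threshold": float(thr), "a": a, "b": b, "c": cc, "d": d,
             "chi2": chi2, "p": p, "valid": valid}
        )
    table = pd.DataFrame(rows)
    result = ThresholdScanResult(
        grid=grid, table=table, n_patients=n, usable=usable,
        stratum=dict(stratum or {}),
    )
    best = select_best(result, tie_rule=tie_rule)
    if best is not None:
        result.best_threshold, result.best_chi2, result.best_p = best
    return result


def select_best(
    result: ThresholdScanResult, tie_rule: str = "lowest"
) -> Optional[tuple[float, float, float]]:
    """Pick the maximal-chi-square threshold; ties broken by ``tie_rule``.

    Returns ``(threshold, chi2, p)`` with the unadjusted p-value, or ``None``
    when no grid point is valid (explicit no-threshold result).
    """
    if tie_rule not in ("lowest", "highest"):
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    tab = result.table[result.table["valid"]]
    if tab.empty:
        return None
    best_chi2 = tab["chi2"].max()
    ties = tab[tab["chi2"] == best_chi2]
    row = ties.iloc[0] if tie_rule == "lowest" else ties.iloc[-1]
    return float(row["threshold"]), float(row["chi2"]), float(row["p"])


SUBGROUPS = ("all", "evd", "ipd", "no_dc")


def _subgroup_mask(cohort: pd.DataFrame, subgroup: str) -> pd.Series:
    if subgroup == "all":
        return pd.Series(True, index=cohort.index)
    if subgroup == "evd":
        return cohort["monitor_type"] == "EVD"
    if subgroup == "ipd":
        return cohort["monitor_type"] == "IPD"
    if subgroup == "no_dc":
        dc = pd.Series(False, index=cohort.index)
        for col in ("dc_primary", "dc_secondary"):
            if col in cohort.columns:
                dc |= cohort[col].astype(bool)
        return ~dc
    raise ValueError(f"unknown subgroup {subgroup!r}")


def run_scan_battery(
    summaries: pd.DataFrame,
    cohort: pd.DataFrame,
    schemes: Sequence[str] = OUTCOME_SCHEMES,
    subgroups: Sequence[str] = SUBGROUPS,
    tie_rule: str = "lowest",
) -> list[ThresholdScanResult]:
    """Scan every (scheme x metric x segment x subgroup) cell.

    ``summaries`` is the long-format table from
    :func:`lprx.burden.summaries_to_frame` (one row per patient per metric
    cell); ``cohort`` has one row per patient with columns ``patient_id``,
    ``gos``, ``monitor_type`` and optionally ``dc_primary``/``dc_secondary``.
    Every configured cell yields a result row; empty or degenerate strata are
    marked unusable and the battery continues.
    """
    cohort = cohort.set_index("patient_id", drop=False)
    results: list[ThresholdScanResult] = []
    metric_cells = summaries[
        ["metric", "window_minutes", "threshold", "segment"]
    ].drop_duplicates()

    for scheme in schemes:
        classes_all = cohort["gos"].map(lambda g: dichotomize_gos(g, scheme))
        for subgroup in subgroups:
            mask = _subgroup_mask(cohort, subgroup)
            ids = cohort.index[mask]
            for _, cell in metric_cells.iterrows():
                sel = (
                    (summaries["metric"] == cell["metric"])
                    & (summaries["segment"] == cell["segment"])
                )
                if pd.notna(cell["window_minutes"]):
                    sel &= summaries["window_minutes"] == cell["window_minutes"]
                else:
                    sel &= summaries["window_minutes"].isna()
                if pd.notna(cell["threshold"]):
                    sel &= summaries["threshold"] == cell["threshold"]
                else:
                    sel &= summaries["threshold"].isna()
                sub = summaries[sel].set_index("patient_id")["value"]
                sub = sub.reindex(ids)
                kind = {
                    "mean_lprx": "lprx",
                    "mean_icp": "icp",
                    "pct_above": "pct_time",
                }[cell["metric"]]
                grid = ThresholdGrid.for_kind(kind)
                stratum = {
                    "scheme": scheme,
                    "subgroup": subgroup,
                    "metric": cell["metric"],
                    "window_minutes": cell["window_minutes"],
                    "key_threshold": cell["threshold"],
                    "segment": cell["segment"],
                }
                results.append(
                    scan_thresholds(
                        sub.to_numpy(dtype=float),
                        classes_all.reindex(ids).to_numpy(dtype=int),
                        grid,
                        tie_rule=tie_rule,
                        stratum=stratum,
                    )
                )
    return results


def battery_table(results: Sequence[ThresholdScanResult]) -> pd.DataFrame:
    """Tidy one-row-per-scan summary of a battery."""
    rows = []
    for r in results:
        row = dict(r.stratum)
        row.update(
            n_patients=r.n_patients,
            usable=r.usable,
            n_grid=len(r.table),
            best_threshold=r.best_threshold,
            best_chi2=r.best_chi2,
            best_p=r.best_p,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def mann_whitney_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction.

    Returns ``(U_for_group_a, p)``.  Raises if either group is empty.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def binary_mann_whitney(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided rank test p-value for a binary variable between two groups.

    Mann-Whitney U on 0/1 indicator vectors with tie correction and
    continuity correction — equivalent to R's ``wilcox.test`` default, the
    dialect that reproduces published demographic-table p-values exactly.
    Group 1 has ``k1`` positives of ``n1``; group 2 has ``k2`` of ``n2``.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2 and n1 > 0 and n2 > 0):
        raise ValueError("counts must satisfy 0 <= k <= n with n > 0")
    g1 = np.r_[np.ones(k1), np.zeros(n1 - k1)]
    g2 = np.r_[np.ones(k2), np.zeros(n2 - k2)]
    res = stats.mannwhitneyu(
        g1, g2, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)
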