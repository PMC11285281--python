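"""Synthetic neuromonitoring cohorts with known ground-truth reactivity.

Each patient gets a latent coupling coefficient ``rho`` in [-1, 1].  MAP is a
baseline plus slow sinusoidal waves plus white noise; the ICP fluctuation is
built from the *standardized* MAP fluctuation Z and an independent component W
as ``g * (rho * Z) + noise_sd_icp * sqrt(1 - rho^2) * W``, so the population
Pearson correlation of paired samples equals ``rho`` whenever the coupled
gain ``g`` equals ``noise_sd_icp`` (the default).  W is an independent
realization of the same slow-wave-plus-noise process, which keeps the
*windowed* sample correlation centred on ``rho`` even for short windows.

Outcomes: the configured model maps ``rho`` to a death probability (GOS 1);
among survivors a second, weaker logistic (decreasing in ``rho``) draws
favorable (GOS 4/5, split evenly) versus unfavorable survival (GOS 2/3).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import truncnorm

from .types import PatientRecord, PhysioSeries

_BASE_DT = 0.5  # minutes; resolution of the latent signal

# Inter-sample interval distribution (minutes): median 1, IQR [1, 2],
# range 0.5-5, emulating sporadic bedside-archive sampling.
_INTERVAL_CHOICES = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0])
_INTERVAL_PROBS = np.array([0.20, 0.40, 0.10, 0.15, 0.07, 0.05, 0.03])


@dataclass
class ReactivityDist:
    """Distribution of the per-patient latent coupling on [-1, 1].

    kind: ``truncnorm`` (mean, sd, lo, hi), ``uniform`` (lo, hi) or
    ``point`` (value).
    """

    kind: str = "truncnorm"
    mean: float = 0.1
    sd: float = 0.25
    lo: float = -0.8
    hi: float = 0.9
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("truncnorm", "uniform", "point"):
            raise ValueError(f"unknown reactivity distribution {self.kind!r}")
        if not (-1 <= self.lo <= self.hi <= 1):
            raise ValueError("support must satisfy -1 <= lo <= hi <= 1")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(size, float(self.value))
        if self.kind == "uniform":
            return rng.uniform(self.lo, self.hi, size)
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=size, random_state=rng
        )

    @property
    def support(self) -> tuple[float, float]:
        if self.kind == "point":
            return (self.value, self.value)
        return (self.lo, self.hi)


@dataclass
class StepOutcome:
    """P(death) jumps from ``p_below`` to ``p_above`` at ``theta_star``."""

    theta_star: float = 0.30
    p_below: float = 0.10
    p_above: float = 0.70

    def p_death(self, rho: np.ndarray) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        return np.where(rho > self.theta_star, self.p_above, self.p_below)


@dataclass
class LogisticOutcome:
    """P(death) = expit(intercept + slope * rho)."""

    intercept: float = -2.0
    slope: float = 4.0

    def p_death(self, rho: np.ndarray) -> np.ndarray:
        return expit(self.intercept + self.slope * np.asarray(rho, dtype=float))


@dataclass
class SimParams:
    """Full specification of a synthetic cohort."""

    n_patients: int = 100
    stay_range_days: tuple[float, float] = (1.0, 16.0)
    map_baseline: float = 78.0
    icp_baseline: float = 12.0
    slow_wave_period_range: tuple[float, float] = (10.0, 60.0)
    slow_wave_amplitude: float = 4.0
    noise_sd_map: float = 4.0
    noise_sd_icp: float = 3.0
    icp_coupling_gain: Optional[float] = None  # defaults to noise_sd_icp
    reactivity_distribution: ReactivityDist = field(default_factory=ReactivityDist)
    outcome_model: StepOutcome | LogisticOutcome = field(default_factory=StepOutcome)
    favorable_center: float = 0.05  # survivor favorable-vs-not logistic
    favorable_slope: float = 3.0
    frac_evd: float = 0.5
    drainage_rate: float = 2.0  # expected open-drain episodes / day (EVD)
    artifact_rate: float = 1.0  # expected out-of-range spikes / day / signal
    sampling_interval_range: tuple[float, float] = (0.5, 5.0)
    seed: int = 0
    # break-day extension: after this many minutes the coupling switches to an
    # independently resampled rho (outcomes stay tied to the initial rho)
    reactivity_break_minute: Optional[float] = None
    # windowed sample correlations are biased toward 0 for short windows;
    # when set, the coupling coefficient is inflated so the *expected
    # n-sample correlation* equals rho for this window length
    calibrate_window: Optional[int] = 10

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.drainage_rate < 0 or self.artifact_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.frac_evd <= 1:
            raise ValueError("frac_evd must be in [0, 1]")
        lo, hi = self.stay_range_days
        if lo <= 0 or hi < lo:
            raise ValueError("stay_range_days must be a positive increasing pair")
        slo, shi = self.sampling_interval_range
        if not 0 < slo <= shi:
            raise ValueError("sampling_interval_range must be positive increasing")
        if isinstance(self.outcome_model, StepOutcome):
            m = self.outcome_model
            if not (0 <= m.p_below <= 1 and 0 <= m.p_above <= 1):
                raise ValueError("step probabilities must be in [0, 1]")
            lo_r, hi_r = self.reactivity_distribution.support
            if not lo_r <= m.theta_star <= hi_r:
                raise ValueError("theta_star must lie within the reactivity support")

    @property
    def coupling_gain(self) -> float:
        if self.icp_coupling_gain is not None:
            return self.icp_coupling_gain
        return self.noise_sd_icp if self.noise_sd_icp > 0 else 3.0

    @property
    def expected_sampling_interval(self) -> float:
        """Mean inter-sample interval implied by the sampling distribution."""
        lo, hi = self.sampling_interval_range
        if lo == hi:
            return lo
        mask = (_INTERVAL_CHOICES >= lo) & (_INTERVAL_CHOICES <= hi)
        probs = _INTERVAL_PROBS[mask] / _INTERVAL_PROBS[mask].sum()
        return float(np.sum(_INTERVAL_CHOICES[mask] * probs))


@dataclass
class GroundTruth:
    patient_id: str
    rho_true: float
    outcome_gos: int

    def __post_init__(self) -> None:
        if not -1 <= self.rho_true <= 1:
            raise ValueError("rho_true must be in [-1, 1]")
        if not 1 <= int(self.outcome_gos) <= 5:
            raise ValueError("outcome_gos must be in 1..5")


def debias_rho(rho: float, n: int) -> float:
    """Coupling coefficient whose expected n-sample correlation is ``rho``.

    Inverts the first-order small-sample bias of the Pearson estimator,
    E[r] ~= x * (1 - (1 - x^2) / (2 * (n - 1))), on [-1, 1] (monotone).
    """
    if abs(rho) >= 1 or n <= 2:
        return float(rho)
    coef = 1.0 / (2.0 * (n - 1))
    x = float(rho)
    for _ in range(50):
        f = x * (1 - coef * (1 - x * x)) - rho
        df = 1 - coef + 3 * coef * x * x
        step = f / df
        x -= step
        if abs(step) < 1e-12:
            break
    return float(np.clip(x, -1.0, 1.0))


_CALIBRATION_CACHE: dict = {}


def _calibration_curve(params: "SimParams") -> tuple[np.ndarray, np.ndarray]:
    """Measured mean-window-correlation response of the configured process.

    Short windowed correlations are attenuated relative to the per-pair
    coupling (small-sample bias plus the reduced within-window variance of
    slow waves).  A deterministic internal probe simulation measures the
    response so the coupling can invert it, keeping the contract that the
    expected window correlation equals the requested rho.
    """
    key = (
        params.slow_wave_amplitude, params.noise_sd_map, params.noise_sd_icp,
        params.coupling_gain, params.slow_wave_period_range,
        params.sampling_interval_range, params.calibrate_window,
    )
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    from dataclasses import replace

    from .signal import moving_pearson, to_minute_grid

    probe_params = replace(
        params, calibrate_window=None, reactivity_break_minute=None
    )
    probes = np.array([0.2, 0.45, 0.7, 0.9])
    measured = []
    for rho in probes:
        vals = []
        for seed in (90001, 90002, 90003):
            map_s, icp_s = generate_patient_series(
                float(rho), 1440.0, probe_params, seed
            )
            x, y = to_minute_grid(map_s), to_minute_grid(icp_s)
            T = max(len(x), len(y))
            xv = np.full(T, np.nan)
            xv[: len(x)] = x.v
            yv = np.full(T, np.nan)
            yv[: len(y)] = y.v
            r = moving_pearson(xv, yv, params.calibrate_window)
            vals.append(np.nanmean(r))
        measured.append(float(np.mean(vals)))
    xs = np.maximum.accumulate(np.r_[0.0, measured, 1.0])
    ys = np.r_[0.0, probes, 1.0]
    _CALIBRATION_CACHE[key] = (xs, ys)
    return xs, ys


def _calibrated_coupling(rho: float, params: "SimParams") -> float:
    """Coupling coefficient whose expected window correlation is ``rho``."""
    if (
        params.calibrate_window is None
        or params.noise_sd_icp == 0
        or abs(rho) >= 1
    ):
        return float(rho)
    xs, ys = _calibration_curve(params)
    return float(np.sign(rho) * np.interp(abs(rho), xs, ys))


def _slow_waves(
    rng: np.random.Generator, t: np.ndarray, amplitude: float,
    period_range: tuple[float, float],
) -> np.ndarray:
    """Sum of 1-3 sinusoids with random period/phase, total amplitude scaled."""
    k = int(rng.integers(1, 4))
    out = np.zeros_like(t)
    for _ in range(k):
        period = rng.uniform(*period_range)
        phase = rng.uniform(0, 2 * math.pi)
        out += np.sin(2 * math.pi * t / period + phase)
    return out * (amplitude / math.sqrt(k))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _sample_intervals(
    rng: np.random.Generator, duration: float, lo: float, hi: float
) -> np.ndarray:
    if lo == hi:
        n = int(duration / lo)
        return np.full(n, lo)
    mask = (_INTERVAL_CHOICES >= lo) & (_INTERVAL_CHOICES <= hi)
    choices = _INTERVAL_CHOICES[mask]
    probs = _INTERVAL_PROBS[mask] / _INTERVAL_PROBS[mask].sum()
    n_est = int(duration / choices.min()) + 2
    return rng.choice(choices, size=n_est, p=probs)


def _median_aggregate(
    base: np.ndarray, t: np.ndarray, agg: np.ndarray
) -> np.ndarray:
    """Median of the latent base grid over ``(t - agg, t]`` for each sample."""
    j = np.rint(t / _BASE_DT).astype(int)
    m = np.rint(agg / _BASE_DT).astype(int)
    out = np.empty(t.size)
    for mm in np.unique(m):
        sel = m == mm
        idx = j[sel, None] - np.arange(mm - 1, -1, -1)[None, :]
        out[sel] = np.median(base[idx], axis=1)
    return out


def generate_patient_series(
    rho: float,
    duration: float,
    params: SimParams,
    seed: int,
) -> tuple[PhysioSeries, PhysioSeries]:
    """Generate one patient's paired (MAP, ICP) sporadic series.

    Returns ``(map_series, icp_series)`` on a shared irregular sampling grid.
    Reproducible: a fixed ``seed`` yields bit-identical series.
    """
    if not -1 <= rho <= 1:
        raise ValueError(f"rho must be in [-1, 1], got {rho}")
    if duration < 360:
        raise ValueError(
            "duration must be at least 360 min (inclusion requires > 6 h)"
        )
    rng = np.random.default_rng(seed)
    tb = np.arange(0.0, duration + _BASE_DT / 2, _BASE_DT)

    slow = _slow_waves(rng, tb, params.slow_wave_amplitude,
                       params.slow_wave_period_range)
    map_fluct = slow + params.noise_sd_map * rng.standard_normal(tb.size)
    map_base = params.map_baseline + map_fluct

    z = _standardize(map_fluct)
    # independent component: same spectral character as the shared one
    w_slow = _slow_waves(rng, tb, params.slow_wave_amplitude,
                         params.slow_wave_period_range)
    w = _standardize(w_slow + params.noise_sd_map * rng.standard_normal(tb.size))

    def effective(r: float) -> float:
        return _calibrated_coupling(r, params)

    rho_t = np.full(tb.size, effective(float(rho)))
    if params.reactivity_break_minute is not None:
        late = tb >= params.reactivity_break_minute
        if late.any():
            rho_late = float(params.reactivity_distribution.sample(rng, 1)[0])
            rho_t[late] = effective(rho_late)
    coupled = params.coupling_gain * rho_t * z
    indep = params.noise_sd_icp * np.sqrt(1.0 - rho_t**2) * w
    icp_base = params.icp_baseline + coupled + indep
    # keep the latent signals strictly inside the validity limits so that
    # injected artifacts are the *only* out-of-range samples (exact
    # round-trip accounting); binds with negligible probability
    icp_base = np.clip(icp_base, 0.5, 79.5)
    map_base = np.clip(map_base, 0.5, 399.5)

    lo, hi = params.sampling_interval_range
    intervals = _sample_intervals(rng, duration, lo, hi)
    t = np.cumsum(intervals)
    keep = t <= duration
    t, agg = t[keep], intervals[keep]

    map_v = _median_aggregate(map_base, t, agg)
    icp_v = _median_aggregate(icp_base, t, agg)
    return (
        PhysioSeries(t.copy(), map_v, agg.copy()),
        PhysioSeries(t.copy(), icp_v, agg.copy()),
    )


def inject_artifacts(
    series: PhysioSeries,
    rate: float,
    seed: int,
    limits: tuple[float, float] = (0.0, 80.0),
) -> tuple[PhysioSeries, np.ndarray]:
    """Overwrite Poisson-many samples with out-of-range spike values.

    ``rate`` is the expected number of artifacts per monitored day.  Returns
    the corrupted series and the (sorted) indices of the injected samples,
    so round-trip bookkeeping against artifact filtering is exact.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    days = series.span / 1440.0
    n = int(rng.poisson(rate * days)) if rate > 0 else 0
    n = min(n, len(series))
    if n == 0:
        return series, np.array([], dtype=int)
    pos = np.sort(rng.choice(len(series), size=n, replace=False))
    lo, hi = limits
    v = series.v.copy()
    high = rng.random(n) < 0.5
    v[pos[high]] = hi + rng.uniform(0, 20, int(high.sum()))
    v[pos[~high]] = lo  # at the limit: removed under strict inequality
    return series.with_values(v), pos


def _draw_gos(
    rng: np.random.Generator, rho: np.ndarray, params: SimParams
) -> np.ndarray:
    p_dead = params.outcome_model.p_death(rho)
    dead = rng.random(rho.size) < p_dead
    p_fav = expit(-(rho - params.favorable_center) * params.favorable_slope)
    fav = rng.random(rho.size) < p_fav
    half = rng.random(rho.size) < 0.5
    gos = np.where(fav, np.where(half, 4, 5), np.where(half, 2, 3))
    gos[dead] = 1
    return gos.astype(int)


def generate_cohort(
    params: SimParams,
) -> tuple[list[PatientRecord], list[GroundTruth]]:
    """Generate a full cohort of patient records with ground truth."""
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    records: list[PatientRecord] = []
    truths: list[GroundTruth] = []
    if n == 0:
        return records, truths

    rho = params.reactivity_distribution.sample(rng, n)
    stays = rng.uniform(*params.stay_range_days, n) * 1440.0
    stays = np.maximum(stays, 361.0)
    evd = rng.random(n) < params.frac_evd
    gos = _draw_gos(rng, rho, params)
    child_seeds = rng.integers(0, 2**31 - 1, size=(n, 4))

    for i in range(n):
        pid = f"P{i:04d}"
        map_s, icp_s = generate_patient_series(
            float(rho[i]), float(stays[i]), params, int(child_seeds[i, 0])
        )
        drainage: list[tuple[float, float]] = []
        if evd[i] and params.drainage_rate > 0:
            drng = np.random.default_rng(int(child_seeds[i, 1]))
            t0 = 0.0
            while True:
                t0 += drng.exponential(1440.0 / params.drainage_rate)
                if t0 >= stays[i]:
                    break
                dur = drng.uniform(5.0, 60.0)
                drainage.append((t0, min(t0 + dur, stays[i])))
                t0 += dur
        icp_s, icp_art = inject_artifacts(
            icp_s, params.artifact_rate, int(child_seeds[i, 2]), limits=(0.0, 80.0)
        )
        map_s, map_art = inject_artifacts(
            map_s, params.artifact_rate, int(child_seeds[i, 3]), limits=(0.0, 400.0)
        )
        cov = _draw_covariates(rng)
        records.append(
            PatientRecord(
                patient_id=pid,
                monitor_type="EVD" if evd[i] else "IPD",
                icp=icp_s,
                map=map_s,
                drainage_intervals=drainage,
                gos=int(gos[i]),
                covariates=cov,
                meta={
                    "icp_artifacts_injected": int(icp_art.size),
                    "map_artifacts_injected": int(map_art.size),
                },
            )
        )
        truths.append(GroundTruth(pid, float(rho[i]), int(gos[i])))
    return records, truths


def _draw_covariates(rng: np.random.Generator) -> dict:
    pupils = rng.choice(
        ["bilat_reactive", "unilateral_unreactive", "bilat_unreactive"],
        p=[0.75, 0.14, 0.11],
    )
    return {
        "age": float(np.clip(rng.normal(50, 15), 16, 90)),
        "sex_male": bool(rng.random() < 0.78),
        "gcs": int(rng.integers(3, 9)),
        "pupils": str(pupils),
        "hypoxia": bool(rng.random() < 0.31),
        "hypotension": bool(rng.random() < 0.32),
        "epidural_hematoma": bool(rng.random() < 0.16),
        "surgical_evacuation": bool(rng.random() < 0.60),
        "dc_primary": bool(rng.random() < 0.08),
        "dc_secondary": bool(rng.random() < 0.02),
        "marshall": int(rng.integers(1, 7)),
    }
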