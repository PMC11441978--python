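"""FRAP normalization, single-exponential recovery fitting, half times.

A fluorescence-recovery-after-photobleaching series is normalized to
percent of the mean pre-bleach intensity and fit, from the bleach frame
onward, with the one-component recovery model

    I(t) = D + (P − D) · (1 − exp(−k t)),

where D is the bleach depth (%), P the recovery plateau (%), and
k the recovery rate; the half recovery time is ln 2 / k and the mobile
fraction (P − D)/(100 − D). A single-exponential model is the minimal
model consistent with summarizing recovery by one half time; a
two-component fit is available behind a flag but is not the default.

Replicates are fit separately (the replicate SD is the reported error),
and the fit of the replicate-averaged curve plus a model-free reading
of the half-recovery crossing are also reported for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class FrapSeries:
    """One FRAP time series normalized to percent of pre-bleach."""

    times_s: np.ndarray
    raw: np.ndarray
    bleach_index: int
    normalized: np.ndarray  # percent of mean pre-bleach intensity

    @property
    def post_times_s(self) -> np.ndarray:
        """Times measured from the bleach frame."""
        return self.times_s[self.bleach_index :] - self.times_s[self.bleach_index]

    @property
    def post_values(self) -> np.ndarray:
        return self.normalized[self.bleach_index :]


@dataclass(frozen=True)
class FrapFit:
    bleach_depth_pct: float
    plateau_pct: float
    rate_per_s: float
    half_time_s: float
    half_time_sd_s: float
    mobile_fraction: float
    replicate_half_times_s: np.ndarray
    averaged_curve_half_time_s: float
    crossing_half_time_s: float


def normalize_frap(
    raw: np.ndarray,
    bleach_index: int,
    times: np.ndarray | None = None,
    frame_interval_s: float = 3.0,
) -> FrapSeries:
    """Normalize a raw series to percent of the mean pre-bleach intensity."""
    raw = np.asarray(raw, dtype=float)
    if bleach_index < 1:
        raise ValueError("bleach_index must be >= 1 (need pre-bleach frames)")
    if bleach_index >= raw.size:
        raise ValueError("bleach_index beyond end of series")
    pre_mean = raw[:bleach_index].mean()
    if not pre_mean > 0:
        raise ValueError("pre-bleach mean must be positive")
    if times is None:
        times = np.arange(raw.size) * frame_interval_s
    times = np.asarray(times, dtype=float)
    if times.size != raw.size or np.any(np.diff(times) <= 0):
        raise ValueError("times must match the series and be strictly increasing")
    return FrapSeries(times, raw, bleach_index, 100.0 * raw / pre_mean)


def _recovery_model(t: np.ndarray, d: float, p: float, k: float) -> np.ndarray:
    return d + (p - d) * (1.0 - np.exp(-k * t))


def _fit_single(t: np.ndarray, y: np.ndarray, restarts: int, seed: int) -> tuple[float, float, float]:
    """Fit (D, P, k); deterministic initialization plus jittered restarts."""
    d0 = float(y[0])
    p0 = float(y[-5:].mean())
    half_level = 0.5 * (d0 + p0)
    above = np.nonzero(y >= half_level)[0]
    t_half = t[above[0]] if above.size and t[above[0]] > 0 else (t[-1] / 4 or 1.0)
    k0 = math.log(2.0) / t_half
    lo = [0.0, 0.0, 1e-6]
    hi = [200.0, 200.0, np.inf]
    rng = np.random.default_rng(seed)
    best, best_cost = None, np.inf
    for trial in range(restarts + 1):
        if trial == 0:
            guess = [d0, p0, k0]
        else:
            guess = [
                max(d0 * rng.uniform(0.5, 1.5), 1e-3),
                max(p0 * rng.uniform(0.8, 1.2), 1e-3),
                k0 * rng.uniform(0.3, 3.0),
            ]
        try:
            popt, _ = curve_fit(
                _recovery_model, t, y, p0=guess, bounds=(lo, hi), maxfev=20000
            )
        except RuntimeError:
            continue
        cost = float(np.sum((_recovery_model(t, *popt) - y) ** 2))
        if cost < best_cost:
            best, best_cost = popt, cost
    if best is None:
        raise RuntimeError("recovery fit did not converge after restarts")
    d, p, k = (float(v) for v in best)
    if k <= 0:
        raise RuntimeError("non-positive recovery rate at optimum")
    return d, p, k


def crossing_half_time(series: FrapSeries) -> float:
    """Model-free half time: first crossing of (D + P)/2, linearly interpolated."""
    return _crossing(series.post_times_s, series.post_values)


def _crossing(t: np.ndarray, y: np.ndarray) -> float:
    d, p = y[0], float(y[-5:].mean())
    level = 0.5 * (d + p)
    above = np.nonzero(y >= level)[0]
    if above.size == 0 or above[0] == 0:
        return float("nan")
    i = above[0]
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def fit_recovery(replicates: list[FrapSeries], restarts: int = 3, seed: int = 0) -> FrapFit:
    """Fit each replicate separately and aggregate half recovery times.

    The reported half time is the mean of replicate half times with its
    SD across replicates; D, P, k are from the fit of the
    replicate-averaged curve, which is also summarized by its own half
    time and the model-free crossing estimate.
    """
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    for rep in replicates:
        if rep.post_values.size < 5:
            raise ValueError("need at least 5 post-bleach frames per replicate")
    half_times = []
    for i, rep in enumerate(replicates):
        _, _, k = _fit_single(rep.post_times_s, rep.post_values, restarts, seed + i)
        half_times.append(math.log(2.0) / k)
    half_times = np.asarray(half_times)

    t0 = replicates[0].post_times_s
    if any(rep.post_values.size != t0.size for rep in replicates):
        raise ValueError("replicates must share the acquisition grid")
    avg_curve = np.mean([rep.post_values for rep in replicates], axis=0)
    d, p, k_avg = _fit_single(t0, avg_curve, restarts, seed + 1000)
    mobile = (p - d) / (100.0 - d) if d < 100.0 else float("nan")
    return FrapFit(
        bleach_depth_pct=d,
        plateau_pct=p,
        rate_per_s=k_avg,
        half_time_s=float(half_times.mean()),
        half_time_sd_s=float(half_times.std(ddof=1)) if half_times.size > 1 else 0.0,
        mobile_fraction=mobile,
        replicate_half_times_s=half_times,
        averaged_curve_half_time_s=math.log(2.0) / k_avg,
        crossing_half_time_s=_crossing(t0, avg_curve),
    )


def fit_recovery_biexponential(series: FrapSeries, seed: int = 0):
    """Optional two-component recovery fit (fast + slow pools).

    Returns (d, p, k_fast, k_slow, fast_fraction). Not the default
    summary; provided for series that a single exponential underfits.
    """
    t, y = series.post_times_s, series.post_values

    def model(t, d, p, kf, ks, a):
        return d + (p - d) * (1.0 - a * np.exp(-kf * t) - (1 - a) * np.exp(-ks * t))

    d0, p0 = float(y[0]), float(y[-5:].mean())
    popt, _ = curve_fit(
        model,
        t,
        y,
        p0=[d0, p0, 0.1, 0.01, 0.5],
        bounds=([0, 0, 1e-6, 1e-7, 0], [200, 200, np.inf, np.inf, 1]),
        maxfev=40000,
    )
    return tuple(float(v) for v in popt)
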