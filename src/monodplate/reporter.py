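"""Promoter activity from OD+GFP series and pulse detection.

Promoter activity is the rate of GFP accumulation per unit biomass,
PA(t) = (dGFP/dt) / OD(t), with the derivative taken as a sliding-window OLS
slope on the GFP grid (default 24 min = 3 GFP samples) and OD interpolated
onto the GFP grid linearly in ln(OD). The reporter (GFPmut2) is treated as
fast-folding and stable: no maturation delay, no degradation.

Pulse detection compares PA to an exponential-phase basal level. Basal
activity is nutrient-level independent, so a basal measured on a non-limiting
control may be supplied; otherwise the median over the condition's own
exponential window (times up to the deceleration start) is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import defaults
from .calibration import SubstrateSeries
from .growth import ArrestResult, ConditionSeries


@dataclass
class PASeries:
    """Promoter activity on the interior of the GFP grid (AU/OD/min)."""

    times: np.ndarray
    pa: np.ndarray
    sem_pa: np.ndarray | None
    window_min: float


@dataclass
class PulseResult:
    """Features of the pre-arrest promoter-activity pulse."""

    detected: bool
    basal_pa: float
    onset_time: float | None = None        # min
    onset_substrate: float | None = None   # mM
    peak_time: float | None = None
    peak_pa: float | None = None
    fold_change: float | None = None
    shutdown_time: float | None = None
    generations_before_arrest: float | None = None


def promoter_activity_series(series: ConditionSeries,
                             window_min: float = defaults.PA_WINDOW) -> PASeries:
    """PA(t) = [sliding OLS slope of mean GFP vs time] / mean OD(t).

    Defined on GFP-grid points whose window is not truncated. The SEM is
    propagated from the replicate SEMs of the GFP points in each window
    (OD error contributes negligibly in comparison).
    """
    if series.mean_gfp is None or series.gfp_times is None:
        raise ValueError(f"condition {series.condition_id!r} has no GFP channel")
    tg = series.gfp_times
    gfp = series.mean_gfp
    dt = float(np.min(np.diff(tg)))
    if window_min < 2 * dt - 1e-9:
        raise ValueError("PA window must cover at least 2 GFP intervals")
    half = window_min / 2.0

    # OD interpolated onto the GFP grid, linear in ln OD
    od_g = np.exp(np.interp(tg, series.times, np.log(series.mean_od)))

    times, pa, sem = [], [], []
    for i in range(tg.size):
        lo = np.searchsorted(tg, tg[i] - half - 1e-9, side="left")
        hi = np.searchsorted(tg, tg[i] + half + 1e-9, side="right")
        t = tg[lo:hi]
        if t.size < 2 or t[-1] - t[0] < window_min - dt - 1e-9:
            continue  # truncated endpoint window
        tc = t - t.mean()
        denom = float(np.dot(tc, tc))
        slope = float(np.dot(tc, gfp[lo:hi])) / denom
        times.append(tg[i])
        pa.append(slope / od_g[i])
        if series.sem_gfp is not None:
            var = float(np.dot(tc**2, series.sem_gfp[lo:hi] ** 2)) / denom**2
            sem.append(math.sqrt(var) / od_g[i])
    if not times:
        raise ValueError("series too short for the PA window")
    return PASeries(
        times=np.asarray(times), pa=np.asarray(pa),
        sem_pa=np.asarray(sem) if sem else None, window_min=window_min,
    )


def detect_pulse(pa: PASeries, ss: SubstrateSeries, arrest: ArrestResult,
                 basal_pa: float | None = None, k_onset: float = 0.5,
                 shutdown_factor: float = 1.5, min_fold: float = 2.0,
                 persistence: int = 2) -> PulseResult:
    """Detect and quantify the pre-arrest promoter-activity pulse.

    * basal: median PA over the exponential window (t <= deceleration start),
      unless an externally measured ``basal_pa`` is supplied;
    * onset: the sample preceding the first run of ``persistence`` samples
      with PA > basal*(1+k_onset) (counters the one-sample detection lag);
      when the series starts above threshold the first sample is the onset;
    * peak: maximum PA after onset; detection requires peak/basal >= min_fold;
    * shutdown: first post-peak time with PA <= shutdown_factor*basal;
    * generations before arrest: (t_arrest - peak_time) * mu_max / ln 2.

    The onset/peak search is restricted to times up to the detected arrest:
    the pulse precedes the stop of growth, and once growth (and hence GFP
    accumulation) has ceased the windowed slope of the large flat GFP signal
    is measurement noise.
    """
    if basal_pa is None:
        if arrest.t_dec_start is None:
            raise ValueError("no deceleration start available for the basal "
                             "window; supply basal_pa explicitly")
        basal_mask = pa.times <= arrest.t_dec_start
        if basal_mask.sum() < 3:
            raise ValueError("fewer than 3 PA samples in the basal window; "
                             "supply basal_pa from a non-limiting control")
        basal_pa = float(np.median(pa.pa[basal_mask]))
    if basal_pa <= 0:
        raise ValueError("basal promoter activity must be positive")

    last = len(pa.pa)
    if arrest.t_arrest is not None:
        last = int(np.searchsorted(pa.times, arrest.t_arrest, side="right"))
    if last < persistence + 1:
        return PulseResult(detected=False, basal_pa=basal_pa)

    above = pa.pa[:last] > basal_pa * (1.0 + k_onset)
    onset_idx = None
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= persistence:
            onset_idx = max(i - persistence, 0)  # sample before the run
            break
    if onset_idx is None:
        return PulseResult(detected=False, basal_pa=basal_pa)

    seg = slice(onset_idx, last)
    peak_rel = int(np.argmax(pa.pa[seg]))
    peak_idx = onset_idx + peak_rel
    peak_pa = float(pa.pa[peak_idx])
    fold = peak_pa / basal_pa
    onset_time = float(pa.times[onset_idx])
    onset_substrate = float(np.interp(onset_time, ss.times, ss.s))
    peak_time = float(pa.times[peak_idx])

    shutdown_time = None
    post = pa.pa[peak_idx:]
    below = post <= shutdown_factor * basal_pa
    if below.any():
        shutdown_time = float(pa.times[peak_idx + int(np.argmax(below))])

    generations = None
    if arrest.t_arrest is not None and arrest.mu_max > 0:
        generations = (arrest.t_arrest - peak_time) * (arrest.mu_max / 60.0) / math.log(2)

    return PulseResult(
        detected=bool(fold >= min_fold), basal_pa=basal_pa,
        onset_time=onset_time, onset_substrate=onset_substrate,
        peak_time=peak_time, peak_pa=peak_pa, fold_change=float(fold),
        shutdown_time=shutdown_time, generations_before_arrest=generations,
    )
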