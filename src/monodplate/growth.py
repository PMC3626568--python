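"""Replicate averaging, growth-rate estimation and growth-arrest analysis.

The growth rate is the logarithmic derivative of the averaged OD signal,
estimated as the slope of a sliding-window ordinary-least-squares line of
ln(OD) against time (default window 21 min = 7 OD samples). Arrest detection
operationalises "zero growth" as the rate staying below 5% of its maximum
for at least 15 min, and classifies the stop as abrupt, mixed or gradual
from the duration and shape of the deceleration phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import defaults
from .plates import PlateDataset


@dataclass
class ConditionSeries:
    """Replicate-averaged trajectory of one condition."""

    condition_id: str
    times: np.ndarray            # OD grid (min)
    mean_od: np.ndarray
    sem_od: np.ndarray | None    # None when only one well is present
    n_wells: int
    gfp_times: np.ndarray | None = None
    mean_gfp: np.ndarray | None = None
    sem_gfp: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValueError("a condition needs at least one well")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class GrowthRateSeries:
    """Instantaneous growth rate mu(t) on the OD grid (1/h)."""

    times: np.ndarray
    mu: np.ndarray
    window_min: float
    mu_max: float
    generation_time: float  # ln2/mu_max, in minutes
    full_support: np.ndarray | None = None  # points with >= half-window support


@dataclass
class ArrestResult:
    """Detected growth arrest and its classification."""

    t_arrest: float | None       # first sustained time mu <= frac_low*mu_max
    t_dec_start: float | None    # last time mu >= frac_high*mu_max before it
    T_dec: float | None          # deceleration duration (min)
    stop_class: str              # abrupt | mixed | gradual | no-arrest
    mu_max: float
    frac_high: float
    frac_low: float
    sustain_min: float


def average_replicates(dataset: PlateDataset) -> dict[str, ConditionSeries]:
    """Per-condition mean and SEM over the wells present, channel by channel.

    Missing wells (in the design but absent from the records) simply reduce
    the per-timepoint n. SEM is reported only when n >= 2.
    """
    out: dict[str, ConditionSeries] = {}
    for cid in dataset.design.conditions:
        od_wide = dataset.values(cid, "OD600")
        if od_wide.shape[1] == 0:
            raise ValueError(f"condition {cid!r} has no wells with OD data")
        times = od_wide.index.to_numpy(dtype=float)
        n = int(od_wide.shape[1])
        mean_od = od_wide.mean(axis=1).to_numpy()
        sem_od = (od_wide.std(axis=1, ddof=1) / math.sqrt(n)).to_numpy() if n >= 2 else None

        gfp_wide = dataset.values(cid, "GFP535")
        gfp_times = mean_gfp = sem_gfp = None
        if gfp_wide.shape[1] > 0:
            gfp_times = gfp_wide.index.to_numpy(dtype=float)
            ng = int(gfp_wide.shape[1])
            mean_gfp = gfp_wide.mean(axis=1).to_numpy()
            sem_gfp = (
                (gfp_wide.std(axis=1, ddof=1) / math.sqrt(ng)).to_numpy()
                if ng >= 2 else None)

        out[cid] = ConditionSeries(
            condition_id=cid, times=times, mean_od=mean_od, sem_od=sem_od,
            n_wells=n, gfp_times=gfp_times, mean_gfp=mean_gfp, sem_gfp=sem_gfp,
        )
    return out


def sliding_log_slope(times: np.ndarray, values: np.ndarray,
                      window_min: float) -> tuple[np.ndarray, np.ndarray]:
    """OLS slope of ln(values) vs time in a centered sliding window.

    Returns (slopes per minute, full_support mask). Endpoint windows are
    truncated one-sided; a point has full support when its window is not
    truncated (covers the nominal span up to one sampling interval).
    Truncated endpoint estimates are noisier — basing extrema on them would
    bias the maximal rate upward — so they are excluded from mu_max.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("values must be positive for log-slope estimation")
    half = window_min / 2.0
    dt = float(np.min(np.diff(times)))
    logv = np.log(values)
    n = times.size
    slopes = np.empty(n)
    support = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = np.searchsorted(times, times[i] - half - 1e-9, side="left")
        hi = np.searchsorted(times, times[i] + half + 1e-9, side="right")
        t = times[lo:hi]
        if t.size < 2:
            slopes[i] = np.nan
            continue
        tc = t - t.mean()
        slopes[i] = np.dot(tc, logv[lo:hi]) / np.dot(tc, tc)
        support[i] = (t[-1] - t[0]) >= window_min - dt - 1e-9
    return slopes, support


def growth_rate_series(series: ConditionSeries,
                       window_min: float = defaults.GROWTH_WINDOW) -> GrowthRateSeries:
    """Logarithmic derivative of the averaged OD, in 1/h.

    mu_max is taken over points whose window spans at least half its nominal
    width, and the generation time is ln2/mu_max in minutes.
    """
    dt = np.min(np.diff(series.times))
    if window_min < 2 * dt - 1e-9:
        raise ValueError("window must cover at least 2 sampling intervals")
    if window_min > series.times[-1] - series.times[0]:
        raise ValueError("window larger than the series span")
    slopes, support = sliding_log_slope(series.times, series.mean_od, window_min)
    mu = slopes * 60.0  # 1/min -> 1/h
    eligible = mu[support & np.isfinite(mu)]
    if eligible.size == 0:
        raise ValueError("no growth-rate points with sufficient window support")
    mu_max = float(np.max(eligible))
    gen = math.log(2) / mu_max * 60.0 if mu_max > 0 else math.inf
    return GrowthRateSeries(times=series.times, mu=mu, window_min=window_min,
                            mu_max=mu_max, generation_time=gen,
                            full_support=support)


def detect_arrest(gr: GrowthRateSeries, frac_high: float = 0.9,
                  frac_low: float = 0.05,
                  sustain_min: float = 15.0) -> ArrestResult:
    """Locate growth arrest and classify the deceleration.

    * t_arrest: first time mu <= frac_low*mu_max sustained for >= sustain_min;
    * t_dec_start: last time before that with mu >= frac_high*mu_max;
    * class: abrupt if T_dec <= 60 min; mixed when a gradual drift below
      frac_high lasting >= 60 min precedes a terminal drop of >= 0.5*mu_max
      completed within 60 min; gradual when no such terminal drop exists.
      A fast terminal drop preceded by less than 60 min of drift is still
      called abrupt (the stop is dominated by the crash).

    When mu never stays below frac_low*mu_max the result is the class
    ``no-arrest`` rather than an exception.
    """
    t, mu = gr.times, gr.mu
    mu_max = gr.mu_max
    low = mu <= frac_low * mu_max

    t_arrest = None
    i = 0
    n = t.size
    while i < n:
        if low[i] and np.isfinite(mu[i]):
            j = i
            while j + 1 < n and low[j + 1]:
                j += 1
            if t[j] - t[i] >= sustain_min:
                t_arrest = t[i]
                break
            i = j + 1
        else:
            i += 1
    if t_arrest is None:
        return ArrestResult(None, None, None, "no-arrest", mu_max,
                            frac_high, frac_low, sustain_min)

    before = (t < t_arrest) & (mu >= frac_high * mu_max)
    if not before.any():
        t_dec_start = float(t[0])
    else:
        t_dec_start = float(t[before][-1])
    T_dec = float(t_arrest - t_dec_start)

    if T_dec <= 60.0:
        stop_class = "abrupt"
    else:
        # terminal drop: a loss of >= 0.5*mu_max completed within 60 min.
        # t_drop = last time in the final hour where mu was still at least
        # 0.5*mu_max above the arrest level; the drift below frac_high before
        # that drop must have lasted >= 60 min for a "mixed" stop.
        mask60 = (t >= t_arrest - 60.0) & (t <= t_arrest) & np.isfinite(mu) \
            & (mu >= (frac_low + 0.5) * mu_max)
        if mask60.any():
            t_drop = float(t[mask60][-1])
            drift = t_drop - t_dec_start
            stop_class = "mixed" if drift >= 60.0 else "abrupt"
        else:
            stop_class = "gradual"

    return ArrestResult(float(t_arrest), t_dec_start, T_dec, stop_class,
                        mu_max, frac_high, frac_low, sustain_min)
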