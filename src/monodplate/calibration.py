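"""Final-OD vs initial-substrate calibration and substrate inference.

Under the constant-yield assumption the final OD of a substrate-limited
culture is linear in the initial substrate level, OD_f = a*s0 + b. The slope
gives the OD-to-substrate conversion c = 1/a (mM per OD unit), and the
instantaneous substrate follows from the OD trajectory,

    s(t) = s(0) - c * OD(t)      (constant-yield relation).

Two anchorings of that relation are provided:

* ``initial``: s(t) = s0 - c*(OD(t) - OD(0)), so s(0) equals the nominal s0.
* ``final``:   s(t) = c*(OD_f - OD(t)), anchored at the exhausted plateau.

The final anchor makes the zero of the substrate axis self-calibrating: it
does not inherit the (tens of μM) uncertainty of the carryover estimate and
is therefore the default for μM-scale half-saturation fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import defaults
from .growth import ArrestResult, ConditionSeries


@dataclass
class FinalOD:
    """Plateau OD of one condition (median over the last ``tail_min``)."""

    value: float
    is_final: bool          # False when the culture is still growing
    tail_min: float
    rel_drift: float        # relative OD change across the tail


@dataclass
class CalibrationResult:
    """OLS line OD_f = a*s0 + b and the derived conversion c = 1/a."""

    a: float
    a_se: float
    b: float
    b_se: float
    c: float
    c_se: float
    r2: float
    conditions_used: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(
                "calibration slope must be positive (non-limiting data?)")


@dataclass
class SubstrateSeries:
    """Inferred substrate trajectory (mM), clipped at zero."""

    times: np.ndarray
    s: np.ndarray
    s0_nominal: float
    c_used: float
    anchor: str
    n_clipped: int
    #: per-point measurement noise of s (mM), estimated from the
    #: high-frequency OD fluctuations of the final plateau; NaN when the
    #: series has no plateau to estimate from
    s_noise_sd: float = float("nan")


def final_od(series: ConditionSeries, tail_min: float = 60.0,
             arrest: ArrestResult | None = None,
             drift_tol: float = 0.02) -> FinalOD:
    """Median OD over the last ``tail_min`` of the series.

    Flagged not-final (and thus excluded from calibration) when the tail
    still drifts by more than ``drift_tol`` relative, or when a detected
    arrest is not at least ``tail_min`` before the end of the series.
    """
    t = series.times
    if t[-1] - t[0] < tail_min:
        raise ValueError("series shorter than the requested tail")
    mask = t >= t[-1] - tail_min
    tail = series.mean_od[mask]
    value = float(np.median(tail))
    half = tail.size // 2
    rel_drift = float(
        (np.median(tail[half:]) - np.median(tail[:half])) / value) if half >= 1 else 0.0
    is_final = abs(rel_drift) <= drift_tol
    if arrest is not None:
        if arrest.t_arrest is None or arrest.t_arrest > t[-1] - tail_min:
            is_final = False
    return FinalOD(value=value, is_final=is_final, tail_min=tail_min,
                   rel_drift=rel_drift)


def fit_final_od_calibration(
    points: list[tuple[float, float]] | list[tuple[str, float, float]],
    s0_max: float = defaults.S0_LIMITING_MAX,
) -> CalibrationResult:
    """OLS fit of final OD against initial substrate on limiting conditions.

    ``points`` are (s0, final_od) pairs, optionally labelled
    (condition_id, s0, final_od). Conditions with s0 > s0_max (default 1 mM,
    below the saturation knee) are excluded. The conversion c = 1/a carries a
    delta-method standard error c_se = a_se/a^2.
    """
    labelled = [
        (str(p[0]), float(p[1]), float(p[2])) if len(p) == 3
        else (f"cond{i}", float(p[0]), float(p[1]))
        for i, p in enumerate(points)
    ]
    used = [p for p in labelled if p[1] <= s0_max]
    s0s = np.array([p[1] for p in used])
    ods = np.array([p[2] for p in used])
    if len(used) < 2 or np.unique(s0s).size < 2:
        raise ValueError(
            f"calibration needs >= 2 distinct limiting s0 values, got {len(used)}")
    res = stats.linregress(s0s, ods)
    a, b = float(res.slope), float(res.intercept)
    if a <= 0:
        raise ValueError("calibration slope is non-positive; are these "
                         "conditions actually substrate-limited?")
    a_se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    b_se = float(res.intercept_stderr) if np.isfinite(res.intercept_stderr) else 0.0
    return CalibrationResult(
        a=a, a_se=a_se, b=b, b_se=b_se,
        c=1.0 / a, c_se=a_se / a**2,
        r2=float(res.rvalue**2), conditions_used=used,
    )


def estimate_carryover(cal: CalibrationResult, od0: float) -> float:
    """Inoculum substrate carryover implied by the calibration intercept.

    OD_f = od0 + (s0 + carry)/c gives b = od0 + carry/c, hence
    carry = c*(b - od0). Clipped at zero.
    """
    return max(0.0, cal.c * (cal.b - od0))


def infer_substrate(series: ConditionSeries, s0: float, c: float,
                    anchor: str = "initial",
                    od_offset: float | None = None,
                    od_final_value: float | None = None) -> SubstrateSeries:
    """Instantaneous substrate from the averaged OD via constant yield.

    ``anchor="initial"``: s(t) = s0 - c*(OD(t) - od_offset) with od_offset
    defaulting to the series' first OD so that s(0) = s0 (pass ``s0``
    including any carryover correction). ``anchor="final"``:
    s(t) = c*(od_final_value - OD(t)), with od_final_value defaulting to the
    median of the last hour. Negative values are clipped at zero and counted.
    """
    if c <= 0:
        raise ValueError("conversion c must be positive")
    od = series.mean_od
    if anchor == "initial":
        offset = float(od[0]) if od_offset is None else float(od_offset)
        raw = s0 - c * (od - offset)
    elif anchor == "final":
        if od_final_value is None:
            od_final_value = final_od(series).value
        raw = c * (od_final_value - od)
    else:
        raise ValueError("anchor must be 'initial' or 'final'")
    n_clipped = int(np.sum(raw < 0))

    # noise scale of the inferred substrate: robust sd of the successive OD
    # differences over the last hour (where the true signal is flat), times c
    tail = series.mean_od[series.times >= series.times[-1] - 60.0]
    s_noise = float("nan")
    if tail.size >= 8:
        d = np.diff(tail)
        mad = np.median(np.abs(d - np.median(d)))
        s_noise = c * 1.4826 * mad / math.sqrt(2.0)

    return SubstrateSeries(times=series.times, s=np.clip(raw, 0.0, None),
                           s0_nominal=float(s0), c_used=float(c),
                           anchor=anchor, n_clipped=n_clipped,
                           s_noise_sd=s_noise)
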