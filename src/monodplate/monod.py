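"""Monod-law fitting: pair instantaneous growth rate with inferred substrate.

Only the deceleration region carries information about the half-saturation
constant, so points are restricted to low substrate (default s <= 0.2 mM)
and to times around the deceleration onset, with the growth rate recomputed
on a narrow (15 min) window; the upper points of that range sit on the
mu ~ mu0 plateau and anchor mu0. Confidence intervals come from a seeded
case-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from . import defaults
from .calibration import SubstrateSeries
from .growth import ArrestResult, GrowthRateSeries


@dataclass
class MonodFitResult:
    """Nonlinear least-squares fit of mu = mu0*s/(Ks+s)."""

    mu0_hat: float              # 1/h
    mu0_ci: tuple[float, float]
    Ks_hat: float               # mM
    Ks_ci: tuple[float, float]
    n_points: int
    rss: float
    converged: bool
    diagnostic: str = ""
    bootstrap_reps: int = 0
    conditions_used: list[str] = field(default_factory=list)


def select_deceleration_points(
    gr: GrowthRateSeries,
    ss: SubstrateSeries,
    s_window: float = defaults.S_FIT_WINDOW,
    arrest: ArrestResult | None = None,
    pair_substrate: str = "log_mean",
    noise_floor_k: float = defaults.S_NOISE_FLOOR_K,
    min_points: int = 5,
) -> np.ndarray:
    """Paired (s, mu) points from the deceleration region, as an (n, 2) array.

    Keeps points with 0 < s <= s_window; when an ``arrest`` is supplied, also
    requires t_dec_start - window <= t <= t_arrest + window (after arrest the
    inferred substrate is read noise around zero and carries no information).

    ``pair_substrate`` selects the substrate value paired with each windowed
    rate estimate:

    * ``"log_mean"`` (default): the logarithmic mean (s1-s2)/ln(s1/s2) of the
      substrate at the window edges. The windowed log-slope is the
      time-average rate over the window, and integrating the Monod system
      across a window (biomass near-constant there) gives exactly
      mu_avg = mu0*(s1-s2)/[(s1-s2) + Ks*ln(s1/s2)] — the Monod form
      evaluated at the log-mean — so this pairing stays on the curve even
      when the window straddles the fast deceleration transition.
    * ``"center"``: the substrate at the window centre.
    * ``"window_mean"``: the time-average substrate over the window. Both
      alternatives sit below the Monod curve during the transition (mu is
      concave in s), inflating the fitted Ks.

    Points whose window edges fall below ``noise_floor_k`` times the
    substrate measurement noise (estimated from the final plateau) are
    excluded: once the substrate is exhausted the inferred s is read noise
    around zero, and pairing those values with mu ~ 0 forces the fitted
    half-saturation up to the noise scale.
    """
    if not np.array_equal(gr.times, ss.times):
        s_on_grid = np.interp(gr.times, ss.times, ss.s)
    else:
        s_on_grid = ss.s

    floor = 0.0
    if noise_floor_k > 0 and np.isfinite(ss.s_noise_sd):
        floor = noise_floor_k * ss.s_noise_sd

    half = gr.window_min / 2.0
    t = gr.times
    if pair_substrate == "center":
        s_pair = np.where(s_on_grid > floor, s_on_grid, np.nan)
    elif pair_substrate in ("window_mean", "log_mean"):
        s_pair = np.full_like(s_on_grid, np.nan)
        for i in range(t.size):
            lo = np.searchsorted(t, t[i] - half - 1e-9, side="left")
            hi = np.searchsorted(t, t[i] + half + 1e-9, side="right")
            win = s_on_grid[lo:hi]
            s1, s2 = win[0], win[-1]
            if s1 <= floor or s2 <= floor or s1 <= 0 or s2 <= 0:
                continue  # an edge is in the exhausted/noise regime
            if pair_substrate == "window_mean":
                s_pair[i] = win.mean()
            else:
                s_pair[i] = (s1 - s2) / np.log(s1 / s2) if s1 != s2 else s1
    else:
        raise ValueError(
            "pair_substrate must be 'log_mean', 'center' or 'window_mean'")

    keep = np.isfinite(s_pair) & (s_pair > 0) & (s_pair <= s_window) \
        & np.isfinite(gr.mu)
    if arrest is not None and arrest.t_dec_start is not None:
        keep &= gr.times >= arrest.t_dec_start - gr.window_min
    if arrest is not None and arrest.t_arrest is not None:
        keep &= gr.times <= arrest.t_arrest + gr.window_min
    pts = np.column_stack([s_pair[keep], gr.mu[keep]])
    if pts.shape[0] < min_points:
        raise ValueError(
            f"only {pts.shape[0]} deceleration points survive selection "
            f"(min_points={min_points}); pool more conditions or seeds")
    return pts


def _monod(s, mu0, Ks):
    return mu0 * s / (Ks + s)


def _fit_once(s: np.ndarray, mu: np.ndarray, robust: bool = True,
              mu0_cap: float | None = None,
              ) -> tuple[float, float, float, bool]:
    """One NLS fit; returns (mu0, Ks, rss, ok).

    ``robust`` uses a soft-L1 loss with scale 0.04/h (about one standard
    error of a narrow-window rate estimate), which tames the occasional
    transition-straddling outlier; at zero residuals it coincides with plain
    least squares. ``mu0_cap`` bounds mu0 above by that multiple of the
    largest observed rate.
    """
    mu0_init = float(np.max(mu))
    half = mu0_init / 2.0
    order = np.argsort(s)
    ks_init = float(np.interp(half, mu[order], s[order]))
    if not np.isfinite(ks_init) or ks_init <= 0:
        ks_init = float(np.median(s))
    model = Model(_monod)
    params = model.make_params(
        mu0=mu0_init if mu0_cap is None else mu0_init * min(mu0_cap, 1.0),
        Ks=ks_init)
    params["mu0"].set(min=1e-9,
                      max=np.inf if mu0_cap is None else mu0_cap * mu0_init)
    params["Ks"].set(min=1e-12)
    kwargs = {}
    if robust:
        kwargs = dict(method="least_squares",
                      fit_kws={"loss": "soft_l1", "f_scale": 0.04})
    try:
        res = model.fit(mu, params, s=s, **kwargs)
    except Exception:
        return np.nan, np.nan, np.nan, False
    return (float(res.params["mu0"].value), float(res.params["Ks"].value),
            float(np.sum(res.residual**2)), bool(res.success))


def fit_monod(points: np.ndarray, bootstrap_reps: int = 500,
              seed: int = 0, span_min: float = 5.0,
              robust: bool = True,
              mu0_cap: float | None = None) -> MonodFitResult:
    """Fit the Monod law to pooled (s, mu) points.

    Initialisation: mu0 from the largest observed rate, Ks from the
    interpolated substrate at half-maximum. A substrate span below
    ``span_min``-fold (default half a decade — below that every point sits on
    one side of the bend and the curvature is unidentifiable) marks Ks as
    unidentifiable (``converged=False``) rather than raising. CIs are 2.5/97.5
    percentiles of ``bootstrap_reps`` case-resampled refits (skipped when
    reps = 0).

    ``mu0_cap``: optional upper bound on mu0, as a multiple of the largest
    observed rate. When the selection window reaches the mu ~ mu0 plateau
    (the pipeline's default selection does), the fitted mu0 cannot
    legitimately exceed the largest rate actually observed; the bound breaks
    the mu0-Ks likelihood ridge that otherwise lets rate noise at the bend
    inflate both parameters together. Leave ``None`` when the points do not
    reach the plateau.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need an (n>=5, 2) array of (s, mu) points")
    s, mu = pts[:, 0], pts[:, 1]
    if np.any(s <= 0):
        raise ValueError("substrate values must be positive")

    mu0_hat, ks_hat, rss, ok = _fit_once(s, mu, robust, mu0_cap)
    diagnostic = ""
    span = float(np.max(s) / np.min(s))
    if span < span_min:
        ok = False
        diagnostic = (f"Ks unidentifiable: substrate span {span:.1f}-fold "
                      f"< {span_min:.0f}-fold")
    elif not ok:
        diagnostic = "optimizer stalled"

    mu0_ci = (mu0_hat, mu0_hat)
    ks_ci = (ks_hat, ks_hat)
    if ok and bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        n = s.size
        boot = np.empty((bootstrap_reps, 2))
        for r in range(bootstrap_reps):
            idx = rng.integers(0, n, size=n)
            m0, ks, _, bok = _fit_once(s[idx], mu[idx], robust, mu0_cap)
            boot[r] = (m0, ks) if bok else (np.nan, np.nan)
        good = boot[np.all(np.isfinite(boot), axis=1)]
        if good.shape[0] >= max(10, bootstrap_reps // 10):
            mu0_ci = tuple(np.percentile(good[:, 0], [2.5, 97.5]))
            ks_ci = tuple(np.percentile(good[:, 1], [2.5, 97.5]))

    return MonodFitResult(
        mu0_hat=mu0_hat, mu0_ci=mu0_ci, Ks_hat=ks_hat, Ks_ci=ks_ci,
        n_points=int(s.size), rss=rss, converged=ok, diagnostic=diagnostic,
        bootstrap_reps=bootstrap_reps,
    )
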