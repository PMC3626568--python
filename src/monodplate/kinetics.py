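"""Deterministic forward models of batch growth on a single limiting substrate.

The core model is Monod growth with yield-coupled substrate depletion,

    dOD/dt = mu(s) * OD,        ds/dt = -c * mu(s) * OD,

with mu(s) = mu0*s/(Ks+s), so that s + c*(OD - od0) is conserved and the
final OD is od0 + (s0 + carryover)/c. Three variants cover the observed
phenotypes:

``regulated``
    The half-saturation constant is transporter-limited and scales inversely
    with the relative assimilation-enzyme level e: Ks_eff = Ks*gain/e. e
    relaxes toward the promoter-activity fold (de/dt = mu0*(PA/basal - e)),
    so e = 1 in basal exponential growth and e -> gain at full induction.
``mutant_no_pulse``
    Same equations with e frozen at 1 (the expression pulse is genetically
    prevented), so the culture decelerates on the basal Ks_eff = Ks*gain.
``nonlimiting_entry``
    Phenomenological density inhibition mu -> mu/(1 + (OD/od_cap)^m) for
    cultures whose nominal substrate would support more biomass than other
    factors allow; models the gradual entry to stationary phase.

A reporter is integrated alongside in every mode: dGFP/dt = PA(s)*OD, where
PA(s) is a band-pass of two Hill gates (activation below theta_on, shutdown
below theta_off).

Units: time min; growth rates 1/h; substrate mM; OD dimensionless; promoter
activity AU/OD/min.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import quad, solve_ivp

from . import defaults

MODES = ("monod", "regulated", "mutant_no_pulse", "nonlimiting_entry")


@dataclass(frozen=True)
class SimParams:
    """Ground-truth kinetic constants for one simulated culture."""

    mu0: float = defaults.MU0          # maximal specific growth rate (1/h)
    Ks: float = defaults.KS_NITROGEN   # Monod half-saturation (mM)
    c: float = defaults.C_NITROGEN     # substrate consumed per OD produced (mM/OD)
    s0: float = 0.2                    # nominal initial substrate (mM)
    s_carryover: float = defaults.S_CARRYOVER_NITROGEN  # inoculum carryover (mM)
    od0: float = defaults.OD0          # inoculum OD
    t_end: float = defaults.T_END      # horizon (min)
    mode: str = "monod"
    density_cap_od: float = 0.45       # OD scale of non-substrate inhibition
    density_cap_exponent: float = 6.0  # steepness of that inhibition
    solver_rel_tol: float = 1e-8
    solver_abs_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")
        if self.Ks <= 0:
            raise ValueError("Ks must be positive")
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.s0 < 0 or self.s_carryover < 0:
            raise ValueError("substrate concentrations must be non-negative")
        if self.od0 <= 0:
            raise ValueError("od0 must be positive")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.solver_rel_tol <= 0 or self.solver_abs_tol <= 0:
            raise ValueError("solver tolerances must be positive")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.density_cap_od <= 0 or self.density_cap_exponent <= 0:
            raise ValueError("density cap parameters must be positive")

    @property
    def s_total(self) -> float:
        """Total available substrate, nominal plus carryover (mM)."""
        return self.s0 + self.s_carryover

    @property
    def od_final(self) -> float:
        """Final OD if all substrate is converted to biomass."""
        return self.od0 + self.s_total / self.c


@dataclass(frozen=True)
class PromoterParams:
    """Band-pass promoter-activity model: basal activity, amplified in the
    window theta_off < s < theta_on by two Hill gates."""

    pa_basal: float = 100.0     # basal activity (AU/OD/min)
    fold_amp: float = 5.0       # peak-to-basal amplitude
    theta_on: float = 0.25      # activation threshold (mM)
    h_on: float = 24.0          # activation Hill coefficient (switch-like)
    theta_off: float = 0.005    # shutdown threshold (mM)
    h_off: float = 4.0          # shutdown Hill coefficient
    enzyme_gain: float = 5.0    # assimilation-capacity boost at full induction

    def __post_init__(self) -> None:
        if self.pa_basal <= 0:
            raise ValueError("pa_basal must be positive")
        if self.fold_amp < 1:
            raise ValueError("fold_amp must be >= 1")
        if not (0 <= self.theta_off < self.theta_on):
            raise ValueError("need 0 <= theta_off < theta_on")
        if self.h_on < 1 or self.h_off < 1:
            raise ValueError("Hill coefficients must be >= 1")
        if self.enzyme_gain < 1:
            raise ValueError("enzyme_gain must be >= 1")


@dataclass
class Trajectory:
    """Deterministic solution of one simulated culture on a time grid."""

    times: np.ndarray   # min
    od: np.ndarray
    s: np.ndarray       # mM
    pa: np.ndarray      # AU/OD/min
    gfp: np.ndarray     # AU
    e: np.ndarray | None = None  # relative enzyme level (regulated/mutant)
    params: SimParams | None = None
    promoter: PromoterParams | None = None

    def mu(self) -> np.ndarray:
        """Instantaneous specific growth rate along the trajectory (1/h)."""
        p = self.params
        if p is None:
            raise ValueError("trajectory has no params attached")
        if p.mode == "monod":
            return monod_mu(self.s, p.mu0, p.Ks)
        if p.mode == "nonlimiting_entry":
            cap = 1.0 + (self.od / p.density_cap_od) ** p.density_cap_exponent
            return monod_mu(self.s, p.mu0, p.Ks) / cap
        e = self.e if self.e is not None else np.ones_like(self.s)
        ks_eff = p.Ks * self.promoter.enzyme_gain / e
        return p.mu0 * self.s / (ks_eff + self.s)


def monod_mu(s, mu0: float, Ks: float):
    """Monod growth rate mu0*s/(Ks+s).

    Parameters
    ----------
    s : float or array
        Substrate concentration (mM), must be >= 0.
    mu0 : float
        Maximal specific growth rate (1/h).
    Ks : float
        Half-saturation constant (mM).
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentration must be non-negative")
    if mu0 <= 0 or Ks <= 0:
        raise ValueError("mu0 and Ks must be positive")
    out = mu0 * s / (Ks + s)
    return float(out) if out.ndim == 0 else out


def promoter_activity(s, p: PromoterParams):
    """Band-pass promoter activity PA(s) in AU/OD/min.

    PA = basal * (1 + (fold-1) * gate_on(s) * gate_off(s)) with
    gate_on = theta_on^h/(theta_on^h + s^h) (rises as s falls below theta_on)
    and gate_off = s^h/(theta_off^h + s^h) (shuts activity down near s = 0).
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentration must be non-negative")
    # Hill gates evaluated via ratios to stay finite at large exponents.
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        gate_on = 1.0 / (1.0 + (s / p.theta_on) ** p.h_on)
        if p.theta_off > 0:
            gate_off = np.where(
                s > 0, 1.0 / (1.0 + (p.theta_off / np.where(s > 0, s, 1.0)) ** p.h_off), 0.0
            )
        else:
            gate_off = np.where(s > 0, 1.0, 0.0)
    out = p.pa_basal * (1.0 + (p.fold_amp - 1.0) * gate_on * gate_off)
    return float(out) if out.ndim == 0 else out


def initial_gfp(params: SimParams, promoter: PromoterParams) -> float:
    """Reporter fluorescence carried in with the inoculum.

    The overnight culture grows in balanced non-limiting conditions where
    GFP/OD settles at pa_basal/mu (steady state of dGFP/dt = PA*OD with
    exponential OD), so the inoculum brings od0 * pa_basal * 60/mu0.
    """
    return params.od0 * promoter.pa_basal * 60.0 / params.mu0


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the solver's diagnostic message."""


def simulate_batch(
    params: SimParams,
    promoter: PromoterParams | None = None,
    grid: Sequence[float] | np.ndarray | None = None,
) -> Trajectory:
    """Integrate one batch culture and return its trajectory on ``grid``.

    ``grid`` defaults to 3-min sampling over [0, t_end]; it must lie within
    the simulation horizon. The substrate state is clipped at zero inside the
    right-hand side (uptake ceases when the substrate is exhausted).
    """
    promoter = promoter or PromoterParams()
    if grid is None:
        grid = np.arange(0.0, params.t_end + 1e-9, defaults.OD_PERIOD)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-D array")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid times must be strictly increasing")
    if grid[0] < 0 or grid[-1] > params.t_end + 1e-9:
        raise ValueError("grid must lie within [0, t_end]")

    mode = params.mode
    with_enzyme = mode in ("regulated", "mutant_no_pulse")
    mu0_min = params.mu0 / 60.0  # per-minute rate

    def mu_of(s: float, od: float, e: float) -> float:
        if mode == "monod":
            return mu0_min * s / (params.Ks + s)
        if mode == "nonlimiting_entry":
            cap = 1.0 + (od / params.density_cap_od) ** params.density_cap_exponent
            return mu0_min * s / (params.Ks + s) / cap
        ks_eff = params.Ks * promoter.enzyme_gain / e
        return mu0_min * s / (ks_eff + s)

    def rhs(t: float, y: np.ndarray) -> list[float]:
        od, s, gfp = y[0], max(y[1], 0.0), y[2]
        e = y[3] if with_enzyme else 1.0
        pa = float(promoter_activity(s, promoter))
        mu = mu_of(s, od, e)
        dod = mu * od
        ds = -params.c * dod
        dgfp = pa * od
        if not with_enzyme:
            return [dod, ds, dgfp]
        if mode == "mutant_no_pulse":
            de = 0.0
        else:
            de = mu0_min * (pa / promoter.pa_basal - e)
        return [dod, ds, dgfp, de]

    y0 = [params.od0, params.s_total, initial_gfp(params, promoter)]
    if with_enzyme:
        y0.append(1.0)

    sol = solve_ivp(
        rhs,
        (grid[0], grid[-1]),
        y0,
        method="LSODA",
        t_eval=grid,
        rtol=params.solver_rel_tol,
        atol=params.solver_abs_tol,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed in mode {mode!r}: {sol.message} "
            f"(params: mu0={params.mu0}, Ks={params.Ks}, s0={params.s0})"
        )
    od = sol.y[0]
    s = np.clip(sol.y[1], 0.0, None)
    gfp = sol.y[2]
    e = sol.y[3] if with_enzyme else None
    pa = promoter_activity(s, promoter)
    return Trajectory(
        times=grid, od=od, s=s, pa=np.asarray(pa), gfp=gfp, e=e,
        params=params, promoter=promoter,
    )


def implicit_monod_time(od_target: float, params: SimParams) -> float:
    """Time (min) at which the Monod-mode culture reaches ``od_target``.

    Separation of variables of the coupled biomass-substrate system gives
    time as an explicit quadrature in OD,

        t = int_{od0}^{od_target} (Ks + s(x)) / (mu0_min * s(x) * x) dx,

    with s(x) = s_total - c*(x - od0). Evaluated with adaptive quadrature,
    fully independent of the ODE integrator; serves as its oracle.
    """
    if params.mode != "monod":
        raise ValueError("implicit_monod_time applies to monod mode only")
    lo, hi = params.od0, params.od_final
    if not (lo <= od_target < hi):
        raise ValueError(
            f"od_target must lie in [od0, od0 + s_total/c) = [{lo:.6g}, {hi:.6g})"
        )
    if od_target == lo:
        return 0.0
    mu0_min = params.mu0 / 60.0

    def integrand(x: float) -> float:
        s = params.s_total - params.c * (x - params.od0)
        return (params.Ks + s) / (mu0_min * s * x)

    val, _ = quad(integrand, lo, od_target, limit=200)
    return float(val)
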