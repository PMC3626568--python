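"""Forward-model tests: Monod law, promoter band-pass, batch integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from monodplate.kinetics import (PromoterParams, SimParams, implicit_monod_time,
                                 initial_gfp, monod_mu, promoter_activity,
                                 simulate_batch)


class TestMonodMu:
    @pytest.mark.parametrize("s, mu0, Ks, expected", [
        (0.0026, 0.705, 0.0026, 0.3525),            # half-saturation
        (0.0, 0.705, 0.0026, 0.0),                  # no substrate, no growth
        (0.2, 0.705, 0.0026, 0.6959526159921026),   # frozen regression value
    ])
    def test_values(self, s, mu0, Ks, expected):
        assert monod_mu(s, mu0, Ks) == pytest.approx(expected, rel=1e-12)

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            monod_mu(-0.1, 0.7, 0.01)

    @settings(derandomize=True, max_examples=50)
    @given(s=st.floats(0, 10), ds=st.floats(0.01, 10),
           mu0=st.floats(0.01, 5), Ks=st.floats(1e-4, 10))
    def test_monotone_and_bounded(self, s, ds, mu0, Ks):
        lo, hi = monod_mu(s, mu0, Ks), monod_mu(s + ds, mu0, Ks)
        assert lo < hi <= mu0


class TestPromoterActivity:
    P = PromoterParams(pa_basal=100.0, fold_amp=5.0, theta_on=0.25,
                       h_on=4.0, theta_off=0.005, h_off=4.0)

    def test_basal_at_high_substrate(self):
        assert promoter_activity(50.0, self.P) == pytest.approx(100.0, rel=1e-4)

    def test_basal_at_zero_substrate(self):
        # the shutdown gate closes the pulse completely at s = 0
        assert promoter_activity(0.0, self.P) == 100.0

    def test_peak_between_thresholds(self):
        # brute-force maximisation over a dense grid: the peak-to-basal ratio
        # stays below fold_amp because the two Hill gates overlap
        s = np.geomspace(1e-5, 1.0, 20001)
        ratio = promoter_activity(s, self.P) / self.P.pa_basal
        peak = ratio.max()
        assert 4.0 <= peak <= 5.0
        s_peak = s[np.argmax(ratio)]
        assert self.P.theta_off < s_peak < self.P.theta_on

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PromoterParams(theta_on=0.1, theta_off=0.2)  # off must be < on
        with pytest.raises(ValueError):
            PromoterParams(fold_amp=0.5)


class TestSimulateBatch:
    def test_conservation_monod_and_regulated(self):
        for mode in ("monod", "regulated"):
            p = SimParams(s0=0.2, mode=mode)
            tr = simulate_batch(p, PromoterParams())
            err = np.abs(tr.s + p.c * (tr.od - p.od0) - p.s_total)
            assert err.max() < 10 * p.solver_abs_tol * max(1.0, p.s0)

    def test_mu_bounded_by_mu0_all_modes(self):
        for mode in ("monod", "regulated", "mutant_no_pulse",
                     "nonlimiting_entry"):
            p = SimParams(s0=0.47, mode=mode)
            tr = simulate_batch(p, PromoterParams())
            assert np.all(tr.mu() <= p.mu0 + 1e-9)

    def test_small_Ks_limit_exponential_then_plateau(self):
        # with Ks -> 0, growth is exponential at mu0 until the substrate is
        # gone; the final OD is fixed by the yield bookkeeping
        p = SimParams(s0=0.2, Ks=1e-7)
        tr = simulate_batch(p)
        assert tr.od[-1] == pytest.approx(p.od_final, rel=1e-6)
        early = tr.times <= 120
        mu = np.gradient(np.log(tr.od[early]), tr.times[early]) * 60
        assert np.allclose(mu, p.mu0, rtol=1e-3)

    def test_od_nondecreasing_s_nonincreasing(self):
        tr = simulate_batch(SimParams(s0=0.31))
        assert np.all(np.diff(tr.od) >= -1e-12)
        assert np.all(np.diff(tr.s) <= 1e-12)
        assert np.all(tr.s >= 0)
        assert np.all(np.diff(tr.gfp) >= -1e-12)

    def test_grid_outside_horizon_rejected(self):
        with pytest.raises(ValueError):
            simulate_batch(SimParams(t_end=100.0), grid=np.arange(0, 200, 3.0))

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            SimParams(mode="chemostat")

    def test_reporter_consistency_fine_grid(self):
        # finite-difference dGFP/dt / OD reproduces PA(s(t)) on a fine grid
        p = SimParams(s0=0.24, mode="regulated")
        prom = PromoterParams()
        tr = simulate_batch(p, prom, np.arange(0.0, 600.0, 0.5))
        dgfp = np.gradient(tr.gfp, tr.times)
        pa_fd = dgfp / tr.od
        pa_model = promoter_activity(tr.s, prom)
        rel = (pa_fd[2:-2] - pa_model[2:-2]) / pa_model[2:-2]
        assert np.sqrt(np.mean(rel**2)) < 0.01

    def test_initial_gfp_is_balanced_growth_level(self):
        p, prom = SimParams(), PromoterParams()
        assert initial_gfp(p, prom) == pytest.approx(
            p.od0 * prom.pa_basal * 60 / p.mu0)


class TestImplicitMonodOracle:
    def test_identity_at_inoculum(self):
        p = SimParams(s0=0.2)
        assert implicit_monod_time(p.od0, p) == 0.0

    def test_exponential_limit(self):
        p = SimParams(s0=0.5, Ks=1e-9)
        target = 0.01
        t = implicit_monod_time(target, p)
        assert t == pytest.approx(math.log(target / p.od0) / p.mu0 * 60,
                                  rel=1e-4)

    def test_monotonicity(self):
        p = SimParams(s0=0.2)
        ts = [implicit_monod_time(od, p) for od in (0.003, 0.006, 0.012, 0.018)]
        assert ts == sorted(ts) and len(set(ts)) == len(ts)

    def test_out_of_range_rejected(self):
        p = SimParams(s0=0.2)
        with pytest.raises(ValueError):
            implicit_monod_time(p.od_final * 1.01, p)
        with pytest.raises(ValueError):
            implicit_monod_time(p.od0 / 2, p)

    def test_ode_agrees_with_quadrature_across_parameter_sweep(self):
        # >= 20 random parameter sets: the ODE trajectory must reach each
        # target OD within 0.1 min of the separation-of-variables oracle
        rng = np.random.default_rng(42)
        for _ in range(24):
            p = SimParams(
                mu0=rng.uniform(0.3, 1.2), Ks=10 ** rng.uniform(-3, -1),
                c=rng.uniform(5, 30), s0=rng.uniform(0.1, 2.0),
                s_carryover=rng.uniform(0, 0.1),
                od0=rng.uniform(5e-4, 5e-3), t_end=2000.0)
            tr = simulate_batch(p, grid=np.arange(0.0, 2000.0, 0.25))
            od_target = math.sqrt(p.od0 * 0.9 * p.od_final)  # mid-log target
            t_oracle = implicit_monod_time(od_target, p)
            t_ode = float(np.interp(od_target, tr.od, tr.times))
            assert abs(t_ode - t_oracle) < 0.1, f"params {p}"

    def test_wrong_mode_rejected(self):
        with pytest.raises(ValueError):
            implicit_monod_time(0.01, SimParams(mode="regulated"))
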