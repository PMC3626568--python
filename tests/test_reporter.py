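"""Promoter-activity computation and pulse-detection tests."""

import math

import numpy as np
import pytest

from monodplate.calibration import SubstrateSeries, infer_substrate
from monodplate.growth import ArrestResult, ConditionSeries
from monodplate.kinetics import PromoterParams, SimParams, promoter_activity, simulate_batch
from monodplate.reporter import PASeries, detect_pulse, promoter_activity_series


def _series_with_gfp(times, od, gfp_times, gfp):
    return ConditionSeries("x", times, od, None, 1,
                           gfp_times=gfp_times, mean_gfp=gfp)


class TestPromoterActivitySeries:
    def test_definition_inversion_constant_pa(self):
        # gfp = k * integral(od dt) exactly -> pa == k
        r = 0.7 / 60.0
        t = np.arange(0.0, 400.0, 3.0)
        tg = np.arange(0.0, 400.0, 8.0)
        od = lambda x: 0.01 * np.exp(r * x)
        k = 42.0
        gfp = k * (od(tg) - 0.01) / r  # integral of od
        pas = promoter_activity_series(_series_with_gfp(t, od(t), tg, gfp))
        assert np.allclose(pas.pa, k, rtol=0.01)

    def test_constant_gfp_gives_zero(self):
        t = np.arange(0.0, 400.0, 3.0)
        tg = np.arange(0.0, 400.0, 8.0)
        s = _series_with_gfp(t, np.full(t.size, 0.02), tg, np.full(tg.size, 5.0))
        pas = promoter_activity_series(s)
        assert np.allclose(pas.pa, 0.0, atol=1e-12)

    def test_missing_channel_rejected(self):
        t = np.arange(0.0, 400.0, 3.0)
        s = ConditionSeries("x", t, np.full(t.size, 0.02), None, 1)
        with pytest.raises(ValueError, match="GFP"):
            promoter_activity_series(s)

    def test_zero_noise_regulated_matches_model_where_smooth(self):
        # measured PA tracks PA(s(t)); the comparison excludes samples where
        # the switch-like activation sweeps through the smoothing window
        p = SimParams(s0=0.24, mode="regulated")
        prom = PromoterParams()
        fine = np.arange(0.0, 1200.0, 1.0)
        tr = simulate_batch(p, prom, fine)
        t = np.arange(0.0, 1200.0 + 1e-9, 3.0)
        tg = np.arange(0.0, 1200.0 + 1e-9, 8.0)
        cs = _series_with_gfp(t, np.interp(t, fine, tr.od),
                              tg, np.interp(tg, fine, tr.gfp))
        pas = promoter_activity_series(cs)
        pa_true = promoter_activity(np.interp(pas.times, fine, tr.s), prom)
        # smoothness mask: true PA changes < 5% across the window
        pa_lo = promoter_activity(
            np.interp(pas.times - 12, fine, tr.s), prom)
        pa_hi = promoter_activity(
            np.interp(pas.times + 12, fine, tr.s), prom)
        smooth = (np.abs(pa_hi - pa_lo) / pa_true < 0.05) & (pas.times < 400)
        rel = (pas.pa[smooth] - pa_true[smooth]) / pa_true[smooth]
        assert np.sqrt(np.mean(rel**2)) < 0.02


class TestDetectPulse:
    def _flat_pa(self, value=100.0, n=50):
        t = np.arange(8.0, 8.0 * (n + 1), 8.0)
        return PASeries(times=t, pa=np.full(n, value), sem_pa=None,
                        window_min=24.0)

    def _ss(self, t):
        return SubstrateSeries(times=t, s=np.linspace(0.3, 0.0, t.size),
                               s0_nominal=0.3, c_used=15.1, anchor="final",
                               n_clipped=0)

    def _arrest(self, t_arrest=320.0):
        return ArrestResult(t_arrest=t_arrest, t_dec_start=300.0, T_dec=20.0,
                            stop_class="abrupt", mu_max=0.7, frac_high=0.9,
                            frac_low=0.05, sustain_min=15.0)

    def test_flat_series_not_detected(self):
        pa = self._flat_pa()
        res = detect_pulse(pa, self._ss(pa.times), self._arrest())
        assert not res.detected
        assert res.onset_time is None

    def test_pulse_features_ordered(self):
        pa = self._flat_pa()
        pa.pa[20:35] = 450.0
        pa.pa[30:35] = 480.0
        res = detect_pulse(pa, self._ss(pa.times), self._arrest())
        assert res.detected
        assert res.onset_time < res.peak_time <= res.shutdown_time
        assert res.fold_change >= 2

    def test_external_basal_used(self):
        pa = self._flat_pa(300.0)  # elevated from the start
        res = detect_pulse(pa, self._ss(pa.times), self._arrest(),
                           basal_pa=100.0)
        assert res.detected
        assert res.basal_pa == 100.0
        assert res.onset_time == pa.times[0]  # already above threshold


class TestRegulatedSimulations:
    def test_onset_substrate_near_activation_threshold(self, reporter_runs):
        # mean over the three lowest nitrogen levels and seeds: 0.25 +/- 0.04
        per_seed = []
        for _, _, res in reporter_runs:
            vals = [a.pulse.onset_substrate
                    for cid, a in res.conditions.items()
                    if a.pulse is not None and a.pulse.detected
                    and a.condition.strain == "wildtype"]
            assert len(vals) == 3
            per_seed.append(np.mean(vals))
        assert abs(np.mean(per_seed) - 0.25) <= 0.04

    def test_onset_substrate_invariant_across_conditions(self, reporter_runs):
        by_cond = {}
        for _, _, res in reporter_runs:
            for cid, a in res.conditions.items():
                if a.pulse and a.pulse.detected and a.condition.strain == "wildtype":
                    by_cond.setdefault(cid, []).append(a.pulse.onset_substrate)
        means = {cid: np.mean(v) for cid, v in by_cond.items()}
        grand = np.mean(list(means.values()))
        assert all(abs(m - grand) <= 0.04 for m in means.values()), means

    def test_fold_change_in_published_range(self, reporter_runs):
        # simulated amplitude 5 -> measured fold change 4-6
        folds = {}
        for _, _, res in reporter_runs:
            for cid, a in res.conditions.items():
                if a.pulse and a.condition.strain == "wildtype":
                    folds.setdefault(cid, []).append(a.pulse.fold_change)
        for cid, v in folds.items():
            assert 4.0 <= np.mean(v) <= 6.0, (cid, np.mean(v))

    def test_nonlimiting_control_shows_no_pulse(self, reporter_runs):
        for _, _, res in reporter_runs:
            ctrl = res.conditions["N18.7r"]
            assert ctrl.pulse is not None
            assert not ctrl.pulse.detected

    def test_pulse_peaks_about_one_generation_before_arrest(self, reporter_runs):
        gens = []
        for _, _, res in reporter_runs:
            for cid, a in res.conditions.items():
                if a.pulse and a.pulse.detected and a.condition.strain == "wildtype":
                    gens.append(a.pulse.generations_before_arrest)
        assert 0.5 <= np.mean(gens) <= 1.5

    def test_shutdown_follows_growth_stop(self, reporter_runs):
        # activity returns to low levels once growth stops
        for _, _, res in reporter_runs:
            for cid, a in res.conditions.items():
                if a.pulse and a.pulse.detected and a.condition.strain == "wildtype":
                    assert a.pulse.shutdown_time is not None
                    assert a.pulse.shutdown_time >= a.pulse.peak_time
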