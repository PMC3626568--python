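"""Plate design, noise model and file-format tests."""

import numpy as np
import pandas as pd
import pytest

from monodplate.growth import average_replicates, growth_rate_series
from monodplate.kinetics import PromoterParams, SimParams, simulate_batch
from monodplate.plates import (Condition, NoiseParams, PlateFormatError,
                               generate_plate, make_checkerboard_design,
                               read_plate, write_plate)

COND_A = Condition(nutrient="nitrogen", s0=0.2)
COND_B = Condition(nutrient="nitrogen", s0=0.47)


def _params(cond, **over):
    return SimParams(s0=cond.s0, **over), None


class TestCheckerboard:
    def test_counts_48_each(self):
        d = make_checkerboard_design(COND_A, COND_B)
        assert len(d.wells_of("A")) == 48 and len(d.wells_of("B")) == 48

    def test_no_orthogonal_neighbours_share_condition(self):
        d = make_checkerboard_design(COND_A, COND_B)
        rows = "ABCDEFGH"
        for r in range(8):
            for c in range(1, 13):
                me = d.wells[f"{rows[r]}{c}"]
                for rr, cc in ((r + 1, c), (r, c + 1)):
                    if rr < 8 and cc < 13:
                        assert d.wells[f"{rows[rr]}{cc}"] != me

    def test_identical_conditions_rejected(self):
        with pytest.raises(ValueError):
            make_checkerboard_design(COND_A, COND_A)


class TestGeneratePlate:
    def test_zero_noise_equals_trajectory(self):
        d = make_checkerboard_design(COND_A, COND_B)
        noise = NoiseParams(0, 0, 0, 0, seed=0)
        ds = generate_plate(d, {"A": _params(COND_A), "B": _params(COND_B)},
                            noise)
        truth = simulate_batch(SimParams(s0=COND_A.s0),
                               grid=np.arange(0.0, 1200.0 + 1e-9, 3.0))
        wide = ds.values("A", "OD600")
        rel = np.abs(wide.to_numpy() - truth.od[:, None]) / truth.od[:, None]
        assert rel.max() < 1e-9

    def test_same_seed_identical(self):
        d = make_checkerboard_design(COND_A, COND_B)
        params = {"A": _params(COND_A), "B": _params(COND_B)}
        ds1 = generate_plate(d, params, NoiseParams(seed=7))
        ds2 = generate_plate(d, params, NoiseParams(seed=7))
        pd.testing.assert_frame_equal(ds1.records, ds2.records)

    def test_different_seed_differs(self):
        d = make_checkerboard_design(COND_A, COND_B)
        params = {"A": _params(COND_A), "B": _params(COND_B)}
        ds1 = generate_plate(d, params, NoiseParams(seed=7))
        ds2 = generate_plate(d, params, NoiseParams(seed=8))
        assert not ds1.records["value"].equals(ds2.records["value"])

    def test_missing_condition_params_rejected(self):
        d = make_checkerboard_design(COND_A, COND_B)
        with pytest.raises(KeyError):
            generate_plate(d, {"A": _params(COND_A)}, NoiseParams(seed=0))

    def test_static_well_factor_cancels_in_log_derivative(self):
        # per-well scale spread alone must not bias single-well growth rates
        d = make_checkerboard_design(COND_A, COND_B)
        noise = NoiseParams(well_scale_cv=0.3, read_cv=0.0, gfp_read_cv=0.0,
                            day_scale_cv=0.0, seed=3)
        ds = generate_plate(d, {"A": _params(COND_A), "B": _params(COND_B)},
                            noise)
        wide = ds.values("A", "OD600")
        well = wide.columns[0]
        from monodplate.growth import ConditionSeries
        cs = ConditionSeries("A", wide.index.to_numpy(float),
                             wide[well].to_numpy(), None, 1)
        gr = growth_rate_series(cs)
        truth = SimParams(s0=COND_A.s0)
        mu_t0 = 0.705 * truth.s_total / (truth.Ks + truth.s_total)
        assert gr.mu_max == pytest.approx(mu_t0, rel=0.01)


class TestPlateIO:
    @pytest.fixture()
    def dataset(self):
        d = make_checkerboard_design(COND_A, COND_B)
        return generate_plate(d, {"A": _params(COND_A), "B": _params(COND_B)},
                              NoiseParams(seed=5))

    def test_round_trip(self, dataset, tmp_path):
        path = tmp_path / "plate.csv"
        write_plate(dataset, path)
        back = read_plate(path)
        pd.testing.assert_frame_equal(
            back.records.reset_index(drop=True),
            dataset.records.reset_index(drop=True))
        assert back.design.wells == dataset.design.wells
        assert back.design.conditions == dataset.design.conditions

    def test_negative_value_rejected_with_row(self, dataset, tmp_path):
        path = tmp_path / "plate.csv"
        write_plate(dataset, path)
        df = pd.read_csv(path)
        df.loc[10, "value"] = -0.01
        df.to_csv(path, index=False)
        with pytest.raises(PlateFormatError, match="row 10"):
            read_plate(path)

    def test_unknown_channel_rejected(self, dataset, tmp_path):
        path = tmp_path / "plate.csv"
        write_plate(dataset, path)
        df = pd.read_csv(path)
        df.loc[3, "channel"] = "OD420"
        df.to_csv(path, index=False)
        with pytest.raises(PlateFormatError, match="channel"):
            read_plate(path)

    def test_non_monotone_times_rejected(self, dataset, tmp_path):
        path = tmp_path / "plate.csv"
        write_plate(dataset, path)
        df = pd.read_csv(path)
        well = df.loc[0, "well"]
        sel = df[(df.well == well) & (df.channel == "OD600")].index[:2]
        df.loc[sel, "time_min"] = df.loc[sel, "time_min"].to_numpy()[::-1]
        df.to_csv(path, index=False)
        with pytest.raises(PlateFormatError, match="non-monotone"):
            read_plate(path)

    def test_missing_wells_accepted_and_reduce_n(self, dataset, tmp_path):
        path = tmp_path / "plate.csv"
        drop = dataset.design.wells_of("A")[:3]
        dataset.records = dataset.records[~dataset.records.well.isin(drop)]
        write_plate(dataset, path)
        back = read_plate(path)
        series = average_replicates(back)
        assert series["A"].n_wells == 45
        assert series["B"].n_wells == 48


class TestNoiseCalibration:
    def test_od_sem_near_two_percent_in_exponential_phase(self):
        # default noise model: SEM/mean over 48 replicates ~ 2%, averaged
        # over the exponential phase and a few seeds
        vals = []
        for seed in (11, 12, 13):
            d = make_checkerboard_design(COND_A, COND_B)
            ds = generate_plate(
                d, {"A": _params(COND_A), "B": _params(COND_B)},
                NoiseParams(seed=seed))
            for cid in ("A", "B"):
                s = average_replicates(ds)[cid]
                gr = growth_rate_series(s)
                mask = gr.mu >= 0.9 * gr.mu_max
                vals.append(np.mean(s.sem_od[mask] / s.mean_od[mask]))
        assert 0.015 <= np.mean(vals) <= 0.025
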