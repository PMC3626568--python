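"""Synthetic 96-well plate datasets emulating the robotic growth assay.

A plate holds two conditions in a checkerboard layout with 48 replicate wells
each. OD600 is sampled every 3 min and GFP535 (reporter wells only) every
8 min over ~20 h. The noise model is multiplicative and three-layered:

* a day factor, one lognormal multiplier per plate (CV 7%, the day-to-day
  reproducibility error);
* a static well factor drawn once per well (CV 13%; pipetting/optical path
  spread that is constant in time and therefore cancels in log-derivatives);
* per-read noise, i.i.d. lognormal per measurement (CV 2% OD, 10% GFP).

With 48 replicates this yields an OD standard error of the mean of
sqrt(0.13^2 + 0.02^2)/sqrt(48) ~ 1.9% per time point.

File format: a long CSV (plate_id, well, time_min, channel, value) plus a
design sidecar CSV (well, condition_id, nutrient, s0_mM, strain, reporter)
and a small JSON with generation metadata.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import defaults
from .kinetics import PromoterParams, SimParams, simulate_batch

ROWS = "ABCDEFGH"
COLS = range(1, 13)
CHANNELS = ("OD600", "GFP535")
STRAINS = ("wildtype", "mutant_no_pulse", "nonlimiting")


@dataclass(frozen=True)
class Condition:
    """One experimental condition: nutrient series, level and strain."""

    nutrient: str               # "nitrogen" or "glucose"
    s0: float                   # nominal initial substrate (mM)
    strain: str = "wildtype"
    reporter: str | None = None  # promoter name, or None for OD-only wells

    def __post_init__(self) -> None:
        if self.nutrient not in ("nitrogen", "glucose"):
            raise ValueError(f"unknown nutrient {self.nutrient!r}")
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if self.strain not in STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}")


@dataclass
class PlateDesign:
    """Well -> condition assignment for one plate."""

    plate_id: str
    wells: dict[str, str]              # well label -> condition_id
    conditions: dict[str, Condition]   # condition_id -> Condition

    def __post_init__(self) -> None:
        if len(self.wells) > 96:
            raise ValueError("a plate has at most 96 wells")
        for well, cid in self.wells.items():
            if cid not in self.conditions:
                raise ValueError(f"well {well} references unknown condition {cid!r}")

    def wells_of(self, condition_id: str) -> list[str]:
        return sorted(w for w, c in self.wells.items() if c == condition_id)


@dataclass(frozen=True)
class NoiseParams:
    """Multiplicative noise model of the plate reader assay."""

    well_scale_cv: float = 0.13   # static per-well scale spread
    read_cv: float = 0.02         # per-read OD noise
    gfp_read_cv: float = 0.10     # per-read GFP noise
    day_scale_cv: float = 0.07    # per-plate (day) factor spread
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("well_scale_cv", "read_cv", "gfp_read_cv", "day_scale_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PlateDataset:
    """Long-format measurements plus the design that generated them."""

    design: PlateDesign
    records: pd.DataFrame   # columns: well, time_min, channel, value
    meta: dict = field(default_factory=dict)

    def values(self, condition_id: str, channel: str) -> pd.DataFrame:
        """Wide table (time_min x wells) for one condition and channel."""
        wells = self.design.wells_of(condition_id)
        sub = self.records[
            self.records["well"].isin(wells) & (self.records["channel"] == channel)
        ]
        return sub.pivot(index="time_min", columns="well", values="value")


def well_name(row: int, col: int) -> str:
    return f"{ROWS[row]}{col}"


def make_checkerboard_design(
    cond_a: Condition, cond_b: Condition,
    plate_id: str = "plate",
    id_a: str = "A", id_b: str = "B",
) -> PlateDesign:
    """Alternate two conditions across the 96 wells so no two orthogonal
    neighbours share a condition (48 replicate wells each)."""
    if cond_a == cond_b:
        raise ValueError("checkerboard requires two distinct conditions")
    if id_a == id_b:
        raise ValueError("condition ids must differ")
    wells = {
        well_name(r, c): (id_a if (r + c) % 2 == 0 else id_b)
        for r in range(8) for c in COLS
    }
    return PlateDesign(plate_id=plate_id, wells=wells,
                       conditions={id_a: cond_a, id_b: cond_b})


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal factor(s) with unit mean and the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size=size))


def generate_plate(
    design: PlateDesign,
    params_by_condition: Mapping[str, tuple[SimParams, PromoterParams | None]],
    noise: NoiseParams,
    od_period: float = defaults.OD_PERIOD,
    gfp_period: float = defaults.GFP_PERIOD,
) -> PlateDataset:
    """Simulate every well of ``design`` and apply the noise model.

    Each well's value is day_factor * well_factor * truth(t) * read_noise.
    Randomness is drawn from streams seeded per (seed, plate, well index), so
    the draws for a given well do not depend on which other wells exist.
    """
    missing = [cid for cid in design.conditions if cid not in params_by_condition]
    if missing:
        raise KeyError(f"no simulation parameters for condition(s) {missing}")

    plate_key = zlib.crc32(design.plate_id.encode()) % (2**31)
    # One day factor per seed: a seed represents one experiment day, and all
    # plates measured that day share the instrument/inoculum scale factor.
    day_rng = np.random.default_rng(np.random.SeedSequence((noise.seed, 10_000)))
    day_factor = float(_lognormal_factor(day_rng, noise.day_scale_cv))

    # one deterministic trajectory per condition, sampled on both grids
    truths: dict[str, dict[str, np.ndarray]] = {}
    for cid, cond in design.conditions.items():
        sim, prom = params_by_condition[cid]
        od_grid = np.arange(0.0, sim.t_end + 1e-9, od_period)
        gfp_grid = np.arange(0.0, sim.t_end + 1e-9, gfp_period)
        union = np.union1d(od_grid, gfp_grid)
        traj = simulate_batch(sim, prom, union)
        truths[cid] = {
            "od_grid": od_grid,
            "gfp_grid": gfp_grid,
            "od": np.interp(od_grid, union, traj.od),
            "gfp": np.interp(gfp_grid, union, traj.gfp),
            "has_gfp": cond.reporter is not None,
        }

    well_order = sorted(design.wells)  # stable well indexing
    frames = []
    for idx, well in enumerate(well_order):
        cid = design.wells[well]
        truth = truths[cid]
        rng = np.random.default_rng(
            np.random.SeedSequence((noise.seed, plate_key, idx)))
        wf = float(_lognormal_factor(rng, noise.well_scale_cv))
        od_vals = (
            day_factor * wf * truth["od"]
            * _lognormal_factor(rng, noise.read_cv, truth["od"].size)
        )
        frames.append(pd.DataFrame({
            "well": well, "time_min": truth["od_grid"],
            "channel": "OD600", "value": od_vals,
        }))
        if truth["has_gfp"]:
            gfp_vals = (
                day_factor * wf * truth["gfp"]
                * _lognormal_factor(rng, noise.gfp_read_cv, truth["gfp"].size)
            )
            frames.append(pd.DataFrame({
                "well": well, "time_min": truth["gfp_grid"],
                "channel": "GFP535", "value": gfp_vals,
            }))

    records = pd.concat(frames, ignore_index=True)
    meta = {
        "noise": asdict(noise),
        "day_factor": day_factor,
        "od_period": od_period,
        "gfp_period": gfp_period,
        "conditions": {
            cid: {
                "condition": asdict(design.conditions[cid]),
                "sim_params": asdict(params_by_condition[cid][0]),
                "promoter_params": (
                    asdict(params_by_condition[cid][1])
                    if params_by_condition[cid][1] is not None else None),
            }
            for cid in design.conditions
        },
    }
    return PlateDataset(design=design, records=records, meta=meta)


class PlateFormatError(ValueError):
    """Malformed plate file; message names the offending row where known."""


def write_plate(dataset: PlateDataset, path: str | Path) -> None:
    """Write records CSV plus ``<stem>.design.csv`` and ``<stem>.meta.json``."""
    path = Path(path)
    out = dataset.records.copy()
    out.insert(0, "plate_id", dataset.design.plate_id)
    out.to_csv(path, index=False, float_format="%.17g")

    design_rows = [
        {
            "well": well,
            "condition_id": cid,
            "nutrient": dataset.design.conditions[cid].nutrient,
            "s0_mM": dataset.design.conditions[cid].s0,
            "strain": dataset.design.conditions[cid].strain,
            "reporter": dataset.design.conditions[cid].reporter or "",
        }
        for well, cid in sorted(dataset.design.wells.items())
    ]
    pd.DataFrame(design_rows).to_csv(path.with_suffix(".design.csv"), index=False)
    path.with_suffix(".meta.json").write_text(json.dumps(dataset.meta, indent=1))


def read_plate(path: str | Path) -> PlateDataset:
    """Read a plate written by :func:`write_plate`, validating the records.

    Wells listed in the design but absent from the records are accepted
    (replicate averaging then uses the number of wells actually present).
    """
    path = Path(path)
    records = pd.read_csv(path)
    expected = ["plate_id", "well", "time_min", "channel", "value"]
    if list(records.columns) != expected:
        raise PlateFormatError(
            f"{path}: expected columns {expected}, found {list(records.columns)}")
    try:
        records["time_min"] = records["time_min"].astype(float)
        records["value"] = records["value"].astype(float)
    except (TypeError, ValueError) as exc:
        raise PlateFormatError(f"{path}: non-numeric time or value: {exc}")

    bad_channel = ~records["channel"].isin(CHANNELS)
    if bad_channel.any():
        row = int(records.index[bad_channel][0])
        raise PlateFormatError(
            f"{path}: unknown channel {records['channel'][row]!r} at row {row}")
    nonpos = records["value"] <= 0
    if nonpos.any():
        row = int(records.index[nonpos][0])
        raise PlateFormatError(
            f"{path}: non-positive value {records['value'][row]!r} at row {row}")
    if records["value"].isna().any() or records["time_min"].isna().any():
        row = int(records.index[records["value"].isna() | records["time_min"].isna()][0])
        raise PlateFormatError(f"{path}: missing value at row {row}")
    for (well, channel), grp in records.groupby(["well", "channel"], sort=False):
        dt = np.diff(grp["time_min"].to_numpy())
        if np.any(dt <= 0):
            raise PlateFormatError(
                f"{path}: non-monotone times for well {well} channel {channel}")

    design_df = pd.read_csv(path.with_suffix(".design.csv"),
                            keep_default_na=False)
    conditions: dict[str, Condition] = {}
    wells: dict[str, str] = {}
    for _, row in design_df.iterrows():
        cid = str(row["condition_id"])
        cond = Condition(
            nutrient=row["nutrient"], s0=float(row["s0_mM"]),
            strain=row["strain"], reporter=(row["reporter"] or None),
        )
        if cid in conditions and conditions[cid] != cond:
            raise PlateFormatError(
                f"{path}: condition {cid!r} redefined inconsistently")
        conditions[cid] = cond
        wells[str(row["well"])] = cid

    extra = set(records["well"].astype(str)) - set(wells)
    if extra:
        raise PlateFormatError(f"{path}: wells {sorted(extra)} missing from design")

    plate_ids = records["plate_id"].unique()
    if len(plate_ids) != 1:
        raise PlateFormatError(f"{path}: expected a single plate_id, got {plate_ids}")

    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    design = PlateDesign(plate_id=str(plate_ids[0]), wells=wells,
                         conditions=conditions)
    return PlateDataset(design=design,
                        records=records.drop(columns="plate_id"), meta=meta)
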