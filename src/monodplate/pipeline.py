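"""End-to-end orchestration: simulate plates, analyze, write reports.

A run emulates one experiment day: a set of two-condition checkerboard
plates generated with one seed, followed by the analysis chain

    average -> growth rate -> arrest -> final-OD calibration ->
    substrate inference -> Monod fit -> promoter activity -> pulse.

The same analysis functions accept plate files from disk (``analyze`` mode),
so simulated and externally produced datasets go through identical code.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import defaults
from .calibration import (CalibrationResult, FinalOD, SubstrateSeries,
                          estimate_carryover, final_od,
                          fit_final_od_calibration, infer_substrate)
from .growth import (ArrestResult, ConditionSeries, GrowthRateSeries,
                     average_replicates, detect_arrest, growth_rate_series)
from .kinetics import PromoterParams, SimParams
from .monod import MonodFitResult, fit_monod, select_deceleration_points
from .plates import (Condition, NoiseParams, PlateDataset, PlateDesign,
                     generate_plate, make_checkerboard_design, read_plate,
                     write_plate)
from .reporter import PASeries, PulseResult, detect_pulse, promoter_activity_series

log = logging.getLogger("monodplate")

try:
    __version__ = version("monodplate")
except PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"


class ConfigError(ValueError):
    """Invalid run configuration; message names the offending field."""


@dataclass
class RunConfig:
    """Structured configuration of one simulate/analyze/full run."""

    mode: str = "full"                      # simulate | analyze | full
    seed: int | None = None
    out: str = "results/run"
    input: str | None = None                # plate-file directory (analyze)
    nutrient: str = "nitrogen"
    panels: tuple[str, ...] = ("calibration", "reporter")
    reporter_name: str = "glnA"            # promoter followed by the reporter
    noise: dict = field(default_factory=dict)     # NoiseParams overrides
    sim: dict = field(default_factory=dict)       # SimParams overrides
    promoter: dict = field(default_factory=dict)  # PromoterParams overrides
    growth_window: float = defaults.GROWTH_WINDOW
    monod_window: float = defaults.MONOD_WINDOW
    pa_window: float = defaults.PA_WINDOW
    s_fit_window: float = defaults.S_FIT_WINDOW
    tail_min: float = 60.0
    bootstrap_reps: int = 500
    verbose: bool = False

    _KNOWN_PANELS = ("calibration", "reporter", "growth_full")

    def validate(self) -> None:
        if self.mode not in ("simulate", "analyze", "full"):
            raise ConfigError(f"mode must be simulate/analyze/full, got {self.mode!r}")
        if self.mode in ("simulate", "full") and self.seed is None:
            raise ConfigError(f"mode {self.mode!r} requires a seed")
        if self.seed is not None and not (0 <= int(self.seed) < 2**31):
            raise ConfigError("seed must be an integer in [0, 2^31)")
        if self.nutrient not in ("nitrogen", "glucose"):
            raise ConfigError(f"unknown nutrient {self.nutrient!r}")
        for p in self.panels:
            if p not in self._KNOWN_PANELS:
                raise ConfigError(f"unknown panel {p!r}; known: {self._KNOWN_PANELS}")
        if self.mode == "analyze" and not self.input:
            raise ConfigError("analyze mode requires an input directory")
        if self.mode == "analyze" and not Path(self.input).exists():
            raise ConfigError(f"input path {self.input!r} does not exist")
        for name in ("growth_window", "monod_window", "pa_window", "tail_min"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.bootstrap_reps < 0:
            raise ConfigError("bootstrap_reps must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "panels" in raw:
            raw["panels"] = tuple(raw["panels"])
        cfg = cls(**raw)
        return cfg

    def echo(self) -> dict:
        d = asdict(self)
        d["panels"] = list(self.panels)
        d["package_version"] = __version__
        return d


# ---------------------------------------------------------------------------
# condition and plate construction


def condition_id(cond: Condition) -> str:
    tag = "N" if cond.nutrient == "nitrogen" else "G"
    rep = "r" if cond.reporter else ""
    strain = {"wildtype": "", "mutant_no_pulse": "m", "nonlimiting": ""}[cond.strain]
    return f"{tag}{cond.s0:g}{rep}{strain}"


def mode_for(cond: Condition) -> str:
    """Simulation mode implied by strain and reporter."""
    if cond.strain == "nonlimiting":
        return "nonlimiting_entry"
    if cond.strain == "mutant_no_pulse":
        return "mutant_no_pulse"
    return "regulated" if cond.reporter else "monod"


def sim_params_for(cond: Condition, sim_overrides: dict | None = None,
                   promoter_overrides: dict | None = None,
                   ) -> tuple[SimParams, PromoterParams | None]:
    """Ground-truth parameters for one condition under the study defaults."""
    if cond.nutrient == "nitrogen":
        base = dict(Ks=defaults.KS_NITROGEN, c=defaults.C_NITROGEN,
                    s_carryover=defaults.S_CARRYOVER_NITROGEN)
    else:
        # the 11 mM glucose control would exhaust glucose at OD ~ 0.52, so
        # the density-driven entry to stationary phase must engage below
        # that for the observed gradual slowdown; byproduct accumulation in
        # glucose batch culture motivates the lower cap
        base = dict(Ks=defaults.KS_GLUCOSE, c=defaults.C_GLUCOSE,
                    s_carryover=defaults.S_CARRYOVER_GLUCOSE,
                    density_cap_od=0.35)
    base.update(s0=cond.s0, mode=mode_for(cond))
    base.update(sim_overrides or {})
    sim = SimParams(**base)
    prom = PromoterParams(**(promoter_overrides or {})) if (
        cond.reporter or sim.mode in ("regulated", "mutant_no_pulse")) else None
    return sim, prom


def panel_conditions(cfg: RunConfig) -> list[Condition]:
    """Conditions implied by the configured panels, in plate-pairing order."""
    nut = cfg.nutrient
    conds: list[Condition] = []
    if nut == "nitrogen":
        limiting = defaults.NITROGEN_LIMITING
        lowest = defaults.NITROGEN_LOWEST3
        saturating = defaults.NITROGEN_SATURATING
        full = defaults.NITROGEN_PANEL
    else:
        limiting = defaults.GLUCOSE_LIMITING + (defaults.GLUCOSE_SATURATING,)
        lowest = defaults.GLUCOSE_LIMITING
        saturating = defaults.GLUCOSE_SATURATING
        full = defaults.GLUCOSE_PANEL

    def add(c: Condition) -> None:
        if all(condition_id(c) != condition_id(x) for x in conds):
            conds.append(c)

    if "calibration" in cfg.panels:
        for s0 in limiting:
            strain = "nonlimiting" if s0 == saturating else "wildtype"
            add(Condition(nutrient=nut, s0=s0, strain=strain))
    if "reporter" in cfg.panels:
        for s0 in lowest:
            add(Condition(nutrient=nut, s0=s0, reporter=cfg.reporter_name))
        add(Condition(nutrient=nut, s0=saturating, strain="nonlimiting",
                      reporter=cfg.reporter_name))
    if "growth_full" in cfg.panels:
        for s0 in full:
            strain = "nonlimiting" if s0 >= saturating else "wildtype"
            add(Condition(nutrient=nut, s0=s0, strain=strain))
    if len(conds) % 2 == 1:
        # checkerboard plates hold two distinct conditions; pad with a control
        for cand in (
            Condition(nutrient=nut, s0=saturating, strain="nonlimiting"),
            Condition(nutrient=nut, s0=lowest[0], strain="mutant_no_pulse"),
        ):
            if all(condition_id(cand) != condition_id(x) for x in conds):
                add(cand)
                break
    if len(conds) % 2 == 1:
        raise ConfigError("could not pair conditions onto two-condition plates")
    return conds


def build_designs(conditions: Sequence[Condition],
                  prefix: str = "plate") -> list[PlateDesign]:
    """Pair consecutive conditions onto two-condition checkerboard plates."""
    if len(conditions) % 2 != 0:
        raise ValueError("need an even number of conditions (2 per plate)")
    designs = []
    for k in range(0, len(conditions), 2):
        a, b = conditions[k], conditions[k + 1]
        designs.append(make_checkerboard_design(
            a, b, plate_id=f"{prefix}{k // 2 + 1:02d}",
            id_a=condition_id(a), id_b=condition_id(b)))
    return designs


def simulate_run(cfg: RunConfig) -> list[PlateDataset]:
    """Generate every plate of the configured panels, deterministically."""
    conds = panel_conditions(cfg)
    designs = build_designs(conds, prefix=f"{cfg.nutrient[0]}plate")
    noise = NoiseParams(**{**cfg.noise, "seed": int(cfg.seed)})
    datasets = []
    for design in designs:
        params = {
            cid: sim_params_for(c, cfg.sim, cfg.promoter)
            for cid, c in design.conditions.items()
        }
        t0 = time.perf_counter()
        datasets.append(generate_plate(design, params, noise))
        log.info("simulated %s (%d wells) in %.2fs", design.plate_id,
                 len(design.wells), time.perf_counter() - t0)
    return datasets


# ---------------------------------------------------------------------------
# analysis


@dataclass
class ConditionAnalysis:
    """Everything the pipeline derives for one condition."""

    condition: Condition
    series: ConditionSeries
    growth: GrowthRateSeries
    arrest: ArrestResult
    final: FinalOD
    substrate: SubstrateSeries | None = None
    pa: PASeries | None = None
    pulse: PulseResult | None = None


@dataclass
class RunResult:
    conditions: dict[str, ConditionAnalysis]
    calibration: CalibrationResult | None
    carryover_hat: float | None
    monod: MonodFitResult | None
    summary: dict


def _conditions_of(datasets: Sequence[PlateDataset]) -> dict[str, Condition]:
    out: dict[str, Condition] = {}
    for ds in datasets:
        for cid, cond in ds.design.conditions.items():
            if cid in out and out[cid] != cond:
                raise ValueError(f"condition id {cid!r} is inconsistent across plates")
            out[cid] = cond
    return out


def analyze_run(datasets: Sequence[PlateDataset], cfg: RunConfig) -> RunResult:
    """Run the full analysis chain on a set of plates."""
    conds = _conditions_of(datasets)

    # 1. replicate averaging (per plate, conditions are plate-local)
    series: dict[str, ConditionSeries] = {}
    for ds in datasets:
        for cid, s in average_replicates(ds).items():
            series[cid] = s
    log.info("averaged %d conditions from %d plates", len(series), len(datasets))

    # 2. growth rates + arrest + plateau OD
    analyses: dict[str, ConditionAnalysis] = {}
    for cid, s in series.items():
        gr = growth_rate_series(s, cfg.growth_window)
        arrest = detect_arrest(gr)
        fin = final_od(s, cfg.tail_min, arrest=arrest)
        analyses[cid] = ConditionAnalysis(
            condition=conds[cid], series=s, growth=gr, arrest=arrest, final=fin)
        log.info("%s: mu_max=%.3f/h gen=%.1f min stop=%s", cid, gr.mu_max,
                 gr.generation_time, arrest.stop_class)

    # 3. final-OD calibration on limiting, plateaued conditions
    cal_pts = [
        (cid, a.condition.s0, a.final.value)
        for cid, a in analyses.items()
        if a.condition.s0 <= defaults.S0_LIMITING_MAX and a.final.is_final
    ]
    calibration = carryover_hat = None
    if len({p[1] for p in cal_pts}) >= 2:
        calibration = fit_final_od_calibration(cal_pts)
        od0s = [analyses[cid].series.mean_od[0] for cid, _, _ in cal_pts]
        carryover_hat = estimate_carryover(calibration, float(np.mean(od0s)))
        log.info("calibration: a=%.4f b=%.4f c=%.2f (carryover~%.3f mM)",
                 calibration.a, calibration.b, calibration.c, carryover_hat)

    # 4. substrate inference (final-anchored) for limiting conditions
    if calibration is not None:
        for cid, a in analyses.items():
            if a.condition.s0 <= defaults.S0_LIMITING_MAX and a.final.is_final:
                a.substrate = infer_substrate(
                    a.series, a.condition.s0 + carryover_hat, calibration.c,
                    anchor="final", od_final_value=a.final.value)

    # 5. Monod fit on pooled deceleration points (narrow-window rates).
    # Only wild-type OD-only conditions enter: reporter strains carry the
    # regulated assimilation machinery whose effective half-saturation
    # changes with enzyme level, so they do not probe the bare growth law.
    monod_fit = None
    if calibration is not None:
        pts, used = [], []
        for cid, a in analyses.items():
            if a.substrate is None or a.arrest.t_arrest is None:
                continue
            if a.condition.reporter is not None or \
                    a.condition.strain != "wildtype":
                continue
            gr9 = growth_rate_series(a.series, cfg.monod_window)
            try:
                p = select_deceleration_points(
                    gr9, a.substrate, cfg.s_fit_window, arrest=a.arrest,
                    min_points=1)  # pooled count is checked below
            except ValueError:
                continue
            pts.append(p)
            used.append(cid)
        if pts:
            pooled = np.vstack(pts)
            if pooled.shape[0] >= 5:
                monod_fit = fit_monod(pooled, cfg.bootstrap_reps,
                                      seed=(cfg.seed or 0) + 1, mu0_cap=1.0)
                monod_fit.conditions_used = used
                log.info("Monod fit: mu0=%.3f/h Ks=%.2f uM (n=%d, %s)",
                         monod_fit.mu0_hat, monod_fit.Ks_hat * 1e3,
                         monod_fit.n_points,
                         "ok" if monod_fit.converged else monod_fit.diagnostic)

    # 6. promoter activity and pulse features
    reporter_cids = [cid for cid, a in analyses.items()
                     if a.series.mean_gfp is not None]
    basal_global = None
    for cid in reporter_cids:  # basal from the non-limiting control
        a = analyses[cid]
        if a.condition.strain == "nonlimiting":
            a.pa = promoter_activity_series(a.series, cfg.pa_window)
            t_end_basal = a.arrest.t_dec_start if a.arrest.t_dec_start is not None \
                else a.series.times[-1]
            mask = a.pa.times <= t_end_basal
            if mask.sum() >= 3:
                basal_global = float(np.median(a.pa.pa[mask]))
                log.info("basal PA from %s: %.3g AU/OD/min", cid, basal_global)
    for cid in reporter_cids:
        a = analyses[cid]
        if a.pa is None:
            a.pa = promoter_activity_series(a.series, cfg.pa_window)
        if a.condition.strain == "nonlimiting" and basal_global is not None:
            # control: verify absence of a pulse against its own basal
            ss = a.substrate or infer_substrate(
                a.series, a.condition.s0, defaults.C_NITROGEN
                if a.condition.nutrient == "nitrogen" else defaults.C_GLUCOSE,
                anchor="initial")
            a.pulse = detect_pulse(a.pa, ss, a.arrest, basal_pa=basal_global)
            continue
        if a.substrate is None:
            continue
        a.pulse = detect_pulse(a.pa, a.substrate, a.arrest, basal_pa=basal_global)
        if a.pulse.detected:
            log.info("%s: pulse onset s=%.3f mM fold=%.2f", cid,
                     a.pulse.onset_substrate, a.pulse.fold_change)

    summary = _summarize(analyses, calibration, carryover_hat, monod_fit, cfg)
    return RunResult(conditions=analyses, calibration=calibration,
                     carryover_hat=carryover_hat, monod=monod_fit,
                     summary=summary)


def _summarize(analyses, calibration, carryover_hat, monod_fit,
               cfg: RunConfig) -> dict:
    limiting = [a for a in analyses.values()
                if a.condition.s0 <= defaults.S0_LIMITING_MAX]
    gen_times = [a.growth.generation_time for a in limiting] or \
        [a.growth.generation_time for a in analyses.values()]
    pulses = {cid: a.pulse for cid, a in analyses.items()
              if a.pulse is not None and a.condition.strain != "nonlimiting"}
    summary = {
        "config": cfg.echo(),
        "n_conditions": len(analyses),
        "generation_time_min": float(np.mean(gen_times)),
        "mu_max_per_h": {cid: a.growth.mu_max for cid, a in analyses.items()},
        "stop_class": {cid: a.arrest.stop_class for cid, a in analyses.items()},
        "T_dec_min": {cid: a.arrest.T_dec for cid, a in analyses.items()},
        "final_od": {cid: a.final.value for cid, a in analyses.items()},
    }
    if calibration is not None:
        summary["calibration"] = {
            "a": calibration.a, "a_se": calibration.a_se,
            "b": calibration.b, "b_se": calibration.b_se,
            "c": calibration.c, "c_se": calibration.c_se,
            "r2": calibration.r2, "carryover_hat_mM": carryover_hat,
        }
    if monod_fit is not None:
        summary["monod"] = {
            "mu0_hat_per_h": monod_fit.mu0_hat,
            "mu0_ci": list(monod_fit.mu0_ci),
            "Ks_hat_mM": monod_fit.Ks_hat,
            "Ks_hat_uM": monod_fit.Ks_hat * 1e3,
            "Ks_ci_mM": list(monod_fit.Ks_ci),
            "n_points": monod_fit.n_points,
            "converged": monod_fit.converged,
            "diagnostic": monod_fit.diagnostic,
        }
    if pulses:
        summary["pulse"] = {
            cid: {
                "detected": p.detected,
                "onset_substrate_mM": p.onset_substrate,
                "fold_change": p.fold_change,
                "generations_before_arrest": p.generations_before_arrest,
            }
            for cid, p in pulses.items()
        }
    return summary


# ---------------------------------------------------------------------------
# disk IO / entry points


def write_outputs(result: RunResult, out_dir: str | Path) -> None:
    """Write the per-module CSV reports and the run summary JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for cid, a in result.conditions.items():
        mu_on_grid = a.growth.mu
        for i, t in enumerate(a.series.times):
            rows.append({
                "condition_id": cid, "time_min": t,
                "mean_od": a.series.mean_od[i],
                "sem_od": a.series.sem_od[i] if a.series.sem_od is not None else np.nan,
                "mu_per_h": mu_on_grid[i],
            })
    pd.DataFrame(rows).to_csv(out / "growth_curves.csv", index=False)

    pd.DataFrame([
        {"condition_id": cid, "s0_mM": a.condition.s0,
         "strain": a.condition.strain, "n_wells": a.series.n_wells,
         "mu_max_per_h": a.growth.mu_max,
         "generation_time_min": a.growth.generation_time,
         "t_arrest_min": a.arrest.t_arrest, "T_dec_min": a.arrest.T_dec,
         "stop_class": a.arrest.stop_class, "final_od": a.final.value,
         "final_is_plateau": a.final.is_final}
        for cid, a in result.conditions.items()
    ]).to_csv(out / "arrest_summary.csv", index=False)

    if result.calibration is not None:
        c = result.calibration
        pd.DataFrame([{
            "a": c.a, "a_se": c.a_se, "b": c.b, "b_se": c.b_se,
            "c": c.c, "c_se": c.c_se, "r2": c.r2,
            "n_conditions": len(c.conditions_used),
            "carryover_hat_mM": result.carryover_hat,
        }]).to_csv(out / "calibration.csv", index=False)

    sub_rows = [
        {"condition_id": cid, "time_min": t, "s_mM": s}
        for cid, a in result.conditions.items() if a.substrate is not None
        for t, s in zip(a.substrate.times, a.substrate.s)
    ]
    if sub_rows:
        pd.DataFrame(sub_rows).to_csv(out / "substrate.csv", index=False)

    if result.monod is not None:
        (out / "monod_fit.json").write_text(json.dumps({
            "mu0_hat_per_h": result.monod.mu0_hat,
            "mu0_ci": list(result.monod.mu0_ci),
            "Ks_hat_mM": result.monod.Ks_hat,
            "Ks_ci_mM": list(result.monod.Ks_ci),
            "n_points": result.monod.n_points,
            "rss": result.monod.rss,
            "converged": result.monod.converged,
            "diagnostic": result.monod.diagnostic,
            "bootstrap_reps": result.monod.bootstrap_reps,
            "conditions_used": result.monod.conditions_used,
        }, indent=1))

    pa_rows = [
        {"condition_id": cid, "time_min": t, "pa": v,
         "sem_pa": (a.pa.sem_pa[i] if a.pa.sem_pa is not None else np.nan)}
        for cid, a in result.conditions.items() if a.pa is not None
        for i, (t, v) in enumerate(zip(a.pa.times, a.pa.pa))
    ]
    if pa_rows:
        pd.DataFrame(pa_rows).to_csv(out / "promoter_activity.csv", index=False)

    pulse_rows = [
        {"condition_id": cid, **asdict(a.pulse)}
        for cid, a in result.conditions.items() if a.pulse is not None
    ]
    if pulse_rows:
        pd.DataFrame(pulse_rows).to_csv(out / "pulse_report.csv", index=False)

    (out / "summary.json").write_text(json.dumps(result.summary, indent=1))


def run_simulate(cfg: RunConfig) -> list[Path]:
    """Simulate the configured panels and write one file set per plate."""
    cfg.validate()
    datasets = simulate_run(cfg)
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest = {"config": cfg.echo(), "plates": []}
    for ds in datasets:
        path = out / f"{ds.design.plate_id}.csv"
        write_plate(ds, path)
        paths.append(path)
        manifest["plates"].append({
            "plate_id": ds.design.plate_id, "file": path.name,
            "conditions": {cid: asdict(c)
                           for cid, c in ds.design.conditions.items()},
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return paths


def run_analyze(cfg: RunConfig,
                datasets: Sequence[PlateDataset] | None = None) -> RunResult:
    """Analyze plates from disk (or in memory) and write reports."""
    cfg.validate()
    if datasets is None:
        files = sorted(Path(cfg.input).glob("*.csv"))
        files = [f for f in files if not f.name.endswith(".design.csv")]
        if not files:
            raise ConfigError(f"no plate files found under {cfg.input!r}")
        datasets = [read_plate(f) for f in files]
    result = analyze_run(datasets, cfg)
    write_outputs(result, cfg.out)
    return result


def run_full(cfg: RunConfig) -> RunResult:
    """Simulate and analyze in one pass; plate files are also written."""
    cfg.validate()
    datasets = simulate_run(cfg)
    out = Path(cfg.out)
    (out / "plates").mkdir(parents=True, exist_ok=True)
    manifest = {"config": cfg.echo(), "plates": []}
    for ds in datasets:
        path = out / "plates" / f"{ds.design.plate_id}.csv"
        write_plate(ds, path)
        manifest["plates"].append({"plate_id": ds.design.plate_id,
                                   "file": f"plates/{path.name}"})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    result = analyze_run(datasets, cfg)
    write_outputs(result, cfg.out)
    return result
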