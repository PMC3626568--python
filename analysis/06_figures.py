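"""Diagnostic figures: growth curves, rate curves, calibration line,
Monod fit and the promoter-activity pulse.

Reads the reports written by the earlier scripts plus the plate files, and
saves PNGs under results/figures/.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from monodplate.kinetics import monod_mu
from monodplate.pipeline import RunConfig, analyze_run
from monodplate.plates import read_plate

PLATES = Path("results/plates/nitrogen")
OUT = Path("results/figures")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    files = [f for f in sorted(PLATES.glob("*.csv"))
             if not f.name.endswith(".design.csv")]
    datasets = [read_plate(f) for f in files]
    cfg = RunConfig(mode="analyze", input=str(PLATES), out="unused",
                    bootstrap_reps=0)
    res = analyze_run(datasets, cfg)
    order = sorted(res.conditions, key=lambda c: res.conditions[c].condition.s0)

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for cid in order:
        a = res.conditions[cid]
        axes[0].semilogy(a.series.times / 60, a.series.mean_od, label=cid)
        axes[1].plot(a.growth.times / 60, a.growth.mu, label=cid)
    axes[0].set(xlabel="time (h)", ylabel="OD600", title="averaged growth curves")
    axes[1].set(xlabel="time (h)", ylabel="growth rate (1/h)",
                title="logarithmic derivative")
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(OUT / "growth_and_rate.png", dpi=120)

    if res.calibration is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        pts = res.calibration.conditions_used
        s0s = [p[1] for p in pts]
        ods = [p[2] for p in pts]
        ax.plot(s0s, ods, "o")
        grid = np.linspace(0, max(s0s) * 1.1, 50)
        ax.plot(grid, res.calibration.a * grid + res.calibration.b, "-")
        ax.set(xlabel="initial substrate (mM)", ylabel="final OD",
               title=f"a={res.calibration.a:.4f}, c={res.calibration.c:.1f}")
        fig.tight_layout()
        fig.savefig(OUT / "final_od_calibration.png", dpi=120)

    if res.monod is not None:
        from monodplate.growth import growth_rate_series
        from monodplate.monod import select_deceleration_points
        fig, ax = plt.subplots(figsize=(4.5, 4))
        for cid in order:
            a = res.conditions[cid]
            if a.substrate is None or a.condition.reporter is not None:
                continue
            gr9 = growth_rate_series(a.series, cfg.monod_window)
            try:
                pts = select_deceleration_points(
                    gr9, a.substrate, cfg.s_fit_window, arrest=a.arrest,
                    min_points=1)
            except ValueError:
                continue
            ax.plot(pts[:, 0] * 1e3, pts[:, 1], "o", ms=4, label=cid)
        grid = np.geomspace(0.1, 100, 200) / 1e3
        ax.plot(grid * 1e3, monod_mu(grid, res.monod.mu0_hat,
                                     res.monod.Ks_hat), "k-",
                label=f"fit Ks={res.monod.Ks_hat * 1e3:.1f} uM")
        ax.set(xscale="log", xlabel="substrate (uM)", ylabel="growth rate (1/h)",
               title="Monod fit, deceleration phase")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(OUT / "monod_fit.png", dpi=120)

    fig, ax = plt.subplots(figsize=(5, 4))
    for cid in order:
        a = res.conditions[cid]
        if a.pa is not None:
            ax.plot(a.pa.times / 60, a.pa.pa, label=cid)
    ax.set(xlabel="time (h)", ylabel="promoter activity (AU/OD/min)",
           title="reporter promoter activity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(OUT / "promoter_activity.png", dpi=120)
    print(f"figures written under {OUT}")


if __name__ == "__main__":
    main()
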