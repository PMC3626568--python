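"""Fit the Monod growth law to the deceleration-phase (substrate, rate) pairs.

Pairs narrow-window growth-rate estimates with the inferred instantaneous
substrate in the deceleration region of every limiting wild-type condition,
pools the points, and fits mu = mu0*s/(Ks+s) with bootstrap confidence
intervals. Expected recovery: Ks of a few micromolar (nitrogen ~2.6 uM,
glucose ~5 uM) and mu0 ~ 0.7/h.

Reads results/plates/, writes results/monod/<nutrient>/monod_fit.json.
"""

from pathlib import Path

from monodplate.pipeline import RunConfig, run_analyze

PLATES = Path("results/plates")
OUT = Path("results/monod")


def main() -> None:
    for nutrient in ("nitrogen", "glucose"):
        cfg = RunConfig(mode="analyze", input=str(PLATES / nutrient),
                        out=str(OUT / nutrient), bootstrap_reps=500)
        result = run_analyze(cfg)
        fit = result.monod
        lo, hi = (1e3 * fit.Ks_ci[0], 1e3 * fit.Ks_ci[1])
        print(f"{nutrient}: mu0 = {fit.mu0_hat:.3f}/h "
              f"[{fit.mu0_ci[0]:.3f}, {fit.mu0_ci[1]:.3f}], "
              f"Ks = {1e3 * fit.Ks_hat:.2f} uM [{lo:.2f}, {hi:.2f}] "
              f"(n = {fit.n_points} points from {len(fit.conditions_used)} "
              f"conditions, {fit.bootstrap_reps} bootstrap reps)")


if __name__ == "__main__":
    main()
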