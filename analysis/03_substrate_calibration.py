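"""Final-OD calibration: convert optical density into substrate units.

For the limiting conditions the final OD is linear in the initial substrate,
OD_f = a*s0 + b. The slope gives the conversion c = 1/a (mM consumed per OD
unit produced); the intercept reflects substrate carried over with the
inoculum. The instantaneous substrate then follows from the constant-yield
relation s(t) = s(0) - c*OD(t).

Reads results/plates/, writes results/calibration/<nutrient>/.
"""

from pathlib import Path

from monodplate.pipeline import RunConfig, run_analyze

PLATES = Path("results/plates")
OUT = Path("results/calibration")


def main() -> None:
    for nutrient in ("nitrogen", "glucose"):
        cfg = RunConfig(mode="analyze", input=str(PLATES / nutrient),
                        out=str(OUT / nutrient), bootstrap_reps=0)
        result = run_analyze(cfg)
        cal = result.calibration
        print(f"{nutrient}: OD_f = a*s0 + b with "
              f"a = {cal.a:.4f} +/- {cal.a_se:.4f} OD/mM, "
              f"b = {cal.b:.4f} +/- {cal.b_se:.4f} OD (r2 = {cal.r2:.4f})")
        print(f"          conversion c = 1/a = {cal.c:.2f} +/- {cal.c_se:.2f} "
              f"mM/OD; implied inoculum carryover "
              f"{result.carryover_hat:.3f} mM")


if __name__ == "__main__":
    main()
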