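"""Growth-rate curves and arrest classification from the simulated plates.

Averages the 48 replicate wells of every condition, estimates mu(t) as the
sliding-window logarithmic derivative of the mean OD, and classifies how
growth stops. Expected picture: all limiting levels stop abruptly (the
deceleration lasts tens of minutes), the saturating controls slow down
gradually over hours.

Writes results/growth/<nutrient>/{growth_curves,arrest_summary}.csv.
"""

from pathlib import Path

from monodplate.pipeline import RunConfig, run_analyze

PLATES = Path("results/plates")
OUT = Path("results/growth")


def main() -> None:
    for nutrient in ("nitrogen", "glucose"):
        cfg = RunConfig(mode="analyze", input=str(PLATES / nutrient),
                        out=str(OUT / nutrient), bootstrap_reps=0)
        result = run_analyze(cfg)
        print(f"--- {nutrient}")
        for cid, a in sorted(result.conditions.items(),
                             key=lambda kv: kv[1].condition.s0):
            print(f"  {cid:8s} s0={a.condition.s0:6.2f} mM  "
                  f"mu_max={a.growth.mu_max:5.3f}/h  "
                  f"gen={a.growth.generation_time:5.1f} min  "
                  f"T_dec={a.arrest.T_dec!s:>6} min  stop={a.arrest.stop_class}")


if __name__ == "__main__":
    main()
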