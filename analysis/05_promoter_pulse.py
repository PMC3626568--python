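"""Promoter-activity pulse of the nitrogen-assimilation reporter.

Computes promoter activity (dGFP/dt per OD) for the reporter conditions,
detects the pre-arrest expression pulse, and reports its onset substrate
level, amplitude and timing. Expected picture: under limiting nitrogen the
glnA promoter pulses 4-6 fold about one generation before growth stops, with
onset near 0.25 mM inferred substrate, and shuts down at arrest; the
non-limiting control stays at basal activity.

Reads results/plates/nitrogen, writes results/pulse/.
"""

from pathlib import Path

from monodplate.pipeline import RunConfig, run_analyze

PLATES = Path("results/plates/nitrogen")
OUT = Path("results/pulse")


def main() -> None:
    cfg = RunConfig(mode="analyze", input=str(PLATES), out=str(OUT),
                    bootstrap_reps=0)
    result = run_analyze(cfg)
    for cid, a in sorted(result.conditions.items(),
                         key=lambda kv: kv[1].condition.s0):
        if a.pulse is None:
            continue
        p = a.pulse
        if not p.detected:
            print(f"  {cid:8s} s0={a.condition.s0:6.2f} mM  no pulse "
                  f"(basal {p.basal_pa:.1f} AU/OD/min)")
            continue
        print(f"  {cid:8s} s0={a.condition.s0:6.2f} mM  "
              f"onset at s={p.onset_substrate:.3f} mM  "
              f"fold={p.fold_change:.2f}  "
              f"peak {p.generations_before_arrest:.2f} generations "
              f"before arrest  shutdown t={p.shutdown_time:.0f} min")


if __name__ == "__main__":
    main()
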