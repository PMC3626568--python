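"""Simulate the full synthetic experiment: nitrogen and glucose plate sets.

Writes, under results/plates/, one long-format CSV (+ design sidecar and
metadata) per 96-well checkerboard plate:

* nitrogen: the four limiting calibration levels, the three lowest levels
  with the glnA reporter, and the non-limiting 18.7 mM reporter control;
* glucose: the three limiting levels plus the non-limiting 11 mM control.

Every later script reads these files, so the whole analysis is reproducible
from the plate data alone.
"""

import sys
from pathlib import Path

from monodplate.pipeline import RunConfig, run_simulate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20130325
OUT = Path("results/plates")


def main() -> None:
    for nutrient, panels in (("nitrogen", ("calibration", "reporter")),
                             ("glucose", ("calibration",))):
        cfg = RunConfig(mode="simulate", seed=SEED, nutrient=nutrient,
                        panels=panels, out=str(OUT / nutrient))
        paths = run_simulate(cfg)
        print(f"{nutrient}: wrote {len(paths)} plates "
              f"({2 * len(paths)} conditions x 48 wells) under {OUT / nutrient}")


if __name__ == "__main__":
    main()
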