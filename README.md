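# monodplate

Analysis of the last generation of bacterial growth on a limiting nutrient,
from high-resolution microplate time series — as a tested, fully synthetic
pipeline: simulate the plate-reader experiment, then recover the growth law
and the gene-expression response from the simulated data alone.

**Who it is for.** Researchers analysing batch-culture growth curves
(OD600 every few minutes, optionally GFP reporters) who want to estimate,
from the deceleration phase alone: the maximal growth rate μ0, the
half-saturation constant Ks of the Monod law, the OD-to-substrate
conversion, the instantaneous substrate trajectory, and the timing and
amplitude of the nutrient-assimilation expression pulse that precedes
growth arrest.

**The model.** Batch growth on a single limiting substrate s with constant
yield:

    dOD/dt = μ(s)·OD,     ds/dt = −c·μ(s)·OD,     μ(s) = μ0·s/(Ks + s)

so the final OD is linear in the initial substrate (OD_f = a·s0 + b,
c = 1/a) and the instantaneous substrate follows from the OD curve,
s(t) = s(0) − c·OD(t). Promoter activity is measured as dGFP/dt ÷ OD and
modelled as a band-pass of two Hill gates (activation below ~0.25 mM,
shutdown at exhaustion). Variant modes cover regulated (pulse-competent)
strains, pulse-less mutants, and density-limited entry to stationary phase.
See `docs/methods.md` for the full model, noise model and estimator design.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
plates (one fixed seed; ~30 s total):

```
python analysis/01_simulate_plates.py      # 6 plates -> results/plates/
python analysis/02_growth_rates.py
python analysis/03_substrate_calibration.py
python analysis/04_monod_fit.py
python analysis/05_promoter_pulse.py
python analysis/06_figures.py
```

`02` prints, per condition, the maximal growth rate, generation time,
deceleration duration and stop class — limiting levels stop abruptly within
~20–35 min, saturating controls decelerate for hours:

```
  N0.24    s0=  0.24 mM  mu_max=0.726/h  gen= 57.3 min  T_dec=  24.0 min  stop=abrupt
  N0.94    s0=  0.94 mM  mu_max=0.726/h  gen= 57.3 min  T_dec=  18.0 min  stop=abrupt
  N18.7r   s0= 18.70 mM  mu_max=0.726/h  gen= 57.3 min  T_dec= 372.0 min  stop=gradual
```

`03` recovers the final-OD calibration line and the OD→substrate conversion:

```
nitrogen: OD_f = a*s0 + b with a = 0.0642 +/- 0.0008 OD/mM, b = 0.0061 +/- 0.0004 OD (r2 = 0.9992)
          conversion c = 1/a = 15.58 +/- 0.19 mM/OD; implied inoculum carryover 0.065 mM
```

`04` pairs deceleration-phase growth rates with the inferred substrate and
fits the Monod law (bootstrap 95% CIs in brackets):

```
nitrogen: mu0 = 0.705/h [0.692, 0.720], Ks = 2.89 uM [2.06, 4.25] (n = 28 points from 4 conditions)
glucose:  mu0 = 0.725/h [0.691, 0.743], Ks = 6.29 uM [4.24, 8.04] (n = 32 points from 3 conditions)
```

i.e. micromolar half-saturation constants: growth stays maximal until the
substrate is ~100-fold below the 0.25 mM threshold at which the assimilation
promoter fires. `05` quantifies that pulse:

```
  N0.2r    s0=  0.20 mM  onset at s=0.256 mM  fold=5.31  peak 1.12 generations before arrest
  N18.7r   s0= 18.70 mM  no pulse (basal 101.1 AU/OD/min)
```

— a 4–6-fold rise about one generation before arrest under limiting
nitrogen, absent in the non-limiting control.

## Library and CLI

Everything the scripts do is library code (`monodplate.*`): `simulate_batch`
(forward models), `generate_plate`/`read_plate`/`write_plate` (synthetic
96-well datasets, long-CSV format), `average_replicates`,
`growth_rate_series`, `detect_arrest`, `fit_final_od_calibration`,
`infer_substrate`, `select_deceleration_points`, `fit_monod`,
`promoter_activity_series`, `detect_pulse`, and the orchestrating
`run_simulate`/`run_analyze`/`run_full`. A thin CLI wraps the pipeline:

```
monodplate --mode full --seed 7 --out results/run7
monodplate --config cfg.yaml --mode analyze --input results/plates/nitrogen --out results/reanalysis
```

Configuration is a YAML file with the same fields as
`monodplate.RunConfig`; unknown keys are rejected and simulate/full modes
require a seed (exit code 2 on configuration errors).

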