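# hemovisc

Noninvasive, personalized estimation of microvascular whole-blood viscosity
at low shear from routine clinical measurements.

The whole microvascular bed is idealized as a single slender tube carrying
steady laminar Newtonian flow (Poiseuille regime). Collapsing the flow
intermediates algebraically gives a closed form for viscosity,

    mu = k * R^6 * PP / (BSA * CO)        k = pi^2 * 133.3 * (60*60*0.0252)/8 ≈ 14904

with pulse pressure PP (mmHg), body surface area BSA (m^2), cardiac output
CO (ml/min) and a latent model radius R. R^6 cannot be measured, so it is
calibrated per BMI group by ordinary least squares against clinically
measured viscosity: overweight subjects (BMI ≥ 25) regress R^6 on SV/PP and
heart rate; normal subjects (18.5–24.9) on SV/PP and weight. The fitted
models then yield a personalized viscosity estimate for subjects with no
viscometry at all.

The package includes:

- `hemovisc.hemodynamics` — subject records and derived parameters
  (BSA, BMI + class, stroke volume from LV diameters, CO, PP)
- `hemovisc.viscosity` — the Poiseuille chain, the consolidated closed
  form, its inverse, and re-derivation of the constant 14904
- `hemovisc.calibration` — BMI-stratified OLS calibration and the
  personalized estimate; literature-fixed reference models
- `hemovisc.validation` — outlier exclusion, seeded cohort split, balance
  checks (Levene + Welch) and Pearson-correlation validation
- `hemovisc.synthetic` — seeded synthetic-cohort generator with planted
  R^6/viscosity ground truth, for end-to-end testing without clinical data
- `hemovisc.pipeline` / `hemovisc.cli` — CSV I/O, configuration and the
  full command-line pipeline

## CLI

The `hemovisc` entry point has six subcommands:

```sh
# generate a 79-subject synthetic cohort with planted ground truth
hemovisc simulate --n 79 --seed 1 --out cohort.csv --truth-out truth.csv

# derived hemodynamic parameters per subject
hemovisc derive --input cohort.csv --output derived.csv

# fit the two BMI-group calibration models
hemovisc calibrate --input cohort.csv --output models.json

# personalized viscosity estimates (models.json or the built-in 'reference' set)
hemovisc estimate --input cohort.csv --models models.json --output estimates.csv

# Pearson validation against measured viscosity
hemovisc validate --input cohort.csv --models models.json --output summary.json

# full pipeline: outlier exclusion -> split -> fit -> estimate -> validate
hemovisc run --input cohort.csv --outdir out/ --seed 1 --ratio 0.5
```

`run` writes `models.json`, `subjects.csv` (one row per input subject with
status `ok` / `excluded-outlier` / `invalid-r6` / `row-error`) and
`summary.json` (split, balance reports, correlations on the validation,
experimental and full subsets). Runs are byte-identical for identical
inputs, config and seeds. Exit codes: 0 ok, 1 stage error, 2 config/schema
error, 3 partial load.

Input CSV schema (UTF-8, dot decimals; `measured_viscosity_cp` may be blank):

```
subject_id,height_cm,weight_kg,heart_rate_bpm,sbp_mmHg,dbp_mmHg,lv_edd_mm,lv_esd_mm[,measured_viscosity_cp]
```

Model constants can be overridden via `--constants constants.json`, e.g.
`{"pi_value": 3.14159, "mmHg_to_pa": 133.322}`; `ModelConstants.exact()`
gives the exact-constants mode (k = 14921.6 instead of 14904).

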