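# cardiofuzz

Takagi–Sugeno neuro-fuzzy (ANFIS) modelling of cardiorenal status: predict
ejection fraction (EF, %) or cystatin-C-based GFR (CKD-EPI, mL/min/1.73 m²)
from NT-proBNP, serum sodium and serum potassium.

The pipeline consists of:

- **`normalization`** — min-max scaling of all five clinical variables to
  [0, 1] (bounds default to the published cohort extremes, so normalized
  thresholds such as K⁺ 3.5 mmol/L → 0.20 are reproducible), the
  `PatientRecord`/`CohortTable` containers and the cohort CSV dialect.
- **`anfis`** — the fuzzy core: 3 inputs × 3 trapezoidal membership functions
  arranged as a Ruspini partition, the full 27-rule base with linear
  consequents, product (or min) t-norm, strength normalization and
  weighted-sum output; JSON model (de)serialization.
- **`training`** — seed-deterministic 70/15/15 train/test/check split, MSE,
  full-batch backprop (`bp`) or per-epoch least-squares consequent solving
  (`hybrid`), early stopping at MSE ≤ 5·10⁻⁴ within 1000 epochs, and
  held-out evaluation including the relative test/check deviation.
- **`cohort`** — synthetic 90-subject cohorts calibrated by moment matching
  to the published per-variable min/max/mean/SD (truncated normals for
  Na⁺/K⁺/age, a censored lognormal for NT-proBNP), with a latent monotone
  response so that EF and GFR genuinely depend on the predictors.
- **`surfaces`** — response surfaces over input pairs and risk-band
  classification (EF < 0.5 normalized → serious adverse event, GFR < 0.58
  normalized → renal failure, electrolyte stability bands).
- **`cli`** — the `cardiofuzz` command tying everything together.

## CLI

```bash
# synthetic cohort (CSV + spec sidecar + summary + manifest)
cardiofuzz simulate --seed 42 --n 90 --males 52 --output runs/sim

# train one model and evaluate on the held-out sets
cardiofuzz fit --cohort runs/sim/cohort.csv --target ef --mode hybrid --output runs/fit

# predictions, one response surface, risk report
cardiofuzz predict --model runs/fit/model_ef.json --cohort runs/sim/cohort.csv --output runs/pred
cardiofuzz surface --model runs/fit/model_ef.json --var-x ntprobnp --var-y k --output runs/surf
cardiofuzz report --model-ef runs/fit/model_ef.json --model-epi runs/e2e/model_epi.json \
    --cohort runs/sim/cohort.csv --output runs/report

# the whole pipeline in one go (both outputs, six surfaces, classification)
cardiofuzz end-to-end --seed 42 --output runs/e2e
```

Every subcommand writes a `manifest.json` with the effective configuration
and SHA-256 checksums of its artifacts; rerunning with the same seed
reproduces them byte-for-byte. Training options can also come from a YAML
config (`--config`), with command-line flags taking precedence.

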