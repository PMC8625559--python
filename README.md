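# ivperm

In vitro permeation analysis: from raw plate absorbances to
replacement-corrected cumulative permeation profiles, steady-state flux,
lag time, permeability coefficient (logP_m / logK_p), normalized AUC,
permeability class, and QC flags — plus artificial-membrane vs ex vivo
skin comparison and a Fickian-diffusion synthetic-data generator so the
whole pipeline is testable with no wet-lab data.

## What it does

- **`ivperm.timecourse`** — calibration-curve inversion (A = slope·c +
  intercept), cumulative-amount bookkeeping for both acceptor-handling
  modes (full replacement and sample-and-replace), sink-condition and
  donor-depletion QC checks.
- **`ivperm.metrics`** — OLS flux and lag-time fit over the linear
  window (default 0–30 min including the origin), logP_m =
  log10(J/C_D) with C_D in µg/cm³, trapezoidal AUC normalized to C_D,
  low/medium/high classification (contiguous cutpoints −2.4 / −1.2,
  configurable), replicate aggregation (logP_m averaged on the log
  scale).
- **`ivperm.solubility`** — stepwise approximate-solubility
  classification on a decade/quarter grid (1–1000 mg/mL with `">1000"`
  / `"<1"` sentinels), donor-concentration rule (cap 500 mg/mL),
  intrinsic solubility, sink cap, shake-flask logP.
- **`ivperm.comparison`** — pairing of membrane and skin panels, OLS
  regressions (log-permeability and permeated-amount correlations),
  externally studentized outlier flagging, per-pair flux concordance
  categories, membrane-integrity assessment.
- **`ivperm.simulate`** — analytic slab-membrane solution of Fick's
  second law (constant donor, perfect sink) with series lag term,
  assay simulation with replacement bookkeeping and mean-preserving
  lognormal measurement noise, partition-experiment and
  dissolution-oracle generators.
- **`ivperm.datasets`** — the packaged 13-solvent study panel
  (solubilities, membrane metrics, skin metrics) used in regression
  tests and as default input to `ivperm compare`.
- **`ivperm.io` / `ivperm.cli`** — long-format CSV readers with row-level
  validation, YAML pipeline config, deterministic CSV/JSON reports.

## CLI

```sh
# simulate a plate-assay timecourse (P_m in cm/h, C_D in mg/mL)
ivperm simulate --pm 0.05 --lag-min 1 --cd 10 --cv 0.05 --seed 7 --out tc.csv

# analyze it (config: calibration, geometry, window, thresholds)
ivperm analyze --profiles tc.csv --config config.yaml --out report.csv

# QC flags only (exit 1 when any replicate is flagged)
ivperm qc --profiles tc.csv --config config.yaml

# membrane vs skin comparison (defaults to the packaged panel)
ivperm compare --exclude S1,S6 --out comparison.json

# stepwise solubility with a simulated dissolution oracle; shake-flask logP
ivperm solubility --true-s 60
ivperm logp --runs runs.csv   # columns: A0, A1, Vaq_ml, Voct_ml
```

Example `config.yaml`:

```yaml
calibration:
  slope: 117.95          # absorbance per (mg/mL)
  intercept: 0.01
  valid_range_ug_ml: [9.0, 90.0]
acceptor_volume_ml: 0.18
exposure_area_cm2: 0.3
donor_volume_ml: 0.07
replacement_mode: full_replacement   # or sample_and_replace (+ sampled_volume_ml)
window: {t_min: 0.0, t_max: 0.5, include_origin: true}
horizon_h: 6.0
acceptor_solubility_mg_ml: 3.45      # enables the sink-condition check
```

Timecourse CSVs are long-format with columns `solvent_code, replicate,
time_h` (or `time_min`), and `concentration_mg_ml` or `absorbance`
(+ optional `dilution`, `C_D_mg_ml`).

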