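# smdmeta

Meta-analysis pipeline for controlled two-arm feeding trials: from a
per-comparison extraction table (control vs. treated arm summaries plus
study-level moderators) to pooled standardized mean differences,
heterogeneity statistics, subgroup and meta-regression moderator analyses,
and a publication-bias robustness verdict.

## What it does

- **ingest** — reads/writes the comparison CSV dialect, converts SE to SD
  (`SD = SE * sqrt(n)`), normalizes categorical moderators, and bins doses
  (0–5 / 6–10 / 11–14 g/kg) and rearing phases (starter / finisher / overall).
- **effect_size** — Hedges' g (bias-corrected SMD, sign = treated − control)
  with its large-sample sampling variance.
- **pooling** — fixed- and random-effects inverse-variance pooling
  (DerSimonian–Laird τ² by default, REML opt-in), Cochran's Q, I², and
  per-level subgroup analyses.
- **meta_regression** — univariable mixed-effects meta-regression with the
  omnibus QM test, residual τ²/I², and R² (percent heterogeneity accounted
  for).
- **publication_bias** — Rosenberg's weighted fail-safe number and the
  `Nfs > 5n + 10` robustness rule.
- **synthetic** — ensemble generator with normal random-effects structure,
  moderator shifts, and chi-square–sampled arm SDs, for estimator-recovery
  testing (the original extraction database is not publicly deposited).
- **report / cli** — full-pipeline orchestration, forest/subgroup/
  meta-regression/bias tables as CSV, and a JSON run summary.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (printed-table
consistency checks, estimator oracles, parameter-recovery and coverage
simulations); the rest are per-module unit and property tests.

## CLI

```bash
# deterministic 12-row toy table
smdmeta fixture --out fixture.csv

# synthetic ensemble (CSV + true-parameter file)
smdmeta simulate --k 84 --mu 0.33 --tau2 0.65 --seed 1 --out sim/

# full pipeline: tables + summary.json under --out
smdmeta analyze --input sim/simulated.csv --out results/

# individual analyses
smdmeta subgroup --input sim/simulated.csv --moderator dose_bin --outcome FI
smdmeta metareg  --input sim/simulated.csv --moderator strain
smdmeta bias     --input sim/simulated.csv --outcome FI
```

Global flags: `--alpha` (default 0.05), `--model {random,fixed}`,
`--tau2-method {DL,REML}`, `--seed`, `--config` (YAML key-value file),
`--out`.

The input CSV has a header row with columns
`study_id,country,strain,leaf_type,microbes,dose_g_per_kg,phase_start_day,
phase_end_day,outcome,mean_c,sd_c,se_c,n_c,mean_t,sd_t,se_t,n_t`;
empty string means missing (per row, SD or SE may be omitted but not both).

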