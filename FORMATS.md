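# File formats

All inputs and outputs are plain text (TSV/CSV/JSON).

## Inputs

### ASV/OTU count table (TSV)
Read by `read_asv_table`, written by `write_asv_table`.

- First column: taxon id (header `taxon_id`), unique.
- Remaining columns: one per sample; header row holds sample ids, unique.
- Cells: non-negative integers; empty or non-integer cells are rejected
  with the offending (taxon, sample) named.

```
taxon_id	S00001	S00002
ASV0001	12	0
ASV0002	0	7
```

### Sample metadata (CSV)
Read by `read_metadata`. Required columns:

| column     | type   | meaning                              |
|------------|--------|--------------------------------------|
| sample_id  | str    | must match count-table sample ids    |
| age_years  | float  | age in years                         |
| sex        | str    | `M` / `F`                            |
| ethnic     | str    | ethnic group label (e.g. `U`, `K`)   |
| geography  | str    | location label (e.g. `S`,`W`,`H`,`N`)|
| height_m   | float  | height in metres                     |
| weight_kg  | float  | weight in kilograms                  |

Optional `bmiaz` (BMI-for-age z-score); the `zscore` subcommand appends
it from an LMS reference when absent.

### Taxonomy (TSV)
Two columns: taxon id, SINTAX-style lineage string
`d:Bacteria,p:Firmicutes,c:...,o:...,f:...,g:...`.  Ranks missing from
the string are pooled into `unclassified` when aggregating.

### LMS growth reference (CSV)
Columns `measure` (`bmi`/`height`/`weight`), `sex` (`M`/`F`),
`age_months`, `L`, `M`, `S`.  Ages must be strictly increasing per
(measure, sex); `M > 0`, `S > 0`.  A synthetic reference
(`synthetic_lms_reference()`) ships for tests and examples; it is not a
WHO table.

## Outputs

### Posterior summary (CSV) — `fit` subcommand, `write_posterior_summary`
Columns: `parameter, mean, sd, q2.5, q97.5, ess, rhat, failed`.
Parameters are `beta:<column>` (log-mean coefficients), `gamma:<column>`
(zero-model coefficients), `tau`, `theta0`, `theta` as applicable.
When `failed` is true all numeric fields are empty (NA).

### Differential-abundance effects (CSV) — `da` subcommand, `DAResult.effects`
One row per taxon x design column:
`taxon, parameter, effect, sd, q2.5, q97.5, discriminatory, highlight, failed`.
`discriminatory` = 95% credible interval excludes 0; `highlight` = age or
bmiaz effect with |posterior mean| > 0.35.

### Per-taxon characterization (CSV) — `characterize` subcommand
`taxon, mean, sd, zero_fraction, phi_hat, inv_theta_hat,
inv_theta_nb_hat, zero_inflated`.

### Cohort summary (JSON) — `characterize --summary-out`
`n_taxa, n_skipped, zero_inflated_fraction, mean_phi_zero_inflated,
overdispersed_fraction`.

### Interaction report (CSV) — `da --interactions-out`
`taxon, ethnic, geography, effect, q2.5, q97.5, nonoverlap_flag` —
combined effect of each (ethnic, geography) level pair relative to the
reference pair.

### Benchmark results (CSV) — `benchmark` subcommand
Tidy rows `n, effect_level, phi, inv_theta, replicate, model, arb,
est_inv_theta, failed`; summary CSV adds per-cell `mean_arb, sd_arb,
mean_est_inv_theta, n_failed, n_total`.

### Acceptance report (JSON) — `scripts/acceptance.py`
`{"<quantity>": {"value": <number>, "n": <problem size>}, ...}`.
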