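# lprx

Long pressure-reactivity index (LPRx) analysis pipeline for minute-resolution
neuromonitoring data, with a synthetic cohort simulator for end-to-end testing.

LPRx is a moving Pearson correlation of consecutive minute-by-minute ICP and
MAP samples (windows of 10/15/20/30/60/90/120 min, evaluated every minute).
The package implements the full analysis chain:

- **`lprx.synthetic`** — cohorts of sporadically sampled ICP/MAP series
  (0.5–5-min aggregated samples, median interval 1 min, IQR 1–2 min) with a
  known per-patient reactivity coupling `rho`, slow-wave MAP fluctuations
  coupled into ICP, artifact spikes, EVD drainage gaps and GOS outcomes
  statistically linked to `rho`.  The coupling is internally calibrated so
  the expected windowed correlation equals `rho`.
- **`lprx.signal`** — artifact filtering (strict validity limits
  `0 < ICP < 80`, `0 < MAP < 400` mmHg), half-open open-drain interval
  removal, minute-grid projection honoring per-sample aggregation spans, an
  optional gap-limited linear-interpolation imputation, and the moving
  pairwise-complete Pearson correlation.
- **`lprx.burden`** — per-patient segment summaries: grand means and
  % time above threshold over the full stay, first 24/48/96/144 h and days
  1–7 (half-open minute conventions throughout).
- **`lprx.scan`** — the sequential chi-square method: dichotomize outcome
  (survival GOS 1 vs 2–5; favorable GOS 1–3 vs 4–5), sweep a threshold grid
  (LPRx −0.5…0.7 step 0.05; ICP 0…40 step 0.5 mmHg; %-time 0…1 step 0.05),
  compute an uncorrected Pearson 2×2 chi-square at each grid point and select
  the maximal-chi-square critical threshold; plus Mann–Whitney comparisons
  and the whole battery over schemes × metrics × segments × monitor
  subgroups.
- **`lprx.report`** — demographic/physiologic comparison table, full
  pipeline orchestration, chi-square-vs-threshold plots, and a run manifest
  with per-patient data-loss accounting.

## CLI

A single `lprx` entry point with subcommands (exit codes: 0 ok, 1 config
error, 2 runtime failure):

```bash
lprx simulate --config config.yaml --out cohort_dir     # synthetic cohort CSVs
lprx lprx     --cohort cohort_dir --out idx_dir --windows 10,30
lprx scan     --summaries segment_summaries.csv --cohort cohort_summary.csv --out battery.csv
lprx report   --config config.yaml                      # full run + plots
lprx all      --config config.yaml [--out DIR] [--seed N]
```

Example config (YAML or JSON):

```yaml
seed: 1
out_dir: out
windows: [10, 30, 120]
segments: [full, first_24h, day_1, day_2]
pct_thresholds: [0.0, 0.2, 0.3]
schemes: [survival, favorable]
subgroups: [all, evd, ipd, no_dc]
use_imputation: false
tie_rule: lowest
sim:
  n_patients: 200
  stay_range_days: [1, 16]
  frac_evd: 0.5
  outcome_model: {kind: step, theta_star: 0.30, p_below: 0.10, p_above: 0.70}
```

All outputs are plain text (CSV/JSON); missing values serialize as empty
fields.  Identical config + seed gives byte-identical outputs.

## Conventions

- Time is minutes since monitoring start; intervals are half-open
  `[start, end)`; minute-grid stamps are minute-ending (`(k-1, k]`).
- Index values at minute `t` summarize `(t - window, t]` (right-aligned);
  windows with fewer than 80% valid pairs, or a constant signal, yield
  missing values (never 0).
- Dichotomization is strict (`value > threshold`); equal-chi-square ties
  resolve to the lowest threshold by default.
- Chi-square is the uncorrected Pearson statistic (df = 1); p-values are
  unadjusted for multiple comparisons.  Demographic-table binary
  comparisons use a Mann–Whitney rank test on indicators (continuity
  corrected), the dialect of R's `wilcox.test`.
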