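# dualchange

A pipeline for dual-factor pre/post evaluation of mental-health programs:
instrument scoring with severity cutoffs, reliable change indices (RCI),
within-person differential change patterns across well-being and distress
dimensions, multivariate group statistics, and a synthetic cohort generator so
every stage is testable without participant data.

## What it does

- **`dualchange.scales`** — declarative instrument definitions (14-item
  well-being continuum, 5-item life satisfaction, 21-item distress scale with
  doubled-sum subscales and standard severity bands, 6-item resilience scale
  with reverse-coded items), scoring, severity categorisation, per-outcome
  "problematic" flags, and Cronbach's alpha. Cutoffs and reverse-coding keys
  live in `src/dualchange/data/instruments.yaml` and can be overridden.
- **`dualchange.reliable_change`** — SEdiff (difference-score variant, with the
  classic Jacobson–Truax baseline variant behind a switch), orientation-
  normalised RCI values with the strict |RCI| > 1.96 rule, dual-factor change
  patterns (both / well-being only / distress only / none), pattern frequency
  tables and distress-type subgroup breakdowns.
- **`dualchange.group_stats`** — paired repeated-measures tests, one- and
  two-sample Hotelling T² (Wilks Λ, exact F, partial η²), η² conversions,
  Welch/pooled baseline-stratified t tests with Cohen's d, Mann–Whitney
  robustness checks, outcome correlation matrices, and univariate outlier
  flagging (flag-and-report; exclusion is an explicit, logged config action).
- **`dualchange.synthetic`** — cohort generator with configurable per-outcome
  means/SDs, sign-structured cross-outcome correlations, pre/post correlation,
  a latent well-being-vs-distress change-factor correlation, a student
  subgroup with worse baselines, and MCAR post-timepoint missingness; plus a
  one-factor item-response generator targeting a given alpha. Deterministic
  under a fixed seed.
- **`dualchange.pipeline` / CLI** — config-driven orchestration with a full
  run log sufficient to reproduce any run byte-for-byte.

## CLI

```bash
# generate a synthetic cohort (long-format CSV + provenance side-car)
dualchange simulate -o cohort.csv --seed 7 --n 89

# run the full analysis (accepts scale-level or item-level long CSV)
dualchange analyze -i cohort.csv -o results/

# or simulate + analyze from one config
dualchange analyze -c run.yaml -o results/

# print the formatted report
dualchange report -b results/
```

Exit codes: 2 = config error, 3 = data error, 4 = degenerate statistics.

A run config (YAML) may contain: `input_csv` or `simulate` (generator
parameters), `scales_file` (cutoff overrides), `sediff_variant`
(`difference`/`baseline`), `grouping` (outcome → wellbeing/distress/excluded),
`rci_threshold`, `outlier_threshold`, `exclude` (participant ids),
`ttest_mode` (`welch`/`pooled`), `seed`.

Input CSV format (long): columns `participant_id`, `timepoint` (`pre`/`post`),
optional `cohort` (`student`/`general`), and either the six outcome columns
(`overall_wellbeing`, `life_satisfaction`, `dass_depression`, `dass_anxiety`,
`dass_stress`, `resilience`) or item-level columns `<scale>_<item#>`
(e.g. `mhcsf_1` … `mhcsf_14`), which are scored automatically.

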