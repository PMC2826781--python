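# markovcea

A Markov cohort cost-effectiveness model for comparing two adjuvant
chemotherapy strategies (TAC vs FAC) in node-positive breast cancer, built
as a reusable, tested Python package.

The model follows a cohort through four health states — No Recurrence,
Locoregional Recurrence, Distant (Metastatic) Recurrence and Dead — on a
6-month cycle across two phases: a 5-year trial horizon driven by a
transition matrix derived from arm-level outcome counts, and a
life-expectancy extrapolation phase for survivors. Costs (2006 CAD),
life-years and QALYs are discounted at 5%/year and aggregated into
incremental ratios (ICER in CAD per life-year gained, ICUR in CAD per
QALY gained).

## Layout

| module | responsibility |
| --- | --- |
| `markovcea.parameters` | all model inputs (trial summaries, unit costs, utilities, settings), YAML config loading/validation, derived cost/utility aggregates |
| `markovcea.transitions` | rate-to-probability conversion (`1 − e^(−rate·time)`), transition-matrix assembly, calibration to 5-year outcomes |
| `markovcea.markov_engine` | discounted two-phase cohort simulation, `CohortTrace` accumulators |
| `markovcea.outcomes` | per-arm totals, incremental ratios, dominance handling |
| `markovcea.sensitivity` | one-way scenario catalogue, bootstrap resampling, primary G-CSF prophylaxis model |
| `markovcea.synthetic_data` | synthetic two-arm trial generator and parameter-recovery harness |
| `markovcea.cli_report` | CLI commands and run manifests |

Bundled inputs live in `src/markovcea/data/`: the base-case configuration
(`tacfac_2006.yaml`), the one-way scenario catalogue
(`base_scenarios.yaml`) and the primary-prophylaxis adverse-event rates
(`primary_prophylaxis.yaml`). Unprinted structural parameters (the
locoregional/distant relapse split, per-state death allocation,
locoregional progression probability and remaining life expectancies) are
explicit configuration entries, calibrated so the model reproduces the
reported 5-year outcome proportions and incremental results; they are
never hard-coded.

## CLI

```sh
markovcea run-base --out runs/base
markovcea run-sensitivity --out runs/oneway            # bundled catalogue
markovcea run-bootstrap --n-boot 500 --seed 1 --out runs/boot
markovcea run-primary-prophylaxis --out runs/pp
markovcea generate-synthetic --seed 7 --out runs/synth
```

Every command accepts `--config` (defaults to the bundled base case),
writes delimited tables plus a `manifest.json` recording config path,
seed, timestamp and package version, and echoes all resolved parameters to
`run.log`.

## Modelling conventions

- The rate conversion uses the cumulative 5-year proportion directly as
  the rate (matching the source's own worked example), not the actuarial
  `−ln(1 − P)` transform.
- Per-cycle transitions are mutually exclusive (no within-cycle compound
  events); state membership is evaluated at cycle start, with no
  half-cycle correction.
- One-off costs (treatment, adverse events, prophylaxis, supportive care,
  diagnostics, labs) are applied undiscounted at time 0; expected
  metastatic chemotherapy cost is charged on each transition into the
  Distant state.
- Extrapolation-phase life-years are discounted as a continuous annuity
  anchored at the end of the trial horizon.
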