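# hdtfc

A lifetime Markov cohort model of Huntington disease (HD) functional
decline. Cohorts move annually through the 14 Total Functional Capacity
(TFC) states (13 = normal down to 0, treated as death) at a constant rate
derived by simple linear regression from short-horizon trajectory
observations, compete with background mortality from a US life table, and
accrue utilities and direct/societal costs by Shoulson–Fahn (SF) stage.
The package covers:

- **`parameters`** — validated domain types, the packaged base-case input
  registry, and method-of-moments constructors for normal/beta/log-normal
  sampling distributions pinned to printed means and 95% intervals.
- **`progression`** — OLS trajectory slope → annual one-state transition
  probability → row-stochastic transition matrices.
- **`onset`** — logistic cumulative onset-curve fitting by CAG stratum,
  renormalized annual onset schedules to age 100, schedule shift/pause
  transforms, and the configurable prognostic-index composite score.
- **`engine`** — annual-cycle cohort traces for SF1/SF2 cohorts and pooled
  60-subcohort prefunctional-decline (PFD) cohorts; discounted and
  undiscounted life years, QALYs, and stage/category-split costs.
- **`dmt`** — hypothetical disease-modifying-treatment scenarios
  (A: 3-year arrest + 0.75 rate ratio; B: 2 y + 0.85; C: 1 y + 0.95) and
  incremental outcomes versus natural history.
- **`uncertainty`** — probabilistic sensitivity analysis (5,000 default
  simulations, correlated 12-/36-month trajectory draws, per-draw slope
  refit), empirical 95% credible ranges, and ±25% one-way (tornado)
  analysis.
- **`fileio` / `cli`** — CSV/YAML/JSON readers and writers, packaged
  fixtures, run manifests, and the `hdtfc` command-line interface.

Packaged fixtures (`src/hdtfc/data/`) are plain CSV: a Gompertz–Makeham
smooth of US all-population mortality anchors, and a clearly labeled
synthetic stand-in for the cumulative onset-probability points (the source
staging-system curves are not published in reusable form; PFD results
therefore depend on this fixture, while SF1/SF2 results do not use it).

## Command line

```sh
hdtfc run  --population SF1                 # natural-history outcomes (JSON)
hdtfc run  --population SF1 --discount 0 --trace-csv trace.csv
hdtfc pfd  --cag 40                         # pooled-onset PFD cohort
hdtfc dmt  --population SF2 --scenario A    # incremental outcomes
hdtfc psa  --population SF1 --n 5000 --seed 1
hdtfc owsa --population SF1 --scenario A --csv tornado.csv
hdtfc fit-onset                             # fitted (mu, s) per CAG stratum
```

All subcommands accept `--config` (YAML/JSON overrides of any base-case
input), `--life-table` (CSV with columns `age,qx`), and `--out`. Every
result document embeds a manifest (parameter digest, seed, version) that
makes it re-derivable.

## Python API

```python
from hdtfc import load_parameters, run_cohort, accumulate_outcomes
from hdtfc.fileio import default_life_table

params = load_parameters(population="SF1")
trace = run_cohort(params, default_life_table())
outcomes = accumulate_outcomes(trace, params.payoffs, params.discount_rate)
print(outcomes.life_years.discounted, outcomes.median_survival_years)
```

## Conventions

- Accrual at cycle start with discount factor `(1 + d)^-t`, no half-cycle
  correction; the cycle-start row at the horizon accrues nothing.
- Background death is applied before progression within a cycle.
- 95% intervals convert to standard deviations as `(upper - lower) / 3.92`;
  credible ranges are 2.5th/97.5th percentiles with linear interpolation
  between order statistics.
- The SF5 annual cost can be charged as a one-time terminal payoff
  (`apply_sf5_terminal_cost: true` in config); it is off by default, which
  matches the published base-case totals.
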