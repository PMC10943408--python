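# youthpa

Microsimulation of socioeconomic disparities in US youth physical activity
and their lifetime health and economic consequences.

A national cohort of 6–17-year-old agents — stratified by sex, age band, and
federal-poverty-level (FPL) category, with national sampling weights — is
simulated day by day through childhood with an energy-balance model (weekly
draws of days with ≥60 minutes of activity, calibrated caloric intake that
holds each agent's BMI percentile at baseline behavior, daily surplus/deficit
partitioned into fat and fat-free mass). At 18, each agent's BMI category
selects the entry state of an annual 15-state disease model (coronary heart
disease, stroke, type-2 diabetes, cancer; state-, age-, and sex-specific
probabilities) that accrues direct medical costs, productivity losses
(wage × (1 − utility) × duration), and QALYs, discounted at 3%/year to 2023.

Counterfactual scenarios raise each stratum's mean activity level toward the
best-performing FPL category of the same sex/age cell by a reduction fraction
r ∈ [0, 1], under **common random numbers**: baseline and counterfactual arms
consume identical uniform draws, so an r = 0 scenario averts exactly zero
outcomes and contrasts are low-variance. Sensitivity axes: minutes of
activity on non-active days (0–45) and compensatory eating (a fraction of
extra expenditure eaten back in lower-SES groups, or a 2% intake decrease).

**Data provenance.** The packaged strata table
(`src/youthpa/data/strata.csv`: populations, activity means/SEs,
overweight/obesity prevalence for 24 strata) is the only empirical input.
Growth references and all adult disease-model parameters (transition
matrices, event probabilities, case fatality, costs, utilities) are **seeded
synthetic stand-ins**: structurally valid (rows normalize, risk rises with
BMI tier by construction) and order-of-magnitude plausible, but carrying no
empirical authority. Absolute national outputs therefore should not be
compared against published headline figures; directional and structural
results (monotonicity in r, sensitivity orderings, the savings slope shape)
are the meaningful outputs.

## CLI

```sh
# one paired baseline vs counterfactual experiment
youthpa simulate --reduction 1.0 --n-agents 20000 --replicates 5 --seed 1 \
    --offday-minutes 30 --compensation none --out results/run

# compensation flags: none | frac:0.25 | diet:0.02
youthpa simulate --reduction 1.0 --compensation frac:0.5 --out results/comp

# 25/50/75/100% disparity-reduction grid with the savings slope
youthpa sweep --n-agents 20000 --replicates 5 --seed 1 --out results/sweep
```

Outputs per run: `averted_by_stratum.csv` (per-stratum means and 95%
percentile CIs over replicates), `outcomes_table.csv` (outcome × scenario
rows, sex × age-band columns), and `run_summary.json` (config, replicate
seeds, national totals). A YAML config with a `run:` section mirroring the
flags can be passed via `--config`.

## Python API

```python
import youthpa as yp

table  = yp.load_strata_table()
cfg    = yp.RunConfig(n_agents=20_000, n_replicates=5, seed=1)
ledger = yp.run_pair(yp.ScenarioSpec(reduction=1.0), cfg)
print(ledger.summary())                      # strata + total, mean/lo/hi
ledgers, slope = yp.disparity_sweep([0.25, 0.5, 0.75, 1.0], cfg)
```

## Layout

- `youthpa.params` — strata fixture loader; seeded synthetic growth
  reference and adult disease parameter set
- `youthpa.cohort` — agent population construction, weight classification
- `youthpa.metabolic` — daily energy balance, intake calibration, the
  multi-arm childhood engine
- `youthpa.scenarios` — targets, reduction shifts, weekly draws, compensation
- `youthpa.lifecourse` — annual disease model (scalar ops + vectorized engine)
- `youthpa.econ` — discounting, productivity losses, record valuation
- `youthpa.experiments` — paired runs, ledgers, sweeps, reports
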