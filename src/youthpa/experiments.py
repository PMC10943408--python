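"""Pipeline driver: paired baseline/counterfactual runs and reporting.

Each replicate builds a fresh cohort, simulates childhood and the adult
life-course for a baseline arm and one or more scenario arms under common
random numbers (all arms consume identical uniform draws), scales per-agent
contrasts to national counts via sampling weights, and tallies averted
outcomes per stratum.  Replicate-level percentile intervals give the 95% CIs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortSpec, build_cohort
from .econ import EconParams
from .lifecourse import (
    DEATH_CAUSE_BACKGROUND,
    ENTRY_STATES,
    LifeCourseBatch,
    run_lifecourse_batch,
)
from .metabolic import ChildhoodArm, MetabolicParams, simulate_childhood
from .params import (
    ADULT_AGE_DAYS,
    AGE_BANDS,
    DAYS_PER_YEAR,
    EVENT_TYPES,
    MAX_ADULT_AGE,
    SEXES,
    GrowthReference,
    MarkovParamSet,
    StrataTable,
    load_strata_table,
    synthesize_growth_reference,
    synthesize_markov_params,
)
from .scenarios import ScenarioSpec, shifted_pa_means

#: FPL categories treated as "lower SES" when compensatory eating applies.
LOW_SES_FPL_IDX = (0, 1)

COUNT_METRICS = (
    "overweight_obesity_cases",
    *(f"{t}_cases" for t in EVENT_TYPES),
    "disease_cases",
    *(f"{t}_deaths" for t in EVENT_TYPES),
    "background_deaths",
    "deaths",
)
VALUE_METRICS = ("qalys", "life_years", "direct_cost", "productivity_cost",
                 "societal_cost")
AVERTED_NAMES = {
    **{m: f"{m}_averted" for m in COUNT_METRICS},
    "qalys": "qalys_saved",
    "life_years": "life_years_saved",
    "direct_cost": "payer_savings",
    "productivity_cost": "productivity_savings",
    "societal_cost": "societal_savings",
}
LEDGER_COLUMNS = [AVERTED_NAMES[m] for m in (*COUNT_METRICS, *VALUE_METRICS)]


@dataclass(frozen=True)
class RunConfig:
    """Replicated-run configuration."""

    n_agents: int = 50_000
    n_replicates: int = 20
    seed: int = 0
    pa_day_sd_individual: float = 1.5
    max_age: int = MAX_ADULT_AGE
    count_recurrent_events: bool = False
    output_dir: str = None

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def replicate_seed(self, rep: int) -> int:
        return self.seed * 100_003 + rep


@dataclass
class OutcomeLedger:
    """Averted-outcome tallies, per stratum and replicate, national scale."""

    scenario: ScenarioSpec
    replicates: list = field(default_factory=list)  # DataFrames, 24 strata rows

    def add_replicate(self, frame: pd.DataFrame) -> None:
        if self.replicates and len(frame) != len(self.replicates[0]):
            raise ValueError("replicate stratum-count divergence")
        self.replicates.append(frame)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def totals(self) -> pd.DataFrame:
        """One row per replicate: national totals (exact stratum sums)."""
        return pd.DataFrame([f.sum() for f in self.replicates])

    def mean_total(self, metric: str) -> float:
        return float(self.totals()[metric].mean())

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Mean and percentile CI per stratum and for the total."""
        lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
        stacked = np.stack([f.to_numpy() for f in self.replicates])  # (R,24,M)
        tot = stacked.sum(axis=1, keepdims=True)                     # (R,1,M)
        both = np.concatenate([stacked, tot], axis=1)
        index = pd.MultiIndex.from_tuples(
            list(StrataTable.stratum_keys()) + [("total", "total", "total")],
            names=["sex", "age_band", "fpl"])
        cols = self.replicates[0].columns
        out = {}
        for stat, arr in (("mean", both.mean(axis=0)),
                          ("lo", np.percentile(both, lo_q, axis=0)),
                          ("hi", np.percentile(both, hi_q, axis=0))):
            out[stat] = pd.DataFrame(arr, index=index, columns=cols)
        return pd.concat(out, axis=1).swaplevel(axis=1).sort_index(axis=1)


def baseline_prevalence(table: StrataTable) -> float:
    """Population-weighted overweight+obesity prevalence (%), all 24 strata."""
    df = table.frame
    w = df.population.to_numpy(dtype=float)
    prev = (df.overweight_prev + df.obesity_prev).to_numpy(dtype=float)
    return float((w * prev).sum() / w.sum())


def ols_slope_musd_per_ppt(reduction_pct, savings_busd) -> float:
    """OLS slope of societal savings (billions USD) against disparity
    reduction (percent), in millions USD per percentage point."""
    x = np.asarray(reduction_pct, dtype=float)
    y = np.asarray(savings_busd, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two points")
    slope_busd = np.polyfit(x, y, 1)[0]
    return float(slope_busd * 1000.0)


# ---------------------------------------------------------------------------
# Simulation core
# ---------------------------------------------------------------------------

def _arm_metrics(case: np.ndarray, batch: LifeCourseBatch) -> dict:
    out = {"overweight_obesity_cases": case.astype(float)}
    for t, name in enumerate(EVENT_TYPES):
        out[f"{name}_cases"] = batch.event_first[t]
    out["disease_cases"] = batch.total_disease_cases
    for t, name in enumerate(EVENT_TYPES):
        out[f"{name}_deaths"] = (batch.death_cause == t).astype(float)
    out["background_deaths"] = (batch.death_cause == DEATH_CAUSE_BACKGROUND).astype(float)
    out["deaths"] = batch.dead.astype(float)
    out["qalys"] = batch.qalys_discounted
    out["life_years"] = batch.life_years.astype(float)
    out["direct_cost"] = batch.direct_cost_discounted
    out["productivity_cost"] = batch.productivity_discounted
    out["societal_cost"] = (batch.direct_cost_discounted
                            + batch.productivity_discounted)
    return out


def _build_arms(cohort: Cohort, table: StrataTable,
                scenarios: list[ScenarioSpec]) -> list[ChildhoodArm]:
    offdays = {s.offday_minutes for s in scenarios}
    if len(offdays) != 1:
        raise ValueError(
            "scenarios sharing a baseline arm must agree on offday_minutes")
    offday = offdays.pop()
    arms = [ChildhoodArm(pa_days_mean=cohort.pa_days_mean,
                         offday_minutes=offday, label="baseline")]
    for s in scenarios:
        pa = shifted_pa_means(cohort.pa_days_mean, cohort.stratum_idx,
                              table, s.reduction)
        if s.compensation_mode == "fraction_of_extra":
            # Compensatory eating applies in the lower-SES categories.
            mask = np.isin(cohort.fpl_idx, LOW_SES_FPL_IDX)
        elif s.compensation_mode == "diet_improvement":
            # Diet improvement accompanies an actual activity increase.
            mask = pa > cohort.pa_days_mean
        else:
            mask = None
        arms.append(ChildhoodArm(
            pa_days_mean=pa, offday_minutes=s.offday_minutes,
            compensation_mode=s.compensation_mode,
            compensation_value=(s.compensation_value
                                or (0.02 if s.compensation_mode
                                    == "diet_improvement" else 0.0)),
            compensation_mask=mask,
            label=s.label or f"r={s.reduction}",
        ))
    return arms


def run_scenarios(scenarios: list[ScenarioSpec], config: RunConfig,
                  table: StrataTable = None, growth: GrowthReference = None,
                  markov: MarkovParamSet = None,
                  metabolic: MetabolicParams = None,
                  econ: EconParams = None) -> list[OutcomeLedger]:
    """Paired simulation of several scenarios against one shared baseline.

    All scenarios must share ``offday_minutes`` (the baseline assumption);
    use separate calls for off-day sensitivity runs.
    """
    table = table or load_strata_table()
    growth = growth or synthesize_growth_reference(config.seed)
    markov = markov or synthesize_markov_params(config.seed)
    metabolic = metabolic or MetabolicParams()
    econ = econ or EconParams()

    ledgers = [OutcomeLedger(scenario=s) for s in scenarios]
    for rep in range(config.n_replicates):
        seed_rep = config.replicate_seed(rep)
        cohort = build_cohort(table, growth, CohortSpec(
            n_agents=config.n_agents,
            pa_day_sd_individual=config.pa_day_sd_individual,
            seed=seed_rep))
        if cohort.n != config.n_agents:
            raise RuntimeError("replicate agent-count divergence")
        arms = _build_arms(cohort, table, scenarios)

        child_rng = np.random.default_rng([seed_rep, 0x6368696C])
        child = simulate_childhood(cohort, arms, growth, metabolic, child_rng)

        entries = np.array(ENTRY_STATES)[
            np.stack([r.weight_class_at_18 for r in child])]
        years_offset = (ADULT_AGE_DAYS - cohort.age_days) / DAYS_PER_YEAR
        adult_rng = np.random.default_rng([seed_rep, 0x6164756C])
        batches = run_lifecourse_batch(
            entries, cohort.sex, years_offset, markov, adult_rng,
            discount_rate=econ.discount_rate, max_age=config.max_age,
            count_recurrent=config.count_recurrent_events)

        base = _arm_metrics(child[0].weight_class_at_18 > 0, batches[0])
        w = cohort.sampling_weight
        for li, (cres, batch) in enumerate(zip(child[1:], batches[1:])):
            arm = _arm_metrics(cres.weight_class_at_18 > 0, batch)
            cols = {}
            for m in (*COUNT_METRICS, *VALUE_METRICS):
                delta = (base[m] - arm[m]) * w
                cols[AVERTED_NAMES[m]] = np.bincount(
                    cohort.stratum_idx, weights=delta, minlength=24)
            frame = pd.DataFrame(cols, index=pd.MultiIndex.from_tuples(
                StrataTable.stratum_keys(), names=["sex", "age_band", "fpl"]))
            ledgers[li].add_replicate(frame[LEDGER_COLUMNS])
    return ledgers


def run_pair(scenario: ScenarioSpec, config: RunConfig,
             **components) -> OutcomeLedger:
    """Baseline vs a single counterfactual under common random numbers."""
    return run_scenarios([scenario], config, **components)[0]


def disparity_sweep(fractions, config: RunConfig, **components):
    """Ledgers for a grid of reduction fractions plus the savings slope.

    Returns ``(ledgers, slope)`` with the slope in millions USD per
    percentage point of disparity reduction, fit by OLS on the
    replicate-mean societal savings.
    """
    fractions = sorted(fractions)
    if len(fractions) < 2:
        raise ValueError("sweep needs at least two fractions")
    scenarios = [ScenarioSpec(reduction=r, label=f"r={r:g}") for r in fractions]
    ledgers = run_scenarios(scenarios, config, **components)
    savings_busd = [l.mean_total("societal_savings") / 1e9 for l in ledgers]
    slope = ols_slope_musd_per_ppt([100 * r for r in fractions], savings_busd)
    return ledgers, slope


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _stratum_summary_long(ledger: OutcomeLedger) -> pd.DataFrame:
    summ = ledger.summary()
    rows = []
    for (sex, band, fpl), row in summ.iterrows():
        for metric in LEDGER_COLUMNS:
            rows.append({
                "scenario": ledger.scenario.label or f"r={ledger.scenario.reduction:g}",
                "sex": sex, "age_band": band, "fpl": fpl, "metric": metric,
                "mean": row[(metric, "mean")],
                "lo": row[(metric, "lo")],
                "hi": row[(metric, "hi")],
            })
    return pd.DataFrame(rows,
                        columns=["scenario", "sex", "age_band", "fpl",
                                 "metric", "mean", "lo", "hi"])


def _table2_style(ledgers: list[OutcomeLedger]) -> pd.DataFrame:
    """Outcome x scenario rows; sex x age-band columns plus the total."""
    cells = [(s, b) for s in SEXES for b in AGE_BANDS]
    rows = {}
    for ledger in ledgers:
        label = ledger.scenario.label or f"r={ledger.scenario.reduction:g}"
        stacked = np.stack([f.to_numpy() for f in ledger.replicates])
        frame0 = ledger.replicates[0]
        for mi, metric in enumerate(frame0.columns):
            for stat_name, reducer in (
                    ("mean", lambda a: a.mean(axis=0)),
                    ("lo", lambda a: np.percentile(a, 2.5, axis=0)),
                    ("hi", lambda a: np.percentile(a, 97.5, axis=0))):
                vals = {}
                per_rep = stacked[:, :, mi]  # (R, 24)
                for sex, band in cells:
                    idx = [i for i, k in enumerate(StrataTable.stratum_keys())
                           if k[0] == sex and k[1] == band]
                    vals[f"{sex}_{band}"] = reducer(per_rep[:, idx].sum(axis=1))
                vals["total"] = reducer(per_rep.sum(axis=1))
                rows[(metric, label, stat_name)] = vals
    out = pd.DataFrame(rows).T
    out.index.names = ["metric", "scenario", "stat"]
    return out


def write_report(ledgers: list[OutcomeLedger], config: RunConfig,
                 output_dir, plot: bool = False) -> dict:
    """Write stratum-level and outcome-table CSVs plus a JSON run summary."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    long_frames = [_stratum_summary_long(l) for l in ledgers]
    long = (pd.concat(long_frames, ignore_index=True) if long_frames
            else pd.DataFrame(columns=["scenario", "sex", "age_band", "fpl",
                                       "metric", "mean", "lo", "hi"]))
    strata_path = outdir / "averted_by_stratum.csv"
    long.to_csv(strata_path, index=False)

    table2_path = outdir / "outcomes_table.csv"
    if ledgers:
        _table2_style(ledgers).to_csv(table2_path)
    else:
        pd.DataFrame(columns=["metric", "scenario", "stat"]).to_csv(
            table2_path, index=False)

    summary = {
        "config": asdict(config),
        "replicate_seeds": [config.replicate_seed(r)
                            for r in range(config.n_replicates)],
        "scenarios": [asdict(l.scenario) for l in ledgers],
        "totals_mean": {
            (l.scenario.label or f"r={l.scenario.reduction:g}"):
                {m: l.mean_total(m) for m in LEDGER_COLUMNS}
            for l in ledgers
        },
    }
    json_path = outdir / "run_summary.json"
    json_path.write_text(json.dumps(summary, indent=2, default=str))

    paths = {"strata_csv": strata_path, "table_csv": table2_path,
             "summary_json": json_path}
    if plot and ledgers:
        paths["figure"] = _savings_figure(ledgers, outdir)
    return paths


def _savings_figure(ledgers: list[OutcomeLedger], outdir: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [l.scenario.label or f"r={l.scenario.reduction:g}" for l in ledgers]
    means = [l.mean_total("societal_savings") / 1e9 for l in ledgers]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(labels, means)
    ax.set_ylabel("Societal savings (billion USD)")
    ax.set_xlabel("Scenario")
    fig.tight_layout()
    path = outdir / "societal_savings.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
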