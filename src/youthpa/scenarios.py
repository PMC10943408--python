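"""Disparity-reduction scenarios and weekly activity realisation.

A scenario raises each stratum's mean days/week with >=60 min of activity
toward the best-performing federal-poverty-level category of the same sex and
age band; the reduction fraction interpolates linearly between the status quo
(0) and full parity (1).  Shifts are applied to each agent's individual mean,
preserving within-stratum dispersion, and are never negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .cohort import Agent
from .params import AGE_BANDS, SEXES, StrataTable

COMPENSATION_MODES = ("none", "fraction_of_extra", "diet_improvement")
DIET_IMPROVEMENT_FRACTION = 0.02  # 2% total-intake decrease


@dataclass(frozen=True)
class ScenarioSpec:
    """A counterfactual: reduction fraction, off-day minutes, compensation."""

    reduction: float = 0.0
    offday_minutes: float = 30.0
    compensation_mode: str = "none"
    compensation_value: float = 0.0
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        if not 0.0 <= self.reduction <= 1.0:
            raise ValueError("reduction fraction must lie in [0, 1]")
        if not 0.0 <= self.offday_minutes <= 60.0:
            raise ValueError("offday_minutes must lie in [0, 60]")
        if self.compensation_mode not in COMPENSATION_MODES:
            raise ValueError(f"unknown compensation mode {self.compensation_mode!r}")
        if self.compensation_mode == "fraction_of_extra":
            if not 0.0 <= self.compensation_value <= 1.0:
                raise ValueError("compensation fraction must lie in [0, 1]")

    @classmethod
    def from_compensation_flag(cls, flag: str, **kw) -> "ScenarioSpec":
        """Parse CLI shorthand: 'none', 'frac:0.25', or 'diet:0.02'."""
        if flag == "none":
            return cls(compensation_mode="none", **kw)
        kind, _, value = flag.partition(":")
        value = float(value) if value else None
        if kind == "frac":
            return cls(compensation_mode="fraction_of_extra",
                       compensation_value=value, **kw)
        if kind == "diet":
            return cls(compensation_mode="diet_improvement",
                       compensation_value=abs(value) if value is not None
                       else DIET_IMPROVEMENT_FRACTION, **kw)
        raise ValueError(f"cannot parse compensation flag {flag!r}")


@dataclass(frozen=True)
class WeeklyDraw:
    """One realised week: days with >=60 min; remaining days get off-day minutes."""

    active_days: int
    offday_minutes: float

    def __post_init__(self):
        if not 0 <= self.active_days <= 7:
            raise ValueError("active_days must lie in 0..7")

    def minutes_on(self, day_of_week: int) -> float:
        return 60.0 if day_of_week < self.active_days else self.offday_minutes


def target_level(table: StrataTable, sex: str, age_band: str) -> float:
    """Highest mean activity days/week across FPL categories for a sex/age band."""
    rows = table.frame.loc[(sex, age_band)]
    return float(rows.pa_days_mean.max())


def target_levels(table: StrataTable) -> np.ndarray:
    """Targets for all (sex, age band) cells, shape (2, 3)."""
    return np.array([[target_level(table, s, b) for b in AGE_BANDS]
                     for s in SEXES])


def stratum_shift(table: StrataTable, reduction: float) -> np.ndarray:
    """Per-stratum upward mean shift, canonical order (24,).

    shift = reduction x max(target - stratum mean, 0); the top stratum in
    each sex/age cell is unmoved for any reduction.
    """
    ordered = table.ordered()
    tgt = target_levels(table)
    shifts = np.empty(24)
    for i, (sex, band, _fpl) in enumerate(table.stratum_keys()):
        t = tgt[SEXES.index(sex), AGE_BANDS.index(band)]
        shifts[i] = reduction * max(t - float(ordered.iloc[i].pa_days_mean), 0.0)
    return shifts


def shifted_pa_means(pa_days_mean: np.ndarray, stratum_idx: np.ndarray,
                     table: StrataTable, reduction: float) -> np.ndarray:
    """Apply the stratum-level shift to individual means, capped at 7."""
    shifts = stratum_shift(table, reduction)
    return np.minimum(np.asarray(pa_days_mean, dtype=float)
                      + shifts[stratum_idx], 7.0)


def apply_reduction(agent: Agent, table: StrataTable,
                    spec: ScenarioSpec) -> Agent:
    """Return the agent with their activity mean shifted per the scenario."""
    t = target_level(table, SEXES[agent.sex], agent.age_band)
    mean = float(table.row(SEXES[agent.sex], agent.age_band, agent.fpl).pa_days_mean)
    shift = spec.reduction * max(t - mean, 0.0)
    return agent.replace(pa_days_mean=min(agent.pa_days_mean + shift, 7.0))


def active_days_from_uniform(u, pa_days_mean) -> np.ndarray:
    """Invert the binomial(7, mean/7) CDF at a shared uniform.

    Monotone in the mean, which couples scenario arms: the same ``u`` never
    yields fewer active days under a higher mean.
    """
    p = np.clip(np.asarray(pa_days_mean, dtype=float) / 7.0, 0.0, 1.0)
    cdf = binom.cdf(np.arange(7)[None, :], 7, np.atleast_1d(p)[:, None])
    out = (np.atleast_1d(u)[:, None] > cdf).sum(axis=1)
    return out if np.ndim(u) else int(out[0])


def draw_week(agent: Agent, spec: ScenarioSpec,
              rng: np.random.Generator) -> WeeklyDraw:
    """Sample one week of activity for an agent (expectation = their mean)."""
    days = active_days_from_uniform(rng.random(), agent.pa_days_mean)
    return WeeklyDraw(active_days=int(days), offday_minutes=spec.offday_minutes)


def intake_adjustment(extra_pa_kcal: float, baseline_intake: float,
                      spec: ScenarioSpec) -> float:
    """Caloric-intake change accompanying additional activity.

    none -> 0; fraction_of_extra c -> +c x extra expenditure;
    diet_improvement -> -2% (or the configured fraction) of baseline intake.
    """
    if extra_pa_kcal < 0:
        raise ValueError("extra_pa_kcal must be >= 0")
    if spec.compensation_mode == "none":
        return 0.0
    if spec.compensation_mode == "fraction_of_extra":
        c = spec.compensation_value
        if not 0.0 <= c <= 1.0:
            raise ValueError("compensation fraction must lie in [0, 1]")
        return c * extra_pa_kcal
    value = spec.compensation_value or DIET_IMPROVEMENT_FRACTION
    return -value * baseline_intake
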