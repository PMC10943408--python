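"""Agent population construction from the national strata table.

Agents are allocated to the 24 strata proportionally to the printed
populations (largest-remainder rounding, ties broken by canonical stratum
order), carry national sampling weights ``population / agents``, and draw
baseline weight class and individual activity level to match the stratum
summary measures in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .params import (
    ADULT_AGE_DAYS,
    AGE_BAND_YEARS,
    AGE_BANDS,
    DAYS_PER_YEAR,
    FPL_LEVELS,
    SEXES,
    GrowthReference,
    StrataTable,
)

WEIGHT_CLASSES = ("normal", "overweight", "obese")

#: Baseline fat fraction of body weight by (weight class, sex); the source
#: model's initialisation rule is unpublished, so this is a config-exposed
#: convention.
DEFAULT_FAT_FRACTION = {
    "normal": (0.20, 0.25),
    "overweight": (0.28, 0.32),
    "obese": (0.35, 0.40),
}


@dataclass
class Agent:
    """One simulated child."""

    id: int
    sex: int                 # 0 male, 1 female
    age_days: int
    age_band: str
    fpl: str
    height_cm: float
    fat_mass_kg: float
    fat_free_mass_kg: float
    pa_days_mean: float
    bmi_percentile_at_baseline: float
    weight_class: int        # index into WEIGHT_CLASSES
    sampling_weight: float   # persons represented per agent

    @property
    def weight_kg(self) -> float:
        return self.fat_mass_kg + self.fat_free_mass_kg

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2

    def replace(self, **kw) -> "Agent":
        return replace(self, **kw)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-build configuration."""

    n_agents: int
    pa_day_sd_individual: float = 1.5
    seed: int = 0
    fat_fraction: dict = None

    def __post_init__(self):
        if self.n_agents < 24:
            raise ValueError("n_agents must be >= 24 (one per stratum)")
        if self.fat_fraction is None:
            object.__setattr__(self, "fat_fraction", DEFAULT_FAT_FRACTION)


@dataclass
class Cohort:
    """Column-array view of the agent population (one row per agent)."""

    ids: np.ndarray
    sex: np.ndarray            # int, 0/1
    age_days: np.ndarray       # int
    band_idx: np.ndarray       # int into AGE_BANDS
    fpl_idx: np.ndarray        # int into FPL_LEVELS
    stratum_idx: np.ndarray    # int 0..23, canonical order
    height_cm: np.ndarray
    fat_mass_kg: np.ndarray
    fat_free_mass_kg: np.ndarray
    pa_days_mean: np.ndarray
    bmi_percentile_at_baseline: np.ndarray
    weight_class: np.ndarray   # int 0/1/2
    sampling_weight: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def weight_kg(self) -> np.ndarray:
        return self.fat_mass_kg + self.fat_free_mass_kg

    @property
    def bmi(self) -> np.ndarray:
        return self.weight_kg / (self.height_cm / 100.0) ** 2

    def agent(self, i: int) -> Agent:
        return Agent(
            id=int(self.ids[i]),
            sex=int(self.sex[i]),
            age_days=int(self.age_days[i]),
            age_band=AGE_BANDS[self.band_idx[i]],
            fpl=FPL_LEVELS[self.fpl_idx[i]],
            height_cm=float(self.height_cm[i]),
            fat_mass_kg=float(self.fat_mass_kg[i]),
            fat_free_mass_kg=float(self.fat_free_mass_kg[i]),
            pa_days_mean=float(self.pa_days_mean[i]),
            bmi_percentile_at_baseline=float(self.bmi_percentile_at_baseline[i]),
            weight_class=int(self.weight_class[i]),
            sampling_weight=float(self.sampling_weight[i]),
        )

    def agents(self):
        for i in range(self.n):
            yield self.agent(i)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids,
            "sex": np.take(SEXES, self.sex),
            "age_days": self.age_days,
            "age_band": np.take(AGE_BANDS, self.band_idx),
            "fpl": np.take(FPL_LEVELS, self.fpl_idx),
            "height_cm": self.height_cm,
            "fat_mass_kg": self.fat_mass_kg,
            "fat_free_mass_kg": self.fat_free_mass_kg,
            "weight_kg": self.weight_kg,
            "bmi": self.bmi,
            "bmi_percentile_at_baseline": self.bmi_percentile_at_baseline,
            "pa_days_mean": self.pa_days_mean,
            "weight_class": np.take(WEIGHT_CLASSES, self.weight_class),
            "sampling_weight": self.sampling_weight,
        })


def allocate_strata(populations: np.ndarray, n_agents: int) -> np.ndarray:
    """Largest-remainder allocation of ``n_agents`` across strata.

    Ties in the fractional remainders are broken by position (canonical
    stratum order).
    """
    populations = np.asarray(populations, dtype=float)
    quota = n_agents * populations / populations.sum()
    base = np.floor(quota).astype(int)
    remainder = quota - base
    short = n_agents - base.sum()
    # stable sort descending on remainder -> earlier strata win ties
    order = np.argsort(-remainder, kind="stable")
    base[order[:short]] += 1
    return base


def truncnorm_mean_shift(target_mean: float, sd: float,
                         lo: float = 0.0, hi: float = 7.0) -> float:
    """Location mu such that a normal(mu, sd) truncated to [lo, hi] has the
    requested mean.  Naively centring at the target biases the realised mean
    because the truncation is asymmetric for means near the bounds."""
    if not lo < target_mean < hi:
        raise ValueError(f"target mean {target_mean} outside ({lo}, {hi})")

    def gap(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return truncnorm.mean(a, b, loc=mu, scale=sd) - target_mean

    span = 5 * sd
    mu_lo, mu_hi = lo - span, hi + span
    # widen until the gap brackets zero (gap is monotone increasing in mu)
    for _ in range(60):
        if gap(mu_lo) <= 0:
            break
        mu_lo -= span
    for _ in range(60):
        if gap(mu_hi) >= 0:
            break
        mu_hi += span
    return brentq(gap, mu_lo, mu_hi, xtol=1e-10)


def sample_pa_days(target_mean: float, sd: float, size: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Individual activity levels: truncated normal on [0, 7] whose *mean*
    equals the stratum mean."""
    if sd == 0:
        return np.full(size, target_mean)
    mu = truncnorm_mean_shift(target_mean, sd)
    a, b = (0.0 - mu) / sd, (7.0 - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def classify_weight(bmi, sex, age_days, growth: GrowthReference) -> np.ndarray:
    """Weight class from BMI: 0 normal (< p85), 1 overweight [p85, p95),
    2 obese (>= p95).  Boundary cases classify upward.

    Raises if any age falls outside the 6–18 y reference range.
    """
    age_days = np.asarray(age_days)
    if (age_days < 6 * DAYS_PER_YEAR).any() or (age_days > ADULT_AGE_DAYS).any():
        raise ValueError("age outside growth-reference range 6-18 y")
    bmi = np.asarray(bmi, dtype=float)
    t85 = growth.threshold_85(sex, age_days)
    t95 = growth.threshold_95(sex, age_days)
    return (bmi >= t85).astype(int) + (bmi >= t95).astype(int)


def build_cohort(table: StrataTable, growth: GrowthReference,
                 spec: CohortSpec) -> Cohort:
    """Construct the agent population.

    Per stratum: agents proportional to the printed population
    (largest-remainder); baseline weight class multinomial on the printed
    overweight/obesity prevalences; ages uniform by day within the band;
    individual activity means from a mean-matched truncated normal;
    ``sampling_weight = population / agents``.
    """
    rng = np.random.default_rng([spec.seed, 0x636F686F])
    keys = table.stratum_keys()
    ordered = table.ordered()
    pops = ordered.population.to_numpy(dtype=float)
    counts = allocate_strata(pops, spec.n_agents)
    if (counts == 0).any():
        empty = [keys[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(
            f"n_agents={spec.n_agents} leaves {len(empty)} strata empty: {empty}"
        )

    cols = {name: [] for name in (
        "sex", "age_days", "band_idx", "fpl_idx", "stratum_idx",
        "pa_days_mean", "weight_class", "bmi_pct", "sampling_weight")}

    for si, ((sex_name, band, fpl), n_s) in enumerate(zip(keys, counts)):
        row = ordered.iloc[si]
        sx = SEXES.index(sex_name)
        bi = AGE_BANDS.index(band)
        fi = FPL_LEVELS.index(fpl)
        lo_y, hi_y = AGE_BAND_YEARS[band]
        ages = rng.integers(lo_y * DAYS_PER_YEAR, (hi_y + 1) * DAYS_PER_YEAR,
                            size=n_s)
        pa = sample_pa_days(float(row.pa_days_mean), spec.pa_day_sd_individual,
                            n_s, rng)
        p_ow = float(row.overweight_prev) / 100.0
        p_ob = float(row.obesity_prev) / 100.0
        u = rng.random(n_s)
        wclass = np.zeros(n_s, dtype=int)
        wclass[u < p_ow + p_ob] = 1
        wclass[u < p_ob] = 2
        # Baseline BMI percentile drawn uniformly within the class band.
        pct = np.empty(n_s)
        for cls, (plo, phi) in enumerate(((1.0, 85.0), (85.0, 95.0), (95.0, 99.7))):
            m = wclass == cls
            pct[m] = rng.uniform(plo, phi, m.sum())

        cols["sex"].append(np.full(n_s, sx))
        cols["age_days"].append(ages)
        cols["band_idx"].append(np.full(n_s, bi))
        cols["fpl_idx"].append(np.full(n_s, fi))
        cols["stratum_idx"].append(np.full(n_s, si))
        cols["pa_days_mean"].append(pa)
        cols["weight_class"].append(wclass)
        cols["bmi_pct"].append(pct)
        cols["sampling_weight"].append(np.full(n_s, float(row.population) / n_s))

    arr = {k: np.concatenate(v) for k, v in cols.items()}
    n = spec.n_agents
    sex = arr["sex"].astype(int)
    age_days = arr["age_days"].astype(int)
    height = np.asarray(growth.height_cm(sex, age_days), dtype=float)
    bmi = np.asarray(growth.bmi_at_percentile(sex, age_days, arr["bmi_pct"]))
    weight = bmi * (height / 100.0) ** 2
    ff = np.empty(n)
    for cls, name in enumerate(WEIGHT_CLASSES):
        fr = spec.fat_fraction[name]
        m = arr["weight_class"] == cls
        ff[m] = np.take(fr, sex[m])
    fat = ff * weight

    return Cohort(
        ids=np.arange(n),
        sex=sex,
        age_days=age_days,
        band_idx=arr["band_idx"].astype(int),
        fpl_idx=arr["fpl_idx"].astype(int),
        stratum_idx=arr["stratum_idx"].astype(int),
        height_cm=height,
        fat_mass_kg=fat,
        fat_free_mass_kg=weight - fat,
        pa_days_mean=arr["pa_days_mean"],
        bmi_percentile_at_baseline=arr["bmi_pct"],
        weight_class=arr["weight_class"].astype(int),
        sampling_weight=arr["sampling_weight"],
    )
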