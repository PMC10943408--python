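"""Input parameters: the national strata fixture and seeded synthetic stand-ins.

The strata table (population counts, mean days/week with >=60 min of physical
activity, overweight/obesity prevalence by sex x age band x federal-poverty-level
category) ships with the package as a CSV fixture and is loaded verbatim.

Everything else the simulation needs — growth/BMI references and the adult
multi-state disease parameter set (transition matrices, event probabilities,
costs, utilities) — is *synthesized* from a seed.  The synthetic values are
structurally valid (probabilities normalise, risk gradients hold by
construction, magnitudes are order-of-magnitude plausible) but are explicitly
non-authoritative stand-ins, swappable for real tables through the same types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

SEXES = ("male", "female")
AGE_BANDS = ("6-10", "11-13", "14-17")
AGE_BAND_YEARS = {"6-10": (6, 10), "11-13": (11, 13), "14-17": (14, 17)}
FPL_LEVELS = ("<100%", "100-199%", "200-399%", ">=400%")

DAYS_PER_YEAR = 365
CHILD_START_AGE_Y = 6
ADULT_AGE_Y = 18
ADULT_AGE_DAYS = ADULT_AGE_Y * DAYS_PER_YEAR

#: z-scores of the 85th / 95th percentiles, the overweight / obesity cutoffs.
Z85 = float(ndtri(0.85))
Z95 = float(ndtri(0.95))

_FIXTURE_NAME = "strata.csv"
_FIXTURE_COLUMNS = [
    "sex", "age_band", "fpl", "population",
    "pa_days_mean", "pa_days_se",
    "overweight_prev", "overweight_se",
    "obesity_prev", "obesity_se",
]


class StrataTable:
    """24 survey strata: (sex x age band x FPL category) summary measures.

    Wraps a DataFrame indexed by ``(sex, age_band, fpl)`` with columns
    ``population``, ``pa_days_mean``, ``pa_days_se``, ``overweight_prev``,
    ``obesity_prev`` (prevalences in percent).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if set(_FIXTURE_COLUMNS) - set(frame.columns):
            missing = sorted(set(_FIXTURE_COLUMNS) - set(frame.columns))
            raise ValueError(f"strata table missing columns: {missing}")
        frame = frame.set_index(["sex", "age_band", "fpl"], drop=False)
        self.frame = frame.sort_index()
        self.validate()

    # -- canonical stratum ordering: sex-major, then age band, then FPL -------
    @staticmethod
    def stratum_keys() -> list[tuple[str, str, str]]:
        return [(s, b, f) for s in SEXES for b in AGE_BANDS for f in FPL_LEVELS]

    def validate(self) -> None:
        df = self.frame
        if len(df) != 24:
            raise ValueError(f"expected 24 strata, got {len(df)}")
        for key in self.stratum_keys():
            if key not in df.index:
                raise ValueError(f"stratum {key} missing from table")
        if (df.population <= 0).any():
            raise ValueError("non-positive stratum population")
        if ((df.pa_days_mean < 0) | (df.pa_days_mean > 7)).any():
            raise ValueError("pa_days_mean outside [0, 7]")
        tot = df.overweight_prev + df.obesity_prev
        if ((tot < 0) | (tot > 100)).any():
            raise ValueError("overweight + obesity prevalence outside [0, 100]")

    def row(self, sex: str, age_band: str, fpl: str) -> pd.Series:
        return self.frame.loc[(sex, age_band, fpl)]

    @property
    def total_population(self) -> float:
        return float(self.frame.population.sum())

    def ordered(self) -> pd.DataFrame:
        """Rows in canonical stratum order (used for allocation tie-breaks)."""
        return self.frame.loc[self.stratum_keys()]


def load_strata_table() -> StrataTable:
    """Load the packaged national strata fixture.

    Raises a hard error naming the fixture file if it is absent or corrupt.
    """
    try:
        ref = resources.files("youthpa.data").joinpath(_FIXTURE_NAME)
        with ref.open("r") as fh:
            frame = pd.read_csv(fh)
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise FileNotFoundError(
            f"packaged strata fixture '{_FIXTURE_NAME}' not found"
        ) from exc
    try:
        return StrataTable(frame)
    except ValueError as exc:
        raise ValueError(f"corrupt strata fixture '{_FIXTURE_NAME}': {exc}") from exc


# Alias matching the table's provenance-free role as "the Table 1 input".
load_table1 = load_strata_table


# ---------------------------------------------------------------------------
# Growth reference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthReference:
    """Synthetic sex-specific growth reference for ages 6–18.

    Height follows a monotone blend of linear growth and a logistic pubertal
    spurt; the BMI distribution at each age is log-normal with an
    age-increasing median and log-SD, from which percentiles and the
    85th/95th overweight/obesity thresholds derive.  A stand-in for national
    growth charts: same interface, synthetic coefficients.
    """

    height_at_6: tuple[float, float]      # cm, (male, female)
    height_at_18: tuple[float, float]
    spurt_age: tuple[float, float]        # years
    spurt_scale: tuple[float, float]      # years
    spurt_weight: float                   # fraction of gain in logistic part
    bmi_median_at_6: tuple[float, float]  # kg/m^2
    bmi_median_at_18: tuple[float, float]
    bmi_median_power: float
    bmi_log_sd_at_6: float
    bmi_log_sd_at_18: float
    seed: int

    def _sex_idx(self, sex) -> np.ndarray:
        return np.asarray(sex, dtype=int)

    def _age_years(self, age_days) -> np.ndarray:
        a = np.asarray(age_days, dtype=float) / DAYS_PER_YEAR
        return np.clip(a, CHILD_START_AGE_Y, ADULT_AGE_Y)

    def _blend(self, t: np.ndarray, s: np.ndarray) -> np.ndarray:
        t0 = np.take(self.spurt_age, s)
        sc = np.take(self.spurt_scale, s)
        lin = (t - 6.0) / 12.0
        sig = 1.0 / (1.0 + np.exp(-(t - t0) / sc))
        sig6 = 1.0 / (1.0 + np.exp(-(6.0 - t0) / sc))
        sig18 = 1.0 / (1.0 + np.exp(-(18.0 - t0) / sc))
        log = (sig - sig6) / (sig18 - sig6)
        w = self.spurt_weight
        return (1.0 - w) * lin + w * log

    def height_cm(self, sex, age_days) -> np.ndarray:
        """Median height (cm) at the given age in days."""
        s = self._sex_idx(sex)
        t = self._age_years(age_days)
        h6 = np.take(self.height_at_6, s)
        h18 = np.take(self.height_at_18, s)
        return h6 + (h18 - h6) * self._blend(t, s)

    def height_velocity_cm_per_day(self, sex, age_days) -> np.ndarray:
        a = np.asarray(age_days, dtype=float)
        return (self.height_cm(sex, a + 1) - self.height_cm(sex, a)) / 1.0

    def bmi_median(self, sex, age_days) -> np.ndarray:
        s = self._sex_idx(sex)
        t = self._age_years(age_days)
        m6 = np.take(self.bmi_median_at_6, s)
        m18 = np.take(self.bmi_median_at_18, s)
        frac = ((t - 6.0) / 12.0) ** self.bmi_median_power
        return m6 + (m18 - m6) * frac

    def bmi_log_sd(self, sex, age_days) -> np.ndarray:
        t = self._age_years(age_days)
        frac = (t - 6.0) / 12.0
        sd = self.bmi_log_sd_at_6 + (self.bmi_log_sd_at_18 - self.bmi_log_sd_at_6) * frac
        return np.broadcast_to(sd, np.broadcast_shapes(np.shape(sex), np.shape(t))).copy()

    def bmi_zscore(self, sex, age_days, bmi) -> np.ndarray:
        m = self.bmi_median(sex, age_days)
        sd = self.bmi_log_sd(sex, age_days)
        return (np.log(np.asarray(bmi, dtype=float)) - np.log(m)) / sd

    def bmi_percentile(self, sex, age_days, bmi) -> np.ndarray:
        """BMI percentile (0–100) against the reference distribution."""
        return 100.0 * ndtr(self.bmi_zscore(sex, age_days, bmi))

    def bmi_at_zscore(self, sex, age_days, z) -> np.ndarray:
        m = self.bmi_median(sex, age_days)
        sd = self.bmi_log_sd(sex, age_days)
        return m * np.exp(np.asarray(z, dtype=float) * sd)

    def bmi_at_percentile(self, sex, age_days, pct) -> np.ndarray:
        z = ndtri(np.asarray(pct, dtype=float) / 100.0)
        return self.bmi_at_zscore(sex, age_days, z)

    def threshold_85(self, sex, age_days) -> np.ndarray:
        return self.bmi_at_zscore(sex, age_days, Z85)

    def threshold_95(self, sex, age_days) -> np.ndarray:
        return self.bmi_at_zscore(sex, age_days, Z95)

    def table(self, sex: int, step_days: int = 30) -> pd.DataFrame:
        """Tabular export: age, median height, velocity, 85th/95th thresholds."""
        ages = np.arange(CHILD_START_AGE_Y * DAYS_PER_YEAR, ADULT_AGE_DAYS + 1, step_days)
        s = np.full(ages.shape, sex)
        return pd.DataFrame({
            "age_days": ages,
            "height_cm": self.height_cm(s, ages),
            "height_velocity_cm_per_day": self.height_velocity_cm_per_day(s, ages),
            "bmi_p85": self.threshold_85(s, ages),
            "bmi_p95": self.threshold_95(s, ages),
        })


def synthesize_growth_reference(seed: int) -> GrowthReference:
    """Deterministic synthetic growth reference; same seed, same tables."""
    rng = np.random.default_rng([seed, 0x67726F77])
    jit = lambda: float(1.0 + rng.uniform(-0.005, 0.005))  # noqa: E731
    return GrowthReference(
        height_at_6=(116.0 * jit(), 115.4 * jit()),
        height_at_18=(176.1 * jit(), 163.2 * jit()),
        spurt_age=(13.5, 11.5),
        spurt_scale=(1.1, 1.0),
        spurt_weight=0.35,
        bmi_median_at_6=(15.4 * jit(), 15.3 * jit()),
        bmi_median_at_18=(21.7 * jit(), 21.3 * jit()),
        bmi_median_power=1.1,
        bmi_log_sd_at_6=0.11,
        bmi_log_sd_at_18=0.16,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Adult multi-state disease parameter set
# ---------------------------------------------------------------------------

#: State topology (a declared stand-in; only the count and the BMI entry rule
#: are externally constrained).  Indices 0–11 are the cross of BMI tier
#: {normal, overweight, obese} (major) and risk severity {healthy, moderate,
#: high, diseased} (minor).  Two merged states follow: 12 = post-event,
#: 13 = complicated multimorbid.  14 = death (absorbing).
BMI_TIERS = ("normal", "overweight", "obese")
SEVERITIES = ("healthy", "moderate", "high", "diseased")
STATE_LABELS = tuple(
    f"{b}_{s}" for b in BMI_TIERS for s in SEVERITIES
) + ("post_event", "complicated", "death")
N_STATES = 15
DEATH_STATE = 14
POST_EVENT_STATE = 12
COMPLICATED_STATE = 13

EVENT_TYPES = ("chd", "stroke", "t2d", "cancer")
N_EVENTS = len(EVENT_TYPES)

MIN_ADULT_AGE = 18
MAX_ADULT_AGE = 100
ADULT_AGES = np.arange(MIN_ADULT_AGE, MAX_ADULT_AGE + 1)
N_ADULT_AGES = len(ADULT_AGES)


@dataclass
class MarkovParamSet:
    """Adult disease-model parameters, all synthetic stand-ins.

    Arrays are indexed ``[sex, age_index, ...]`` with ``age_index =
    age - 18`` covering ages 18–100 inclusive.
    """

    transition: np.ndarray       # (2, n_ages, 15, 15) annual transition probs
    event_prob: np.ndarray       # (4, 2, n_ages, 15) annual event probabilities
    case_fatality: np.ndarray    # (4, 2, n_ages) prob an event is fatal
    state_cost: np.ndarray       # (15,) annual direct medical cost, USD
    event_cost: np.ndarray       # (4,) one-time event cost, USD
    state_utility: np.ndarray    # (15,) in [0, 1]; 0 for death
    event_disutility: np.ndarray  # (4,) same-year utility decrement
    daily_wage: float            # USD
    seed: int = 0
    transition_cum: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.transition_cum is None:
            self.transition_cum = np.cumsum(self.transition, axis=-1)

    def validate(self) -> None:
        t = self.transition
        if t.shape != (2, N_ADULT_AGES, N_STATES, N_STATES):
            raise ValueError(f"bad transition shape {t.shape}")
        rowsum = t.sum(axis=-1)
        if not np.allclose(rowsum, 1.0, atol=1e-12, rtol=0):
            raise ValueError("transition rows do not sum to 1 within 1e-12")
        if (t < 0).any() or (t > 1).any():
            raise ValueError("transition probabilities outside [0, 1]")
        death_rows = t[:, :, DEATH_STATE, :]
        expect = np.zeros(N_STATES)
        expect[DEATH_STATE] = 1.0
        if not np.array_equal(
            death_rows, np.broadcast_to(expect, death_rows.shape)
        ):
            raise ValueError("death state is not absorbing")
        e = self.event_prob
        if (e < 0).any() or (e > 1).any():
            raise ValueError("event probabilities outside [0, 1]")
        # Risk gradient: at fixed severity, normal <= overweight <= obese.
        for sev in range(len(SEVERITIES)):
            idx = [b * len(SEVERITIES) + sev for b in range(len(BMI_TIERS))]
            tiers = e[:, :, :, idx]
            if (np.diff(tiers, axis=-1) < 0).any():
                raise ValueError("event risk not monotone across BMI tiers")
        if (self.case_fatality < 0).any() or (self.case_fatality > 1).any():
            raise ValueError("case fatality outside [0, 1]")
        if (self.state_cost < 0).any() or (self.event_cost < 0).any():
            raise ValueError("negative cost")
        if (self.state_utility < 0).any() or (self.state_utility > 1).any():
            raise ValueError("utility outside [0, 1]")
        if self.state_utility[DEATH_STATE] != 0.0:
            raise ValueError("death utility must be 0")
        if self.daily_wage <= 0:
            raise ValueError("non-positive daily wage")

    def row(self, sex: int, age: int, state: int) -> np.ndarray:
        return self.transition[sex, age - MIN_ADULT_AGE, state]


def _severity_index(bmi_tier: int, severity: int) -> int:
    return bmi_tier * len(SEVERITIES) + severity


def synthesize_markov_params(seed: int) -> MarkovParamSet:
    """Build a structurally valid synthetic adult parameter set.

    Magnitudes are plausible for annual US rates/costs but carry no empirical
    authority.  The BMI risk gradient and row normalisation hold by
    construction for every seed.
    """
    rng = np.random.default_rng([seed, 0x6D61726B])
    ages = ADULT_AGES.astype(float)
    da = ages - MIN_ADULT_AGE  # age since 18

    n_sev = len(SEVERITIES)
    trans = np.zeros((2, N_ADULT_AGES, N_STATES, N_STATES))

    # Background (non-event) mortality: Gompertz in age, scaled by state.
    d0 = np.array([2.0e-4, 1.5e-4]) * rng.uniform(0.9, 1.1)
    gomp = np.exp(0.085 * da)
    sev_death = np.array([1.0, 1.3, 1.8, 2.8])
    bmi_death = np.array([1.0, 1.15, 1.4])
    merged_death = {POST_EVENT_STATE: 3.5, COMPLICATED_STATE: 4.5}

    prog0 = 0.02 * rng.uniform(0.8, 1.2)      # severity progression at 18
    prog_slope = 8.0e-4
    regress = 0.01
    bmi_up, bmi_down = 0.02, 0.01
    bmi_prog = np.array([1.0, 1.4, 1.9])
    to_post = 0.03                             # diseased -> post-event
    to_complicated = 0.02

    for sx in range(2):
        death_p = np.minimum(d0[sx] * gomp, 0.9)  # (n_ages,)
        for b in range(3):
            for sv in range(n_sev):
                i = _severity_index(b, sv)
                d = np.minimum(death_p * sev_death[sv] * bmi_death[b], 0.9)
                p_up = np.minimum((prog0 + prog_slope * da) * bmi_prog[b], 0.3)
                row = np.zeros((N_ADULT_AGES, N_STATES))
                row[:, DEATH_STATE] = d
                if sv < n_sev - 1:
                    row[:, _severity_index(b, sv + 1)] = p_up
                else:
                    row[:, POST_EVENT_STATE] = to_post
                if sv > 0:
                    row[:, _severity_index(b, sv - 1)] = regress
                if b < 2:
                    row[:, _severity_index(b + 1, sv)] = bmi_up
                if b > 0:
                    row[:, _severity_index(b - 1, sv)] = bmi_down
                stay = 1.0 - row.sum(axis=1)
                if (stay < 0).any():
                    raise AssertionError("transition construction overflow")
                row[:, i] = stay
                trans[sx, :, i, :] = row
        for m, mult in merged_death.items():
            d = np.minimum(death_p * mult, 0.9)
            row = np.zeros((N_ADULT_AGES, N_STATES))
            row[:, DEATH_STATE] = d
            if m == POST_EVENT_STATE:
                row[:, COMPLICATED_STATE] = np.minimum(
                    to_complicated + 3.0e-4 * da, 0.2
                )
            row[:, m] = 1.0 - row.sum(axis=1)
            trans[sx, :, m, :] = row
        trans[sx, :, DEATH_STATE, DEATH_STATE] = 1.0

    # Annual event probabilities: base hazard x BMI tier x severity, clipped.
    base = {
        "chd": (5.0e-5, 0.075, (1.0, 0.6)),
        "stroke": (3.0e-5, 0.080, (1.0, 0.85)),
        "t2d": (1.5e-3, 0.040, (1.0, 0.9)),
        "cancer": (1.0e-4, 0.070, (1.0, 1.0)),
    }
    bmi_mult = np.array([1.0, 1.5, 2.2])
    sev_mult = np.array([1.0, 1.5, 2.2, 3.2])
    events = np.zeros((N_EVENTS, 2, N_ADULT_AGES, N_STATES))
    for ti, name in enumerate(EVENT_TYPES):
        b0, slope, sex_f = base[name]
        b0 *= rng.uniform(0.8, 1.2)
        for sx in range(2):
            haz = b0 * sex_f[sx] * np.exp(slope * da)
            for b in range(3):
                for sv in range(n_sev):
                    i = _severity_index(b, sv)
                    events[ti, sx, :, i] = haz * bmi_mult[b] * sev_mult[sv]
            events[ti, sx, :, POST_EVENT_STATE] = haz * bmi_mult[2] * 3.0
            events[ti, sx, :, COMPLICATED_STATE] = haz * bmi_mult[2] * 4.0
    np.clip(events, 0.0, 0.5, out=events)
    events[:, :, :, DEATH_STATE] = 0.0

    cf = np.zeros((N_EVENTS, 2, N_ADULT_AGES))
    cf_base = {"chd": 0.20, "stroke": 0.18, "t2d": 0.02, "cancer": 0.35}
    for ti, name in enumerate(EVENT_TYPES):
        c = cf_base[name] * rng.uniform(0.9, 1.1)
        cf[ti] = np.minimum(c + 0.003 * da, 0.9)[None, :]

    sev_cost = np.array([400.0, 1200.0, 3000.0, 9000.0])
    bmi_cost = np.array([1.0, 1.1, 1.3])
    state_cost = np.zeros(N_STATES)
    for b in range(3):
        for sv in range(n_sev):
            state_cost[_severity_index(b, sv)] = sev_cost[sv] * bmi_cost[b]
    state_cost[POST_EVENT_STATE] = 12000.0
    state_cost[COMPLICATED_STATE] = 20000.0
    state_cost[:DEATH_STATE] *= rng.uniform(0.9, 1.1, N_STATES - 1)

    event_cost = np.array([45000.0, 52000.0, 12000.0, 80000.0])
    event_cost = event_cost * rng.uniform(0.9, 1.1, N_EVENTS)

    sev_util = np.array([0.93, 0.88, 0.82, 0.72])
    bmi_util = np.array([1.0, 0.99, 0.96])
    util = np.zeros(N_STATES)
    for b in range(3):
        for sv in range(n_sev):
            util[_severity_index(b, sv)] = min(sev_util[sv] * bmi_util[b], 1.0)
    util[POST_EVENT_STATE] = 0.68
    util[COMPLICATED_STATE] = 0.58
    util[DEATH_STATE] = 0.0

    disutil = np.array([0.10, 0.15, 0.05, 0.20]) * rng.uniform(0.9, 1.1, N_EVENTS)

    params = MarkovParamSet(
        transition=trans,
        event_prob=events,
        case_fatality=cf,
        state_cost=state_cost,
        event_cost=event_cost,
        state_utility=util,
        event_disutility=np.clip(disutil, 0.0, 1.0),
        daily_wage=float(230.0 * rng.uniform(0.95, 1.05)),
        seed=seed,
    )
    params.validate()
    return params


@dataclass(frozen=True)
class SynthesisConfig:
    """Plumbing for seeded parameter synthesis."""

    seed: int = 0
    cohort_size: int = 50_000

    def growth(self) -> GrowthReference:
        return synthesize_growth_reference(self.seed)

    def markov(self) -> MarkovParamSet:
        return synthesize_markov_params(self.seed)
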