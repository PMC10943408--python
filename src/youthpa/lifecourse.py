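"""Annual multi-state progression from age 18 to death.

Each cycle: one state transition sampled from the (state, age, sex) row, then
event draws (coronary heart disease, stroke, type-2 diabetes onset, cancer
onset) conditional on the post-transition state, each with a case-fatality
draw.  Death is absorbing.  Agents enter at the metabolically healthy state of
their end-of-childhood BMI category — agents who changed weight but not
category enter identically.

Random draws follow a fixed schedule (drawn every cycle for every agent,
alive or dead), so paired baseline/counterfactual runs consuming the same
stream stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    DEATH_STATE,
    EVENT_TYPES,
    MAX_ADULT_AGE,
    MIN_ADULT_AGE,
    N_EVENTS,
    N_STATES,
    SEVERITIES,
    MarkovParamSet,
)

#: Entry state per end-of-childhood weight class: the "healthy" severity tier
#: of the matching BMI tier.
ENTRY_STATES = tuple(b * len(SEVERITIES) for b in range(3))

DEATH_CAUSE_NONE = -1
DEATH_CAUSE_BACKGROUND = N_EVENTS  # causes 0..3 are the event types


def entry_state(weight_class: int) -> int:
    """Map weight class (0 normal / 1 overweight / 2 obese) to entry state."""
    if weight_class not in (0, 1, 2):
        raise ValueError(f"invalid weight class {weight_class}")
    return ENTRY_STATES[weight_class]


@dataclass(frozen=True)
class TransitionContext:
    age: int
    sex: int
    state: int

    def __post_init__(self):
        if self.age < MIN_ADULT_AGE:
            raise ValueError("adult transitions start at age 18")


@dataclass
class LifeCourseRecord:
    """State path and tallies for one agent's adult years."""

    sex: int
    entry: int
    age: int = MIN_ADULT_AGE
    state: int = field(default=None)
    alive: bool = True
    states: list = field(default_factory=list)          # state after each cycle
    events: list = field(default_factory=list)          # per-cycle bool[4]
    death_cause: int = DEATH_CAUSE_NONE
    years_from_reference_at_entry: float = 0.0

    def __post_init__(self):
        if self.state is None:
            self.state = self.entry

    @property
    def life_years(self) -> int:
        return sum(s != DEATH_STATE for s in self.states)

    def event_counts(self, first_only: bool = True) -> dict:
        out = {}
        for t, name in enumerate(EVENT_TYPES):
            flags = [ev[t] for ev in self.events]
            out[name] = (int(any(flags)) if first_only else int(sum(flags)))
        return out

    @property
    def total_disease_cases(self) -> int:
        return sum(self.event_counts(first_only=True).values())


def _draws(rng: np.random.Generator):
    """Fixed per-cycle draw schedule: transition, events, fatalities."""
    return rng.random(), rng.random(N_EVENTS), rng.random(N_EVENTS)


def step_year(record: LifeCourseRecord, params: MarkovParamSet,
              rng: np.random.Generator) -> LifeCourseRecord:
    """Advance one annual cycle in place (draws consumed even when dead)."""
    u_t, u_e, u_f = _draws(rng)
    if not record.alive:
        return record
    age_idx = min(record.age, MAX_ADULT_AGE) - MIN_ADULT_AGE
    row = params.transition[record.sex, age_idx, record.state]
    rowsum = row.sum()
    if abs(rowsum - 1.0) > 1e-9:
        raise ValueError(
            f"malformed transition row (sex={record.sex}, age={record.age}, "
            f"state={record.state}): sums to {rowsum!r}"
        )
    new_state = int(np.searchsorted(np.cumsum(row), u_t, side="right"))
    new_state = min(new_state, N_STATES - 1)

    occurred = [False] * N_EVENTS
    if new_state != DEATH_STATE:
        for t in range(N_EVENTS):
            p = params.event_prob[t, record.sex, age_idx, new_state]
            if u_e[t] < p:
                occurred[t] = True
        for t in range(N_EVENTS):
            if occurred[t] and u_f[t] < params.case_fatality[t, record.sex, age_idx]:
                if new_state != DEATH_STATE:
                    record.death_cause = t
                new_state = DEATH_STATE
    else:
        record.death_cause = DEATH_CAUSE_BACKGROUND

    record.state = new_state
    record.alive = new_state != DEATH_STATE
    record.states.append(new_state)
    record.events.append(occurred)
    record.age += 1
    return record


def run_lifecourse(entry: int, sex: int, params: MarkovParamSet,
                   rng: np.random.Generator, max_age: int = MAX_ADULT_AGE,
                   years_from_reference_at_entry: float = 0.0,
                   ) -> LifeCourseRecord:
    """Iterate annual cycles until death or the age cap (censored survivors)."""
    record = LifeCourseRecord(
        sex=sex, entry=entry,
        years_from_reference_at_entry=years_from_reference_at_entry)
    while record.alive and record.age < max_age:
        step_year(record, params, rng)
    return record


# ---------------------------------------------------------------------------
# Vectorised multi-arm engine with economic accrual
# ---------------------------------------------------------------------------

@dataclass
class LifeCourseBatch:
    """Per-agent adult-phase tallies for one arm (arrays of length n)."""

    life_years: np.ndarray
    event_first: np.ndarray        # (4, n) 0/1 first onsets
    death_cause: np.ndarray        # (n,) -1 alive/censored, 0..3 event, 4 background
    qalys_discounted: np.ndarray
    direct_cost_discounted: np.ndarray
    productivity_discounted: np.ndarray
    final_state: np.ndarray
    occupancy: np.ndarray = None   # (n_cycles, 15) post-cycle state counts
    label: str = ""

    @property
    def total_disease_cases(self) -> np.ndarray:
        return self.event_first.sum(axis=0)

    @property
    def dead(self) -> np.ndarray:
        return self.death_cause >= 0


def run_lifecourse_batch(entry_states: np.ndarray, sex: np.ndarray,
                         years_offset: np.ndarray, params: MarkovParamSet,
                         rng: np.random.Generator,
                         discount_rate: float = 0.03,
                         daily_wage: float = None,
                         max_age: int = MAX_ADULT_AGE,
                         count_recurrent: bool = False,
                         record_occupancy: bool = False,
                         ) -> list[LifeCourseBatch]:
    """Simulate all arms' adult lives with shared random draws.

    ``entry_states`` has shape (n_arms, n); arms consume identical uniforms
    each cycle, so agents whose entry states coincide across arms follow
    bit-identical paths.  ``years_offset`` is each agent's years from the
    cohort reference date at adult entry (for discounting).

    Accrual convention per cycle: transition, then events; event costs accrue
    to everyone who had the event (fatal or not); state cost, utility and the
    life-year accrue only if the agent survives the cycle.
    """
    entry_states = np.atleast_2d(entry_states)
    n_arms, n = entry_states.shape
    sex = np.asarray(sex, dtype=int)
    wage = params.daily_wage if daily_wage is None else daily_wage
    disc = 1.0 / (1.0 + discount_rate)

    state = entry_states.astype(int).copy()
    ly = np.zeros((n_arms, n))
    first = np.zeros((n_arms, N_EVENTS, n))
    cause = np.full((n_arms, n), DEATH_CAUSE_NONE, dtype=int)
    qaly = np.zeros((n_arms, n))
    cost = np.zeros((n_arms, n))
    prod = np.zeros((n_arms, n))
    had = np.zeros((n_arms, N_EVENTS, n), dtype=bool)
    n_cycles = max_age - MIN_ADULT_AGE
    occupancy = (np.zeros((n_arms, n_cycles, N_STATES), dtype=np.int64)
                 if record_occupancy else None)

    sex_groups = [np.flatnonzero(sex == s) for s in (0, 1)]

    for age in range(MIN_ADULT_AGE, max_age):
        ai = age - MIN_ADULT_AGE
        u_t = rng.random(n)
        u_e = rng.random((N_EVENTS, n))
        u_f = rng.random((N_EVENTS, n))
        df = disc ** (years_offset + (age - MIN_ADULT_AGE))
        for a in range(n_arms):
            s_cur = state[a]
            alive = s_cur != DEATH_STATE
            new = s_cur.copy()
            for sx, idx in enumerate(sex_groups):
                if idx.size == 0:
                    continue
                rows = params.transition_cum[sx, ai][s_cur[idx]]  # (m, 15)
                new[idx] = (u_t[idx, None] > rows[:, :-1]).sum(axis=1)
            new[~alive] = DEATH_STATE
            cause[a][alive & (new == DEATH_STATE)] = DEATH_CAUSE_BACKGROUND

            ep = np.empty((N_EVENTS, n))
            for sx, idx in enumerate(sex_groups):
                if idx.size:
                    ep[:, idx] = params.event_prob[:, sx, ai, :][:, new[idx]]
            occurred = alive[None, :] & (new != DEATH_STATE)[None, :] \
                & (u_e < ep)
            if count_recurrent:
                first[a] += occurred
            else:
                first[a] += occurred & ~had[a]
            had[a] |= occurred

            cf = np.empty((N_EVENTS, n))
            for sx, idx in enumerate(sex_groups):
                if idx.size:
                    cf[:, idx] = params.case_fatality[:, sx, ai][:, None]
            fatal = occurred & (u_f < cf)
            for t in range(N_EVENTS):
                dies = fatal[t] & (new != DEATH_STATE)
                cause[a][dies] = t
                new[dies] = DEATH_STATE

            survives = new != DEATH_STATE
            disutil = (occurred * params.event_disutility[:, None]).sum(axis=0)
            qw = np.clip(params.state_utility[new] - disutil, 0.0, None)
            ly[a] += survives
            qaly[a] += df * qw * survives
            event_cost = (occurred * params.event_cost[:, None]).sum(axis=0)
            cost[a] += df * (params.state_cost[new] * survives + event_cost)
            prod[a] += df * wage * (1.0 - qw) * 365.0 * survives
            state[a] = new
            if record_occupancy:
                occupancy[a, ai] = np.bincount(new, minlength=N_STATES)

    return [LifeCourseBatch(
        life_years=ly[a], event_first=first[a], death_cause=cause[a],
        qalys_discounted=qaly[a], direct_cost_discounted=cost[a],
        productivity_discounted=prod[a], final_state=state[a],
        occupancy=None if occupancy is None else occupancy[a],
    ) for a in range(n_arms)]
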