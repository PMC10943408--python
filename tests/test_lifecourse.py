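import dataclasses

import numpy as np
import pytest

from youthpa.lifecourse import (
    DEATH_CAUSE_BACKGROUND,
    DEATH_STATE,
    ENTRY_STATES,
    LifeCourseRecord,
    entry_state,
    run_lifecourse,
    run_lifecourse_batch,
    step_year,
)
from youthpa.params import (
    MIN_ADULT_AGE,
    N_ADULT_AGES,
    N_EVENTS,
    N_STATES,
    synthesize_markov_params,
)


def degenerate_params(markov, stay_forever=False, die_at_entry=False):
    """Copy of the parameter set with a degenerate transition structure."""
    p = dataclasses.replace(markov)
    t = np.zeros_like(markov.transition)
    if stay_forever:
        for s in range(N_STATES):
            t[:, :, s, s] = 1.0
        p.event_prob = np.zeros_like(markov.event_prob)
    elif die_at_entry:
        t[:, :, :, DEATH_STATE] = 1.0
    p.transition = t
    p.transition_cum = np.cumsum(t, axis=-1)
    return p


class TestEntryState:
    def test_mapping(self):
        assert entry_state(0) == ENTRY_STATES[0] == 0
        assert entry_state(1) == 4
        assert entry_state(2) == 8

    def test_same_category_same_entry(self):
        # weight changed, category unchanged -> identical entry (conservative rule)
        assert entry_state(1) == entry_state(1)

    def test_invalid(self):
        with pytest.raises(ValueError):
            entry_state(3)


class TestStepYear:
    def test_dead_agent_unchanged(self, markov, rng):
        rec = LifeCourseRecord(sex=0, entry=0)
        rec.alive = False
        rec.state = DEATH_STATE
        before = (rec.age, rec.state, list(rec.states))
        step_year(rec, markov, rng)
        assert (rec.age, rec.state, list(rec.states)) == before

    def test_identity_matrix_static(self, markov, rng):
        p = degenerate_params(markov, stay_forever=True)
        rec = LifeCourseRecord(sex=1, entry=4)
        for _ in range(80):
            step_year(rec, p, rng)
        assert rec.state == 4
        assert rec.life_years == 80
        assert rec.total_disease_cases == 0

    def test_malformed_row_named(self, markov, rng):
        p = dataclasses.replace(markov)
        p.transition = markov.transition.copy()
        p.transition[0, 0, 3, 3] += 0.5
        rec = LifeCourseRecord(sex=0, entry=3)
        with pytest.raises(ValueError, match=r"sex=0, age=18, state=3"):
            step_year(rec, p, rng)

    def test_single_step_frequencies(self, markov):
        # 50 000 single steps from one row vs its exact probabilities
        rng = np.random.default_rng(77)
        sex, age, state = 0, 40, 8
        p = dataclasses.replace(markov)
        p.event_prob = np.zeros_like(markov.event_prob)  # isolate the transition
        n = 50_000
        counts = np.zeros(N_STATES)
        for _ in range(n):
            rec = LifeCourseRecord(sex=sex, entry=state)
            rec.age = age
            step_year(rec, p, rng)
            counts[rec.states[-1]] += 1
        probs = markov.transition[sex, age - MIN_ADULT_AGE, state]
        se = np.sqrt(probs * (1 - probs) / n)
        assert (np.abs(counts / n - probs) <= 3 * se + 3 / n).all()


class TestRunLifecourse:
    def test_immediate_mortality(self, markov):
        p = degenerate_params(markov, die_at_entry=True)
        rec = run_lifecourse(0, 0, p, np.random.default_rng(0))
        assert rec.life_years == 0
        assert not rec.alive
        assert rec.death_cause == DEATH_CAUSE_BACKGROUND

    def test_replay_identical(self, markov):
        a = run_lifecourse(4, 1, markov, np.random.default_rng(42))
        b = run_lifecourse(4, 1, markov, np.random.default_rng(42))
        assert a.states == b.states
        assert a.events == b.events
        assert a.death_cause == b.death_cause

    def test_no_events_after_death(self, markov):
        for seed in range(20):
            rec = run_lifecourse(8, 0, markov, np.random.default_rng(seed))
            dead_cycles = [i for i, s in enumerate(rec.states)
                           if s == DEATH_STATE]
            if dead_cycles:
                for i in dead_cycles[1:]:
                    assert not any(rec.events[i])

    def test_scalar_agrees_with_batch_mean(self, markov):
        # dual route: per-agent loop vs vectorised engine, same distribution
        n_scalar, n_batch = 400, 20_000
        rng = np.random.default_rng(3)
        ly_scalar = np.array([
            run_lifecourse(0, 0, markov, rng).life_years
            for _ in range(n_scalar)])
        batch = run_lifecourse_batch(
            np.zeros((1, n_batch), dtype=int), np.zeros(n_batch, dtype=int),
            np.zeros(n_batch), markov, np.random.default_rng(4))[0]
        se = np.sqrt(ly_scalar.var() / n_scalar + batch.life_years.var() / n_batch)
        assert abs(ly_scalar.mean() - batch.life_years.mean()) < 3 * se


class TestBatch:
    def test_shared_draws_align_identical_entries(self, markov, rng):
        n = 500
        entries = np.zeros((2, n), dtype=int)
        entries[1] = entries[0]
        sex = np.arange(n) % 2
        a, b = run_lifecourse_batch(entries, sex, np.zeros(n), markov, rng)
        np.testing.assert_array_equal(a.final_state, b.final_state)
        np.testing.assert_array_equal(a.life_years, b.life_years)
        np.testing.assert_array_equal(a.qalys_discounted, b.qalys_discounted)

    def test_risk_gradient_by_entry(self, markov):
        n = 20_000
        entries = np.vstack([np.zeros(n, dtype=int), np.full(n, 8, dtype=int)])
        sex = np.arange(n) % 2
        normal, obese = run_lifecourse_batch(entries, sex, np.zeros(n), markov,
                                             np.random.default_rng(9))
        assert obese.total_disease_cases.mean() >= normal.total_disease_cases.mean()
        assert obese.life_years.mean() <= normal.life_years.mean()

    def test_integer_tallies_and_cause_bound(self, markov, rng):
        n = 2000
        batch = run_lifecourse_batch(
            np.full((1, n), 4, dtype=int), np.arange(n) % 2, np.zeros(n),
            markov, rng)[0]
        assert np.array_equal(batch.event_first, batch.event_first.astype(int))
        cause_deaths = ((batch.death_cause >= 0)
                        & (batch.death_cause < N_EVENTS)).sum()
        assert cause_deaths <= batch.dead.sum()

    def test_occupancy_rows_complete(self, markov, rng):
        n = 1000
        batch = run_lifecourse_batch(
            np.zeros((1, n), dtype=int), np.zeros(n, dtype=int), np.zeros(n),
            markov, rng, record_occupancy=True)[0]
        assert batch.occupancy.shape == (N_ADULT_AGES - 1, N_STATES)
        assert (batch.occupancy.sum(axis=1) == n).all()
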