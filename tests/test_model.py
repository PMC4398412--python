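"""Unit and property tests for the agent-level game dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from creolang import (
    ModelParams,
    apply_interaction,
    creolization_check,
    draw_pair,
    init_population,
    measure_fractions,
    run,
    step,
    utter,
)
from creolang.errors import (
    InvalidPopulationError,
    InvariantViolationError,
    TopologyViolationError,
)
from creolang.model import A, B, C, E, EU, M, mask_of, rep_of

REP = frozenset


def params(gamma=0.5, delta=0.5, epsilon=0.5, **kw):
    return ModelParams(gamma=gamma, delta=delta, epsilon=epsilon, **kw)


class TestInitPopulation:
    def test_initial_repertoires(self):
        state = init_population(2, 1, 1)
        assert state.repertoire(0) == REP({E})  # European
        assert state.repertoire(2) == REP({E})  # Mulatto
        assert state.repertoire(3) == REP({A})  # Bozal
        assert state.interactions_elapsed == 0

    def test_all_mulatto_population_is_all_E(self):
        state = init_population(0, 3, 0)
        assert all(state.repertoire(i) == REP({E}) for i in range(3))

    def test_no_hearers_is_invalid(self):
        with pytest.raises(InvalidPopulationError):
            init_population(5, 0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidPopulationError):
            init_population(-1, 2, 2)


class TestDrawPair:
    def test_europeans_never_hear(self, rng):
        state = init_population(10, 1, 0)
        p = params(epsilon=0.5)
        for _ in range(200):
            pair = draw_pair(state, p, rng)
            assert pair is not None
            speaker, hearer = pair
            assert state.group_of(hearer) != EU

    def test_epsilon_zero_blocks_european_bozal_contact(self, rng):
        state = init_population(5, 2, 3)
        p = params(epsilon=0.0)
        for _ in range(500):
            pair = draw_pair(state, p, rng)
            if pair is None:
                continue  # rejected Eu–B draw: a null step
            speaker, hearer = pair
            if state.group_of(speaker) == EU:
                assert state.group_of(hearer) == M

    def test_epsilon_one_matches_unconstrained_pair_frequencies(self, rng):
        # brute force: among Eu-involving pairs the hearer is a Bozal with
        # probability n_b / (n_m + n_b) when no gating is applied
        n_eu, n_m, n_b = 4, 2, 3
        state = init_population(n_eu, n_m, n_b)
        p = params(epsilon=1.0)
        eu_pairs = bozal_hearer = 0
        for _ in range(20000):
            speaker, hearer = draw_pair(state, p, rng)
            if state.group_of(speaker) == EU:
                eu_pairs += 1
                bozal_hearer += state.group_of(hearer) == B
        expected = n_b / (n_m + n_b)
        se = np.sqrt(expected * (1 - expected) / eu_pairs)
        assert abs(bozal_hearer / eu_pairs - expected) < 3 * se

    def test_single_agent_population_cannot_pair(self, rng):
        state = init_population(0, 1, 0)
        with pytest.raises(InvalidPopulationError):
            draw_pair(state, params(), rng)


class TestUtter:
    def test_singleton_repertoire_is_deterministic(self, rng):
        assert utter(REP({E}), rng) == E

    @pytest.mark.parametrize("rep", [REP({A, E}), REP({A, E, C})])
    def test_selection_is_uniform(self, rep, rng):
        draws = [utter(rep, rng) for _ in range(6000)]
        counts = [draws.count(l) for l in sorted(rep)]
        assert stats.chisquare(counts).pvalue > 1e-3

    def test_empty_repertoire_rejected(self, rng):
        with pytest.raises(InvariantViolationError):
            utter(REP(), rng)


class TestCreolizationCheck:
    def test_bilingual_A_E_creolizes_with_certainty(self, rng):
        assert creolization_check(REP({A, E}), 1.0, rng) == REP({C})

    def test_trilingual_creolizes_too(self, rng):
        assert creolization_check(REP({A, E, C}), 1.0, rng) == REP({C})

    @pytest.mark.parametrize("rep", [REP({E, C}), REP({A}), REP({C})])
    def test_rule_inapplicable_without_both_A_and_E(self, rep, rng):
        assert creolization_check(rep, 1.0, rng) == rep

    def test_gamma_zero_never_creolizes(self, rng):
        for _ in range(50):
            assert creolization_check(REP({A, E}), 0.0, rng) == REP({A, E})


class TestApplyInteraction:
    """The learning/collapse rules, exercised on a 1 Eu + 1 M + 1 B state."""

    def make_state(self, m_rep, b_rep):
        state = init_population(1, 1, 1)
        state.masks[0] = mask_of(m_rep)
        state.masks[1] = mask_of(b_rep)
        return state

    def test_unknown_language_is_learned(self, rng):
        # European utters E to a Bozal holding only A
        state = self.make_state(REP({E}), REP({A}))
        out = apply_interaction(state, 0, 2, E, params(gamma=0.0, epsilon=1.0), rng)
        assert out.result == "learned"
        assert state.repertoire(2) == REP({A, E})

    def test_shared_A_succeeds_when_fully_intelligible(self, rng):
        state = self.make_state(REP({A}), REP({A}))
        out = apply_interaction(state, 1, 2, A, params(delta=1.0), rng)
        assert out.result == "success"
        assert state.repertoire(1) == state.repertoire(2) == REP({A})

    def test_shared_A_fails_when_unintelligible(self, rng):
        state = self.make_state(REP({A, E}), REP({A}))
        out = apply_interaction(state, 1, 2, A, params(delta=0.0, gamma=0.0), rng)
        assert out.result == "failed_A"
        assert state.repertoire(1) == REP({A, E})  # nothing happens

    def test_E_collapses_both_repertoires_on_success(self, rng):
        state = self.make_state(REP({E}), REP({E, C}))
        out = apply_interaction(state, 1, 2, E, params(), rng)
        assert out.result == "success"
        assert state.repertoire(1) == state.repertoire(2) == REP({E})

    def test_C_without_E_never_creolizes(self, rng):
        state = self.make_state(REP({C}), REP({A}))
        out = apply_interaction(state, 1, 2, C, params(gamma=1.0), rng)
        assert state.repertoire(2) == REP({A, C})
        assert not out.creolized

    def test_learned_E_on_A_creolizes_with_certainty(self, rng):
        state = self.make_state(REP({E}), REP({A}))
        out = apply_interaction(state, 1, 2, E, params(gamma=1.0), rng)
        assert out.creolized
        assert state.repertoire(2) == REP({C})

    def test_european_hearer_violates_topology(self, rng):
        state = self.make_state(REP({E}), REP({A}))
        with pytest.raises(TopologyViolationError):
            apply_interaction(state, 1, 0, E, params(), rng)

    def test_speaker_must_hold_the_uttered_language(self, rng):
        state = self.make_state(REP({E}), REP({A}))
        with pytest.raises(InvariantViolationError):
            apply_interaction(state, 0, 2, C, params(), rng)


class TestMeasureFractions:
    def test_all_creole(self):
        state = init_population(3, 2, 2)
        state.masks[:] = mask_of(REP({C}))
        s = measure_fractions(state)
        assert (s.f_E, s.f_A, s.f_C) == (0.0, 0.0, 1.0)

    def test_split_weighting_arithmetic(self):
        state = init_population(0, 2, 0)
        state.masks[0] = mask_of(REP({E}))
        state.masks[1] = mask_of(REP({A, E}))
        s = measure_fractions(state)
        assert s.f_E == pytest.approx(0.75)
        assert s.f_A == pytest.approx(0.25)
        assert s.f_C == 0.0

    def test_trilingual_agent_splits_three_ways(self):
        state = init_population(0, 4, 0)
        state.masks[0] = mask_of(REP({A, E, C}))
        state.masks[1:] = mask_of(REP({C}))
        s = measure_fractions(state)
        assert s.f_C == pytest.approx((1 / 3 + 3) / 4)
        assert s.f_E == pytest.approx(1 / 12)
        assert s.f_A == pytest.approx(1 / 12)

    def test_monolingual_weighting_ignores_bilinguals(self):
        state = init_population(0, 3, 0)
        state.masks[0] = mask_of(REP({E}))
        state.masks[1] = mask_of(REP({E}))
        state.masks[2] = mask_of(REP({A, C}))
        s = measure_fractions(state, weighting="monolingual")
        assert s.f_E == 1.0

    def test_europeans_are_excluded(self):
        state = init_population(100, 1, 0)
        state.masks[0] = mask_of(REP({C}))
        assert measure_fractions(state).f_C == 1.0


class TestRun:
    def test_gamma_zero_never_creates_creole(self):
        p = params(gamma=0.0, delta=0.3, epsilon=0.1,
                   max_interactions_per_agent=200)
        state = init_population(10, 10, 20)
        _, summary, _ = run(state, p, seed=3)
        assert summary.f_C == 0.0
        assert not any(state.masks & 4)

    def test_no_bozals_absorbs_to_all_E(self):
        p = params(gamma=0.9, max_interactions_per_agent=500)
        state = init_population(5, 10, 0)
        _, summary, absorbed = run(state, p, seed=4)
        assert absorbed
        assert summary.f_E == 1.0
        assert summary.f_C == 0.0

    def test_seed_determinism(self, paper_params):
        runs = []
        for _ in range(2):
            state = init_population(20, 10, 40)
            p = ModelParams(gamma=0.8, delta=0.1, epsilon=0.06,
                            max_interactions_per_agent=300)
            _, summary, absorbed = run(state, p, seed=9)
            runs.append((tuple(state.masks), summary, absorbed))
        assert runs[0] == runs[1]

    def test_population_counts_conserved_and_repertoires_valid(self):
        p = params(max_interactions_per_agent=300)
        state = init_population(7, 5, 9)
        run(state, p, seed=2)
        assert (state.n_eu, state.n_m, state.n_b) == (7, 5, 9)
        assert state.masks.shape == (14,)
        assert np.all((state.masks >= 1) & (state.masks <= 7))
        assert state.repertoire(0) == REP({E})  # European immutability

    def test_interaction_counter_advances_on_null_steps(self, rng):
        # lone Bozal behind an epsilon=0 wall: every step is a null step
        state = init_population(3, 0, 1)
        p = params(epsilon=0.0)
        for _ in range(5):
            out = step(state, p, rng)
            assert out.result == "null_step"
        assert state.interactions_elapsed == 5
        assert state.repertoire(3) == REP({A})

    def test_degenerate_non_counting_null_config_rejected(self):
        state = init_population(3, 0, 1)
        p = params(epsilon=0.0, epsilon_null_advances_time=False)
        with pytest.raises(InvalidPopulationError):
            run(state, p, seed=0)


class TestStepInvariants:
    """Property checks over many elementary steps of the definitional layer."""

    def test_invariants_hold_along_a_trajectory(self, rng):
        state = init_population(4, 3, 5)
        p = params(gamma=0.6, delta=0.2, epsilon=0.3)
        seen_c = False
        for _ in range(800):
            out = step(state, p, rng)
            assert np.all((state.masks >= 1) & (state.masks <= 7))
            if out.creolized:
                seen_c = True
            if not seen_c:
                # C-genesis: no C before the first creolization event
                assert not any(state.masks & 4)

    def test_A_extinction_is_absorbing(self, rng):
        # once A and C are extinct the all-E state persists forever
        state = init_population(4, 3, 2)
        state.masks[:] = 1
        p = params(gamma=1.0, delta=0.9, epsilon=0.9)
        for _ in range(300):
            step(state, p, rng)
            assert np.all(state.masks == 1)


@given(
    mask=st.integers(min_value=1, max_value=7),
    gamma=st.floats(min_value=0.0, max_value=1.0),
    seed=st.integers(min_value=0, max_value=2**20),
)
@settings(deadline=None, max_examples=60)
def test_creolization_returns_C_or_unchanged(mask, gamma, seed):
    rep = rep_of(mask)
    out = creolization_check(rep, gamma, np.random.default_rng(seed))
    assert out in (rep, REP({C}))
    if not {A, E} <= rep:
        assert out == rep


@given(
    masks=st.lists(st.integers(min_value=1, max_value=7), min_size=1, max_size=30),
    weighting=st.sampled_from(["split", "monolingual"]),
)
@settings(deadline=None, max_examples=60)
def test_fractions_sum_to_one(masks, weighting):
    state = init_population(0, len(masks), 0)
    state.masks[:] = masks
    s = measure_fractions(state, weighting=weighting)
    assert s.f_E + s.f_A + s.f_C == pytest.approx(1.0)
    assert min(s.f_E, s.f_A, s.f_C) >= 0.0
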