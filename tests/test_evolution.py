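"""Evolutionary loop: initialization, variation operators, bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from eafit.evolution import (
    EvolutionConfig,
    SessionAborted,
    SessionState,
    StateError,
    crossover,
    init_parents,
    mutate,
    run_session,
    tournament_select,
)
from eafit.fmap_core import (
    DeviceProfile,
    ExplorationDomain,
    FrequencyMap,
    make_exploration_domain,
    validate,
)
from eafit.fitness import SimulatedListener


def _map(highs, score=None, id="", gen=0, idx=-1):
    bands, prev = [], 50.0
    for h in highs:
        bands.append((prev, float(h)))
        prev = float(h)
    return FrequencyMap(electrodes=tuple(range(1, len(highs) + 1)),
                        bands=tuple(bands), id=id, score=score,
                        generation=gen, creation_index=idx)


class TestInitParents:
    def test_zero_volume_domain_yields_identical_parents(self, toy_profile, rng):
        dom = ExplorationDomain(
            electrodes=(1, 2, 3),
            intervals=((100.0, 110.0), (110.0, 120.0), (120.0, 130.0)),
        )
        parents = init_parents(dom, toy_profile, EvolutionConfig(), rng)
        assert len(parents) == 4
        assert all(p.bands == parents[0].bands for p in parents)
        assert parents[0].f_high == (110.0, 120.0, 130.0)

    def test_seeded_determinism(self, medel, medel_domain):
        cfg = EvolutionConfig(rng_seed=7)
        a = init_parents(medel_domain, medel, cfg, np.random.default_rng(99))
        b = init_parents(medel_domain, medel, cfg, np.random.default_rng(99))
        assert [p.bands for p in a] == [q.bands for q in b]

    def test_parents_valid_for_all_profiles(self, any_profile, rng):
        dom = make_exploration_domain(any_profile)
        for p in init_parents(dom, any_profile, EvolutionConfig(), rng):
            assert validate(p, any_profile) == []

    def test_first_electrode_upper_edge_uniform_on_feasible_interval(self):
        # wide single-band device so 1 Hz quantization is negligible
        prof = DeviceProfile("wide", 1, ((100.0, 10100.0),), 1.0, 1.0)
        dom = make_exploration_domain(prof)
        lo_feasible = prof.global_f_min + prof.min_band_width_hz
        hi = dom.intervals[0][1]
        cfg = EvolutionConfig(n_parents=10_000, rng_seed=0)
        parents = init_parents(dom, prof, cfg, np.random.default_rng(2024))
        xs = np.array([p.f_high[0] for p in parents])
        assert xs.min() >= lo_feasible and xs.max() <= hi
        d, p_value = stats.kstest(xs, stats.uniform(lo_feasible, hi - lo_feasible).cdf)
        assert p_value > 0.01


class TestTournament:
    cfg = EvolutionConfig(rng_seed=0)

    def test_singleton_pool(self, rng):
        a = _map([200, 300], score=5, id="A")
        assert tournament_select([a], rng, self.cfg) is a

    def test_unscored_individual_rejected(self, rng):
        with pytest.raises(StateError):
            tournament_select([_map([200, 300])], rng, self.cfg)

    def test_better_individual_wins_three_quarters_of_two_draws(self, rng):
        # best of 2 drawn with replacement from {A:9, B:2}:
        # A wins unless B is drawn twice -> exactly 3/4
        a, b = _map([200, 300], 9, "A"), _map([210, 310], 2, "B")
        wins = sum(tournament_select([a, b], rng, self.cfg) is a
                   for _ in range(10_000))
        assert wins / 10_000 == pytest.approx(0.75, abs=0.02)

    def test_equal_scores_select_uniformly(self, rng):
        pool = [_map([200 + i, 300 + i], 5, f"M{i}") for i in range(4)]
        counts = {m.id: 0 for m in pool}
        for _ in range(10_000):
            counts[tournament_select(pool, rng, self.cfg).id] += 1
        for c in counts.values():
            assert c / 10_000 == pytest.approx(0.25, abs=0.02)

    def test_win_probability_below_one_lets_loser_through(self, rng):
        cfg = EvolutionConfig(tournament_win_prob=0.5, rng_seed=0)
        a, b = _map([200, 300], 9, "A"), _map([210, 310], 2, "B")
        wins = sum(tournament_select([a, b], rng, cfg) is a for _ in range(10_000))
        # P(A) = P(both draws differ) * 0.5 + P(AA) = 0.5*0.5 + 0.25
        assert wins / 10_000 == pytest.approx(0.5, abs=0.02)


class TestCrossover:
    def test_identical_parents_reproduce_their_vector(self, rng):
        a = _map([200, 300, 400])
        assert crossover(a, a, rng) == [200.0, 300.0, 400.0]

    def test_extreme_mix_copies_one_parent(self, rng):
        a, b = _map([200, 300, 400]), _map([220, 330, 440])
        assert crossover(a, b, rng, mix=1.0) == list(a.f_high)
        assert crossover(a, b, rng, mix=0.0) == list(b.f_high)

    def test_every_locus_copied_verbatim_from_a_parent(self, rng):
        a, b = _map([200, 300, 400, 500]), _map([260, 280, 460, 480])
        for _ in range(200):
            child = crossover(a, b, rng)
            assert all(c in (x, y) for c, x, y in zip(child, a.f_high, b.f_high))

    def test_mismatched_electrode_sets_rejected(self, rng):
        with pytest.raises(StateError):
            crossover(_map([200, 300]), _map([200, 300, 400]), rng)


class TestMutate:
    def test_zero_probability_is_identity(self, medel, medel_domain, rng):
        vec = list(medel.active_default_map().f_high)
        cfg = EvolutionConfig(mutation_prob=0.0)
        assert mutate(vec, medel_domain, medel, cfg, rng) == vec

    def test_vanishing_sigma_is_identity_within_quantization(
        self, medel, medel_domain, rng
    ):
        vec = list(medel.active_default_map().f_high)
        cfg = EvolutionConfig(mutation_prob=1.0, mutation_sigma_frac=1e-12)
        out = mutate(vec, medel_domain, medel, cfg, rng)
        assert np.allclose(out, vec, atol=medel.freq_step_hz)

    def test_mutated_component_count_matches_binomial_mean(
        self, medel, medel_domain
    ):
        vec = list(medel.active_default_map().f_high)
        cfg = EvolutionConfig(mutation_prob=0.2)
        rng = np.random.default_rng(7)
        changed = [
            sum(o != v for o, v in zip(mutate(vec, medel_domain, medel, cfg, rng), vec))
            for _ in range(10_000)
        ]
        # Binomial(12, 0.2): mean 2.4 (clamping never maps an interior
        # Gaussian perturbation back onto the exact original value)
        assert np.mean(changed) == pytest.approx(12 * 0.2, abs=0.1)

    def test_output_clamped_to_exploration_domain(self, medel, medel_domain):
        vec = list(medel_domain.hi)  # start at the ceiling, mutate hard
        cfg = EvolutionConfig(mutation_prob=1.0, mutation_sigma_frac=5.0)
        rng = np.random.default_rng(0)
        out = mutate(vec, medel_domain, medel, cfg, rng)
        for v, (lo, hi) in zip(out, medel_domain.intervals):
            assert lo <= v <= hi


class TestSessionBookkeeping:
    def test_full_session_evaluates_thirteen_maps(self, medel):
        listener = SimulatedListener.random(medel, seed=1, noise_mode="noise_free")
        best, state = run_session(medel, EvolutionConfig(rng_seed=1),
                                  listener.fitness())
        assert state.evaluated_count == 13
        assert [i.id for i in state.individuals] == (
            [f"P{i}" for i in range(1, 5)] + [f"C{i}" for i in range(1, 10)]
        )
        assert state.complete

    def test_population_grows_by_three_per_generation(self, medel):
        listener = SimulatedListener.random(medel, seed=2, noise_mode="noise_free")
        state = SessionState.start(medel, EvolutionConfig(rng_seed=2))
        fit = listener.fitness()
        for p in list(state.individuals):
            state.record_score(p.id, fit(p))
        for g in (1, 2, 3):
            for _ in range(3):
                c = state.next_child()
                state.record_score(c.id, fit(c))
            assert len(state.individuals) == 4 + 3 * g

    def test_breeding_pools_drawn_from_growing_history(self, medel):
        listener = SimulatedListener.random(medel, seed=3)
        _, state = run_session(medel, EvolutionConfig(rng_seed=3),
                               listener.fitness())
        sizes = [ev["source_size"] for ev in state.events
                 if ev["kind"] == "survivors"]
        assert sizes == [4, 7, 10]  # pools feeding generations 1, 2, 3
        assert all(len(ev["pool"]) == 4 for ev in state.events
                   if ev["kind"] == "survivors")

    def test_survivor_pool_always_contains_running_best(self, medel):
        listener = SimulatedListener.random(medel, seed=4)
        state = SessionState.start(medel, EvolutionConfig(rng_seed=4))
        fit = listener.fitness()
        for p in list(state.individuals):
            state.record_score(p.id, fit(p))
        while not state.complete:
            c = state.next_child()
            state.record_score(c.id, fit(c))
            if state.survivor_ids:
                best = max(state.scored(), key=lambda i: i.score)
                pool_scores = [state.get(i).score for i in state.survivor_ids]
                assert max(pool_scores) == best.score

    def test_constant_fitness_keeps_first_four_as_survivors(self, medel):
        _, state = run_session(medel, EvolutionConfig(rng_seed=5), lambda m: 5)
        for ev in state.events:
            if ev["kind"] == "survivors":
                assert ev["pool"] == ["P1", "P2", "P3", "P4"]

    def test_abort_after_first_child_of_second_generation(self, medel):
        calls = 0

        def fitness(fmap):
            nonlocal calls
            calls += 1
            if calls > 8:  # P1-P4, C1-C3, C4 scored; abort on C5
                raise SessionAborted("listener stopped")
            return 6 if fmap.origin == "parent" else 7

        best, state = run_session(medel, EvolutionConfig(rng_seed=6), fitness)
        assert state.evaluated_count == 8
        assert not state.complete
        assert best.score == 7  # best among the scored maps

    def test_abort_after_second_parent_generation_map(self, medel):
        calls = 0

        def fitness(fmap):
            nonlocal calls
            calls += 1
            if calls > 6:  # P1-P4 plus C1, C2
                raise SessionAborted("listener stopped")
            return calls  # strictly increasing scores

        best, state = run_session(medel, EvolutionConfig(rng_seed=6), fitness)
        assert state.evaluated_count == 6
        assert best.id == "C2"

    def test_identical_inputs_give_identical_transcripts(self, medel):
        def session():
            listener = SimulatedListener.random(medel, seed=11)
            return run_session(medel, EvolutionConfig(rng_seed=11),
                               listener.fitness())

        best1, s1 = session()
        best2, s2 = session()
        assert s1.transcript() == s2.transcript()
        assert best1.bands == best2.bands
        assert [i.bands for i in s1.individuals] == [i.bands for i in s2.individuals]

    def test_elitism_final_best_at_least_best_parent(self, medel):
        for seed in range(30):
            listener = SimulatedListener.random(medel, seed=seed,
                                                noise_mode="noise_free")
            best, state = run_session(medel, EvolutionConfig(rng_seed=seed),
                                      listener.fitness())
            best_parent = max(i.score for i in state.individuals
                              if i.origin == "parent")
            assert best.score >= best_parent

    def test_every_generated_map_is_valid(self, any_profile):
        listener = SimulatedListener.random(any_profile, seed=8)
        _, state = run_session(any_profile, EvolutionConfig(rng_seed=8),
                               listener.fitness())
        for ind in state.individuals:
            assert validate(ind, any_profile) == []


class TestFinalSelection:
    def test_tied_best_candidates_all_reported(self, medel):
        scores = {"P1": 5, "P2": 9, "P3": 9, "P4": 2}
        _, state = run_session(
            medel, EvolutionConfig(rng_seed=9),
            lambda m: scores.get(m.id, 1),
        )
        assert {c.id for c in state.best_candidates()} == {"P2", "P3"}

    def test_batch_tie_break_prefers_most_recent(self, medel):
        _, state = run_session(medel, EvolutionConfig(rng_seed=9), lambda m: 5)
        assert state.select_best("latest").id == "C9"
        assert state.select_best("earliest").id == "P1"

    def test_next_child_refuses_pending_scores(self, medel):
        state = SessionState.start(medel, EvolutionConfig(rng_seed=10))
        with pytest.raises(StateError, match="pending"):
            state.next_child()


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_parents": 0},
        {"mutation_prob": 1.5},
        {"mutation_sigma_frac": 0.0},
        {"sigma_reference": "bogus"},
    ])
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EvolutionConfig(**kwargs)
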