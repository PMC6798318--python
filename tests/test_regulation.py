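import numpy as np
import pytest

from fitscape.gpmap import (
    STEP,
    Environment,
    TraitModel,
    fitness,
    preactivation,
    random_environment,
    random_genotype,
    random_model_fixed_degree,
    trait_expression,
)
from fitscape.regulation import (
    LearningState,
    RegulationConfig,
    adapted_count,
    modular_schedule,
    preset_experiment,
    robust_adapted_count,
    run_learning_experiment,
    sswm_step,
    threshold_feedback,
)


def _make_state(model, s, h=None):
    state = LearningState(
        genotype=np.asarray(s, dtype=np.int8).copy(),
        thresholds=model.thresholds.copy() if h is None else np.asarray(h, float),
        regulated=np.zeros(model.n_traits, dtype=bool),
    )
    return state


class TestModularSchedule:
    def test_even_partition_of_four(self):
        blocks = modular_schedule(200, 50)
        assert len(blocks) == 50
        assert all(b.size == 4 for b in blocks)
        assert np.array_equal(np.concatenate(blocks), np.arange(200))

    def test_single_round_is_everything(self):
        (block,) = modular_schedule(7, 1)
        assert np.array_equal(block, np.arange(7))

    def test_uneven_partition_190(self):
        blocks = modular_schedule(200, 190)
        sizes = [b.size for b in blocks]
        assert max(sizes) <= 2
        assert sizes.count(1) >= 180
        assert sum(sizes) == 200

    def test_too_many_rounds_rejected(self):
        with pytest.raises(ValueError):
            modular_schedule(5, 6)


class TestAdaptedCount:
    def test_all_expressed_all_positive(self):
        env = Environment(np.ones(6))
        assert adapted_count(np.ones(6), env) == 6

    def test_exactly_half_counts_nothing(self):
        env = Environment(np.ones(4))
        assert adapted_count(np.full(4, 0.5), env, theta=0.5) == 0

    def test_mixed_hand_example(self):
        env = Environment([1.0, -1.0, 1.0])
        assert adapted_count([0.9, 0.2, 0.4], env, theta=0.5) == 2

    def test_bad_theta_rejected(self):
        with pytest.raises(ValueError):
            adapted_count([0.5], Environment([1.0]), theta=1.0)


class TestSSWM:
    def test_single_beneficial_flip_accepted(self):
        # one trait, b = 1, step sigmoid, w = (1), h = 0.5: s 0 -> 1 raises F
        model = TraitModel([[1.0]], [0.5], STEP)
        env = Environment([1.0])
        state = _make_state(model, [0])
        from fitscape.gpmap import fitness_potential
        state.potential = fitness_potential([0], model, env)
        rng = np.random.default_rng(0)
        for _ in range(50):
            sswm_step(state, model, env, rng, single_flip=True)
        assert state.genotype[0] == 1
        assert state.potential == pytest.approx(1.0)

    def test_no_acceptance_at_local_maximum(self, rng):
        model = TraitModel(np.array([[3.0, 3.0]]), [0.5], STEP)
        env = Environment([1.0])
        state = _make_state(model, [1, 1])
        from fitscape.gpmap import fitness_potential
        state.potential = fitness_potential([1, 1], model, env)
        for _ in range(100):
            sswm_step(state, model, env, rng, single_flip=True)
        assert np.array_equal(state.genotype, [1, 1])

    def test_matches_brute_force_oracle_on_small_models(self):
        # replay every acceptance decision against direct fitness comparison
        for seed in range(5):
            rng = np.random.default_rng(seed)
            model = random_model_fixed_degree(8, 15, 3, "normal", rng, sharpness=1.0)
            env = random_environment(15, 0.8, 1.0, rng)
            s = random_genotype(8, rng)
            state = _make_state(model, s)
            from fitscape.gpmap import fitness_potential
            state.potential = fitness_potential(s, model, env)
            walk_rng = np.random.default_rng(seed + 100)
            oracle_rng = np.random.default_rng(seed + 100)
            current = s.copy()
            for _ in range(300):
                sswm_step(state, model, env, walk_rng, p_flip=0.05)
                mask = oracle_rng.random(8) < 0.05
                if mask.any():
                    cand = current.copy()
                    cand[mask] = 1 - cand[mask]
                    if fitness(cand, model, env) > fitness(current, model, env):
                        current = cand
                assert np.array_equal(state.genotype, current)


class TestThresholdFeedback:
    def test_positive_drive_locks_low_threshold(self):
        model = TraitModel([[5.0]], [0.0], STEP)
        state = _make_state(model, [1])  # S = +5
        threshold_feedback(state, model, d_h=20.0)
        assert state.thresholds[0] == -20.0
        assert state.regulated[0]

    def test_negative_drive_locks_high_threshold(self):
        model = TraitModel([[-5.0]], [0.0], STEP)
        state = _make_state(model, [1])  # S = -5
        threshold_feedback(state, model, d_h=20.0)
        assert state.thresholds[0] == 20.0

    def test_max_abs_drive_wins_with_low_index_ties(self):
        w = np.array([[1.0, 0.0], [0.0, -4.0], [2.0, 0.0]])
        model = TraitModel(w, np.zeros(3), STEP)
        state = _make_state(model, [1, 1])  # S = (1, -4, 2)
        threshold_feedback(state, model, d_h=10.0)
        assert state.regulated.tolist() == [False, True, False]

    def test_no_eligible_trait_is_noop(self):
        model = TraitModel([[5.0]], [0.0], STEP)
        state = _make_state(model, [1])
        state.regulated[0] = True
        h_before = state.thresholds.copy()
        threshold_feedback(state, model, d_h=20.0)
        assert np.array_equal(state.thresholds, h_before)

    def test_ds_gate_skips_weak_drive(self):
        model = TraitModel([[0.5]], [0.0], STEP)
        state = _make_state(model, [1])
        threshold_feedback(state, model, d_h=20.0, d_s=1.0)
        assert not state.regulated[0]

    def test_regulated_trait_is_canalized(self, rng):
        # with D_h above the largest |sum w s|, no genotype changes expression
        model = random_model_fixed_degree(8, 5, 4, "normal", rng, sharpness=STEP)
        s = random_genotype(8, rng)
        state = _make_state(model, s)
        d_h = np.abs(model.weights).sum(axis=1).max() + 1.0
        threshold_feedback(state, model, d_h=d_h)
        j = int(np.flatnonzero(state.regulated)[0])
        work = TraitModel(model.weights, state.thresholds, model.sharpness)
        f_ref = trait_expression(s, work)[j]
        for bits in range(2**8):
            g = np.array([(bits >> i) & 1 for i in range(8)], dtype=np.int8)
            assert trait_expression(g, work)[j] == f_ref


class TestRobustAdaptedCount:
    def test_canalized_correct_trait_counts(self):
        model = TraitModel([[2.0, -1.0]], [-20.0], 1.0)  # locked on
        env = Environment([1.0])
        assert robust_adapted_count([0, 0], model, env, theta=0.95) == 1

    def test_sensitive_trait_does_not_count(self):
        # correct at s but a single flip breaks it
        model = TraitModel([[4.0]], [0.0], STEP)
        env = Environment([1.0])
        assert adapted_count(trait_expression([1], model), env) == 1
        assert robust_adapted_count([1], model, env) == 0


class TestLearningExperiment:
    def test_trace_monotone_fitness(self, rng):
        cfg = RegulationConfig(n_steps=800, rounds=4, record_every=100)
        model = random_model_fixed_degree(10, 20, 5, "normal", rng, sharpness=1.0)
        env = random_environment(20, 0.8, 1.0, rng)
        trace = run_learning_experiment(model, env, cfg, rng)
        # SSWM never accepts a fitness loss; locks may change the potential,
        # but within-round fitness is non-decreasing between lock events
        pot = trace.records["potential"].to_numpy()
        locks = trace.records["n_regulated"].to_numpy()
        same_lock = np.diff(locks) == 0
        assert (np.diff(pot)[same_lock] >= -1e-9).all()

    def test_all_traits_locked_by_end(self, rng):
        cfg = RegulationConfig(n_steps=600, rounds=6, record_every=600)
        model = random_model_fixed_degree(8, 12, 3, "normal", rng, sharpness=1.0)
        env = random_environment(12, 0.8, 1.0, rng)
        trace = run_learning_experiment(model, env, cfg, rng)
        assert trace.state.regulated.all()
        assert set(np.abs(trace.state.thresholds)) == {cfg.d_h}

    def test_lock_sign_learns_b_when_rounds_succeed(self):
        # disjoint regulation sets, one activator and one repressor per trait,
        # one trait per round: each round is an independently solvable
        # problem, so locks must encode sign(b_j)
        rng = np.random.default_rng(5)
        w = np.zeros((4, 8))
        for j in range(4):
            w[j, 2 * j] = 0.5 + abs(rng.standard_normal())
            w[j, 2 * j + 1] = -(0.5 + abs(rng.standard_normal()))
        model = TraitModel(w, np.zeros(4), 1.0)
        env = Environment(np.array([1.0, 1.0, -1.0, 1.0]))
        cfg = RegulationConfig(n_steps=4000, rounds=4, p_flip=0.05, record_every=4000)
        trace = run_learning_experiment(model, env, cfg, rng)
        locks = trace.state.thresholds
        # b_j > 0 should end locked on (h = -D_h), b_j < 0 locked off (+D_h)
        assert (np.sign(locks) == -np.sign(env.b)).all()
        assert trace.final_adapted == 4

    def test_regulation_beats_baseline_in_median(self):
        on, off = [], []
        for seed in range(6):
            on.append(
                preset_experiment(
                    "pleiotropy", 40, True, np.random.default_rng(seed),
                    n_steps=2000,
                ).final_adapted
            )
            off.append(
                preset_experiment(
                    "pleiotropy", 1, False, np.random.default_rng(seed),
                    n_steps=2000,
                ).final_adapted
            )
        assert np.median(on) > np.median(off)

    def test_baseline_never_locks(self, rng):
        cfg = RegulationConfig(n_steps=300, rounds=5, regulate=False,
                               record_every=300)
        model = random_model_fixed_degree(6, 10, 3, "normal", rng, sharpness=1.0)
        env = random_environment(10, 0.8, 1.0, rng)
        trace = run_learning_experiment(model, env, cfg, rng)
        assert not trace.state.regulated.any()
        assert (trace.state.thresholds == cfg.h_neutral).all()

    def test_park_future_variant_parks_and_releases(self, rng):
        cfg = RegulationConfig(n_steps=400, rounds=4, park_future=True,
                               record_every=400)
        model = random_model_fixed_degree(8, 8, 3, "normal", rng, sharpness=1.0)
        env = random_environment(8, 0.8, 1.0, rng)
        trace = run_learning_experiment(model, env, cfg, rng)
        assert trace.state.regulated.all()

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset_experiment("nope", 1, True, np.random.default_rng(0))
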