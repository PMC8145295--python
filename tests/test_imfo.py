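"""Moth-flame wrapper selection: gates, spiral update, fitness, oracle parity."""

import math

import numpy as np
import pytest

from lesionkit import fixtures, imfo
from lesionkit.imfo import (FitnessConfig, FitnessEvaluator, binarize_positions,
                            entropy_gate, flame_count, initialize_population,
                            row_entropy, select_features, sigmoid, update_moths)


@pytest.fixture(scope="module")
def small_dataset():
    spec = fixtures.FeatureDatasetSpec(n_samples_per_class=(60, 60), n_features=12,
                                       n_informative=4, class_separation=2.0, seed=5)
    return fixtures.generate_feature_dataset(spec)


class TestInitialization:
    def test_shapes_and_bounds(self):
        state = initialize_population(20, 100, seed=0)
        assert state.positions.shape == (20, 100)
        assert state.positions.min() >= 0.0 and state.positions.max() <= 1.0

    def test_deterministic(self):
        s1 = initialize_population(5, 10, seed=3)
        s2 = initialize_population(5, 10, seed=3)
        assert np.array_equal(s1.positions, s2.positions)

    def test_uniformity_sanity(self):
        state = initialize_population(20, 150, seed=1)
        assert 0.45 < state.positions.mean() < 0.55

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            initialize_population(1, 10, seed=0)
        with pytest.raises(ValueError):
            initialize_population(5, 0, seed=0)


class TestGates:
    def test_sigmoid_zero_is_half(self):
        assert binarize_positions(np.array([0.0]), V=0.4)[0] == 1
        assert binarize_positions(np.array([0.0]), V=0.6)[0] == 0

    def test_equal_positions_all_gates_closed(self):
        gates = binarize_positions(np.full((3, 8), 1.3))
        assert gates.sum() == 0  # strict > against the row mean

    def test_mean_gate_operating_range_on_centered_positions(self):
        # positions centred slightly below zero keep the adaptive threshold
        # V in the 0.4-0.48 operating band
        rng = np.random.default_rng(0)
        positions = rng.normal(-0.25, 0.8, size=(50, 200))
        V = sigmoid(positions).mean(axis=1)
        assert np.all(V > 0.35) and np.all(V < 0.5)
        assert 0.4 <= np.median(V) <= 0.48

    def test_entropy_of_hand_built_histogram(self):
        # 10 values: 5 in bin 0, 5 in bin 9 -> H = ln2/ln10
        s_targets = np.array([0.05] * 5 + [0.95] * 5)
        positions = np.log(s_targets / (1 - s_targets))  # inverse sigmoid
        H = row_entropy(positions[None, :])[0]
        assert H == pytest.approx(math.log(2) / math.log(10), abs=1e-12)

    def test_zero_entropy_opens_all_positive_sigmoid_gates(self):
        positions = np.full((1, 6), 2.0)  # one bin -> H = 0
        assert entropy_gate(positions).sum() == 6

    def test_max_entropy_closes_all_gates(self):
        s_targets = np.linspace(0.05, 0.95, 10)  # one value per bin -> H = 1
        positions = np.log(s_targets / (1 - s_targets))
        assert entropy_gate(positions[None, :]).sum() == 0


class TestSpiralUpdate:
    def test_hand_evaluated_single_step(self):
        # d=0.5, l=0.5, b=1, flame=0.8: d*e^l*cos(2*pi*l) + flame
        d, l, flame = 0.5, 0.5, 0.8
        expected = d * math.exp(l) * math.cos(2 * math.pi * l) + flame
        assert expected == pytest.approx(0.8 - 0.5 * math.exp(0.5))

        class FixedRng:
            def uniform(self, lo, hi, size=None):
                return np.full(size, 0.5)

        state = initialize_population(2, 1, seed=0)
        state.positions = np.array([[0.3], [0.3]])
        state.flames = np.array([[0.8], [0.8]])
        state.flame_fitness = np.array([0.1, 0.2])
        state.flame_gates = np.ones((2, 1), dtype=np.uint8)
        update_moths(state, max_iter=10**9, rng=FixedRng())  # w ~ 0.9: wF+(1-w)F = F
        assert state.positions[0, 0] == pytest.approx(expected, abs=1e-6)

    def test_zero_distance_collapses_onto_flame(self):
        class FixedRng:
            def uniform(self, lo, hi, size=None):
                return np.full(size, -1.0)

        state = initialize_population(2, 3, seed=1)
        state.flames = state.positions.copy()
        state.flame_fitness = np.zeros(2)
        state.flame_gates = np.ones((2, 3), dtype=np.uint8)
        flames = state.flames.copy()
        update_moths(state, max_iter=100, rng=FixedRng())
        assert np.allclose(state.positions, flames)

    def test_flame_schedule_reaches_one(self):
        assert flame_count(20, 0, 50) == 20
        assert flame_count(20, 50, 50) == 1
        counts = [flame_count(20, it, 50) for it in range(51)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_positions_stay_clipped(self):
        state = initialize_population(10, 20, seed=2)
        state.flame_fitness = np.zeros(10)
        state.flame_gates = np.ones((10, 20), dtype=np.uint8)
        rng = np.random.default_rng(0)
        for _ in range(30):
            update_moths(state, max_iter=30, rng=rng)
        assert np.all(np.abs(state.positions) <= imfo.POSITION_CLIP)


class TestFitness:
    def test_r_one_equals_holdout_error(self, small_dataset):
        fm, labels, _ = small_dataset
        cfg = FitnessConfig(r_weight=1.0, seed=0)
        ev = FitnessEvaluator(fm, labels, cfg)
        gate = np.ones(12, dtype=np.uint8)
        assert ev(gate) == pytest.approx(ev.holdout_error(gate))

    def test_r_zero_is_pure_sparsity(self, small_dataset):
        fm, labels, _ = small_dataset
        cfg = FitnessConfig(r_weight=0.0, seed=0)
        ev = FitnessEvaluator(fm, labels, cfg)
        gate = np.zeros(12, dtype=np.uint8)
        gate[:3] = 1
        assert ev(gate) == pytest.approx(3 / 12)

    def test_direct_substitution(self):
        # r=0.5, Error=0.2, 10/100 selected -> 0.5*0.2 + 0.5*0.1 = 0.15
        assert 0.5 * 0.2 + 0.5 * (10 / 100) == pytest.approx(0.15)

    def test_all_zero_gate_is_worst(self, small_dataset):
        fm, labels, _ = small_dataset
        ev = FitnessEvaluator(fm, labels, FitnessConfig(seed=0))
        assert ev(np.zeros(12, dtype=np.uint8)) == 1.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        with pytest.raises(ValueError):
            FitnessEvaluator(X, np.zeros(20, dtype=int), FitnessConfig())


class TestSelection:
    def test_history_non_increasing_and_subset_valid(self, small_dataset):
        fm, labels, _ = small_dataset
        cfg = FitnessConfig(r_weight=0.9, seed=1)
        res = select_features(fm, labels, cfg, n_iter=10, seed=4)
        hist = res.fitness_history
        assert all(a >= b for a, b in zip(hist, hist[1:]))
        assert len(res.selected_indices) == len(set(res.selected_indices.tolist()))
        assert res.selected_indices.size > 0
        assert res.reduced_matrix.feature_dim == res.selected_indices.size

    def test_never_beats_exhaustive_optimum(self, small_dataset):
        fm, labels, _ = small_dataset
        cfg = FitnessConfig(r_weight=0.9, seed=5)
        ev = FitnessEvaluator(fm, labels, cfg)
        # restrict to 8 columns to keep enumeration cheap
        sub = fm.select_columns(range(8))
        ev8 = FitnessEvaluator(sub, labels, cfg)
        _, best = imfo.exhaustive_oracle(sub, labels, cfg, evaluator=ev8)
        for s in range(3):
            res = select_features(sub, labels, cfg, n_iter=15, seed=s, evaluator=ev8)
            assert res.final_fitness >= best - 1e-12

    def test_mfo_variant_runs_without_adaptive_gates(self, small_dataset):
        fm, labels, _ = small_dataset
        cfg = FitnessConfig(r_weight=0.9, seed=1)
        res = select_features(fm, labels, cfg, n_iter=5, seed=2, variant="mfo")
        assert res.variant == "mfo"
        assert res.selected_indices.size > 0


class TestOracle:
    def test_dim_guard(self):
        X = np.zeros((10, 16))
        with pytest.raises(ValueError):
            imfo.exhaustive_oracle(X, np.arange(10) % 2, FitnessConfig())

    def test_perfectly_separating_feature_wins_at_high_r(self):
        rng = np.random.default_rng(7)
        n = 60
        y = np.arange(n) % 2
        X = rng.normal(size=(n, 3))
        X[:, 1] = y * 10.0 + rng.normal(0, 0.1, n)  # perfect separator
        cfg = FitnessConfig(r_weight=0.9, seed=0)
        gate, fit = imfo.exhaustive_oracle(X, y, cfg)
        assert np.array_equal(gate, [0, 1, 0])
        assert fit == pytest.approx(0.1 * (1 / 3))

    def test_optimum_bounded_by_all_ones_gate(self, small_dataset):
        fm, labels, _ = small_dataset
        cfg = FitnessConfig(r_weight=0.9, seed=3)
        sub = fm.select_columns(range(6))
        ev = FitnessEvaluator(sub, labels, cfg)
        _, best = imfo.exhaustive_oracle(sub, labels, cfg, evaluator=ev)
        assert best <= ev(np.ones(6, dtype=np.uint8)) + 1e-12
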