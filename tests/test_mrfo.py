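"""MRFO: step-equation oracles, elitism/feasibility, optimization sanity."""

import numpy as np
import pytest

from dermoclass.cascade import ParamLayout
from dermoclass.mrfo import (
    MrfoConfig,
    MrfoState,
    chain_step,
    cyclone_step,
    error_rate_fitness,
    optimize,
    somersault_step,
)


def make_state(positions, best, lo=-10.0, hi=10.0):
    positions = np.asarray(positions, dtype=float)
    d = positions.shape[1]
    return MrfoState(
        positions=positions.copy(),
        fitnesses=np.zeros(positions.shape[0]),
        best_position=np.asarray(best, dtype=float),
        best_fitness=0.0,
        lower=np.full(d, lo),
        upper=np.full(d, hi),
    )


# Independent single-equation oracles -------------------------------------


def chain_oracle(x_i, x_prev, x_best, r, r1):
    alpha = 2.0 * r * np.sqrt(abs(np.log(r1)))
    return x_i + r * (x_prev - x_i) + alpha * (x_best - x_i)


def cyclone_oracle(x_i, x_prev, ref, r, r1, t, T):
    beta = 2.0 * np.exp(r1 * (T - t + 1) / T) * np.sin(2.0 * np.pi * r1)
    return ref + r * (x_prev - x_i) + beta * (ref - x_i)


def somersault_oracle(x_i, x_best, s, r2, r3):
    return x_i + s * (r2 * x_best - r3 * x_i)


class TestChainStep:
    def test_stationary_when_all_equal(self):
        state = make_state([[1.0, 2.0], [1.0, 2.0]], best=[1.0, 2.0])
        for i in (1, 2):
            np.testing.assert_allclose(
                chain_step(state, i, r=0.7, r1=0.3), [1.0, 2.0]
            )

    def test_hand_computed_first_agent(self):
        # alpha = 0.5 requires 2*0.5*sqrt(|ln r1|) = 0.5 -> r1 = exp(-0.25)
        state = make_state([[0.0]], best=[1.0])
        r1 = float(np.exp(-0.25))
        new = chain_step(state, 1, r=0.5, r1=r1)
        assert new[0] == pytest.approx(1.0)

    def test_matches_formula_oracle(self, rng):
        pos = rng.normal(size=(5, 3))
        best = rng.normal(size=3)
        state = make_state(pos, best)
        r, r1 = 0.42, 0.73
        for i in range(1, 6):
            prev = best if i == 1 else pos[i - 2]
            expected = np.clip(chain_oracle(pos[i - 1], prev, best, r, r1), -10, 10)
            np.testing.assert_allclose(chain_step(state, i, r, r1), expected, atol=1e-12)

    def test_index_out_of_range(self):
        state = make_state([[0.0]], best=[0.0])
        with pytest.raises(IndexError):
            chain_step(state, 2, 0.5, 0.5)


class TestCycloneStep:
    def test_stationary_at_reference(self):
        state = make_state([[2.0, -1.0], [2.0, -1.0]], best=[2.0, -1.0])
        for i in (1, 2):
            np.testing.assert_allclose(
                cyclone_step(state, i, r=0.3, r1=0.8, t=1, T=10), [2.0, -1.0]
            )

    def test_beta_vanishes_at_half(self):
        # r1 = 0.5 makes sin(pi) = 0: pure move toward the reference
        state = make_state([[0.0], [4.0]], best=[2.0])
        new = cyclone_step(state, 1, r=0.25, r1=0.5, t=1, T=10)
        assert new[0] == pytest.approx(2.0 + 0.25 * (2.0 - 0.0))

    def test_matches_formula_oracle(self, rng):
        pos = rng.normal(size=(4, 2))
        best = rng.normal(size=2)
        state = make_state(pos, best)
        r, r1, t, T = 0.9, 0.37, 3, 7
        for i in range(1, 5):
            prev = best if i == 1 else pos[i - 2]
            expected = np.clip(
                cyclone_oracle(pos[i - 1], prev, best, r, r1, t, T), -10, 10
            )
            np.testing.assert_allclose(
                cyclone_step(state, i, r, r1, t, T), expected, atol=1e-12
            )

    def test_random_reference_uses_box(self):
        state = make_state([[0.0]], best=[5.0], lo=-1.0, hi=1.0)
        r = 0.75
        new = cyclone_step(state, 1, r=r, r1=0.5, t=1, T=10, use_random_reference=True)
        ref = -1.0 + r * 2.0  # L + r (U - L)
        assert new[0] == pytest.approx(ref + r * (ref - 0.0))

    def test_t_beyond_horizon_rejected(self):
        state = make_state([[0.0]], best=[0.0])
        with pytest.raises(ValueError):
            cyclone_step(state, 1, 0.5, 0.5, t=11, T=10)


class TestSomersaultStep:
    def test_stationary_when_at_best_with_equal_draws(self):
        state = make_state([[3.0, 3.0]], best=[3.0, 3.0])
        np.testing.assert_allclose(
            somersault_step(state, 1, r2=0.6, r3=0.6), [3.0, 3.0]
        )

    def test_hand_computed_with_clipping(self):
        state = make_state([[1.0]], best=[1.0], lo=-10, hi=10)
        new = somersault_step(state, 1, r2=1.0, r3=0.0)
        assert new[0] == pytest.approx(3.0)  # 1 + 2*(1 - 0), inside the box
        tight = make_state([[1.0]], best=[1.0], lo=-2.0, hi=2.0)
        assert somersault_step(tight, 1, r2=1.0, r3=0.0)[0] == pytest.approx(2.0)

    def test_matches_formula_oracle(self, rng):
        pos = rng.normal(size=(3, 4))
        best = rng.normal(size=4)
        state = make_state(pos, best)
        for i in range(1, 4):
            expected = np.clip(somersault_oracle(pos[i - 1], best, 2.0, 0.3, 0.9), -10, 10)
            np.testing.assert_allclose(
                somersault_step(state, i, 0.3, 0.9), expected, atol=1e-12
            )


class TestOptimize:
    def test_constant_fitness_flat_trace(self):
        config = MrfoConfig(population=5, max_iter=10, bounds=(-1, 1), dim=2, seed=0)
        _, best, trace = optimize(lambda v: 3.25, config)
        assert best == 3.25
        assert trace == [3.25] * 10

    def test_elitism_and_feasibility(self):
        seen = []

        def sphere(v):
            seen.append(v.copy())
            return float(np.sum(v**2))

        config = MrfoConfig(population=8, max_iter=30, bounds=(-4, 4), dim=3, seed=5)
        _, _, trace = optimize(sphere, config)
        assert np.all(np.diff(trace) <= 0)  # best never worsens
        pts = np.array(seen)
        assert pts.min() >= -4 and pts.max() <= 4  # every evaluation in box

    def test_deterministic_given_seed(self):
        config = MrfoConfig(population=6, max_iter=15, bounds=(-2, 2), dim=2, seed=42)
        r1 = optimize(lambda v: float(np.sum(v**2)), config)
        r2 = optimize(lambda v: float(np.sum(v**2)), config)
        np.testing.assert_array_equal(r1[0], r2[0])
        assert r1[1] == r2[1] and r1[2] == r2[2]

    def test_more_iterations_do_not_hurt(self):
        # median sphere fitness improves monotonically with the budget
        def median_fit(T):
            vals = []
            for seed in range(5):
                cfg = MrfoConfig(population=10, max_iter=T, bounds=(-10, 10), dim=2, seed=seed)
                vals.append(optimize(lambda v: float(np.sum(v**2)), cfg)[1])
            return float(np.median(vals))

        fits = [median_fit(T) for T in (10, 50, 200)]
        assert fits[0] >= fits[1] >= fits[2]

    def test_corner_objective_reaches_corner(self):
        corner = np.array([5.0, 5.0])
        vals = []
        for seed in range(5):
            cfg = MrfoConfig(population=15, max_iter=100, bounds=(-5, 5), dim=2, seed=seed)
            best, _, _ = optimize(lambda v: float(np.linalg.norm(v - corner)), cfg)
            vals.append(np.linalg.norm(best - corner))
        assert float(np.median(vals)) < 0.1

    def test_non_finite_fitness_raises(self):
        config = MrfoConfig(population=4, max_iter=5, bounds=(-1, 1), dim=1, seed=0)
        with pytest.raises(ValueError):
            optimize(lambda v: float("nan"), config)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            MrfoConfig(population=1)
        with pytest.raises(ValueError):
            MrfoConfig(bounds=(2.0, -2.0))
        with pytest.raises(ValueError):
            MrfoConfig(somersault_factor=0.0)


class TestErrorRateFitness:
    def _setup(self, rng):
        layout = ParamLayout(3, 2)
        x = rng.normal(size=(10, 3))
        return layout, x

    def test_trivial_rates(self, rng):
        layout, x = self._setup(rng)
        vec = np.zeros(layout.size)  # all-zero net scores ~0.62: all melanoma
        all_mel = np.array(["melanoma"] * 10)
        assert error_rate_fitness(vec, x, all_mel, layout) == 0.0
        all_ben = np.array(["benign"] * 10)
        assert error_rate_fitness(vec, x, all_ben, layout) == 100.0
        half = np.array(["melanoma"] * 5 + ["benign"] * 5)
        assert error_rate_fitness(vec, x, half, layout) == 50.0

    def test_six_of_150_gives_four_percent(self, rng):
        layout = ParamLayout(3, 2)
        x = rng.normal(size=(150, 3))
        vec = np.zeros(layout.size)  # predicts melanoma everywhere
        labels = np.array(["melanoma"] * 144 + ["benign"] * 6)
        assert error_rate_fitness(vec, x, labels, layout) == pytest.approx(4.0)

    def test_empty_set_rejected(self, rng):
        layout = ParamLayout(3, 2)
        with pytest.raises(ValueError):
            error_rate_fitness(np.zeros(layout.size), np.zeros((0, 3)), [], layout)
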