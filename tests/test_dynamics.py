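"""Toy potentials and the overdamped Langevin integrator."""

import numpy as np
import pytest
from scipy.integrate import quad

from desp.dynamics import (
    LangevinConfig,
    LangevinEngine,
    SimState,
    langevin_step,
    make_cosine_wells,
    make_double_well,
    product_potential,
    run_unbiased,
)
from desp.errors import AdapterError, ConfigurationError


class TestDoubleWell:
    def test_minima_and_barrier(self):
        pot = make_double_well(0.3, 2.5)
        assert pot.energy(np.array([0.3])) == pytest.approx(0.0, abs=1e-14)
        assert pot.energy(np.array([0.3 + np.pi])) == pytest.approx(0.0, abs=1e-12)
        assert pot.energy(np.array([0.3 + np.pi / 2])) == pytest.approx(2.5)

    def test_gradient_zero_at_minima(self):
        pot = make_double_well(-0.7, 1.0)
        assert pot.gradient(np.array([-0.7]))[0] == pytest.approx(0.0, abs=1e-14)
        assert pot.gradient(np.array([-0.7 + np.pi]))[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("factory", [
        lambda: make_double_well(0.4, 3.0),
        lambda: make_cosine_wells([0.1, -1.0], [2.0, 1.0], [2, 3]),
        lambda: product_potential([make_double_well(0.0, 2.0), make_double_well(1.0, 4.0)]),
    ])
    def test_gradient_matches_finite_differences(self, factory):
        pot = factory()
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(100):
            th = rng.uniform(-np.pi, np.pi, size=pot.n_dim)
            g = pot.gradient(th)
            for j in range(pot.n_dim):
                tp, tm = th.copy(), th.copy()
                tp[j] += h
                tm[j] -= h
                fd = (pot.energy(tp) - pot.energy(tm)) / (2 * h)
                assert g[j] == pytest.approx(fd, rel=1e-6, abs=1e-6)

    def test_periodicity(self):
        pot = make_double_well(0.2, 2.0)
        rng = np.random.default_rng(1)
        for _ in range(20):
            th = rng.uniform(-np.pi, np.pi)
            assert pot.energy(np.array([th])) == pytest.approx(
                pot.energy(np.array([th - 2 * np.pi])), abs=1e-9)

    def test_invalid_barrier(self):
        with pytest.raises(ValueError):
            make_double_well(0.0, -1.0)


class TestLangevinStep:
    def test_deterministic_under_seed(self):
        pot = make_double_well(0.0, 2.0)
        cfg = LangevinConfig(seed=0)
        s1 = SimState(np.array([0.5]), 0, np.random.default_rng(4))
        s2 = SimState(np.array([0.5]), 0, np.random.default_rng(4))
        for _ in range(10):
            langevin_step(s1, pot, None, cfg)
            langevin_step(s2, pot, None, cfg)
        assert np.array_equal(s1.angles, s2.angles)
        assert s1.step == 10

    def test_near_zero_temperature_stays_at_minimum(self):
        pot = make_double_well(0.0, 2.0)
        cfg = LangevinConfig(dt=0.01, friction=1.0, kbt=1e-12)
        s = SimState(np.array([0.0]), 0, np.random.default_rng(0))
        for _ in range(100):
            langevin_step(s, pot, None, cfg)
        assert abs(s.angles[0]) < 1e-5

    def test_flat_potential_diffusion_identity(self):
        """MSD per step ~ 2 kBT dt / friction on a flat landscape."""
        flat = make_cosine_wells([0.0], [1e-12], [1])
        cfg = LangevinConfig(dt=0.01, friction=2.0, kbt=1.5)
        s = SimState(np.array([0.0]), 0, np.random.default_rng(8))
        n = 10**5
        prev = s.angles[0]
        sq = 0.0
        for _ in range(n):
            langevin_step(s, flat, None, cfg)
            d = s.angles[0] - prev
            d = (d + np.pi) % (2 * np.pi) - np.pi  # minimal image
            sq += d * d
            prev = s.angles[0]
        expected = 2 * cfg.kbt * cfg.dt / cfg.friction
        assert sq / n == pytest.approx(expected, rel=0.05)

    def test_extra_force_shifts_stationary_point(self):
        pot = make_double_well(0.0, 2.0)
        cfg = LangevinConfig(dt=0.01, kbt=1e-12)
        s = SimState(np.array([0.0]), 0, np.random.default_rng(0))
        f = np.array([1.0])
        for _ in range(2000):
            langevin_step(s, pot, f, cfg)
        # stationary where grad U = f: 4 sin(2 theta)/2 ... solve numerically
        residual = pot.gradient(s.angles)[0] - 1.0
        assert abs(residual) < 1e-4


class TestRunUnbiased:
    def test_frame_count_and_order(self):
        pot = make_double_well(0.0, 2.0)
        cfg = LangevinConfig(seed=1)
        s = SimState(np.array([0.1]), 0, np.random.default_rng(1))
        traj, s = run_unbiased(s, pot, 100, 10, cfg)
        assert traj.n_frames == 10
        assert s.step == 100

    def test_different_seeds_differ(self):
        pot = make_double_well(0.0, 2.0)
        cfg = LangevinConfig()
        t1, _ = run_unbiased(SimState(np.zeros(1), 0, np.random.default_rng(1)), pot, 100, 10, cfg)
        t2, _ = run_unbiased(SimState(np.zeros(1), 0, np.random.default_rng(2)), pot, 100, 10, cfg)
        assert not np.array_equal(t1.angles, t2.angles)

    def test_wrap_invariant(self):
        pot = make_double_well(0.0, 2.0)
        traj, _ = run_unbiased(SimState(np.zeros(1), 0, np.random.default_rng(3)),
                               pot, 5000, 5, LangevinConfig())
        assert np.all(traj.angles > -np.pi)
        assert np.all(traj.angles <= np.pi)

    def test_indivisible_counts_rejected(self):
        pot = make_double_well(0.0, 2.0)
        with pytest.raises(ConfigurationError):
            run_unbiased(SimState(np.zeros(1)), pot, 101, 10, LangevinConfig())

    @pytest.mark.parametrize("pot,n_steps", [
        (make_double_well(0.0, 2.0), 400_000),
        (product_potential([make_double_well(0.0, 1.0), make_double_well(0.5, 1.5)]), 400_000),
    ], ids=["1d", "2d"])
    def test_boltzmann_stationary_distribution(self, pot, n_steps):
        """Long-run histograms match the quadrature Boltzmann weight."""
        cfg = LangevinConfig(dt=0.01, friction=1.0, kbt=1.0)
        s = SimState(np.zeros(pot.n_dim), 0, np.random.default_rng(7))
        traj, _ = run_unbiased(s, pot, n_steps, 10, cfg)
        nb = 24
        edges = np.linspace(-np.pi, np.pi, nb + 1)
        for d in range(pot.n_dim):
            hist, _ = np.histogram(traj.angles[:, d], bins=edges)
            p_emp = hist / hist.sum()
            if pot.n_dim == 1:
                u = lambda x: pot.energy(np.array([x]))
            else:
                # separable potential: marginal of dimension d
                others = np.zeros(pot.n_dim)
                u = lambda x: pot.energy(np.where(np.arange(pot.n_dim) == d, x, others))
            Z = quad(lambda x: np.exp(-u(x)), -np.pi, np.pi)[0]
            p_th = np.array([
                quad(lambda x: np.exp(-u(x)) / Z, edges[i], edges[i + 1])[0]
                for i in range(nb)
            ])
            assert np.abs(p_emp - p_th).sum() < 0.08

    def test_stability_guard(self):
        pot = make_double_well(0.0, 500.0)
        with pytest.raises(ConfigurationError):
            run_unbiased(SimState(np.zeros(1)), pot, 100, 10, LangevinConfig(dt=0.01))


class TestLangevinEngine:
    def test_zero_force_matches_run_unbiased_bitwise(self):
        pot = make_double_well(0.0, 2.0)
        cfg = LangevinConfig()
        eng = LangevinEngine(pot, cfg, np.zeros(1), rng=np.random.default_rng(9))
        frames_blocks = []
        for _ in range(20):
            frames_blocks.extend(eng.advance(50, np.zeros(1), save_every=10))
        traj, _ = run_unbiased(SimState(np.zeros(1), 0, np.random.default_rng(9)),
                               pot, 1000, 10, cfg)
        assert np.array_equal(np.array(frames_blocks), traj.angles)

    def test_wrong_shapes_raise_adapter_error(self):
        pot = make_double_well(0.0, 2.0)
        with pytest.raises(AdapterError):
            LangevinEngine(pot, LangevinConfig(), np.zeros(2))
        eng = LangevinEngine(pot, LangevinConfig(), np.zeros(1))
        with pytest.raises(AdapterError):
            eng.advance(10, np.zeros(3))

    def test_state_dict_round_trip(self):
        pot = make_double_well(0.0, 2.0)
        eng = LangevinEngine(pot, LangevinConfig(), np.zeros(1), rng=np.random.default_rng(2))
        eng.advance(100, None)
        snap = eng.state_dict()
        a = eng.advance(100, None, save_every=10)
        eng2 = LangevinEngine(pot, LangevinConfig(), np.zeros(1), rng=np.random.default_rng(0))
        eng2.load_state_dict(snap)
        b = eng2.advance(100, None, save_every=10)
        assert np.array_equal(np.array(a), np.array(b))
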