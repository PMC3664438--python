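"""Genome coding, fitness scoring, and the genetic algorithm."""

import numpy as np
import pytest

from smclab import AgentParams, BatterySpec, EvolveConfig, Genome, evolve, fitness
from smclab.evolution import (GENE_ORDER, _battery_trials, fitness_many,
                              _reflect_unit)


class TestGenome:
    def test_encode_decode_roundtrip(self, rng):
        for _ in range(20):
            g = Genome(tuple(rng.random(7)))
            g2 = Genome.encode(g.decode())
            np.testing.assert_allclose(g2.as_array(), g.as_array(),
                                       atol=1e-12)

    def test_decode_lands_in_parameter_box(self, rng):
        from smclab import PARAM_RANGES
        p = Genome(tuple(rng.random(7))).decode()
        for name, (lo, hi) in PARAM_RANGES.items():
            assert lo <= getattr(p, name) <= hi
        assert p.v_max == 1.0

    def test_invalid_genes_rejected(self):
        with pytest.raises(ValueError):
            Genome((0.5,) * 6)
        with pytest.raises(ValueError):
            Genome((0.5,) * 6 + (1.5,))

    def test_reflection_keeps_unit_interval(self, rng):
        x = rng.normal(0.5, 1.0, 1000)
        r = _reflect_unit(x)
        assert np.all((r >= 0) & (r <= 1))
        # in-range values are untouched
        assert _reflect_unit(np.array([0.3]))[0] == 0.3


class TestFitness:
    def test_battery_layout(self):
        w, h, off = _battery_trials(BatterySpec(), seed=3)
        assert len(w) == 12
        assert sorted(set(w)) == [1.0, 3.0]
        assert np.all((h >= 0.5) & (h <= 1.0))

    def test_stationary_agent_closed_form(self):
        """An agent that never moves scores exactly the analytic value:
        0 on every narrow trial, d_start/(L/2 - d_start) on wide ones."""
        still = AgentParams(w11=0, w21=0, theta1=0, theta2=0,
                            tau1=1, tau2=1, g_s=0)
        g = Genome.encode(still)
        batt = BatterySpec()
        w, h, off = _battery_trials(batt, seed=5)
        d = np.abs(off)
        expected = np.where(w == 1.0, 0.0,
                            np.minimum(1.0, d / (20.0 - d))).mean()
        assert fitness(g, batt, seed=5) == pytest.approx(expected, abs=1e-12)

    def test_deterministic_per_seed(self, rng):
        g = Genome(tuple(rng.random(7)))
        assert fitness(g, seed=4) == fitness(g, seed=4)

    def test_batch_matches_scalar_simulator(self, rng):
        """The vectorized fitness engine reproduces run_trial endpoints."""
        from smclab import SimState, World, run_trial, wrapped_distance
        from smclab.evolution import _final_distance_batch, _LO, _HI
        genes = rng.random((2, 7))
        batt = BatterySpec()
        w, h, off = _battery_trials(batt, seed=9)
        pmat = _LO + genes * (_HI - _LO)
        d = _final_distance_batch(pmat, w, h, off, batt)
        for gi in (0, 1):
            params = Genome(tuple(genes[gi])).decode()
            for ti in (0, 7, 11):
                world = World.single(width=w[ti], height=h[ti], L=40.0)
                init = SimState(p=(20.0 - off[ti]) % 40.0)
                traj = run_trial(world, params, init, T=batt.T, dt=batt.dt)
                ref = abs(wrapped_distance(traj.p[-1], 20.0, 40.0))
                assert d[gi, ti] == pytest.approx(ref, abs=1e-9)

    def test_order_free_over_trials(self, rng):
        # the mean over per-trial scores cannot depend on trial labelling
        from smclab.evolution import _score
        batt = BatterySpec()
        w, h, off = _battery_trials(batt, seed=2)
        d = rng.uniform(0, 20, (3, len(w)))
        perm = rng.permutation(len(w))
        f1 = _score(d, w, off, batt)
        f2 = _score(d[:, perm], w[perm], off[perm], batt)
        np.testing.assert_allclose(f1, f2, atol=1e-12)


class TestMirrorSymmetry:
    def test_flipping_motor_sign_and_sides_preserves_fitness(self, rng):
        """Negating w21 and theta2 while mirroring start offsets yields the
        exact mirror-image closed loop, hence identical fitness."""
        from smclab.evolution import _final_distance_batch, _LO, _HI
        batt = BatterySpec()
        w, h, off = _battery_trials(batt, seed=21)
        for _ in range(20):
            genes = rng.random((1, 7))
            pmat = (_LO + genes * (_HI - _LO)).copy()
            d1 = _final_distance_batch(pmat, w, h, off, batt)
            pmat2 = pmat.copy()
            pmat2[0, 1] *= -1  # w21
            pmat2[0, 3] *= -1  # theta2
            d2 = _final_distance_batch(pmat2, w, h, -off, batt)
            np.testing.assert_allclose(d1, d2, atol=1e-9)


class TestEvolve:
    SMALL = dict(population=10, generations=8)

    def test_deterministic_per_seed(self):
        r1 = evolve(EvolveConfig(**self.SMALL), seed=5)
        r2 = evolve(EvolveConfig(**self.SMALL), seed=5)
        assert r1.best_genome == r2.best_genome
        assert r1.history == r2.history

    def test_best_so_far_monotone(self):
        r = evolve(EvolveConfig(**self.SMALL), seed=3)
        bsf = [h["best_so_far"] for h in r.history]
        assert all(b >= a for a, b in zip(bsf, bsf[1:]))
        assert r.best_fitness == bsf[-1]

    def test_reported_best_is_reproducible(self):
        # fixed battery: the stored best fitness re-evaluates exactly
        r = evolve(EvolveConfig(**self.SMALL), seed=3)
        assert fitness(r.best_genome, EvolveConfig().battery,
                       seed=3 % 2**31) == pytest.approx(r.best_fitness)

    def test_target_fitness_stops_early(self):
        r = evolve(EvolveConfig(population=10, generations=50,
                                target_fitness=0.1), seed=2)
        assert len(r.history) < 50

    def test_warm_start_is_deterministic_and_valid(self):
        g0 = tuple([0.5] * 7)
        cfg = EvolveConfig(population=10, generations=3, init_genome=g0)
        r1 = evolve(cfg, seed=4)
        r2 = evolve(cfg, seed=4)
        assert r1.best_genome == r2.best_genome
        assert all(0 <= g <= 1 for g in r1.best_genome.genes)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            evolve(EvolveConfig(population=5), seed=0)
        with pytest.raises(ValueError):
            evolve(EvolveConfig(generations=0), seed=0)
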