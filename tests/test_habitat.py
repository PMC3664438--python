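"""Quasi-static fixed points, bifurcation structure, landscapes, ensembles."""

import numpy as np
import pytest

from smclab import (AgentParams, AgentState, SamplingSpec, World,
                    attractor_landscape, bifurcation_diagram,
                    clamped_relaxation, fold_inputs, sample_habitat,
                    solve_fixed_points, tendency)
from smclab.habitat import stable_y1_branches


class TestFixedPoints:
    def test_linear_leak_single_root(self):
        p = AgentParams(w11=0, w21=0, theta1=0, theta2=0, tau1=1, tau2=1,
                        g_s=0)
        for I in (-3.0, 0.0, 2.5):
            fps = solve_fixed_points(p, I)
            assert len(fps) == 1
            assert fps[0].y1 == pytest.approx(I, abs=1e-10)
            assert fps[0].stable

    def test_bistable_triple_at_zero_input(self, bistable_params):
        fps = solve_fixed_points(bistable_params, 0.0)
        assert len(fps) == 3
        mid = fps[1]
        # w11*sigma(0) = 3 balances the leak exactly at y1 = 3; the slope
        # w11*sigma'(0) = 1.5 > 1 makes it unstable
        assert mid.y1 == pytest.approx(3.0, abs=1e-10)
        assert not mid.stable
        assert fps[0].stable and fps[2].stable
        # outer roots symmetric about 3 (F is odd about (3, 0))
        assert fps[0].y1 + fps[2].y1 == pytest.approx(6.0, abs=1e-9)
        assert fps[0].y1 == pytest.approx(0.4243, abs=1e-3)

    def test_residual_and_slaving_invariants(self, bistable_params, rng):
        from scipy.special import expit
        p = bistable_params
        for I in rng.uniform(-3, 3, 10):
            for fp in solve_fixed_points(p, float(I)):
                res = -fp.y1 + p.w11 * expit(fp.y1 + p.theta1) + I
                assert abs(res) < 1e-10
                assert fp.y2 == pytest.approx(
                    p.w21 * expit(fp.y1 + p.theta1), abs=1e-10)

    def test_weak_self_coupling_always_monostable(self, rng):
        """Logistic slope bound: w11 <= 4 admits exactly one fixed point."""
        for _ in range(1000 // 50):
            for I in rng.uniform(-10, 10, 50):
                w11 = rng.uniform(-16, 4)
                th1 = rng.uniform(-16, 16)
                p = AgentParams(w11=w11, w21=0, theta1=th1, theta2=0,
                                tau1=1, tau2=1, g_s=0)
                assert len(solve_fixed_points(p, float(I))) == 1


class TestFolds:
    def test_no_folds_below_threshold(self):
        p = AgentParams(w11=4.0, w21=0, theta1=0, theta2=0, tau1=1, tau2=1,
                        g_s=0)
        assert fold_inputs(p) is None

    def test_closed_form_matches_swept_diagram(self, bistable_params):
        folds = fold_inputs(bistable_params)
        diagram = bifurcation_diagram(bistable_params, (-2, 2), 0.01)
        assert len(diagram.bifurcation_points) == 2
        np.testing.assert_allclose(
            diagram.bifurcation_points, [folds.I_low, folds.I_high],
            atol=1e-6)

    def test_symmetric_about_zero_for_centered_bias(self, bistable_params):
        # theta1 = -w11/2 makes F odd about its middle root: folds mirror
        folds = fold_inputs(bistable_params)
        assert folds.I_low == pytest.approx(-folds.I_high, abs=1e-12)


class TestBifurcationDiagram:
    def test_monostable_sweep_single_branch(self, monostable_params):
        d = bifurcation_diagram(monostable_params, (-3, 3), 0.05)
        assert d.bifurcation_points == []
        assert len(d.branches) == 1

    def test_bistable_branch_counts(self, bistable_params):
        d = bifurcation_diagram(bistable_params, (-2, 2), 0.01)
        folds = fold_inputs(bistable_params)
        inside = 0.5 * (folds.I_low + folds.I_high)
        assert d.branch_count(inside) == 3
        assert d.branch_count(1.5) == 1

    def test_saturation_tracks_identity(self, bistable_params):
        # far outside the fold window y1* ~ I + w11*{0 or 1}
        for I, offset in ((-8.0, 0.0), (8.0, 6.0)):
            fps = solve_fixed_points(bistable_params, I)
            assert len(fps) == 1
            assert fps[0].y1 == pytest.approx(I + offset, abs=0.05)


class TestStableBranchesVectorized:
    def test_agrees_with_scalar_solver(self, bistable_params, rng):
        I = rng.uniform(-2, 2, 200)
        y_low, y_high = stable_y1_branches(bistable_params, I)
        for k in range(0, 200, 7):
            stable = [fp.y1 for fp in solve_fixed_points(bistable_params,
                                                         float(I[k]))
                      if fp.stable]
            got = [y for y in (y_low[k], y_high[k]) if np.isfinite(y)]
            np.testing.assert_allclose(sorted(got), sorted(stable), atol=1e-8)


class TestClampedOracle:
    def test_stable_points_attract_their_basin(self, bistable_params, rng):
        """Each algebraic fixed point is the endpoint of clamped relaxation
        from spread starts within its basin (500 time units)."""
        for I in (-0.2, 0.0, 0.3):
            fps = solve_fixed_points(bistable_params, I)
            stable = [fp for fp in fps if fp.stable]
            unstable = [fp.y1 for fp in fps if not fp.stable]
            for fp in stable:
                if unstable:
                    b = unstable[0]
                    lo, hi = (b + 1e-3, fp.y1 + 5) if fp.y1 > b else \
                             (fp.y1 - 5, b - 1e-3)
                else:
                    lo, hi = fp.y1 - 5, fp.y1 + 5
                starts = np.linspace(lo, hi, 10)
                ends = clamped_relaxation(bistable_params,
                                          np.full(10, I), starts)
                np.testing.assert_allclose(ends, fp.y1, atol=1e-3)


class TestTendency:
    def test_monostable_ignores_state(self, monostable_params):
        fp = tendency(monostable_params, AgentState(y1=-7.0), 0.5)
        fp2 = tendency(monostable_params, AgentState(y1=9.0), 0.5)
        assert fp is not None and fp2 is not None
        assert fp.y1 == pytest.approx(fp2.y1, abs=1e-9)

    def test_basin_boundary_is_the_unstable_point(self, bistable_params):
        fps = solve_fixed_points(bistable_params, 0.0)
        lower, unstable, upper = fps
        below = tendency(bistable_params, AgentState(y1=unstable.y1 - 0.1), 0.0)
        above = tendency(bistable_params, AgentState(y1=unstable.y1 + 0.1), 0.0)
        assert below.y1 == pytest.approx(lower.y1, abs=1e-3)
        assert above.y1 == pytest.approx(upper.y1, abs=1e-3)

    def test_exactly_on_boundary_flags_none(self, bistable_params):
        fps = solve_fixed_points(bistable_params, 0.0)
        with pytest.warns(UserWarning, match="basin boundary"):
            res = tendency(bistable_params, AgentState(y1=fps[1].y1), 0.0)
        assert res is None


class TestLandscape:
    def test_empty_world_uniform(self, bistable_params):
        w = World(circumference=40.0)
        scape = attractor_landscape(w, bistable_params,
                                    np.linspace(0, 10, 21),
                                    np.linspace(-1, 1, 11))
        assert len(np.unique(scape.classes)) == 1

    def test_consistent_with_scalar_solver(self, narrow_world,
                                           bistable_params, rng):
        pg = np.linspace(-3, 3, 31)
        vg = np.linspace(-1, 1, 21)
        scape = attractor_landscape(narrow_world, bistable_params, pg, vg)
        from smclab import sense_gradient
        for _ in range(30):
            i = rng.integers(0, len(pg))
            j = rng.integers(0, len(vg))
            I = bistable_params.g_s * vg[j] * sense_gradient(narrow_world,
                                                             pg[i])
            signs = {1 if fp.v >= 0 else -1
                     for fp in solve_fixed_points(bistable_params, float(I))
                     if fp.stable}
            expect = (0 if signs == {1, -1}
                      else (1 if signs == {1} else -1))
            assert scape.classes[i, j] == expect

    def test_inherits_surface_symmetry(self, narrow_world, bistable_params):
        n = 60
        pg = np.linspace(-3, 3, 2 * n + 1)
        vg = np.linspace(-1, 1, 41)
        scape = attractor_landscape(narrow_world, bistable_params, pg, vg)
        np.testing.assert_array_equal(scape.classes,
                                      scape.classes[::-1, ::-1])

    def test_refinement_stability_of_interior_classes(self, narrow_world,
                                                      bistable_params):
        pg = np.linspace(-3, 3, 61)
        vg = np.linspace(-1, 1, 41)
        coarse = attractor_landscape(narrow_world, bistable_params, pg, vg)
        pg2 = np.linspace(-3, 3, 121)
        vg2 = np.linspace(-1, 1, 81)
        fine = attractor_landscape(narrow_world, bistable_params, pg2, vg2)
        # coarse cell (i, j) is fine cell (2i, 2j); interior cells away from
        # class boundaries must keep their class under refinement
        C, F = coarse.classes, fine.classes[::2, ::2]
        interior = np.ones_like(C, dtype=bool)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                shifted = np.roll(np.roll(C, di, 0), dj, 1)
                interior &= shifted == C
        interior[0, :] = interior[-1, :] = False
        interior[:, 0] = interior[:, -1] = False
        assert np.array_equal(C[interior], F[interior])


class TestEnsembles:
    def test_exact_count_and_determinism(self, bistable_params):
        spec = SamplingSpec(n=5, T=5.0)
        e1 = sample_habitat(bistable_params, spec, seed=11)
        e2 = sample_habitat(bistable_params, spec, seed=11)
        assert len(e1) == 5
        for a, b in zip(e1.members, e2.members):
            assert np.array_equal(a.p, b.p)

    def test_different_seed_differs(self, bistable_params):
        spec = SamplingSpec(n=3, T=5.0)
        e1 = sample_habitat(bistable_params, spec, seed=1)
        e2 = sample_habitat(bistable_params, spec, seed=2)
        assert not all(np.array_equal(a.p, b.p)
                       for a, b in zip(e1.members, e2.members))

    def test_empty_spec_rejected(self, bistable_params):
        with pytest.raises(ValueError):
            sample_habitat(bistable_params, SamplingSpec(n=0), seed=0)

    def test_save_writes_members_and_manifest(self, tmp_path, bistable_params):
        import json
        ens = sample_habitat(bistable_params, SamplingSpec(n=3, T=2.0), seed=4)
        ens.save(tmp_path / "ens")
        manifest = json.loads((tmp_path / "ens" / "manifest.json").read_text())
        assert manifest["seed"] == 4
        assert len(manifest["members"]) == 3
        for name in manifest["members"]:
            assert (tmp_path / "ens" / name).exists()
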