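"""Elliptic nutrient solves and pointwise matrix/enzyme updates."""

import numpy as np
import pytest

from conftest import dense_elliptic_solve, random_elliptic_case
from tumorsim import (EllipticProblem, MdeSolver, SimulationConfig,
                      WellPosednessError, ecm_step, ecm_step_mde, init_cells,
                      mde_step, nutrient_initial, nutrient_steady,
                      solve_elliptic)
from tumorsim.grid import Field, LatticeState


def _all_neumann():
    return {e: None for e in ("top", "bottom", "left", "right")}


def _all_dirichlet(v):
    return {e: v for e in ("top", "bottom", "left", "right")}


class TestSolveElliptic:
    def test_uniform_reaction_source_balance(self):
        # -lap(u) + u = 1 with zero flux has the constant solution u = 1
        n = 8
        problem = EllipticProblem(1.0, np.ones((n, n)), np.ones((n, n)),
                                  _all_neumann())
        assert solve_elliptic(problem).values == pytest.approx(np.ones((n, n)))

    def test_harmonic_with_constant_boundary(self):
        n = 8
        problem = EllipticProblem(10.0, np.zeros((n, n)), np.zeros((n, n)),
                                  _all_dirichlet(1.0))
        assert solve_elliptic(problem).values == pytest.approx(np.ones((n, n)))

    def test_all_neumann_zero_reaction_is_singular(self):
        n = 6
        problem = EllipticProblem(1.0, np.zeros((n, n)), np.ones((n, n)),
                                  _all_neumann())
        with pytest.raises(WellPosednessError):
            solve_elliptic(problem)

    @pytest.mark.parametrize("case", range(8))
    def test_matches_dense_direct_solve(self, case):
        rng = np.random.default_rng(100 + case)
        D, reaction, source, bc = random_elliptic_case(rng)
        got = solve_elliptic(EllipticProblem(D, reaction, source, bc)).values
        want = dense_elliptic_solve(D, reaction, source, bc)
        assert np.linalg.norm(got - want) <= 1e-10 * max(np.linalg.norm(want), 1.0)


class TestNutrientSteady:
    def test_no_cells_gives_vessel_concentration(self):
        cfg = SimulationConfig(n=12, seed_cells=1)
        state = LatticeState(np.zeros((12, 12), np.int8),
                             np.zeros((12, 12), np.int32))
        u = nutrient_steady(state, cfg)
        assert u.values == pytest.approx(np.ones((12, 12)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_discrete_maximum_principle(self, seed):
        # source-free uptake keeps u within [0, u_d] for any occupancy
        rng = np.random.default_rng(seed)
        n = 15
        status = (rng.random((n, n)) < 0.4).astype(np.int8)
        state = LatticeState(status, np.zeros((n, n), np.int32))
        cfg = SimulationConfig(n=n, seed_cells=1, alpha_u=50.0,
                               vessels=frozenset({"left"}))
        u = nutrient_steady(state, cfg).values
        assert u.min() >= -1e-9
        assert u.max() <= 1.0 + 1e-9

    def test_depression_grows_toward_tumour_bulk(self):
        cfg = SimulationConfig(n=41, seed_cells=441, alpha_u=500.0,
                               vessels=frozenset({"left", "right", "top",
                                                  "bottom"}))
        u = nutrient_steady(init_cells(cfg), cfg).values
        mid = u[20, :21]            # vessel edge to lattice centre
        assert u[20, 20] < 1.0      # uptake depresses the centre
        assert np.all(np.diff(mid) <= 1e-12)   # monotone decay inward


class TestNutrientInitial:
    def test_left_right_mirror_symmetry(self):
        cfg = SimulationConfig(n=25, seed_cells=441,
                               vessels=frozenset({"left", "right"}))
        u = nutrient_initial(init_cells(cfg), cfg).values
        assert u == pytest.approx(u[:, ::-1], abs=1e-9)

    def test_source_raises_field_above_vessel_level(self):
        # the CSF supply term pushes the interior slightly above u_d
        cfg = SimulationConfig(n=25, seed_cells=441,
                               vessels=frozenset({"left", "right"}))
        u = nutrient_initial(init_cells(cfg), cfg).values
        assert u.max() > 1.0

    def test_matches_dense_oracle_on_small_lattice(self):
        cfg = SimulationConfig(n=12, seed_cells=9,
                               vessels=frozenset({"top"}))
        state = init_cells(cfg)
        got = nutrient_initial(state, cfg).values
        from tumorsim import cell_mask, vessel_bc
        want = dense_elliptic_solve(cfg.D_u,
                                    cfg.alpha_u * cell_mask(state, True),
                                    np.ones((12, 12)), vessel_bc(cfg))
        assert got == pytest.approx(want, abs=1e-10)


class TestEcmStep:
    def test_single_step_with_default_rates(self):
        f = Field(np.full((4, 4), 0.8))
        out = ecm_step(f, np.ones((4, 4)), 0.01, 0.001, 0.18)
        assert out.values == pytest.approx(0.8 * (1 - 0.18 * 0.009))
        assert round(float(out.values[0, 0]), 4) == 0.7987

    def test_balanced_rates_leave_matrix_unchanged(self):
        f = Field(np.full((3, 3), 0.5))
        out = ecm_step(f, np.ones((3, 3)), 0.02, 0.02, 0.18)
        assert out.values == pytest.approx(0.5)

    @pytest.mark.parametrize("c", [0.0, 1.0])
    def test_constant_occupancy_follows_closed_form(self, c):
        k, alpha, beta, m = 0.18, 0.01, 0.001, 40
        f = Field(np.full((3, 3), 0.8))
        c_src = np.full((3, 3), c)
        for _ in range(m):
            f = ecm_step(f, c_src, alpha, beta, k)
        expected = 0.8 * (1 - k * alpha * c + k * beta) ** m
        assert f.values == pytest.approx(expected, rel=1e-12)

    def test_unstable_rates_rejected(self):
        with pytest.raises(ValueError):
            ecm_step(Field(np.ones((3, 3))), np.ones((3, 3)), 1.0, 0.0, 3.0)


class TestMdeStep:
    @pytest.mark.parametrize("mode", ["steady", "transient"])
    def test_no_cells_no_enzyme(self, mode):
        cfg = SimulationConfig(n=6, seed_cells=1, model_variant="B",
                               mde_mode=mode)
        m = mde_step(Field(np.zeros((6, 6))), np.zeros((6, 6)), cfg)
        assert np.all(m.values == 0.0)

    def test_transient_uniform_source_grows_linearly(self):
        # with full occupancy and no decay, m stays uniform and gains
        # k*beta_m per step (diffusion of a constant vanishes)
        cfg = SimulationConfig(n=6, seed_cells=1, model_variant="B",
                               mde_mode="transient")
        solver = MdeSolver(cfg)
        m = Field(np.zeros((6, 6)))
        for j in range(1, 4):
            m = solver.step(m, np.ones((6, 6)))
            assert m.values == pytest.approx(j * cfg.k * cfg.beta_m, rel=1e-10)

    def test_steady_profile_matches_dense_oracle(self):
        # quasi-steady balance with boundary washout, against the dense solver
        cfg = SimulationConfig(n=10, seed_cells=1, model_variant="B",
                               alpha_m=0.2)
        rng = np.random.default_rng(11)
        c = (rng.random((10, 10)) < 0.4).astype(float)
        got = mde_step(Field(np.zeros((10, 10))), c, cfg).values
        want = dense_elliptic_solve(cfg.D_m, np.full((10, 10), cfg.alpha_m),
                                    cfg.beta_m * c,
                                    {e: 0.0 for e in ("top", "bottom",
                                                      "left", "right")})
        assert got == pytest.approx(want, abs=1e-10)

    def test_steady_profile_independent_of_previous_enzyme_level(self):
        cfg = SimulationConfig(n=8, seed_cells=1, model_variant="B")
        c = np.zeros((8, 8)); c[3:5, 3:5] = 1.0
        solver = MdeSolver(cfg)
        a = solver.step(Field(np.zeros((8, 8))), c)
        b = solver.step(Field(np.full((8, 8), 9.0)), c)
        assert a.values == pytest.approx(b.values)
        assert a.values.max() > 0

    def test_matches_dense_implicit_euler_oracle(self):
        cfg = SimulationConfig(n=8, seed_cells=1, model_variant="B",
                               alpha_m=0.3, mde_mode="transient")
        rng = np.random.default_rng(7)
        m0 = rng.random((8, 8))
        c = (rng.random((8, 8)) < 0.5).astype(float)
        got = mde_step(Field(m0), c, cfg).values

        n, h2 = 8, (1 / 8) ** 2
        L = np.zeros((64, 64))
        for r in range(n):
            for cc_ in range(n):
                i = r * n + cc_
                for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                    rr, c2 = r + dr, cc_ + dc
                    if 0 <= rr < n and 0 <= c2 < n:
                        L[i, rr * n + c2] += 1 / h2
                        L[i, i] -= 1 / h2
        M = np.eye(64) * (1 + cfg.k * cfg.alpha_m) - cfg.k * cfg.D_m * L
        want = np.linalg.solve(M, (m0 + cfg.k * cfg.beta_m * c).ravel())
        assert got == pytest.approx(want.reshape(8, 8), abs=1e-10)


class TestEcmStepMde:
    def test_pure_remodelling_without_enzyme(self):
        cfg = SimulationConfig(n=4, seed_cells=1, model_variant="B")
        f = Field(np.full((4, 4), 0.8))
        out = ecm_step_mde(f, Field(np.zeros((4, 4))), cfg)
        assert out.values == pytest.approx(0.8 * (1 + 0.18 * 0.015))

    def test_equilibrium_enzyme_level(self):
        cfg = SimulationConfig(n=4, seed_cells=1, model_variant="B")
        m = Field(np.full((4, 4), cfg.beta_f_tilde / cfg.alpha_f_tilde))
        f = Field(np.full((4, 4), 0.8))
        assert ecm_step_mde(f, m, cfg).values == pytest.approx(0.8)

    def test_unit_enzyme_factor(self):
        cfg = SimulationConfig(n=4, seed_cells=1, model_variant="B")
        f = Field(np.ones((4, 4)))
        out = ecm_step_mde(f, Field(np.ones((4, 4))), cfg)
        assert out.values == pytest.approx(1 - 0.18 + 0.18 * 0.015)
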