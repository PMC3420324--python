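"""Continuum field solvers: nutrient, extracellular matrix and enzymes.

The nutrient field is quasi-steady — diffusion of oxygen/glucose is fast
compared with cell dynamics — so every iteration solves the elliptic problem

    -D_u * lap(u) + alpha_u * c * u = s

on the lattice with Dirichlet ``u = u_d`` on vessel edges and zero-flux
elsewhere (5-point finite differences, first-order ghost-node closure of the
Neumann edges, direct sparse factorisation).  The initial nutrient field uses
the same operator with a unit source representing supply from the
cerebrospinal fluid.  The ECM equations contain no spatial derivatives and
reduce to pointwise explicit-Euler updates; the enzyme field is advanced with
one implicit-Euler diffusion step per iteration.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import MdeMode, SimulationConfig, stability_check
from .grid import EDGE_SLICES, Field, LatticeState, cell_mask, vessel_bc

#: Relative residual above which a sparse solve is considered failed.
RESIDUAL_TOL = 1e-8


class WellPosednessError(ValueError):
    """Raised for an all-Neumann problem with no reaction (singular system)."""


@dataclasses.dataclass
class EllipticProblem:
    """Discrete problem ``-D*lap(u) + reaction*u = source`` with mixed BCs."""

    diffusivity: float
    reaction: np.ndarray            # (n, n) coefficient of u, >= 0
    source: np.ndarray              # (n, n) right-hand side
    bc: dict[str, float | None]     # edge tag -> Dirichlet value or None

    def __post_init__(self) -> None:
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")
        if np.any(self.reaction < 0):
            raise ValueError("reaction coefficient must be non-negative")


# offsets as (row-slice pairs): (source nodes, neighbour nodes)
_NEIGHBOUR_SLICES = (
    (np.s_[:, :-1], np.s_[:, 1:]),    # east neighbour
    (np.s_[:, 1:], np.s_[:, :-1]),    # west
    (np.s_[1:, :], np.s_[:-1, :]),    # north (row - 1)
    (np.s_[:-1, :], np.s_[1:, :]),    # south
)


def _dirichlet_values(n: int, bc: dict[str, float | None]) -> np.ndarray:
    """(n, n) array of Dirichlet values, NaN on free (non-Dirichlet) nodes."""
    vals = np.full((n, n), np.nan)
    for edge, value in bc.items():
        if value is not None:
            vals[EDGE_SLICES[edge]] = value
    return vals


def assemble_elliptic(problem: EllipticProblem) -> tuple[sp.csr_matrix, np.ndarray]:
    """Assemble the sparse linear system for :func:`solve_elliptic`.

    Dirichlet nodes are kept in the system as identity rows; Neumann edges
    use the ghost-node reflection (the off-grid neighbour is identified with
    the centre node, which simply removes its contribution).
    """
    n = problem.reaction.shape[0]
    h = 1.0 / n
    d_h2 = problem.diffusivity / (h * h)

    dir_vals = _dirichlet_values(n, problem.bc)
    free = np.isnan(dir_vals)
    idx = np.arange(n * n).reshape(n, n)

    rows, cols, vals = [], [], []
    neighbour_count = np.zeros((n, n), dtype=np.int8)
    for src_sl, nb_sl in _NEIGHBOUR_SLICES:
        neighbour_count[src_sl] += 1
        m = free[src_sl]
        rows.append(idx[src_sl][m])
        cols.append(idx[nb_sl][m])
        vals.append(np.full(m.sum(), -d_h2))

    diag = np.where(free, problem.reaction + d_h2 * neighbour_count, 1.0)
    rows.append(idx.ravel())
    cols.append(idx.ravel())
    vals.append(diag.ravel())

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n))
    b = np.where(free, problem.source, dir_vals).ravel()
    return A, b


def solve_elliptic(problem: EllipticProblem) -> Field:
    """Solve the elliptic problem by direct sparse factorisation.

    Raises :class:`WellPosednessError` for the singular all-Neumann,
    zero-reaction case, and ``RuntimeError`` if the residual check fails.
    """
    has_dirichlet = any(v is not None for v in problem.bc.values())
    if not has_dirichlet and not np.any(problem.reaction > 0):
        raise WellPosednessError(
            "all-Neumann problem with zero reaction is singular "
            "(solution defined only up to a constant)")
    A, b = assemble_elliptic(problem)
    u = spla.splu(A.tocsc()).solve(b)
    scale = np.linalg.norm(b) + np.linalg.norm(u)
    resid = np.linalg.norm(A @ u - b) / (scale if scale > 0 else 1.0)
    if not np.isfinite(resid) or resid > RESIDUAL_TOL:
        raise RuntimeError(f"elliptic solve failed: relative residual {resid:.3e}")
    n = problem.reaction.shape[0]
    return Field(values=u.reshape(n, n), bc=dict(problem.bc))


def nutrient_steady(state: LatticeState, config: SimulationConfig) -> Field:
    """Quasi-steady nutrient field with uptake on every occupied site.

    Solves ``-D_u lap(u) + alpha_u*c*u = 0`` with ``u = u_d`` on vessel edges;
    the discrete maximum principle guarantees ``0 <= u <= u_d``.
    """
    c = cell_mask(state, include_necrotic=True)
    problem = EllipticProblem(
        diffusivity=config.D_u,
        reaction=config.alpha_u * c,
        source=np.zeros_like(c),
        bc=vessel_bc(config))
    return solve_elliptic(problem)


def nutrient_initial(state: LatticeState, config: SimulationConfig) -> Field:
    """Initial nutrient availability: ``-D_u lap(u) + alpha_u*c_ini*u = 1``.

    The unit source models nutrient delivery through the cerebrospinal fluid
    before the quasi-steady balance takes over.
    """
    c = cell_mask(state, include_necrotic=True)
    problem = EllipticProblem(
        diffusivity=config.D_u,
        reaction=config.alpha_u * c,
        source=np.ones_like(c),
        bc=vessel_bc(config))
    return solve_elliptic(problem)


def ecm_step(f: Field, c_src: np.ndarray, alpha: float, beta: float,
             k: float) -> Field:
    """One explicit-Euler step of the direct-degradation ECM equation.

    Pointwise ``f <- f * (1 - k*alpha*c + k*beta)``; requires the explicit
    Euler stability bound to hold.  The result is floored at zero so the
    matrix density can never become negative.
    """
    if not stability_check(k, alpha, beta):
        raise ValueError("ECM update violates the explicit-Euler stability bound")
    values = f.values * (1.0 - k * alpha * c_src + k * beta)
    return Field(values=np.maximum(values, 0.0), bc=dict(f.bc))


def ecm_step_mde(f: Field, m: Field, config: SimulationConfig) -> Field:
    """One explicit-Euler step of the enzyme-mediated ECM equation.

    Pointwise ``f <- f * (1 - k*alpha_f_tilde*m + k*beta_f_tilde)``, floored
    at zero (the enzyme concentration is not bounded a priori).
    """
    k = config.k
    factor = 1.0 - k * config.alpha_f_tilde * m.values + k * config.beta_f_tilde
    return Field(values=np.maximum(f.values * factor, 0.0), bc=dict(f.bc))


def _neumann_laplacian(n: int) -> sp.csr_matrix:
    """Discrete Laplacian with zero-flux closure on all edges (times 1/h^2)."""
    h2 = (1.0 / n) ** 2
    idx = np.arange(n * n).reshape(n, n)
    rows, cols, vals = [], [], []
    count = np.zeros((n, n), dtype=np.int8)
    for src_sl, nb_sl in _NEIGHBOUR_SLICES:
        count[src_sl] += 1
        rows.append(idx[src_sl].ravel())
        cols.append(idx[nb_sl].ravel())
        vals.append(np.full(idx[src_sl].size, 1.0 / h2))
    rows.append(idx.ravel())
    cols.append(idx.ravel())
    vals.append(-count.ravel() / h2)
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n))


class MdeSolver:
    """Pre-factorised operator advancing the enzyme field, in either mode.

    Quasi-steady mode solves ``-D_m lap(m) + alpha_m m = beta_m c`` with the
    enzyme washed out (``m = 0``) on the whole boundary: enzyme diffusion,
    like nutrient diffusion, is fast relative to cell dynamics, so each
    iteration sees the equilibrated profile for the current cell mask (the
    zero-flux steady problem would be singular at zero decay).  Transient
    mode advances ``dm/dt = D_m lap(m) + beta_m c - alpha_m m`` by one
    implicit-Euler step of length ``k`` with zero-flux boundaries; diffusion
    and decay are implicit (unconditionally stable), the source explicit.
    Either operator is constant over a run, so its LU factorisation is built
    once and reused.
    """

    def __init__(self, config: SimulationConfig,
                 mode: MdeMode | str | None = None):
        self.config = config
        self.mode = MdeMode(mode) if mode is not None else config.mde_mode
        n = config.n
        k = config.k
        if self.mode is MdeMode.TRANSIENT:
            operator = (sp.identity(n * n, format="csc")
                        * (1.0 + k * config.alpha_m)
                        - k * config.D_m * _neumann_laplacian(n).tocsc())
            self._boundary = None
        else:
            bc = {edge: 0.0 for edge in EDGE_SLICES}
            problem = EllipticProblem(
                diffusivity=config.D_m,
                reaction=np.full((n, n), config.alpha_m),
                source=np.zeros((n, n)), bc=bc)
            operator, _ = assemble_elliptic(problem)
            operator = operator.tocsc()
            self._boundary = np.zeros((n, n), dtype=bool)
            for edge in EDGE_SLICES:
                self._boundary[EDGE_SLICES[edge]] = True
        self._lu = spla.splu(operator)

    def step(self, m: Field, c_src: np.ndarray) -> Field:
        cfg = self.config
        if self.mode is MdeMode.TRANSIENT:
            rhs = m.values.ravel() + cfg.k * cfg.beta_m * c_src.ravel()
        else:
            source = cfg.beta_m * np.asarray(c_src, float).copy()
            source[self._boundary] = 0.0   # Dirichlet rows carry the BC value
            rhs = source.ravel()
        values = self._lu.solve(rhs).reshape(m.values.shape)
        return Field(values=np.maximum(values, 0.0), bc=dict(m.bc))


def mde_step(m: Field, c_src: np.ndarray, config: SimulationConfig,
             solver: MdeSolver | None = None) -> Field:
    """Advance the matrix-degrading-enzyme field by one iteration.

    Building and factorising the operator is the dominant cost; long runs
    should construct one :class:`MdeSolver` and reuse it.
    """
    if solver is None:
        solver = MdeSolver(config)
    return solver.step(m, c_src)
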