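"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from tumorsim import SimulationConfig


def dense_elliptic_solve(D: float, reaction: np.ndarray, source: np.ndarray,
                         bc: dict[str, float | None]) -> np.ndarray:
    """Dense direct solve of -D*lap(u) + r*u = s, built node by node.

    Independent oracle for the sparse elliptic path: assembles the full
    matrix with explicit loops (Dirichlet rows as identities, Neumann edges
    by dropping the off-grid neighbour) and solves with LAPACK.
    """
    n = reaction.shape[0]
    h = 1.0 / n
    dirichlet = np.full((n, n), np.nan)
    edges = {"top": (0, slice(None)), "bottom": (n - 1, slice(None)),
             "left": (slice(None), 0), "right": (slice(None), n - 1)}
    for edge, value in bc.items():
        if value is not None:
            dirichlet[edges[edge]] = value

    N = n * n
    A = np.zeros((N, N))
    b = np.zeros(N)
    for r in range(n):
        for c in range(n):
            i = r * n + c
            if not np.isnan(dirichlet[r, c]):
                A[i, i] = 1.0
                b[i] = dirichlet[r, c]
                continue
            diag = reaction[r, c]
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n and 0 <= cc < n:
                    A[i, rr * n + cc] -= D / h**2
                    diag += D / h**2
            A[i, i] = diag
            b[i] = source[r, c]
    return np.linalg.solve(A, b).reshape(n, n)


def random_elliptic_case(rng: np.random.Generator, n: int | None = None):
    """A random small well-posed elliptic problem with mixed BCs."""
    if n is None:
        n = int(rng.integers(5, 21))
    D = float(rng.uniform(0.5, 20.0))
    reaction = rng.uniform(0.0, 2.0, (n, n)) * rng.integers(0, 2, (n, n))
    source = rng.normal(0.0, 1.0, (n, n))
    edges = ["top", "bottom", "left", "right"]
    n_dirichlet = int(rng.integers(0, 5))
    dirichlet_edges = list(rng.choice(edges, size=n_dirichlet, replace=False))
    if not dirichlet_edges and not np.any(reaction > 0):
        dirichlet_edges = ["left"]
    bc = {e: (float(rng.uniform(0.0, 2.0)) if e in dirichlet_edges else None)
          for e in edges}
    return D, reaction, source, bc


@pytest.fixture
def tiny_config() -> SimulationConfig:
    """A 25-site-wide lattice with the full 441-cell seed and fast solves."""
    return SimulationConfig(n=25, n_steps=10, seed_cells=441,
                            vessels=frozenset({"left", "right", "top", "bottom"}),
                            rng_seed=42)
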