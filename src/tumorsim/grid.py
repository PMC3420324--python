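"""Lattice state, continuum fields and per-step records.

The lattice is an ``n x n`` grid of sites indexed ``(row, col)`` with row 0 at
the top edge; each site holds at most one cell.  Cells are EMPTY, TUMOUR
(proliferating/migrating), QUIESCENT (alive but without free neighbouring
space) or NECROTIC (dead from nutrient deprivation; absorbing).
"""

from __future__ import annotations

import dataclasses
import enum
import math

import numpy as np

from .config import EcmInit, SimulationConfig


class CellStatus(enum.IntEnum):
    EMPTY = 0
    TUMOUR = 1      # proliferating / migrating
    QUIESCENT = 2
    NECROTIC = 3


#: Maps a vessel/edge tag to the slice of boundary sites it covers.
EDGE_SLICES = {
    "top": (0, slice(None)),
    "bottom": (-1, slice(None)),
    "left": (slice(None), 0),
    "right": (slice(None), -1),
}


@dataclasses.dataclass
class LatticeState:
    """Per-site cell status and age-since-division counters."""

    status: np.ndarray  # (n, n) int8 of CellStatus
    age: np.ndarray     # (n, n) int32; meaningful only on living sites

    @property
    def n(self) -> int:
        return self.status.shape[0]

    def copy(self) -> "LatticeState":
        return LatticeState(self.status.copy(), self.age.copy())

    def counts(self) -> dict[str, int]:
        b = np.bincount(self.status.ravel(), minlength=4)
        return {
            "tumour": int(b[CellStatus.TUMOUR]),
            "quiescent": int(b[CellStatus.QUIESCENT]),
            "necrotic": int(b[CellStatus.NECROTIC]),
        }


@dataclasses.dataclass
class Field:
    """A scalar continuum quantity on the lattice with boundary-condition tags.

    ``bc`` maps each edge tag to a Dirichlet value, or ``None`` for zero-flux
    (homogeneous Neumann).  Pointwise fields such as the ECM carry all-Neumann
    tags; they are never used.
    """

    values: np.ndarray
    bc: dict[str, float | None] = dataclasses.field(
        default_factory=lambda: {e: None for e in EDGE_SLICES})

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "Field":
        return Field(self.values.copy(), dict(self.bc))


@dataclasses.dataclass(frozen=True)
class StepRecord:
    """Cell-class counts and field summaries after one iteration."""

    step: int
    hours: float
    n_proliferating_migrating: int
    n_quiescent: int
    n_necrotic: int
    n_nonnecrotic: int
    mean_u: float

    @classmethod
    def from_state(cls, step: int, hours: float, state: LatticeState,
                   u: Field) -> "StepRecord":
        c = state.counts()
        return cls(step=step, hours=hours,
                   n_proliferating_migrating=c["tumour"],
                   n_quiescent=c["quiescent"],
                   n_necrotic=c["necrotic"],
                   n_nonnecrotic=c["tumour"] + c["quiescent"],
                   mean_u=float(u.values.mean()))

    @property
    def total_cells(self) -> int:
        return self.n_nonnecrotic + self.n_necrotic


def init_cells(config: SimulationConfig) -> LatticeState:
    """Seed a centred square block of proliferating cells (age 0)."""
    n = config.n
    s = math.isqrt(config.seed_cells)
    if s * s != config.seed_cells:
        raise ValueError("seed_cells must be a perfect square")
    if s > n:
        raise ValueError("centred seed block does not fit on the lattice")
    status = np.zeros((n, n), dtype=np.int8)
    start = (n - s) // 2
    status[start:start + s, start:start + s] = CellStatus.TUMOUR
    age = np.zeros((n, n), dtype=np.int32)
    return LatticeState(status=status, age=age)


def init_ecm(config: SimulationConfig, rng: np.random.Generator) -> Field:
    """Initial extracellular-matrix density: constant 0.8 or i.i.d. U(0,1)."""
    n = config.n
    if config.f_init is EcmInit.CONSTANT:
        values = np.full((n, n), config.f_const, dtype=float)
    else:
        values = rng.random((n, n))
    return Field(values=values)


def cell_mask(state: LatticeState, include_necrotic: bool = False) -> np.ndarray:
    """Binary cell density c: 1 on occupied sites, 0 elsewhere.

    Living cells (TUMOUR and QUIESCENT) always count; NECROTIC sites count
    only when ``include_necrotic`` is set.
    """
    s = state.status
    mask = (s == CellStatus.TUMOUR) | (s == CellStatus.QUIESCENT)
    if include_necrotic:
        mask = mask | (s == CellStatus.NECROTIC)
    return mask.astype(float)


def vessel_bc(config: SimulationConfig) -> dict[str, float | None]:
    """Boundary tags for the nutrient field: Dirichlet u_d on vessel edges."""
    return {edge: (config.u_d if edge in config.vessels else None)
            for edge in EDGE_SLICES}
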