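"""Per-iteration cell life cycle: necrosis, division, quiescence, movement.

Each living cell, visited in a uniformly random order, is updated as follows:

1. if the local nutrient concentration falls strictly below ``u_crit`` the
   cell dies (NECROTIC, permanent);
2. otherwise a neighbourhood (Moore or von Neumann, fifty-fifty) is drawn for
   this cell and step; if no free site exists in it the cell is QUIESCENT for
   the step (its division clock is frozen);
3. with free space available a quiescent cell re-enters the active TUMOUR
   state; if its age has reached the proliferation interval (16 steps of
   0.5 h for the 8-hour cycle) it divides — one daughter replaces the mother,
   the other is placed chemotactically on the free neighbour with the highest
   nutrient value (ties broken uniformly at random), both with age reset —
   otherwise it attempts one stencil-sampled move (a move into an occupied
   site is cancelled and the cell stays).

Necrotic cells are never revisited and never targeted; there is no apoptosis,
so the number of occupied sites never decreases.
"""

from __future__ import annotations

import enum

import numpy as np

from ._rng import RngStreams
from .config import SimulationConfig
from .grid import CellStatus, Field, LatticeState
from .motion import (OFFSETS5, OFFSETS9, MotionCoefficients,
                     movement_coefficients, probabilities_at)


class Neighbourhood(enum.Enum):
    VON_NEUMANN_4 = 4
    MOORE_8 = 8


NEIGH4: tuple[tuple[int, int], ...] = ((0, 1), (0, -1), (-1, 0), (1, 0))
NEIGH8: tuple[tuple[int, int], ...] = NEIGH4 + ((-1, -1), (1, 1), (1, -1), (-1, 1))


def pick_neighbourhood(rng: np.random.Generator) -> Neighbourhood:
    """Fifty-fifty choice between the Moore and von Neumann neighbourhoods."""
    return Neighbourhood.MOORE_8 if rng.random() < 0.5 else Neighbourhood.VON_NEUMANN_4


def update_order(state: LatticeState, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random permutation of the living (non-necrotic) cell sites.

    Returns an (m, 2) array of (row, col) indices.  A fixed scan order would
    systematically favour the cells visited first, so the order is re-drawn
    every iteration.
    """
    s = state.status
    living = np.argwhere((s == CellStatus.TUMOUR) | (s == CellStatus.QUIESCENT))
    if len(living) == 0:
        return living.reshape(0, 2)
    return living[rng.permutation(len(living))]


def _free_neighbours(state: LatticeState, r: int, c: int,
                     offsets: tuple[tuple[int, int], ...]) -> list[tuple[int, int]]:
    n = state.n
    status = state.status
    out = []
    for dr, dc in offsets:
        rr, cc = r + dr, c + dc
        if 0 <= rr < n and 0 <= cc < n and status[rr, cc] == CellStatus.EMPTY:
            out.append((rr, cc))
    return out


def act(site: tuple[int, int], state: LatticeState, u: Field, f: Field,
        config: SimulationConfig, rng: RngStreams,
        neighbourhood: Neighbourhood | None = None,
        coeffs: MotionCoefficients | None = None,
        acted: np.ndarray | None = None) -> str:
    """Apply the life-cycle rules to the living cell at ``site`` (in place).

    Returns one of ``"necrosis"``, ``"quiescent"``, ``"division"``, ``"move"``
    or ``"stay"`` describing the outcome.  ``coeffs`` may carry precomputed
    stencil coefficients for the current fields; ``acted`` is an optional
    boolean lattice on which newly occupied sites are flagged so the engine
    does not update a cell twice in one iteration.
    """
    r, c = site
    status = state.status
    st = status[r, c]
    if st not in (CellStatus.TUMOUR, CellStatus.QUIESCENT):
        raise RuntimeError(f"act() called on a non-living site {site}")
    uv = u.values

    # 1. necrosis from nutrient deprivation (strict inequality)
    if uv[r, c] < config.u_crit:
        status[r, c] = CellStatus.NECROTIC
        return "necrosis"

    if neighbourhood is None:
        neighbourhood = pick_neighbourhood(rng.neighbourhood)
    nb_offsets = NEIGH4 if neighbourhood is Neighbourhood.VON_NEUMANN_4 else NEIGH8
    free = _free_neighbours(state, r, c, nb_offsets)

    # 2. no free space in the drawn neighbourhood -> quiescent, clock frozen
    if not free:
        status[r, c] = CellStatus.QUIESCENT
        return "quiescent"

    # free space available: a quiescent cell re-enters the active state;
    # the division clock advances (it is frozen only while enclosed)
    status[r, c] = CellStatus.TUMOUR
    state.age[r, c] += 1

    # 3. division once the 8-hour cycle has elapsed
    if state.age[r, c] >= config.proliferation_interval:
        u_free = np.array([uv[rr, cc] for rr, cc in free])
        best = np.flatnonzero(u_free == u_free.max())
        if len(best) == 1:
            pick = best[0]
        else:
            pick = best[min(int(rng.tiebreak.random() * len(best)), len(best) - 1)]
        dr_, dc_ = free[pick]
        status[dr_, dc_] = CellStatus.TUMOUR
        state.age[dr_, dc_] = 0
        state.age[r, c] = 0
        if acted is not None:
            acted[dr_, dc_] = True
        return "division"

    # 4. stencil-sampled movement; blocked moves are cancelled
    if coeffs is None:
        coeffs = movement_coefficients(u, f, config)
    if neighbourhood is Neighbourhood.VON_NEUMANN_4:
        stack, offsets = coeffs.c5, OFFSETS5
    else:
        stack, offsets = coeffs.c9, OFFSETS9
    p = probabilities_at(stack, (r, c), state.n, offsets)
    x = rng.movement.random()
    acc = 0.0
    choice = 0
    for i in range(len(offsets)):
        acc += p[i]
        if x < acc:
            choice = i
            break
    else:   # cumulative rounding guard
        choice = len(offsets) - 1
    dr, dc = offsets[choice]
    if (dr, dc) == (0, 0):
        return "stay"
    rr, cc = r + dr, c + dc
    if status[rr, cc] != CellStatus.EMPTY:
        return "stay"
    status[rr, cc] = CellStatus.TUMOUR
    state.age[rr, cc] = state.age[r, c]
    status[r, c] = CellStatus.EMPTY
    state.age[r, c] = 0
    if acted is not None:
        acted[rr, cc] = True
    return "move"
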