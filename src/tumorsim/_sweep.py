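"""Compiled inner loop of the per-iteration cell sweep.

The engine visits every living cell once per iteration; at realistic cell
numbers this sequential loop dominates the runtime, so it is implemented
here on primitive arrays and JIT-compiled with numba when available (the
same function runs uncompiled otherwise, with identical semantics).  All
randomness is pre-drawn by the caller — one neighbourhood draw, one movement
draw and one tie-break draw per visited cell — which keeps trajectories
reproducible and independent of whether the kernel is compiled.

The life-cycle rules mirror :func:`tumorsim.actions.act`: necrosis below
``u_crit``; quiescence (frozen clock) without free space in the drawn
neighbourhood; division after the proliferation interval with chemotactic
daughter placement; otherwise one stencil-sampled move, cancelled if the
target is occupied.
"""

from __future__ import annotations

import numpy as np

# neighbourhood offsets (row, col): von Neumann first four, Moore all eight
_NB8 = np.array([(0, 1), (0, -1), (-1, 0), (1, 0),
                 (-1, -1), (1, 1), (1, -1), (-1, 1)], dtype=np.int64)
# movement offsets in stencil order: stay, E, W, N, S, NW, SE, SW, NE
_OFF9 = np.array([(0, 0), (0, 1), (0, -1), (-1, 0), (1, 0),
                  (-1, -1), (1, 1), (1, -1), (-1, 1)], dtype=np.int64)

_EMPTY, _TUMOUR, _QUIESCENT, _NECROTIC = 0, 1, 2, 3


def _sweep_impl(status, age, u, c5, c9, order, nb_draws, move_draws,
                tie_draws, u_crit, prolif_interval):
    n = status.shape[0]
    acted = np.zeros((n, n), dtype=np.uint8)
    p = np.empty(9)
    for i in range(order.shape[0]):
        r = order[i, 0]
        c = order[i, 1]
        if acted[r, c] == 1:
            continue
        st = status[r, c]
        if st != _TUMOUR and st != _QUIESCENT:
            continue  # the cell moved away earlier in this sweep

        # 1. necrosis from nutrient deprivation (strict inequality)
        if u[r, c] < u_crit:
            status[r, c] = _NECROTIC
            continue

        moore = nb_draws[i] < 0.5
        n_nb = 8 if moore else 4

        # free sites in the drawn neighbourhood; track the nutrient maximum
        n_free = 0
        best_u = -1.0
        n_best = 0
        for j in range(n_nb):
            rr = r + _NB8[j, 0]
            cc = c + _NB8[j, 1]
            if rr < 0 or rr >= n or cc < 0 or cc >= n:
                continue
            if status[rr, cc] == _EMPTY:
                n_free += 1
                uv = u[rr, cc]
                if uv > best_u:
                    best_u = uv
                    n_best = 1
                elif uv == best_u:
                    n_best += 1

        # 2. fully enclosed -> quiescent, division clock frozen
        if n_free == 0:
            status[r, c] = _QUIESCENT
            continue

        # free space available: (re-)enter the active state; the division
        # clock advances (it is frozen only while enclosed)
        status[r, c] = _TUMOUR
        age[r, c] += 1

        # 3. division once the cell cycle has elapsed: daughter on the free
        #    neighbour with the highest nutrient value, ties uniform
        if age[r, c] >= prolif_interval:
            pick = int(tie_draws[i] * n_best)
            if pick >= n_best:
                pick = n_best - 1
            seen = 0
            for j in range(n_nb):
                rr = r + _NB8[j, 0]
                cc = c + _NB8[j, 1]
                if rr < 0 or rr >= n or cc < 0 or cc >= n:
                    continue
                if status[rr, cc] == _EMPTY and u[rr, cc] == best_u:
                    if seen == pick:
                        status[rr, cc] = _TUMOUR
                        age[rr, cc] = 0
                        acted[rr, cc] = 1
                        break
                    seen += 1
            age[r, c] = 0
            continue

        # 4. stencil-sampled movement (clamp, boundary fold, renormalise)
        stack = c9 if moore else c5
        n_off = 9 if moore else 5
        p0 = stack[0, r, c]
        total = 0.0
        for j in range(1, n_off):
            rr = r + _OFF9[j, 0]
            cc = c + _OFF9[j, 1]
            v = stack[j, r, c]
            if rr < 0 or rr >= n or cc < 0 or cc >= n:
                if v > 0.0:
                    p0 += v   # zero-flux: off-grid mass folds into stay
                p[j] = 0.0
            else:
                p[j] = v if v > 0.0 else 0.0
                total += p[j]
        p[0] = p0 if p0 > 0.0 else 0.0
        total += p[0]

        choice = 0
        if total > 0.0:
            x = move_draws[i] * total
            acc = 0.0
            for j in range(n_off):
                acc += p[j]
                if x < acc:
                    choice = j
                    break

        if choice == 0:
            continue
        rr = r + _OFF9[choice, 0]
        cc = c + _OFF9[choice, 1]
        if status[rr, cc] != _EMPTY:   # blocked move is cancelled
            continue
        status[rr, cc] = _TUMOUR
        age[rr, cc] = age[r, c]
        status[r, c] = _EMPTY
        age[r, c] = 0
        acted[rr, cc] = 1


def _compile(func):
    try:
        from numba import njit
    except Exception:       # pragma: no cover - numba is normally present
        return func
    return njit(cache=True)(func)


#: The sweep entry point used by the engine (compiled when numba is present).
sweep = _compile(_sweep_impl)
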