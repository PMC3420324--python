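"""Movement probabilities from the finite-difference tumour-cell stencil.

The continuum cell equation

    dc/dt = D_c lap(c) - chi div(c grad u) - rho div(c grad f)

is discretised with forward time differences and second-order central space
differences; the resulting 5-point (von Neumann) or 9-point (Moore) stencil
coefficients are read as movement propensities of the individual cell at the
site.  The signs follow from consistency with the equation: chemotaxis and
haptotaxis bias movement *up* the nutrient and matrix gradients, i.e. the
east coefficient carries ``+ (k chi / 4h^2)(u_E - u_W)``.  Negative raw
coefficients (drift dominating diffusion) are clamped to zero and the vector
renormalised; stencil neighbours outside the domain get probability zero with
their mass folded into the stay probability (zero-flux cell movement).

The 9-point construction splits the operator into its orthogonal 5-point part
(weight 2/3) and the diagonally rotated 5-point part with spacing h*sqrt(2)
(weight 1/3), which reproduces the standard 9-point Laplacian weights of 2/3
on orthogonal and 1/6 on diagonal neighbours and uses diagonal central
differences for the drift terms.  Nothing downstream depends on this specific
weighting, only on its symmetry; it is isolated here so alternates can be
swapped in.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import SimulationConfig
from .grid import Field

#: Offset order matches the stencil-probability convention:
#: stay, right, left, up, down [, top-left, bottom-right, bottom-left, top-right]
OFFSETS5: tuple[tuple[int, int], ...] = ((0, 0), (0, 1), (0, -1), (-1, 0), (1, 0))
OFFSETS9: tuple[tuple[int, int], ...] = OFFSETS5 + ((-1, -1), (1, 1), (1, -1), (-1, 1))


@dataclasses.dataclass(frozen=True)
class MoveProbabilities:
    """A categorical distribution over lattice displacements."""

    p: np.ndarray
    offsets: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.p) != len(self.offsets):
            raise ValueError("probability/offset length mismatch")


@dataclasses.dataclass(frozen=True)
class MotionCoefficients:
    """Raw (unclamped) stencil coefficient arrays for a whole lattice.

    ``c5``/``c9`` have shape (5, n, n)/(9, n, n) in the OFFSETS5/OFFSETS9
    order; computing them once per iteration amortises the cost over all
    cells.
    """

    c5: np.ndarray
    c9: np.ndarray

    @property
    def n(self) -> int:
        return self.c5.shape[1]


def _as_values(field) -> np.ndarray:
    return field.values if isinstance(field, Field) else np.asarray(field, float)


def movement_coefficients(u, f, config: SimulationConfig) -> MotionCoefficients:
    """Raw stencil coefficients at every site (edge-replicated at boundaries).

    Boundary sites use replicated neighbour values in the differences; the
    off-grid directions themselves are zeroed during per-site assembly.
    """
    uv = _as_values(u)
    fv = _as_values(f)
    n = uv.shape[0]
    k, h = config.k, 1.0 / n
    h2 = h * h
    a = k * config.D_c / h2            # orthogonal diffusion propensity
    cu = k * config.chi / (4.0 * h2)   # orthogonal drift prefactor (nutrient)
    cf = k * config.rho / (4.0 * h2)   # orthogonal drift prefactor (matrix)

    up = np.pad(uv, 1, mode="edge")
    fp = np.pad(fv, 1, mode="edge")
    mid = np.s_[1:-1]

    def shifts(p):
        return dict(
            E=p[mid, 2:], W=p[mid, :-2], N=p[:-2, mid], S=p[2:, mid],
            NE=p[:-2, 2:], NW=p[:-2, :-2], SE=p[2:, 2:], SW=p[2:, :-2])

    su, sf = shifts(up), shifts(fp)

    drift_e = cu * (su["E"] - su["W"]) + cf * (sf["E"] - sf["W"])
    drift_n = cu * (su["N"] - su["S"]) + cf * (sf["N"] - sf["S"])
    lap5 = (cu * 4.0 * (su["E"] + su["W"] + su["N"] + su["S"] - 4.0 * uv)
            + cf * 4.0 * (sf["E"] + sf["W"] + sf["N"] + sf["S"] - 4.0 * fv))
    stay5 = 1.0 - 4.0 * a - lap5
    c5 = np.stack([stay5, a + drift_e, a - drift_e, a + drift_n, a - drift_n])

    # diagonal (rotated) part: spacing h*sqrt(2) doubles the squared spacing
    ad = a / 2.0
    drift_ne = (cu * (su["NE"] - su["SW"]) + cf * (sf["NE"] - sf["SW"])) / 2.0
    drift_nw = (cu * (su["NW"] - su["SE"]) + cf * (sf["NW"] - sf["SE"])) / 2.0
    lapx = (cu * 2.0 * (su["NE"] + su["NW"] + su["SE"] + su["SW"] - 4.0 * uv)
            + cf * 2.0 * (sf["NE"] + sf["NW"] + sf["SE"] + sf["SW"] - 4.0 * fv))
    stayx = 1.0 - 4.0 * ad - lapx
    w_o, w_d = 2.0 / 3.0, 1.0 / 3.0
    c9 = np.stack([
        w_o * stay5 + w_d * stayx,
        w_o * (a + drift_e), w_o * (a - drift_e),
        w_o * (a + drift_n), w_o * (a - drift_n),
        w_d * (ad + drift_nw),   # top-left
        w_d * (ad - drift_nw),   # bottom-right
        w_d * (ad - drift_ne),   # bottom-left
        w_d * (ad + drift_ne),   # top-right
    ])
    return MotionCoefficients(c5=c5, c9=c9)


def probabilities_at(stack: np.ndarray, site: tuple[int, int], n: int,
                     offsets: tuple[tuple[int, int], ...]) -> np.ndarray:
    """Clamp, boundary-fold and normalise the raw coefficients at one site."""
    r, c = site
    raw = stack[:, r, c].copy()
    if r == 0 or r == n - 1 or c == 0 or c == n - 1:
        for i in range(1, len(offsets)):
            rr, cc = r + offsets[i][0], c + offsets[i][1]
            if not (0 <= rr < n and 0 <= cc < n):
                if raw[i] > 0.0:
                    raw[0] += raw[i]
                raw[i] = 0.0
    p = np.maximum(raw, 0.0)
    total = p.sum()
    if total <= 0.0:        # degenerate: every propensity clamped away
        p[:] = 0.0
        p[0] = 1.0
        return p
    return p / total


def stencil5(u, f, site: tuple[int, int], config: SimulationConfig,
             coeffs: MotionCoefficients | None = None) -> MoveProbabilities:
    """Movement distribution over the von Neumann neighbourhood (plus stay)."""
    if coeffs is None:
        coeffs = movement_coefficients(u, f, config)
    p = probabilities_at(coeffs.c5, site, coeffs.n, OFFSETS5)
    return MoveProbabilities(p=p, offsets=OFFSETS5)


def stencil9(u, f, site: tuple[int, int], config: SimulationConfig,
             coeffs: MotionCoefficients | None = None) -> MoveProbabilities:
    """Movement distribution over the Moore neighbourhood (plus stay)."""
    if coeffs is None:
        coeffs = movement_coefficients(u, f, config)
    p = probabilities_at(coeffs.c9, site, coeffs.n, OFFSETS9)
    return MoveProbabilities(p=p, offsets=OFFSETS9)


def sample_move(p: MoveProbabilities, rng: np.random.Generator) -> tuple[int, int]:
    """Draw one displacement from the categorical distribution."""
    x = rng.random()
    acc = 0.0
    for prob, offset in zip(p.p, p.offsets):
        acc += prob
        if x < acc:
            return offset
    return p.offsets[-1]    # guard against rounding in the cumulative sum
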