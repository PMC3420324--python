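"""Simulation configuration, nondimensionalisation and experiment presets.

All computation happens in the nondimensional frame: the tissue patch is the
unit square covered by an ``n x n`` lattice with spacing ``h = 1/n``, and all
rates/diffusivities are the dimensionless ones obtained by rescaling lengths
by ``L`` and time by ``tau = L**2 / D`` with a reference diffusivity ``D``.
One iteration of the cellular automaton represents ``hours_per_step`` physical
hours, which fixes the dimensionless time-step
``k = hours_per_step * 3600 / tau`` (0.18 with the defaults).
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import NamedTuple

#: Reference length scale L in cm used for nondimensionalisation.
REF_LENGTH_CM = 0.1
#: Reference diffusivity D in cm^2/s defining the time scale tau = L^2/D.
REF_DIFFUSIVITY_CM2_S = 1e-6

VALID_EDGES = frozenset({"left", "right", "top", "bottom"})


class ModelVariant(str, enum.Enum):
    """Which continuum system is coupled to the automaton.

    ``SIMPLIFIED`` ("A"): tumour cells degrade the extracellular matrix
    directly (no enzyme field).  ``MDE`` ("B"): matrix-degrading enzymes are
    simulated explicitly as a diffusing field produced by living cells.
    """

    SIMPLIFIED = "A"
    MDE = "B"


class EcmInit(str, enum.Enum):
    CONSTANT = "constant"
    RANDOM = "random"


class MdeMode(str, enum.Enum):
    """How the enzyme field is advanced each iteration.

    ``STEADY`` (default): quasi-steady balance of diffusion, production and
    decay, with the enzyme washed out (m = 0) at the perfused boundary —
    consistent with treating enzyme diffusion, like nutrient diffusion, as
    fast relative to cell dynamics.  ``TRANSIENT``: one implicit-Euler step
    of the time-dependent equation with zero-flux boundaries per iteration;
    with zero decay the enzyme then accumulates without bound and eventually
    annihilates the matrix everywhere.
    """

    STEADY = "steady"
    TRANSIENT = "transient"


class Nondimensional(NamedTuple):
    """Result of :func:`nondimensionalise`."""

    tau_s: float      # time scale in seconds
    D_u_hat: float    # dimensionless nutrient diffusivity


def nondimensionalise(L: float, D: float, D_u_dim: float) -> Nondimensional:
    """Derive the time scale and dimensionless nutrient diffusivity.

    Parameters
    ----------
    L : reference length in cm.
    D : reference diffusivity in cm^2/s (sets ``tau = L**2 / D``).
    D_u_dim : dimensional nutrient diffusivity in cm^2/s.
    """
    if L <= 0 or D <= 0 or D_u_dim <= 0:
        raise ValueError("nondimensionalise requires strictly positive inputs")
    tau = L * L / D
    return Nondimensional(tau_s=tau, D_u_hat=tau * D_u_dim / (L * L))


def stability_check(k: float, alpha_f: float, beta_f: float) -> bool:
    """Explicit-Euler stability of the pointwise ECM update.

    The ECM equation is solved with an explicit Euler step; in the worst case
    of full cell occupancy (c -> 1) the amplification factor is
    ``1 - k*alpha_f + k*beta_f``, which must have magnitude <= 1.
    """
    if k <= 0:
        raise ValueError("time-step k must be positive")
    return abs(1.0 - k * alpha_f + k * beta_f) <= 1.0


def _is_perfect_square(x: int) -> bool:
    if x < 1:
        return False
    s = math.isqrt(x)
    return s * s == x


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """All dimensionless parameters, lattice geometry and run controls.

    Defaults reproduce the reference glioma setup: a 400 x 400 lattice seeded
    with a centred 21 x 21 block of 441 tumour cells, run for 700 half-hour
    iterations (350 h).  Construction validates every invariant, including
    the explicit-Euler stability requirement for the ECM update.
    """

    model_variant: ModelVariant = ModelVariant.SIMPLIFIED
    n: int = 400
    hours_per_step: float = 0.5
    n_steps: int = 700
    # tumour cells
    D_c: float = 1e-5
    rho: float = 0.26            # haptotaxis coefficient
    chi: float | None = None     # chemotaxis coefficient; None -> equal to rho
    # nutrient
    D_u: float = 10.0
    alpha_u: float = 6.25e-5
    u_d: float = 1.0             # Dirichlet nutrient value at vessels
    u_crit: float = 0.4          # necrosis threshold
    u_hypoxia: float = 0.5       # mean-nutrient hypoxia threshold
    # ECM, variant A (direct degradation by cells)
    alpha_f: float = 0.01
    beta_f: float = 0.001
    # ECM + MDE, variant B
    alpha_f_tilde: float = 1.0
    beta_f_tilde: float = 0.015
    D_m: float = 0.08
    beta_m: float = 1.0
    alpha_m: float = 0.0
    mde_mode: MdeMode = MdeMode.STEADY
    # initial conditions
    f_init: EcmInit = EcmInit.CONSTANT
    f_const: float = 0.8
    vessels: frozenset[str] = frozenset({"left", "bottom"})
    seed_cells: int = 441
    rng_seed: int = 0
    # dimensionless time-step; None -> derived from hours_per_step and tau
    k: float | None = None
    # refresh the nutrient solve every j steps (performance knob; 1 = every step)
    nutrient_refresh_every: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_variant", ModelVariant(self.model_variant))
        object.__setattr__(self, "f_init", EcmInit(self.f_init))
        object.__setattr__(self, "mde_mode", MdeMode(self.mde_mode))
        object.__setattr__(self, "vessels", frozenset(self.vessels))
        if self.chi is None:
            object.__setattr__(self, "chi", self.rho)
        if self.k is None:
            object.__setattr__(self, "k", self.hours_per_step * 3600.0 / self.tau)
        self._validate()

    # -- derived quantities -------------------------------------------------
    @property
    def h(self) -> float:
        """Lattice spacing; h*n = 1 by construction."""
        return 1.0 / self.n

    @property
    def tau(self) -> float:
        """Time scale tau = L^2/D in seconds."""
        return nondimensionalise(REF_LENGTH_CM, REF_DIFFUSIVITY_CM2_S,
                                 REF_DIFFUSIVITY_CM2_S).tau_s

    @property
    def proliferation_interval(self) -> int:
        """Cell-cycle length in iterations (8 h of proliferation)."""
        return round(8.0 / self.hours_per_step)

    @property
    def total_hours(self) -> float:
        return self.n_steps * self.hours_per_step

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        if self.n < 3:
            raise ValueError("lattice side n must be at least 3")
        if self.hours_per_step <= 0:
            raise ValueError("hours_per_step must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        for name in ("D_c", "rho", "chi", "D_u", "alpha_u", "alpha_f", "beta_f",
                     "alpha_f_tilde", "beta_f_tilde", "D_m", "beta_m", "alpha_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")
        if not (0.0 < self.u_crit <= 1.0):
            raise ValueError("u_crit must lie in (0, 1]")
        if not self.vessels:
            raise ValueError("at least one vessel edge is required")
        if not self.vessels <= VALID_EDGES:
            raise ValueError(f"vessels must be a subset of {sorted(VALID_EDGES)}")
        if not _is_perfect_square(self.seed_cells):
            raise ValueError("seed_cells must be a perfect square (centred square seeding)")
        if math.isqrt(self.seed_cells) > self.n:
            raise ValueError("centred seed block does not fit on the lattice")
        if self.proliferation_interval < 1:
            raise ValueError("proliferation interval must be at least one step")
        if self.nutrient_refresh_every < 1:
            raise ValueError("nutrient_refresh_every must be >= 1")
        if not stability_check(self.k, self.alpha_f, self.beta_f):
            raise ValueError(
                "ECM Euler update unstable: |1 - k*alpha_f + k*beta_f| > 1 "
                f"(k={self.k}, alpha_f={self.alpha_f}, beta_f={self.beta_f})")

    def replace(self, **changes) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model_variant"] = self.model_variant.value
        d["f_init"] = self.f_init.value
        d["mde_mode"] = self.mde_mode.value
        d["vessels"] = sorted(self.vessels)
        return d


# -- presets -----------------------------------------------------------------

_PRESETS: dict[str, dict] = {
    # two neighbouring vessels (left + bottom), homogeneous ECM, 350 h
    "fig3_adjacent_vessels_constant_ecm": dict(
        vessels=frozenset({"left", "bottom"}), f_init=EcmInit.CONSTANT, n_steps=700),
    # two parallel vessels (left + right), homogeneous ECM, 350 h
    "fig4_parallel_vessels_constant_ecm": dict(
        vessels=frozenset({"left", "right"}), f_init=EcmInit.CONSTANT, n_steps=700),
    # a single vessel on the right, homogeneous ECM, 375 h
    "fig5_one_vessel_constant_ecm": dict(
        vessels=frozenset({"right"}), f_init=EcmInit.CONSTANT, n_steps=750),
    # vessels on all four sides, heterogeneous (random) ECM, 375 h
    "fig6_all_vessels_random_ecm": dict(
        vessels=frozenset(VALID_EDGES), f_init=EcmInit.RANDOM, n_steps=750),
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str, **overrides) -> SimulationConfig:
    """Return the configuration for a named experiment.

    ``overrides`` are applied on top of the preset (e.g. ``model_variant="B"``,
    ``n=100`` for a reduced-lattice run).
    """
    try:
        base = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {', '.join(preset_names())}"
        ) from None
    params = {**base, **overrides}
    return SimulationConfig(**params)
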