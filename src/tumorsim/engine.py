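"""Coupled per-iteration loop, full runs, ensembles and run comparison.

One iteration: (1) solve the quasi-steady nutrient field on the current cell
mask; (2) advance the matrix — directly degraded by living cells in the
simplified variant, or via the enzyme field in the MDE variant; (3) visit
every living cell in random order and apply the life-cycle rules; (4) record
the cell-class counts and mean nutrient level.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._rng import RngStreams, child_seeds
from ._sweep import sweep
from .actions import update_order
from .config import ModelVariant, SimulationConfig
from .continuum import (MdeSolver, ecm_step, ecm_step_mde, nutrient_initial,
                        nutrient_steady)
from .grid import (CellStatus, Field, LatticeState, StepRecord, cell_mask,
                   init_cells, init_ecm)
from .motion import movement_coefficients


@dataclasses.dataclass
class SimulationFields:
    """The continuum fields carried between iterations."""

    u: Field            # nutrient
    f: Field            # extracellular matrix
    m: Field | None     # matrix-degrading enzymes (MDE variant only)


@dataclasses.dataclass
class SimulationResult:
    config: SimulationConfig
    records: list[StepRecord]
    state: LatticeState
    fields: SimulationFields
    hypoxia_onset_step: int | None   # first step with mean u < u_hypoxia

    def frame(self) -> pd.DataFrame:
        return records_frame(self.records)

    @property
    def hypoxia_onset_hours(self) -> float | None:
        if self.hypoxia_onset_step is None:
            return None
        return self.hypoxia_onset_step * self.config.hours_per_step


def records_frame(records: list[StepRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def step(state: LatticeState, fields: SimulationFields,
         config: SimulationConfig, rng: RngStreams, step_idx: int,
         mde_solver: MdeSolver | None = None) -> StepRecord:
    """Advance the coupled system by one iteration (mutates state/fields)."""
    try:
        if (step_idx - 1) % config.nutrient_refresh_every == 0 or fields.u is None:
            fields.u = nutrient_steady(state, config)
        live = cell_mask(state, include_necrotic=False)
        if config.model_variant is ModelVariant.SIMPLIFIED:
            fields.f = ecm_step(fields.f, live, config.alpha_f, config.beta_f,
                                config.k)
        else:
            fields.m = (mde_solver or MdeSolver(config)).step(fields.m, live)
            fields.f = ecm_step_mde(fields.f, fields.m, config)
    except Exception as exc:
        raise RuntimeError(f"continuum solve failed at step {step_idx}") from exc

    coeffs = movement_coefficients(fields.u, fields.f, config)
    order = update_order(state, rng.order)
    m = len(order)
    # one draw per visited cell from each named substream, pre-drawn so the
    # compiled sweep kernel and any fallback consume randomness identically
    sweep(state.status, state.age, fields.u.values,
          coeffs.c5, coeffs.c9, order.astype(np.int64),
          rng.neighbourhood.random(m), rng.movement.random(m),
          rng.tiebreak.random(m),
          float(config.u_crit), int(config.proliferation_interval))
    return StepRecord.from_state(step_idx, step_idx * config.hours_per_step,
                                 state, fields.u)


def run(config: SimulationConfig, rng_seed: int | None = None) -> SimulationResult:
    """Run a full simulation; reports the hypoxia onset step if reached."""
    if rng_seed is not None:
        config = config.replace(rng_seed=rng_seed)
    rng = RngStreams(config.rng_seed)
    state = init_cells(config)
    fields = SimulationFields(
        u=nutrient_initial(state, config),
        f=init_ecm(config, rng.ecm),
        m=Field(np.zeros((config.n, config.n)))
        if config.model_variant is ModelVariant.MDE else None)
    mde_solver = (MdeSolver(config)
                  if config.model_variant is ModelVariant.MDE else None)

    records = [StepRecord.from_state(0, 0.0, state, fields.u)]
    hypoxia: int | None = 0 if records[0].mean_u < config.u_hypoxia else None
    for step_idx in range(1, config.n_steps + 1):
        rec = step(state, fields, config, rng, step_idx, mde_solver=mde_solver)
        records.append(rec)
        if hypoxia is None and rec.mean_u < config.u_hypoxia:
            hypoxia = step_idx
    return SimulationResult(config=config, records=records, state=state,
                            fields=fields, hypoxia_onset_step=hypoxia)


_COUNT_COLUMNS = ("n_proliferating_migrating", "n_quiescent", "n_necrotic",
                  "n_nonnecrotic", "mean_u")


@dataclasses.dataclass
class EnsembleResult:
    """Per-step mean and standard error over repeated seeded runs."""

    config: SimulationConfig
    seeds: np.ndarray
    mean: pd.DataFrame   # index: step; columns: _COUNT_COLUMNS
    se: pd.DataFrame     # standard error of the mean (SD/sqrt(n_runs))

    @property
    def n_runs(self) -> int:
        return len(self.seeds)

    def frame(self) -> pd.DataFrame:
        mean = self.mean.add_suffix("_mean")
        se = self.se.add_suffix("_se")
        out = pd.concat([mean, se], axis=1)
        out.insert(0, "hours", out.index * self.config.hours_per_step)
        return out.reset_index(names="step")


def run_ensemble(config: SimulationConfig, n_runs: int,
                 base_seed: int | None = None,
                 seeds: np.ndarray | None = None) -> EnsembleResult:
    """Repeat a run with independent seeds and average the step records.

    Seeds are derived deterministically from ``base_seed`` (default: the
    config's own seed) unless given explicitly.
    """
    if seeds is None:
        if n_runs < 2:
            raise ValueError("an ensemble needs at least two runs")
        seeds = child_seeds(config.rng_seed if base_seed is None else base_seed,
                            n_runs)
    seeds = np.asarray(seeds)
    stacks = []
    for seed in seeds:
        result = run(config, rng_seed=int(seed))
        stacks.append(result.frame()[list(_COUNT_COLUMNS)].to_numpy())
    cube = np.stack(stacks)   # (runs, steps+1, columns)
    steps = np.arange(cube.shape[1])
    mean = pd.DataFrame(cube.mean(axis=0), index=steps, columns=_COUNT_COLUMNS)
    sd = cube.std(axis=0, ddof=1) if len(seeds) > 1 else np.zeros_like(cube[0])
    se = pd.DataFrame(sd / np.sqrt(len(seeds)), index=steps,
                      columns=_COUNT_COLUMNS)
    mean.index.name = se.index.name = "step"
    return EnsembleResult(config=config, seeds=seeds, mean=mean, se=se)


#: Difference-image codes: 0 agree, +1 occupied in A only, -1 occupied in B
#: only; both occupied with differing status maps to 10*status_A + status_B.
def difference_image(state_a: LatticeState, state_b: LatticeState) -> np.ndarray:
    """Site-wise comparison of two runs' final cell distributions."""
    sa, sb = state_a.status, state_b.status
    if sa.shape != sb.shape:
        raise ValueError("lattice shapes differ")
    occ_a = sa != CellStatus.EMPTY
    occ_b = sb != CellStatus.EMPTY
    out = np.zeros(sa.shape, dtype=np.int16)
    out[occ_a & ~occ_b] = 1
    out[occ_b & ~occ_a] = -1
    both_diff = occ_a & occ_b & (sa != sb)
    out[both_diff] = 10 * sa[both_diff].astype(np.int16) + sb[both_diff]
    return out
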