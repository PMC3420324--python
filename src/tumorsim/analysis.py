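"""Parameter-estimation sweep over the ECM degradation/remodelling rates.

The direct-degradation variant needs values for the degradation rate
``alpha_f`` and remodelling rate ``beta_f`` that keep the matrix density in a
realistic balance: the enzyme concentration at a tumour site is below the
cell density's maximum of 1, so ``alpha_f`` varies in (0, 1); ``beta_f`` is
bounded above by the enzyme model's remodelling rate 0.015.  Pairs violating
the explicit-Euler stability bound are flagged and skipped.  For each
admissible pair the full simplified-variant simulation is run to an
evaluation time and the ECM value at the domain centre plus a mid-lattice
profile are recorded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ModelVariant, SimulationConfig, stability_check
from .engine import run
from .grid import Field


def profile_extract(f: Field, axis: str = "row") -> np.ndarray:
    """Mid-row (``axis="row"``) or mid-column slice of a field."""
    n = f.n
    if axis == "row":
        return f.values[n // 2, :].copy()
    if axis == "column":
        return f.values[:, n // 2].copy()
    raise ValueError("axis must be 'row' or 'column'")


def sweep_alpha_beta(alpha_grid, beta_grid, config: SimulationConfig,
                     t_eval_hours: float = 325.0
                     ) -> tuple[pd.DataFrame, dict[tuple[float, float], np.ndarray]]:
    """Grid sweep of (alpha_f, beta_f) on the simplified variant.

    Returns a table with one row per pair — ``alpha_f``, ``beta_f``,
    ``stable`` (explicit-Euler admissibility), ``centre_ecm`` (NaN for
    skipped pairs) — and a dict of mid-row ECM profiles keyed by pair.
    ``config`` controls the lattice size and everything else; its step count
    is overridden so the run ends at ``t_eval_hours``.
    """
    alpha_grid = list(alpha_grid)
    beta_grid = list(beta_grid)
    if not alpha_grid or not beta_grid:
        raise ValueError("alpha/beta grids must be non-empty")
    n_steps = round(t_eval_hours / config.hours_per_step)
    rows = []
    profiles: dict[tuple[float, float], np.ndarray] = {}
    for alpha in alpha_grid:
        for beta in beta_grid:
            stable = stability_check(config.k, alpha, beta)
            centre = np.nan
            if stable:
                cfg = config.replace(model_variant=ModelVariant.SIMPLIFIED,
                                     alpha_f=alpha, beta_f=beta,
                                     n_steps=n_steps)
                result = run(cfg)
                f = result.fields.f
                centre = float(f.values[cfg.n // 2, cfg.n // 2])
                profiles[(alpha, beta)] = profile_extract(f, "row")
            rows.append(dict(alpha_f=alpha, beta_f=beta, stable=stable,
                             centre_ecm=centre))
    return pd.DataFrame(rows), profiles
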