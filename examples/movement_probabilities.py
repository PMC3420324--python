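"""Inspect the stencil-derived movement probabilities of a single cell.

The finite-difference stencil of the cell-migration equation is read as a
categorical distribution over staying and moving to the 4 (von Neumann) or
8 (Moore) neighbours.  With flat fields the walk is unbiased; a nutrient
gradient tilts the distribution up-gradient (chemotaxis), and a matrix
gradient does the same (haptotaxis).
"""

import numpy as np

from tumorsim import SimulationConfig, stencil5, stencil9

config = SimulationConfig(n=20, seed_cells=1)
site = (10, 10)
flat_u = np.ones((20, 20))
flat_f = np.full((20, 20), 0.8)

labels5 = ["stay", "east", "west", "north", "south"]

mp = stencil5(flat_u, flat_f, site, config)
print("flat fields (unbiased walk):")
for name, p in zip(labels5, mp.p):
    print(f"  {name:>6}: {p:.4f}")

slope_u = np.tile(np.linspace(0.9, 1.0, 20), (20, 1))   # u rises eastward
mp = stencil5(slope_u, flat_f, site, config)
print("\nnutrient rising to the east (chemotactic bias):")
for name, p in zip(labels5, mp.p):
    print(f"  {name:>6}: {p:.4f}")

mp9 = stencil9(slope_u, flat_f, site, config)
print("\nsame gradient, Moore neighbourhood: "
      f"P(NE)={mp9.p[8]:.4f} P(SE)={mp9.p[6]:.4f} "
      f"P(NW)={mp9.p[5]:.4f} P(SW)={mp9.p[7]:.4f}")
print("probabilities sum to", round(float(mp9.p.sum()), 12))
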