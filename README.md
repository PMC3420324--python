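# tumorsim

Hybrid continuum–discrete simulation of avascular tumour growth on a
lattice, built to compare two formulations of how a growing tumour remodels
its extracellular matrix (ECM): the *common* approach, which explicitly
simulates a diffusing field of matrix-degrading enzymes (MDEs, e.g. uPA and
MMPs) secreted by the cells, and a *simplified* approach in which the cells —
which overexpress those enzymes — degrade the matrix directly, eliminating
one reaction–diffusion equation and its solve from every iteration.

The package is aimed at mathematical-oncology work on glioma-like tumours:
it reproduces the classic avascular morphology (necrotic core, quiescent
rim, outer rim of proliferating/migrating cells), quantifies how vessel
placement and matrix heterogeneity shape invasion, and measures how far the
simplified matrix model can stand in for the enzyme-resolved one.

## Model

Tumour cells live on an `n x n` lattice over the unit square (one cell per
site, binary density `c`), coupled to continuum fields: nutrient `u`,
matrix density `f`, and — in the enzyme variant — MDE concentration `m`.
All quantities are dimensionless (lengths scaled by `L = 0.1 cm`, time by
`tau = L^2/D = 10^4 s`).

Simplified variant (A):

    dc/dt = D_c lap(c) - chi div(c grad u) - rho div(c grad f)
    du/dt = D_u lap(u) - alpha_u u c
    df/dt = -alpha_f f c + beta_f f

Enzyme variant (B) replaces the matrix equation and adds the enzyme field:

    df/dt = -alpha_f~ f m + beta_f~ f
    dm/dt = D_m lap(m) + beta_m c - alpha_m m

Nutrient enters through blood vessels on selected domain edges (Dirichlet
`u = u_d = 1`; zero flux elsewhere) and is solved quasi-steadily each
iteration; the enzyme field is likewise equilibrated by default (see
`docs/methods.md`).  The cell equation is never integrated directly:
its explicit finite-difference stencil coefficients (5-point/von Neumann or
9-point/Moore, chosen fifty-fifty per cell per step) are renormalised into
movement probabilities, so chemotaxis and haptotaxis bias individual cells
up the nutrient and matrix gradients.  Each cell, visited in random order,
dies if `u < u_crit = 0.4` (necrosis, permanent), divides every 8 h when
space allows (the second daughter is placed on the free neighbour with the
highest nutrient), falls quiescent when enclosed, and otherwise performs
one sampled move.  There is no apoptosis.

## Worked example

`examples/single_run.py` grows a tumour from a centred 441-cell seed on a
reduced 100 x 100 lattice, with vessels on the left and bottom edges:

```
lattice 100x100, 90 steps (45 h), vessels: ['bottom', 'left']
  step   hours  prolif  quiesc  necrot   mean u
     0     0.0     441       0       0  1.01378
    15     7.5     423      18       0  1.00000
    30    15.0     816      50       0  1.00000
    45    22.5    1418     228       0  1.00000
    60    30.0    1897     925       0  1.00000
    75    37.5    2146    2158       0  1.00000
    90    45.0    2698    3333       0  1.00000

final occupied sites: 6031 (started from 441)
hypoxia onset: not reached
centre ECM after degradation: 0.7167
```

The proliferating/migrating rim (`prolif`) expands while the enclosed bulk
falls quiescent; the matrix at the permanently occupied centre decays
geometrically (0.8 -> 0.7167 after 90 steps of degradation).  The mean
nutrient starts above the vessel level because the initial field includes a
cerebrospinal-fluid supply term, then relaxes to the quasi-steady balance.
With the literature uptake rate `alpha_u = 6.25e-5`, nutrient depletion on
a reduced lattice is too weak to trigger necrosis or hypoxia; those
pathways are exercised directly in the test suite.

Other examples: `movement_probabilities.py` (stencil probabilities and
taxis bias), `rate_sweep.py` (degradation/remodelling-rate sweep with
stability flags), `variant_comparison.py` (simplified vs enzyme variant,
ensembles and difference image).

A thin CLI wraps the same library:

```sh
tumorsim run --preset fig3_adjacent_vessels_constant_ecm --n 100 \
    --steps 200 --seed 7 --out run1/ --png
tumorsim ensemble --preset fig6_all_vessels_random_ecm --variant B \
    --n 100 --steps 200 --runs 20 --out ensB.csv
tumorsim diff runA/final.npz runB/final.npz --out diff.csv
```

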