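# Methods

## Model overview

`tumorsim` couples a lattice cellular automaton of individually tracked
tumour cells to continuum reaction–diffusion fields on the same grid.  The
domain is the unit square, covered by an `n x n` lattice of spacing
`h = 1/n`; each site holds at most one cell, and the binary cell density
`c` (1 on occupied sites) is what the continuum equations see.  All
quantities are dimensionless: lengths are scaled by `L = 0.1 cm`, time by
`tau = L^2/D = 10^4 s` (with `D = 1e-6 cm^2/s` a representative diffusion
coefficient), and concentrations by their reference values.  One iteration
represents `hours_per_step` (default 0.5 h), fixing the dimensionless step
`k = hours_per_step * 3600 / tau = 0.18`; the default horizon of 700
iterations is 350 h, and the 8-hour cell cycle is 16 iterations.

Two model variants share the cell rules and the nutrient equation and
differ in how the extracellular matrix `f` is degraded:

* **Variant A (simplified)** — cells degrade the matrix directly:
  `df/dt = -alpha_f f c + beta_f f`.
* **Variant B (enzyme-resolved)** — a matrix-degrading-enzyme field `m`
  produced by living cells mediates degradation:
  `df/dt = -alpha_f~ f m + beta_f~ f`, `dm/dt = D_m lap(m) + beta_m c - alpha_m m`.

The scientific question the package makes testable is how much of variant
B's behaviour survives the elimination of the enzyme field.

## Parameters

| name | meaning | default | notes |
| --- | --- | --- | --- |
| `D_c` | cell motility (diffusion) | 1e-5 | dimensionless, from the glioma literature |
| `chi` | chemotaxis coefficient | = `rho` | cells equally attracted to nutrient and matrix |
| `rho` | haptotaxis coefficient | 0.26 | |
| `D_u` | nutrient diffusivity | 10 | `tau * 1e-5 cm^2/s / L^2` |
| `alpha_u` | nutrient uptake rate | 6.25e-5 | per occupied site |
| `u_d` | vessel nutrient level | 1 | Dirichlet value at vessel edges |
| `u_crit` | necrosis threshold | 0.4 | strict inequality kills |
| `u_hypoxia` | hypoxia threshold on mean `u` | 0.5 | reported, never halts a run |
| `alpha_f`, `beta_f` | variant-A degradation/remodelling | 0.01, 0.001 | chosen by the rate sweep (below) |
| `alpha_f~`, `beta_f~` | variant-B degradation/remodelling | 1, 0.015 | literature values |
| `D_m`, `beta_m`, `alpha_m` | enzyme diffusion/production/decay | 0.08, 1, 0 | |
| `seed_cells` | initial cells (centred square) | 441 | 21 x 21 block |
| `f_const` | homogeneous initial matrix | 0.8 | high but below the maximal density 1 |

Constructing a configuration validates every invariant (rates non-negative,
vessels non-empty, perfect-square seed that fits, `u_crit` in (0, 1], the
stability bound below) and fails loudly otherwise.

## Numerical scheme

**Nutrient.**  Oxygen/glucose diffusion is fast relative to cell dynamics,
so `u` is quasi-steady: each iteration solves
`-D_u lap(u) + alpha_u c u = 0` with `u = u_d` on vessel edges and zero
flux elsewhere.  Uptake counts every occupied site — tumour, quiescent and
necrotic alike — because the continuum density `c` covers the whole lesion;
only living cells act as sources for matrix degradation and enzyme
production.  At `t = 0` the same operator with a unit source (nutrient
delivered through the cerebrospinal fluid) provides the initial field,
which is why the recorded mean nutrient starts slightly above `u_d`.
Discretisation is the 5-point finite-difference stencil on the uniform
grid; on such a grid bilinear finite elements assemble the same stencil
structure, so nothing downstream distinguishes the two.  Neumann edges are
closed by first-order ghost-node reflection (the off-grid neighbour is
identified with the centre, i.e. dropped); Dirichlet nodes stay in the
system as identity rows.  The system is solved by direct sparse LU — no
iterative-tolerance ambiguity — and the relative residual is checked
against 1e-8.  An all-Neumann problem with zero reaction is rejected as
ill-posed.  The discrete maximum principle (`0 <= u <= u_d` for the
source-free solve) is asserted in tests against a dense, independently
assembled oracle.

**Matrix.**  The matrix equations contain no spatial operator, so they are
pointwise explicit-Euler updates: `f <- f (1 - k alpha c + k beta)` (and
the `m`-mediated analogue in variant B).  With constant occupancy this is
exactly geometric, which the tests exploit as a closed-form oracle.  The
worst-case (`c -> 1`) amplification factor must satisfy
`|1 - k alpha_f + k beta_f| <= 1`; configurations violating it are
rejected.  Updates floor `f` at zero: in variant B the enzyme level is not
bounded a priori, and a matrix density cannot go negative.  No boundary
condition applies to `f` (the equation is an ODE per site).

**Enzymes.**  The enzyme field defaults to the same quasi-steady treatment
as the nutrient: `-D_m lap(m) + alpha_m m = beta_m c` solved each iteration
with `m = 0` on the whole boundary, representing washout of enzyme at the
perfused edge of the tissue patch.  The steady problem with the nominal
zero decay (`alpha_m = 0`) and zero-flux boundaries would be singular, so a
washout condition is required for well-posedness.  A transient alternative
(`mde_mode="transient"`: one implicit-Euler step of length `k` per
iteration, zero-flux boundaries) is kept as an option and oracle-tested,
but it is not the default for a substantive reason: with `beta_m = 1` and
no decay the transient enzyme field grows without bound (reaching ~5 on a
100-lattice after 200 steps, versus the matrix equilibrium level
`beta_f~ / alpha_f~ = 0.015`), which drives `f` to exactly zero everywhere
and silently removes haptotaxis from variant B.  The quasi-steady field
stays order 0.1–1 near the tumour and small far away, so the matrix is
reduced in a halo around the lesion rather than annihilated globally —
the behaviour the enzyme-resolved model family is meant to produce.  The
operator is constant over a run, so its LU factorisation is reused.

**Cell movement.**  The migration equation
`dc/dt = D_c lap(c) - chi div(c grad u) - rho div(c grad f)` is discretised
with forward time and second-order central space differences, and the
stencil coefficients are read as movement propensities for the cell at the
site: e.g. the east coefficient is
`k D_c / h^2 + (k chi / 4 h^2)(u_E - u_W) + (k rho / 4 h^2)(f_E - f_W)`.
The signs follow from consistency with the conservative form of the
equation — both taxis terms bias motion *up*-gradient — and are pinned by a
direction-of-bias test rather than trusted by transcription.  Negative
coefficients (drift dominating diffusion, common at fine grids) are clamped
to zero and the vector renormalised; off-grid directions get probability
zero with their mass folded into staying, which implements zero-flux cell
movement.  If every propensity clamps away, the cell stays with
probability 1.  The 9-point (Moore) stencil splits the operator into its
orthogonal part (weight 2/3) and the diagonally rotated part at spacing
`h*sqrt(2)` (weight 1/3), reproducing the standard 9-point Laplacian
weights; nothing downstream depends on this choice beyond its symmetry, and
it is isolated in one module so alternates can be swapped.

**Cell life cycle.**  Per iteration, living cells are visited in a
uniformly random order (a fixed scan order would favour the cells visited
first).  Each cell draws its neighbourhood — Moore or von Neumann,
fifty-fifty — once per step, then: (1) dies (necrotic, absorbing) if
`u < u_crit` strictly; (2) with no free neighbour in the drawn
neighbourhood, falls quiescent with its division clock frozen; (3)
otherwise a quiescent cell re-enters the active state, the clock advances,
and the cell divides if the clock has reached 16 steps — one daughter
replaces the mother, the other is placed chemotactically on the free
neighbour with the highest nutrient (ties uniform at random), both clocks
reset — or else performs one sampled move, cancelled if the target is
occupied.  The same drawn neighbourhood serves movement and daughter
placement.  There is no apoptosis, so occupied sites never decrease.  The
sweep over cells is a single compiled kernel (numba, with an identical
uncompiled fallback); all randomness is pre-drawn per step from named,
independently seeded substreams (matrix init, neighbourhood choice, update
order, movement, tie-breaks) so a change in how one component consumes
randomness cannot shift the others, and runs are bit-reproducible for a
given seed.

**Rate estimation.**  `sweep_alpha_beta` reproduces the variant-A rate
choice: `alpha_f` varies in (0, 1) (degradation by cells must stay below
the enzyme-model coefficient 1, but zero would mean no degradation),
`beta_f` in (0, 0.015] (bounded by the enzyme model's remodelling rate).
Pairs violating the Euler bound are flagged and skipped.  For admissible
pairs the full simulation runs to the evaluation time (325 h by default)
and reports the matrix value at the centre site — permanently occupied, so
it follows the `c = 1` geometric decay — plus a mid-row profile.  The
remodelling-only closed form `0.8 (1 + 0.18 beta_f)^650` exceeds 1 at
`beta_f = 0.015`, the argument for the much smaller default 0.001.

## Synthetic conditions, and what the tests do and do not show

There is no external data: every input is generated by the configuration
itself (seed geometry, vessel layout, constant or uniform-random matrix).
Tests and the acceptance script run on reduced lattices — mostly 100 x 100
rather than 400 x 400 — with correspondingly shorter horizons; these sizes
were chosen so a full ensemble comparison stays a few minutes on one CPU.
Two consequences of the reduction should be kept in mind when reading
results:

* The 441-cell seed occupies a 16-fold larger domain fraction than on the
  full lattice, so the tumour fills a 100-lattice within a few hundred
  steps and saturation effects (everything quiescent) arrive early.
* With the literature uptake rate `alpha_u = 6.25e-5` the nutrient field
  stays within ~1% of the vessel level, so necrosis and hypoxia do not
  emerge spontaneously at any tested scale; the necrosis, quiescence and
  hypoxia-reporting pathways are instead exercised with constructed fields.
  Real avascular tumours develop necrotic cores; reproducing that here
  would require a much larger uptake rate than the nominal one.

The two variants agree closely over the early growth phase and then drift
apart: variant B's fifteen-fold faster matrix remodelling steepens the
haptotactic gradient at the rim, and on reduced lattices its ensemble
total-cell curve ends ~20% above variant A's — far outside the ensemble
standard errors (the corresponding strict-agreement test documents this
divergence and fails by construction at this scale).  The difference-image
and ensemble tools are there to make exactly this kind of comparison
quantitative.

## Other design choices and limitations

* Coordinates are `(row, col)` with row 0 the top edge; vessel tags
  left/right/top/bottom map to lattice edges accordingly.
* Division requires `u >= u_crit` only implicitly (a cell below threshold
  is already necrotic); quiescent cells resume with their frozen clock
  rather than a reset one.
* The nutrient solve may be refreshed every `j` steps
  (`nutrient_refresh_every`) as a performance knob; all shipped results
  use `j = 1`.
* 2-D only; no cell–cell adhesion, pushing mechanics, angiogenesis,
  immune response or therapy; host tissue is not represented on the grid.
* Wall-clock time is not an output of interest; variant A is cheaper than
  variant B by one sparse solve per iteration, but no timing is asserted
  anywhere.
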