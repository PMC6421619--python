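# Methods

## Model

The simulator integrates a six-field reaction–diffusion system across the
thickness of a chondral defect, written in dimensionless form. Densities are
measured as fractions of the maximum total cell density (10^6 cells/mm^3),
matrix as a fraction of its maximum (10^-4 g/mm^3), nutrient relative to the
surface reservoir, each growth factor relative to its reference
concentration (10^-10 g/mm^3), length in defect thicknesses (2 mm) and time
in units of the matrix-production time scale

    T = mmax / (p80 · C_total,max0) = 266.7 h ≈ 11.1 days.

Months of healing are converted at 1 month = 30.44 days, so one month is
2.7396 dimensionless time units; this conversion is logged with every run.

Modelling assumptions worth keeping in mind:

- one spatial dimension (thin-defect limit); no defect geometry, no
  mechanical loading, no chondrocyte hypertrophy or ossification;
- implantation of stem cells only (`gf_config` controls growth factors, not
  the seeded cell type); co-implantation of cell mixtures is out of scope;
- nutrient (oxygen) enters only through the cartilage surface, where its
  concentration is pinned to the reservoir value; there is no MSC influx
  from the subchondral bone;
- differentiation, proliferation shut-off and starvation death are
  threshold (Heaviside) processes; BMP-2 lowers the differentiation
  threshold exponentially, FGF-1 adds a saturating boost to chondrocyte
  proliferation.

## Parameters

`params.default_dimensionless()` is the canonical simulation input: the
tabulated dimensionless estimates. `params.default_dimensional()` holds the
dimensional estimates, and `nondimensionalize()` maps one to the other.
The two tables are not mutually consistent for every entry; the computed
mismatches are returned by `nondimensional_discrepancies()` (among them the
proliferation constants p10 and p40, the growth-factor diffusivities, and
the nutrient-uptake constants p6, p7). The dimensionless table always wins
for simulation; the discrepancies are reported, never silently reconciled.

Two entries required a decision:

- **p81 (matrix degradation).** The degradation term p80 − p81·m only has
  consistent units if p81 carries a per-matrix-density unit; the default is
  fixed at p81 = p80/mmax so matrix synthesis stops exactly at the maximum
  matrix density (dimensionless p̄81 = 1).
- **α (threshold reduction factor).** The dimensional estimate (10^10 per
  g/mm^3) together with the BMP-2 reference concentration gives a
  dimensionless factor of 1, while the dimensionless table lists 100. The
  simulator uses 100; the mismatch is flagged by the round-trip check.

Ranged entries are fixed once and documented in the docstrings: nutrient
reservoir at the top of its range (Michaelis constant 0.24 in nutrient
units), stem-cell diffusion constant at the top of its range (1e-2, ten
times the chondrocyte value, which is what makes the stem-cell front lead),
nutrient diffusivity 3e2, matrix diffusivity 1.67e-3 (the value the
dimensional estimates imply), and zero direct FGF-1 matrix deposition
(p800 = 0; its effect is routed through chondrocyte proliferation).

## Initial conditions

Stem cells are seeded against the subchondral bone as a peak-normalised
Gaussian, C_S(x, 0) = 0.25·exp(−(x/w)²) with default width w = 0.1 defect
thicknesses. The peak value is the tabulated implanted density; the shape
and width of the seeding profile are not fully specified by the source
study, so w is an explicit configuration knob — the quantitative
growth-factor percentages, which sample a fast transient, inherit an
irreducible uncertainty from this (see "Fidelity" below). Chondrocytes and
matrix start at small uniform backgrounds (10^-4 of their scales — these
bootstrap the BMP-2 loop and matrix-dependent motility), nutrient at the
reservoir value, growth factors at 10^-2 of their reference concentrations
(zeroed for excluded factors, along with the production constants, so no
initial pulse leaks into comparisons).

## Discretisation and integration

- Uniform grid on [0, 1], default 101 nodes; second-order conservative
  flux-form differences. Interface diffusivities for the matrix-dependent
  cell motilities are evaluated at the arithmetic mean of the matrix
  density at the two adjacent nodes (averaging the argument, not the
  coefficient, preserves second order and the degeneracy at m = 0).
- Boundaries: ghost-node reflection (no flux) for all fields at the bone;
  at the cartilage surface, no flux for cells and matrix, nutrient pinned
  algebraically to 1 (direct substitution keeps the ODE system
  non-singular), and Robin outflow for the growth factors via ghost-node
  elimination (g_ghost = g_{N-1} − 2h(γ/D_g)·g_N).
- Time integration: scipy `solve_ivp` BDF with a block-tridiagonal Jacobian
  sparsity pattern; defaults rtol 1e-6, atol 1e-9, recorded in
  `Trajectory.solver_meta`. No negativity clipping anywhere: undershoot
  beyond −10·atol is a test failure, not something to mask.
- Heaviside gates use a tanh sigmoid of width `eps` (one knob for all
  gates). Default `eps = 1e-3`: the value was required to sit in the
  converged regime, operationalised as the 2-month mean matrix density
  changing by less than 2% when eps is halved (enforced in the test suite;
  measured change ≈ 0.3% at the default, versus tens of percent at 1e-2,
  where the gate width still shifts the differentiation switching time).
- Verification: observed spatial order ≈ 2 by Richardson extrapolation on
  nested grids (51/101/201; these runs use eps = 1e-2 to keep profiles
  smooth on the coarse grid, and tightened time tolerances so spatial error
  dominates); exact agreement (1e-4 relative) with an independently coded
  fixed-step RK4 integration of the raw kinetics in the zero-diffusion
  uniform reduction; discrete mass conservation under no-flux boundaries
  with reactions off; nutrient maximum principle (n ≤ 1).

## Scenarios and summaries

Four growth-factor configurations (`none`, `fgf_only`, `bmp_only`, `both`)
run through one code path; excluded factors have production constant and
initial concentration zeroed. Sensitivity sweeps vary one dimensionless
parameter (or scenario knob) at a time. Summaries are trapezoidal spatial
means, percent differences against a baseline run, half-maximum front
positions (largest crossing, linearly interpolated), and the first time the
minimum matrix density exceeds a fill threshold (default 0.9; the source
narrative says "fills up" without a criterion).

## Fidelity and known limitations

What the default study conditions reproduce (all quantities below are
computed by the test suite or `scripts/acceptance.py`):

- the 11.1-day matrix-production time scale and the tabulated dimensionless
  groups (p̄2 = 1, p̄9 = 26.67, C̄S(0) = 0.25) exactly;
- baseline differentiation onset in the 1–3-month window (the maximum
  stem-cell density first exceeds the 0.35 threshold at ≈ 2.25 months),
  followed by stem-cell and chondrocyte fronts migrating toward the
  nutrient supply with the stem-cell front ahead;
- BMP-2 dominance: the BMP-2-only run differs from the both-factors run by
  < 5% in the 2-month matrix profile, and FGF-1 alone contributes < 20% of
  the combined effect;
- the sensitivity orderings of the threshold pathway: raising BMP-2
  production ten-fold, slowing its degradation hundred-fold, or lowering
  the minimum threshold to 0.28 each brings differentiation forward, while
  weakening the threshold response (ᾱ = 1) delays it the most;
- growth-factor enhancement at 4 months: +24% matrix, +27% chondrocytes
  (reported: +34%, +19%), and +61% chondrocytes at 2 months (reported
  +66%).

What it does not reproduce: the reported +65% matrix enhancement at
2 months (this simulator: ≈ +1%) and the −13% stem-cell deficit at 4 months
(here the deficit appears from about month five; at 4 months the stem-cell
mean is still ≈ 4% above baseline). Both quantities sample the
differentiation transient, where percent differences of small means are
extremely sensitive to the exact switching time — varying only the gate
width between 1e-3 and 1e-2 moves the 2-month matrix figure between ≈ 1%
and ≈ 41%. The switching time in turn depends on the unspecified seeding
profile; under the fixed default conditions these two figures disagree with
the reported ones and are reported as computed, not adjusted.

Other limitations: the synthetic scenarios probe the model's own dynamics,
not patient data — passing tests say nothing about biological calibration
beyond the parameter estimates themselves; matrix fills the defect from the
cartilage-surface side and the bone-side matrix lags (whether a fill
threshold is met within a finite horizon depends strongly on the
starvation-death gate near the bone); sharp-Heaviside event-located
integration is unsupported (the tanh regularisation is the supported
treatment, with the eps-convergence guard above).
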