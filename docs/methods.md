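# Methods

`cortexfold` couples the migration of discrete cohorts of neurons,
modeled as advection–diffusion of cell-density fields, to finite-growth
mechanics of the developing cortex. This note records the model, the
numerical methods, the parameter choices, and the design decisions made
where the problem was genuinely open, together with known limitations.

## Model

### Kinematics and elasticity

The deformation gradient factors multiplicatively, `F = Fe·Fg`. The
growth part is transversely isotropic about the radial glial fiber
direction `N` (a unit vector fixed in the reference configuration):

    Fg = (1 + k_par c) N⊗N + (1 + k_perp c) (1 − N⊗N),

where `c = Σ_i c_i` is the **total** spatial cell density over cohorts
(μm⁻³) and `k_par`, `k_perp` (μm³) convert accumulated cells into
radial and tangential stretch. Growth is an instantaneous algebraic
function of the local density; it carries no rate constant and is
formally reversible (see Limitations). Only the elastic part stores
energy; the material is compressible neo-Hookean,

    ψ(Ce, Je) = μ/2 [tr Ce − 3 − 2 ln Je] + L/2 ln² Je,
    T = [μ Be + (L ln Je − μ) 1] / Je,

with `μ(r)` stepping from `μ_s = 1 kPa` in the subcortex to
`β_μ μ_s` in the cortex and `L(r) = L_s μ(r)/μ_s` (uniform Poisson
ratio ν = 0.45). The tabulated subcortical second Lamé constant
`L_s = 9.3 kPa` is kept as-is even though `2μν/(1−2ν)` with μ = 1 kPa
gives 9.0 kPa; both numbers are retained as independent inputs and the
small inconsistency is left unresolved.

### Cohort transport

Each cohort density obeys, in spatial form,

    ċ_i + c_i J̇/J = f_i + div q_i,
    q_i = −c_i H(c_i) v̂_i(r) n/|n| + D grad c_i,

with `n = F N` the deformed fiber, `H` a logistic activation in the
normalized excess density `(c_i − c0)/c0` (sensitivity α_c), and
`v̂_i(r) = v_i H(δ_iv − r; α_v) − v_i/2` a signed speed profile that is
`+v_i/2` below the cohort destination `δ_iv`, zero exactly at it, and
`−v_i/2` beyond it. The negative branch is implemented literally; it
acts as a restoring advection that confines cells that overshoot their
destination. All spatial profiles are functions of the *referential*
radius: the destinations (191.6–222.7 μm) lie inside the initial radius
R0 = 239 μm, i.e. they are material coordinates.

The source is `f_i = Gc · Gx(r) · Gt_i(t)` with `Gt_i` a Cauchy bump of
height 1 at the cohort electroporation day (0/3/6, half-width
ε = 2 d). **Orientation of Gx:** the neurogenesis window is
`Gx = H(r − δ_x; α_G)` — proliferation *outside* the ventricular zone
(r < δ_x = 0.2 R0), where the intermediate progenitor cells divide.
The package also provides the flipped, ventricular-confined window
(`neurogenesis_profile: "ventricular"`); the outward-open default
is the literal form of the model equations and reproduces the final
experimental domain length, while the confined variant is required for
the 2-D folding geometry (below).

### Equilibrium

Quasi-static balance `div T = 0` with: the bar fixed at one end and
laterally roller-supported (a 1-D solution), or a plane-strain half
disc with symmetry conditions on the cut edge and a traction-free pial
surface. Plane strain is interpreted morphoelastically: the
through-thickness constraint is **zero elastic out-of-plane strain**
(`Fe_33 = 1`), so out-of-plane growth thickens the slice stress-free
and enters the density dilution through `J`. (Constraining the total
stretch `F_33 = 1` instead would elastically crush the tissue by the
full tangential growth factor and destroys the solvability of the
problem at realistic growth levels.)

## Numerics

* **Space.** Linear displacement finite elements: two-node line
  elements for the bar (61 axial node planes at the default 60
  elements, equivalent to one row of bricks with symmetric faces), and
  four-node quadrilaterals for the half disc (butterfly layout,
  ~1147 elements at default). Transport uses the same meshes and
  shape functions with consistent mass matrices.
* **Transport scheme.** The referential (conservation) form
  `ċ0_i = J f_i + Div(J F⁻¹ q_i)` is integrated by backward Euler with
  the geometric factors frozen at the step start. Natural zero-flux
  boundaries make the Galerkin scheme conserve `∫ c0 dV` exactly up to
  the integrated source (verified to 1e-6 per step in the tests). An
  artificial streamline-diffusion flux with the standard Péclet limiter
  `ν = |W| h/2 (coth Pe − 1/Pe)` stabilizes the advection-dominated
  regime without polluting the diffusion-dominated one; being a flux,
  it is also conservative. Negative densities (undershoots near steep
  fronts) are clipped to zero and the clipped mass is tracked.
* **Growth update.** The spatial density and the dilution it causes
  are mutually dependent: `c = c0/J` with `J = Je · Jg(c)`. Lagging `J`
  a whole step is an unstable fixed-point iteration once the growth
  stretch exceeds ~2 when `Jg ~ θ³` (the 2-D case). The pointwise
  nonlinearity `c · Je · (1 + k_par c)(1 + k_perp c)² = c0` is therefore
  solved exactly per quadrature point each step with a monotone Newton
  iteration, lagging only the slowly varying elastic `Je`.
* **Mechanics.** Full Newton on the total-Lagrangian residual with the
  analytic consistent tangent (`dP/dF`), backtracking line search,
  relative residual tolerance 1e-8, at most 25 iterations; the bar uses
  a dedicated tridiagonal path with the closed-form axial response. On
  failure the driver halves the time step down to dt/64.
* **Coupling.** Staggered: one transport solve, one local growth
  update, one equilibrium solve per step (default dt = 0.05 d, outputs
  every 0.5 d plus the exact preparation times).
* **Imperfection.** The 2-D surface is seeded with deterministic radial
  white noise of amplitude 1e-3 R0 (seeded RNG) so symmetry breaking
  is reproducible; runs are bitwise deterministic given config + seed.

## Time alignment and parameters

Day 0 is E31 (first electroporation); τ = 27 d ends at P16. The
imaging timepoints map to days 8.5 (E39–40), 16.5 (P5–6, birth at
E42) and 27 (P16). Parameter defaults are the ferret calibration values (threshold c0 = 1e-6 μm⁻³, α_c = 0.1,
Gc = 1.41e-5 μm⁻³ d⁻¹, v = 1472.2 μm d⁻¹, δ_iv = 191.6/210.7/222.7 μm,
D = 31612.6 μm² d⁻¹, k_s = 202950 μm³, β_μ = 3, β_k = 1, transition
radii 0.93 R0). Smoothing parameters α_G, α_v (0.05) and α_k, α_μ (1.0)
act on micrometre arguments (μm⁻¹) — the only unit assignment that
gives physically sensible transition widths (20 μm and 1 μm); α_c is
dimensionless on the normalized density.

## What the forward model reproduces — and what it does not

A systematically verified finding of this implementation (confirmed
against an independent method-of-lines/BDF reference at 500–1000 cells,
rtol 1e-7): with the calibrated parameters the bar's growth is
**front-loaded**. Because the birth pulses are centred on days 0–6,
~85% of the time-integrated source is spent by day 8.5, and the domain
length saturates early: 1964 / 2019 / 2053 μm at days 8.5 / 16.5 / 27
(60-element default; grid-converged values are within 0.5%). The
experimental group lengths are 1390 → 1997 → 2390 μm, i.e. the data
keep growing +72% after day 8.5. The simulated length matches the
middle timepoint to ~1% but overshoots the first by ~41% and
undershoots the last by ~14%. No defensible reading of the transport /
growth coupling (source orientation, referential vs spatial source
density, dilution handling, rate-form growth) reproduces the
experimental *trajectory shape*; the implemented literal form is the
closest overall. Downstream consequences: folding in the 2-D geometry
also initiates much earlier than the reported early-postnatal onset.

In the 2-D half disc the outward-open neurogenesis window makes the
source volume feedback unbounded (referential source `J·f` with
`J ~ θ³`); the simulation leaves any physically meaningful regime
within days. The folding and sweep studies therefore use the
ventricular-confined window, which bounds production and yields smooth
disc growth to day 27 (radius ×1.7 at default parameters).

Folding behavior measured on the β_μ × β_k sweep: buckling onset is
monotonically earlier in both the stiffness ratio and the
tangential-radial growth ratio, and the fold wavelength shortens with
β_k. The default cell (β_μ = 3, β_k = 1) never crosses the onset
threshold — verified at the full 1147-element resolution — because the
differential growth at the calibrated densities stays subcritical, and
the β_μ wavelength dependence is weak and slightly negative rather than
positive: the observed folds are global modes (2–4 per half circle),
not film wrinkles of the ~17-μm stiff cortical shell, which would need
several elements through the shell thickness to be resolved. Runs that
fail to converge shortly after onset (creasing, which requires contact
mechanics that is out of scope) contribute their frames up to the
failure; metrics are taken at the onset frame.

## Calibration

The objective balances eight relative density-vector errors (weight
w1 = 11/8) and three relative length errors (w2 = 11/3); profiles are
resampled to 60 points on the normalized [0, 1] grid before taking
Euclidean norms. Search ranges follow the literature where available
(Gc ∈ [1e-6, 1.5e-5], v ∈ [230, 4752], D ∈ [25000, 35000]); the
destinations are searched over [0.4 R0, R0] and k_s over [1e5, 3e5]
(a factor ~2 bracket around the calibrated value, chosen once).

The optimizer is an evolutionary search with a population of 10.
The default strategy is differential evolution (rand/1/bin with a
best-anchored fraction of mutants that ramps from 0 to 0.7 over the
generations, dithered weight F ∈ [0.5, 1], crossover rate 0.9, greedy
slot-wise replacement), run to the generation cap (default 40). A
classic real-coded GA (elitism 1, binary tournament, BLX-0.5
crossover p = 0.9, per-gene Gaussian mutation p = 0.2 with
geometrically annealed width, optional mid-run restart around the
incumbent best) is available as `strategy="tournament"`, with a
plateau stopping rule (best objective improving < 1e-3 over 10
generations). DE is the default because the objective has a curved
multi-parameter valley (Gc, v, k_s and the destinations trade off
against each other): tournament selection into a common pool collapses
a 10-member population before the valley is descended, whereas DE's
slot-wise greedy replacement preserves diversity and its difference
vectors align with the valley. Even so, the landscape under-identifies
`v` and the `Gc`–`k_s` pair at the optimization depth reachable with
~400 forward evaluations: objective values below 0.5 were observed at
parameter sets differing from the generating truth by tens of percent
along compensation directions, so recovery accuracy beyond that point
is limited by the data, not the optimizer. Forward evaluations are
cached by genome; failed forward runs receive a large penalty and are
logged.

Modes: `three_cohort` (full dataset), `leave_out_t3` (fit on the first
two timepoints, validate on the third), `single_cohort` (one cohort,
one destination, single birth pulse at day 0, fitted to summed
densities).

## Synthetic data

The generator runs the calibrated bar model and emits the eight
(cohort, timepoint) profiles — cohort 3 is absent at timepoint 1,
mirroring the imaging layout — plus the three lengths. Default noise
is Poisson counting noise on the expected neuron count per sampling
bin (ROI width 500 μm, section depth 50 μm), which is the measurement
actually performed; a multiplicative Gaussian option exists for
stress-testing. The neuron-table generator draws an inhomogeneous
Poisson point process with intensity `density(y)·W·dz` and uniform x.
What passing tests on these data do **not** show: real images contain
GFP-positive fibers (spurious density peaks), section-to-section
variability between animals, and segmentation errors, none of which
are emulated.

## Folding metrics

Surface deviation is the RMS of the outer radius around its running
circumferential mean (window π/4); onset is the first output frame
where it exceeds 1% of R0 (threshold configurable — there is no
canonical quantitative definition of the buckling point). The fold
wavelength is the dominant nonzero cosine mode of r(θ) on the half
circle, reported as arc length per fold over R0, measured at the onset
frame. `ln λ` maps use the largest principal stretch of the total `F`.
Fiber fan-out is the angle between `n = F N` and the referential radial
direction per element.

## Limitations

* The instantaneous growth law has no ratchet: if the local density
  falls (dilution, migration), the tissue shrinks back. Visible as a
  slight late-time radius decrease in 2-D runs.
* Creasing/self-contact after deep folding is not modeled; 2-D runs
  are meaningful up to and modestly past onset.
* The 60-element bar under-resolves the advective boundary layer at
  the cohort destinations at high stretch; headline lengths at this
  resolution are nevertheless within 0.5% of grid-converged values.
* The single-cohort reduction fixes its birth pulse at day 0, a
  convention of this package.
* Plane-strain out-of-plane handling (zero elastic strain) is a
  modeling contract, not a statement about the 3-D problem; the
  one-eighth-sphere fully 3-D configuration is out of scope.
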