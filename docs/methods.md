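# Methods

## Model

The package models hydrolytic degradation of a semicrystalline polyester
film as random chain scission autocatalysed by carboxylic chain ends.
A population balance over chain lengths would need ~10⁵ equations; it is
reduced to balances for the first three statistical moments
μ_j = Σ_n n^j C_n of the chain-length distribution, coupled to transport
of water, monomer and the mobile oligomers (dimer through nonamer; longer
chains are assumed immobile in the matrix).

Assumptions:

- Scission position is uniform along the chain; every scission consumes
  one water molecule and creates one new chain.
- Kinetics are third order, rate ∝ k_d · C_W · μ₀ per bond: the μ₀
  factor is the autocatalytic acid-end-group effect.
- Monomer is counted inside the moments (μ₀ includes n = 1); this is
  what makes the monomer source 2 k_d C_W (μ₀ − C_M) μ₀ consistent —
  monomer is produced from every chain longer than itself.
- The second-moment balance is closed with μ₃ ≈ 2μ₂²/μ₁ − μ₂μ₁/μ₀. The
  closure is exact for monodisperse distributions, which also fixes the
  grouping of the μ₂ source as k_d C_W (μ₀/3)(μ₁ − 2μ₂²/μ₁ + μ₂μ₁/μ₀):
  only this grouping has units of mol cm⁻³ s⁻¹ given k_d in
  cm⁶ mol⁻² s⁻¹, and it reproduces the exact monodisperse rate
  −(k_d C_W μ₀/3)(μ₃ − μ₁). The μ₀ and μ₁ balances involve no closure.
- Degradation opens diffusive paths:
  D_i = D_i⁰ exp[2.5 (1 − Mn_local/Mn_ref)^0.5], with Mn_local computed
  nodewise from the local moments and the ratio clamped to [0, 1]
  (transient overshoots above the initial molecular weight carry no
  enhancement). D is therefore bounded in [D⁰, D⁰·e^2.5].
- Cross-linking, recombination, unzipping/depolymerization, erosion-front
  motion and temperature dependence of k_d are out of scope.

Nodes where μ₀ = 0 or μ₁ = 0 (empty or fully degraded) produce zero
reaction sources rather than errors, so degraded regions stay integrable.

## Parameters

| parameter | meaning | default | unit |
|---|---|---|---|
| k_d | degradation constant | fit target | cm⁶ mol⁻² s⁻¹ |
| D_M⁰, D_olig⁰ | pristine monomer/oligomer diffusivity | 1e-10 | cm² s⁻¹ |
| D_W⁰ | pristine water diffusivity | 1e-8 | cm² s⁻¹ |
| M_mon | repeating-unit molar mass | 90.08 | g mol⁻¹ |
| ρ_pol | polymer density | 1.2 | g cm⁻³ |
| C_W,surf | surface water concentration | 0.0555 | mol cm⁻³ |
| Mn_ref | molecular weight at degradation onset | specimen Mn₀ | g mol⁻¹ |
| film thickness | characteristic diffusion length | 55 | μm |

The defaults describe the reference polylactide film study bundled in
`reference.py`: four specimens (0/5/10/20 Mrad electron-beam dose) with
initial Mn 406,000 / 64,700 / 43,200 / 23,100 g·mol⁻¹, polydispersity
1.60–1.76 and fitted constants 3.85e-5 / 1.27e-4 / 1.47e-4 / 1.21e-4
cm⁶ mol⁻² s⁻¹. 0.0555 mol cm⁻³ is the molar concentration of pure water.

## Initial states

A uniform film with specified (Mn₀, PD₀) fixes the moments exactly:
μ₁ = ρ/M_mon, μ₀ = ρ/Mn₀, μ₂ = PD₀·μ₁²/μ₀; monomer and oligomer
concentrations start at zero (negligible mass fraction for high-MW
polymer) and the interior is dry unless a pre-saturated start is
requested. The construction inverts the averages map to machine
precision, which anchors the estimation: the forward model's t = 0 state
is exact by construction.

## Discretization and integration

Method of lines over the film **half**-thickness (symmetric degradation;
zero flux at the centre). Space: node-centred conservative finite
volumes on a uniform grid — fluxes −D_face ΔC/Δx with face diffusivity
the arithmetic mean of the nodal values, half-width end cells. This is
the flux form of centred differences, and it makes the conserved
discrete integral exactly the trapezoidal rule used for device-level
averages, so sealed runs conserve ∫μ₁ dx to round-off. Surface boundary
conditions (a modelling choice; the underlying physics papers do not
state them): Dirichlet C_W = C_W,surf and perfect-sink (zero) Dirichlet
for monomer and oligomers, both applied as face fluxes over the half
cell. The moments need no independent boundary conditions: their
transport is by definition the j⁰/j¹/j²-weighted sum of the mobile
species' flux divergences.

Time: stiff implicit integration (BDF with a block-tridiagonal Jacobian
sparsity pattern for spatial runs; LSODA for the 13-equation well-mixed
system), relative tolerance 1e-6 (1e-8 for fitting forward runs), and
per-field absolute tolerances scaled to the initial magnitudes (μ₂ is
~10⁷ times larger than μ₀ in physical units, so a single atol would be
wrong for one of them). Output states with small negative concentrations
are clipped to zero; excursions beyond the absolute tolerance are
logged. Default grid: 51 nodes — device Mn at 51 vs 101 nodes differs by
<10⁻⁵ relative for the reference case, comfortably inside the 1%
convergence requirement the tests assert.

## Estimation

k_d is estimated by `scipy.optimize.least_squares` (TRF) on relative
residuals (Mn_model − Mn_data)/Mn_data, in log₁₀(k_d) within
[1e-8, 1e-2], deterministic start at 10⁻⁵. Rationale: Mn spans
23,100–406,000 g/mol across specimens, so absolute residuals would
weight only the highest-MW specimen; k_d spans orders of magnitude and
must stay positive. The finite-difference step (1e-5 in log₁₀ k_d) is
set well above the integrator noise floor so the Jacobian estimate is
clean. Series whose Mn declines by <10% trigger an identifiability
warning, and estimates at the lower bound are flagged: such data cannot
resolve the constant.

The default forward model for fitting is the single-node well-mixed
model with water pinned at C_W,surf: a 55 μm film equilibrates with
water in minutes–hours at D_W ~ 1e-8 cm² s⁻¹, negligible against
degradation times of weeks–months, and the lumped model removes the
unstated surface boundary conditions from the estimate. The spatially
resolved film is available (`spatial=True`); with it, estimates from
well-mixed-generated data shift by a few percent because surface
oligomer loss slightly changes the device-average Mn trajectory.

## Chain-resolved oracle

`oracle.py` integrates the unreduced population balance (one ODE per
chain length, default Nmax = 300, well-mixed, deterministic — no
Monte-Carlo noise) and computes μ₀..μ₃ by direct summation. It is the
independent check on the moment model: μ₀ and μ₁ must agree to
integrator tolerance (no closure is involved), while μ₂ tests the
closure — within 5% of exact until Mn halves for a monodisperse start.
The oracle guards itself: Σ n·C_n must stay constant (scission conserves
repeating units) to 0.1% or it raises. Under prolonged scission the
oracle's polydispersity drifts from 1 toward 2, the most-probable
distribution, and never beyond.

An additional closed-form oracle covers the well-mixed fixed-water chain
balance, which is logistic: μ₀(t) = μ₁ / (1 + (μ1/μ₀(0) − 1) e^{−λt})
with λ = k_d C_W μ₁; the solver is tested against it directly.

## Synthetic data

The generator emulates GPC degradation series: the well-mixed forward
model evaluated at a specimen's (Mn₀, PD₀, k_d), times chosen so each
curve declines to ~40% of its initial Mn in 12 points (comparable
fractional decline across doses, as such studies are designed), then
multiplicative lognormal noise with unit mean at 3% coefficient of
variation — GPC molecular-weight determinations carry roughly constant
relative error, and 3% keeps recovery well-posed but non-trivial. Fixed
seeds make datasets bit-reproducible; true parameters travel as
metadata.

What it does *not* emulate: spatial heterogeneity of real films,
autocatalysis-driven deviation of real data from the fitted model
(model error), mass loss, water-uptake measurements, inter-laboratory
calibration offsets, or correlated errors between time points. Passing
recovery tests therefore demonstrates the estimator is correct and
well-conditioned *under the model*, not that the model is a complete
description of any particular experiment.

## Problem sizes

Tests and the acceptance script run the well-mixed model (13 ODEs) for
all fitting studies, the 51-node film (663 ODEs, sparse-Jacobian BDF)
for conservation/convergence checks, and the 300-chain oracle for
closure checks; these sizes reproduce the analysis faithfully while the
whole suite completes in about a minute.

## Known limitations

- The μ₂ closure degrades for broad distributions (PD → 2); errors grow
  past the Mn-halving horizon asserted in the tests.
- The fitted k_d is conditional on the assumed water handling
  (well-mixed, fixed C_W); spatial-mode estimates differ by a few
  percent, so constants are comparable across specimens fitted the same
  way rather than absolute.
- No erosion (domain shrinkage) or mass-loss prediction; the film
  geometry is fixed.
- The diffusivity enhancement exponent (2.5) and the mobile-oligomer
  cutoff (nonamer) are taken as fixed model structure, not fit targets.
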