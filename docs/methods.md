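# Methods

## The dimer-gel free-energy model

The mixture is described at mean-field level by a free-energy density (units
k_BT·µM; k_BT = 1 throughout; all concentrations in µM)

    F(ρ_R, ρ_E) = F_ni + F_ex + min(F_dim, F_ind).

**Ideal term.** `F_ni = ρ_R ln(ρ_R/e) + ρ_E ln(ρ_E/e)` is the translational
entropy of the two polymer species. Written on sticker concentrations it is
`(c/L) ln(c/(eL))` per species — the identical quantity.

**Excluded volume.** `F_ex = v_R c_R² + v_E c_E² + v_ER c_E c_R` acts on
sticker concentrations, treating stickers as hard spheres at virial level.
The coefficients derive from the molecular geometry: the Rubisco holoenzyme is
a d_R = 10 nm sphere carrying L_R = 8 stickers, so each sticker carries a 1/8
share of the 4×(volume) pair term, `v_R = 4·(4/3)·(π/8)(d_R/2)³ = 261.80 nm³`;
an EPYC1 sticker-plus-linker segment is a coil of R_g = 1 nm,
`v_E = 4·(4/3)π R_g³ = 16.755 nm³`; the cross term uses a sphere at the mean
effective radius, `v_ER = 8·(4/3)π(d_R/8 + R_g/2)³ = 179.594 nm³`. Volumes are
converted to inverse concentration by ×0.602214 (nm³ → L/mol) and ×10⁻⁶ (→
1/µM). These are derived, cacheable properties of `ModelParams`, not free
inputs.

**Specific binding** takes the minimum of two smooth branches.
The *dimer* branch assumes all bound material is 1:1 EPYC1–Rubisco
heterodimers with molecular dissociation constant K_d:

    F_dim = ρ_d ln K_d + ρ_d ln(ρ_d/e) + (ρ_R−ρ_d) ln((ρ_R−ρ_d)/e)
          + (ρ_E−ρ_d) ln((ρ_E−ρ_d)/e) − ρ_E ln(ρ_E/e) − ρ_R ln(ρ_R/e),

with ρ_d the smaller root of the pairing quadratic (mass action). The
*independent-sticker* branch is the same functional form on sticker variables
(c_R, c_E, c_b, K_b). Both use the 0·ln 0 convention, so every term is finite
and continuous as any concentration → 0⁺. `ln K` is taken with K in µM, the
same unit as all other concentration logarithms; both branch free energies are
invariant under a common change of concentration unit (the log-unit terms
cancel exactly), so the coexistence result does not depend on this choice.
A tie between the branches is labelled "dimer" (deterministic, measure-zero).

Defaults: L_R = 8, L_E = 5, K_d = 0.029 µM (the FCS-measured heterodimer
constant; configurable, as it is reported with a ±12 nM interval), K_b = 60 µM
(the single fitted constant of the model), d_R = 10 nm, R_g = 1 nm.

At the two reference state points the implementation reproduces the branch
separation that justifies keeping only the dominant branch per phase: at
ρ_R = ρ_E = 150 µM the gap (F_dim − F_ind)/ρ ≈ 5.9 k_BT per molecule
(independent stickers dominate, dimer probability ~e⁻⁶); at 0.5 µM the gap
(F_ind − F_dim)/ρ ≈ 2.0 (dimers dominate).

## Chemical potentials

Because the pairing concentration is the mass-action stationary point of its
branch free energy, the envelope theorem collapses each branch gradient to a
closed form, e.g. on the dimer branch

    µ_R = ln ρ_R + L_R(2 v_R c_R + v_ER c_E) + ln((ρ_R − ρ_d)/ρ_R),

and `µ_X = ∂F/∂ρ_X` is exact — no numerical differentiation enters the
coexistence solver. A central finite-difference path (relative step 10⁻⁶) is
retained behind `method="fd"` and cross-checked against the analytic gradients
in the tests; the analytic form was made the default because the Newton solver
needs residuals smooth to ~10⁻¹⁰ and finite differences at that step size leave
visible noise near the 10⁻⁸ convergence target. The grand-potential density is
Ω = F − µ_R ρ_R − µ_E ρ_E.

## Coexistence solver

Two-phase coexistence requires µ_R, µ_E and Ω to agree between a dilute
composition (evaluated on the dimer branch) and a dense composition
(independent-sticker branch) — the two-dimensional common-tangent-plane
construction. Numerics:

1. **Detection.** F is sampled on a 120×120 logarithmic grid over
   [10⁻⁴, 10⁴] µM per axis and the lower convex hull of the (ρ_R, ρ_E, F)
   cloud is taken (axes normalized for Qhull). Facets whose in-plane extent
   exceeds 3× the grid spacing (measured in log₁₀, where the grid is uniform)
   bridge non-convex regions; their extreme vertices seed the refinement.
2. **Refinement.** The tie-line family has one degree of freedom. It is closed
   by pinning the dense endpoint to a ray of fixed composition angle
   φ = atan2(ρ_E, ρ_R) through the origin, leaving three unknowns (log dilute
   composition, log dense radius) for the three equal-field equations, solved
   with a quasi-Newton root finder in log variables (the Ω residual is rescaled
   by the dense total concentration to the µ scale). Converged solutions must
   pass three checks or be rejected: residuals below 10⁻⁸ relative, the dilute
   endpoint actually more dilute, and the min-branch assignment self-consistent
   at both endpoints.
3. **Sweep.** Starting from the seed nearest the equal-concentration ray, the
   family is continued in φ in both directions with an adaptive step (halved on
   failure), stopping when refinement keeps failing (the approach to the
   critical regions, where the two endpoints merge and the Jacobian degenerates)
   or the dilute endpoint leaves the sampled window. The collected family is
   thinned to 60 tie lines uniformly by arc length along the dense branch.

Classification of a bulk point tests membership in the closed binodal polygon
(dilute branch + reversed dense branch) in log space; interior points get an
exact tie line through the bulk composition by solving the three field
equations plus the two lever-rule mass balances for (dilute, dense, λ) — five
equations, five unknowns — so the lever rule holds to solver tolerance by
construction. Points the polygon test accepts but the five-equation solve
cannot resolve (a thin fringe near the critical regions) are conservatively
reported one-phase. Ternary (three-phase) solutions are not searched for.

With the default parameters the binodal crosses the equal-concentration ray at
0.50 µM (dilute) and 181 µM (dense), the dense branch peaks at 231 µM Rubisco,
and two-phase bulk points exist with [EPYC1]/[Rubisco] well above 40. One
documented edge: the dilute boundary crosses EPYC1 = 1 µM at Rubisco
≈ 0.092 µM, so the extreme corner composition (0.05, 1.0) µM of the
experimentally phase-separating window is classified one-phase by the model —
confirmed independently by brute-force minimisation of the lever-rule split
free energy, so it is a property of the model at these parameters, not of the
solver.

## Dilute-phase composition and diffusion

At a dilute-phase composition the EPYC1 monomer fraction is
`(ρ_E − ρ_d)/ρ_E` with ρ_d from mass action; because K_d (29 nM) is far below
dilute-phase concentrations this is effectively the excess rule
max(0, ρ_E − ρ_R)/ρ_E. The FCS-observable diffusion coefficient is the
occupancy-weighted average `f·D_mono + (1−f)·D_dimer` with the empirical
anchors D_mono = 62 and D_dimer = 42 µm²/s. These two anchors (and the
38/41 µm²/s values in the binding module) are instrument measurements; they
enter only as fixed constants, nothing in the package claims to re-derive
them.

## FCS analysis

The multi-tau correlator uses m = 16 linear lags at base resolution and m/2
lags per subsequent stage with the bin width doubled each stage, up to a tenth
of the trace by default. Normalization is symmetric — means taken over the
overlapping segments of each lag pair — which removes the leading bias from
slow drifts. Per-lag uncertainties, when requested, come from correlating ten
contiguous sub-traces independently. A deliberately naive O(N·n_lags)
correlator with identical binning serves as the oracle in the tests; the two
agree to float precision at base-resolution lags and to <10⁻³ at binned lags.

The fit model is the one-species 3D-Gaussian form
`G(τ) = G0/[(1+τ/τ_D)√(1+(τ/τ_D)/κ²)] + c0` with κ = w_z/w_xy **fixed at 5**
(a typical confocal aspect ratio; κ is ill-conditioned against τ_D in a single
curve and is a property of the instrument). No triplet/photophysics term is
included; short-lag residual structure is reported, not modelled. The
detection volume defaults to the calibrated V_eff = 0.58 fL, giving
w_xy = (V_eff/(π^{3/2}κ))^{1/3} = 0.275 µm (note 1 fL = 1 µm³), and
D = w_xy²/(4τ_D). Calibration from a dilution series regresses occupancy
N = 1/G0 = c·N_A·V_eff through the origin and flags series whose per-point
V_eff spreads by more than 25%.

**Fit weighting.** The production pipeline (`measure_diffusion`) fits
*unweighted* and in two passes: an initial fit over the whole ladder, then a
refit restricted to lags ≤ 100·τ̂_D. Segment-derived per-lag errors (10
segments) were evaluated as weights and retained as an option, but on
simulated traces they are themselves so noisy that weighting inflated both the
bias and the spread of recovered D (typical error 4→8% s.d.); with only ten
segments the weight estimates carry ~30% relative error and correlate with the
G estimates they weight.

## Synthetic data

`simulate_fcs_trace` integrates point emitters through a periodic box with
independent Gaussian steps of rms √(2DΔt) per axis and evaluates a 3D-Gaussian
detection profile centred in the box (after wrapping, the coordinate itself is
the minimum-image displacement from the focus); photon counts are Poisson per
bin on the brightness-weighted profile plus background. Displacement noise is
drawn vectorized in float32 chunks from a seeded PCG64 generator and consumed
by a compiled (numba) kernel; everything is bit-reproducible from (config,
seed).

Numerical-fidelity choices: Δt = bin width = 10 µs (rms step ≤ w_xy/5 for the
fastest species, so the focus is resolved); the default box is 12 w_xy
laterally and 12 w_z axially. The box size matters more than the usual ≥8
focal radii: a periodic box suppresses concentration fluctuations at
wavelengths beyond the box, which in an 8-radius box measurably depressed
G(τ) in the mid-decay region and added a recirculation tail, biasing fitted D
by ~+7%; at 12 radii the artifact is below the percent level. The default
occupancy regime is single-molecule-like (0.3 nM ⇒ ⟨N⟩ ≈ 0.05 in V_eff,
G0 ≈ 19) with brightness 3×10⁵ photons/s at focus, chosen so a 60-s trace has
a ≥10 kHz mean count rate and delivers ~10⁴ transits; concentration and
brightness are synthetic stand-ins, not instrument values. What the simulator
does *not* emulate: triplet/blinking/bleaching photophysics, detector
afterpulsing and dead time, background scattering structure, and dense-phase
(intra-condensate) measurement — so passing recovery tests demonstrate
correctness of the correlator/fit pipeline under ideal photon statistics, not
robustness to every artifact of real acquisitions.

The binding generator draws Gaussian noise (σ = 2 µm²/s) around the quadratic
model at the experimental design (10 nM labelled EPYC1, Rubisco 1–600 nM
log-spaced, 12 points); the phase-scan generator evaluates the tie-line
prediction at each bulk point and adds optional noise.

## Binding analysis

The bound fraction uses the full depletion-corrected quadratic
`f = [E+R+K − √((E+R+K)² − 4ER)]/(2E)` (the labelled-species concentration is
comparable to K_d, so the excess-ligand hyperbola is invalid; the two agree
within 1% only once R ≥ 50E). The titration fit floats (K_d, D_bound) with
D_free fixed at the free-species measurement, optimises in log K_d, and
derives the 68% interval from the profile likelihood (χ² + 1 crossings with
D_bound re-optimised at each K_d). When the fitted K_d is within 3× the
labelled-EPYC1 concentration the estimate is flagged as an upper bound —
in that regime depletion of the labelled species dominates the curve shape
and the data constrain K_d only from above. Horizontal (concentration)
uncertainty is not modelled; it is a known systematic of the assay.
Oligomer diffusion uses Stokes-type scaling D ∝ MW^(−1/3) anchored at the
Rubisco-alone measurement (38 µm²/s, 550 kDa) with EPYC1-GFP at 62 kDa,
reported to the nearest integer.

## Problem sizes

The test suite and drivers use: a 120×120 detection grid and 60 tie lines for
the binodal (seconds); 60-s simulated traces at 0.3 nM (≈33 particles, 6×10⁶
steps, a few seconds each), 20 seeds per reference D for the recovery check;
100 seeded titrations for the K_d precision/coverage check. These sizes give
sampling error comfortably below the tolerances they are tested against.

## Known limitations

Mean-field only (no loop corrections, no explicit solvent); no higher-order
complexes (one EPYC1 bridging several Rubiscos, or several EPYC1 per Rubisco)
beyond the 1:1 dimer; the coexistence sweep deliberately stops short of the
critical points, so the binodal is reported only where the two phases are
well separated; the FCS model has no photophysics; κ and V_eff are taken as
known instrument constants rather than fitted.
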