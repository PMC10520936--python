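# Methods

This note records the model as implemented, the numerical choices, the
default parameters and what they rest on, and the known limitations — in
enough detail to reproduce or modify any part.

## Physical picture and assumptions

A spherical cell (radius 3.3 μm) sits at the centre of a spherical bath
(radius 9.9 μm, three cell radii).  A unipolar pulse train at a THz
repetition rate drives the system along the polar axis.  At these
frequencies the wavelength in the aqueous medium far exceeds the domain, so
the electric problem is quasi-static: the potential obeys Laplace's equation
instantaneously in both media, magnetic effects are dropped, and the bulk
media are charge-neutral ohmic conductors (σᵢ inside, σₒ outside).  The
resting potential enters as the initial condition of the membrane-potential
ODE, not as a bulk charge distribution.

The whole model is axisymmetric: every state variable is a function of the
polar angle θ only.  Seven angles (0, π/6, …, π) are always grid nodes and
are the reportable set.

## Module-by-module

### Stimulus

Rectangular unipolar pulses: amplitude E₀, repetition frequency f_rep, duty
cycle d (pulse width d/f_rep), truncated exactly at the stimulation duration
t_on.  An optional raised-cosine edge (fraction of the pulse width per edge)
is provided because ideal steps can excite spurious ringing in explicit
time-stepping; the default is the ideal rectangle, which proved stable at
the default steps.  At fixed (E₀, d, t_on) the delivered ∫E dt is
frequency-independent up to one pulse width — the mechanistic reason for the
band-wide invariance of the cellular response.

### Field solver

2-D (r, θ) finite differences; uniform radial grids in each medium sharing a
single centre node (closed with a solid-angle-average condition), reflection
at the poles with the L'Hôpital-regularized polar term 2/r²·∂²Φ/∂θ², a
potential jump Φᵢ − Φₒ = V_m(θ) at the membrane with continuity of normal
conduction current (second-order one-sided differences on both faces), and
the Dirichlet applied-field condition −E(t)·r·cosθ at the outer boundary.
Rows are equilibrated before the sparse LU factorization (the Laplacian rows
scale like 1/Δr² ≈ 10¹³ while the jump rows are O(1); without scaling the
solve loses ~10 digits).

Because geometry and conductivities are fixed, the solution is affine in
(E, V_m).  The solver precomputes the normal-current response
J_n = j_E·E + M·V_m with N_θ + 1 solves; the time loop then costs one
13×13 matrix-vector product per step.  Full potential fields remain
available through `LaplaceSolver.solve` for diagnostics.

Validation: in the static-field, passive-membrane limit the induced voltage
matches the classical spherical-cell closed form 1.5·E·R·cosθ·(1 − e^(−t/τ)),
τ = R·C_m(1/σᵢ + 1/(2σₒ)), to 0.6% of the plateau across the whole charging
transient on the default grid.  The finite 3R Dirichlet boundary biases the
plateau by −1.8% relative to an infinite bath (the exact finite-domain
factor is 1/(1 + R³/2R_d³)); this truncation is intentional — it matches the
finite simulated domain — and partially cancels the discretization error on
the default grid.  Halving Δr and Δθ moves the peak induced voltage by 0.9%.

The membrane ODE C_m dV_m/dt = J_n − g₁(V_m − V_rest) − I_p is advanced by
explicit Euler.  The explicit bound from the bulk coupling
(2C_m/|λ_max(M)| ≈ 26 ns for the default grid) is checked at plan time; the
actual steps are orders of magnitude smaller.  The pump current is *not*
included in this balance by default (the membrane balance lists the leak and
the pore current; pump current densities are ~4+ orders below pore current
densities once pores open); `flags.include_pump_current_in_vm` adds it.

### Electroporation

Pore density per angle follows the asymptotic (density-ODE) electroporation
model; pore radii follow the overdamped force balance with electric,
steric, edge and tension terms, coupled through the whole-cell effective
tension σ_eff(A_p) — pores anywhere on the membrane relax the tension
everywhere (the tension argument is the *whole-cell* open area, not a
per-angle one).

Discrete pores are deterministic *cohorts* (radius, fractional count) per
angle.  Newly created density merges into the youngest cohort at the minimum
radius r*; a fresh cohort slot opens every 16 steps; an angle that exhausts
its 64 slots merges its two nearest-radius cohorts at the area-preserving
radius.  Negative density increments (resealing) scale all counts down
proportionally.  These rules make the identity N·A_θ = Σ counts exact at
every step, bound memory over arbitrarily long runs, and keep the simulator
bit-reproducible (there is no stochastic nucleation: the model is a
deterministic density description, so no seed exists in the simulator).
The density ODE sub-steps internally whenever a step would move N by more
than 10% of the local equilibrium density.

Resting state: the zero-voltage equilibrium density N₀ = 1.5×10⁹ m⁻² on
a 137 μm² cell amounts to ~0.2 pores; it is carried as a fractional cohort
at the zero-voltage equilibrium radius (≈ r_m), giving a resting open-area
fraction of ~3×10⁻⁹ — electrically negligible, bookkeeping-exact.

### Pore transport

Fluxes through open pore area use the generalized modified
Poisson–Nernst–Planck law with finite effective ion sizes.  Gradients across
the membrane are two-point differences over the membrane thickness
(∇Φ ≈ −V_m/d_mem, ∇c ≈ (cₒ − cᵢ)/d_mem, outward positive), and the
concentration inside the membrane is the arithmetic mean of the faces.  No
partition or hindrance factor is applied inside pores; fluxes scale with the
fractional open area f_p(θ) only.  The pore current density is the exact
charge-flux identity I_p = F·Σ_j z_j J_j.

Concentrations live in conical-shell compartments (one intra-, one
extracellular per angle).  Updates move moles between paired compartments,
conserving each species to round-off (~10⁻¹⁴ relative over a stimulated
run).  Two guards handle depletion: the step is sub-divided with fluxes
recomputed from the evolving state, and — because the mid-membrane-mean
discretization keeps an outward flux finite even as the source face empties
— a conservative flux limiter caps the moles moved by the moles present.
Limiting the transfer, rather than clamping concentrations at zero,
preserves exact mass conservation.  In the reference run the limiter engages
only for Ca²⁺ at the depolarized pole, whose compartment empties during the
high-voltage window.

Lateral (angle-to-angle) bulk diffusion is off by default: over ≤100 ns the
diffusive displacement √(D·t) ≈ 10–20 nm is far below the μm compartment
scale.  An "infinite bath" mode (`flags.clamp_extracellular`) holds
extracellular concentrations fixed; the default is the closed finite domain.

### Na⁺,K⁺-ATPase

The four-state cycle with voltage-partitioned ion binding: cubic Na and
quadratic K saturating binding fractions on each membrane face, MgATP
saturation on the forward phosphorylation step, MgADP linearity and the
10^(3−pH) phosphate/proton term on the backward steps.  The steady-state
cycle rate is the closed King–Altman expression; a test verifies it against
an independent stationary-distribution solve (exact rational Gaussian
elimination) to 10⁻¹⁰ relative over 1000 random rate vectors spanning five
decades.  The pump responds instantaneously to V_m and concentrations
(steady-state cycle approximation); no relaxation dynamics are added.

The pump is evaluated at each angle's local V_m and face concentrations; the
angle's share of the whole cell's pumps is its area fraction A_θ/A_cell, so
summing per-angle flows recovers the 3:2 whole-cell stoichiometry exactly
(2·J_Na + 3·J_K = 0 at every step, as an identity).  The per-angle power
trace reports the whole-cell-equivalent power at that angle's voltage, and
the headline "average power" is the plain arithmetic mean over the angle
nodes — all angular averages here are unweighted means over the θ nodes,
not solid-angle-weighted ones.

Voltage exponentials are clamped at |argument| = 50 (≈ |V_m| > 1.9 V for the
largest partition coefficient) purely as an overflow guard; a test verifies
it does not engage for |V_m| ≤ 1 V.

**Power accounting.**  One ATP is hydrolyzed per cycle — one third of the
Na⁺ transport rate.  The default mode multiplies the ATP consumption rate in
molecules/s (I/q_e) by the per-molecule hydrolysis energy Q_ATP = 10·k_BT,
giving ~10⁻¹¹ W for tens-of-pA pump currents.  A "literal" mode additionally
divides by N_A (equivalently: reads Q_ATP per mole while consuming in
mol/s); both are exposed because the two conventions appear in print, and
their ratio is exactly N_A.  The per-molecule mode is dimensionally the
power per cell and is the reporting default.

**Fitting.**  `fit_iv` does weighted least squares of the cycle I-V against
data, in log coordinates for positive parameters, with seeded multi-start
and a box of ±1 decade around the initial guess (the model has an exact
F_c–kd scaling ridge once a binding step unsaturates; dissociation constants
and the current scale are physiologically known to order of magnitude, which
the box encodes).  Standard errors are profile-likelihood based: each free
parameter is walked away from its estimate with the others refit, the
3σ crossing (Δχ² = 9) is bisected, and one third of that half-width is
reported per side.  The local Gauss–Newton covariance is also computed (it
feeds the near-singularity identifiability warning) but is overconfident
along the model's curved likelihood valleys.  `FitResult.within_n_se`
evaluates coverage on the natural (log) scale of positive parameters.

The parameter-recovery study in the tests and the acceptance script uses
the guinea-pig parameter set on a −0.12…0.4 V grid: that curve's rise and
peak lie inside the sampled window, making the {F_c, kd_Nao0, kd_Ko0} trio
practically identifiable at 5% noise.  With the rat set, whose rise sits
near +0.4 V, the same noise genuinely rejects the true kd_Ko0 at >3σ in
roughly a tenth of noise draws (verified by evaluating the profile
likelihood at the truth): a recovery study on such a design tests the
experimental design, not the fitter.

### Orchestrator

Fixed first-order operator splitting per step: stimulus → potential
response → membrane ODE → pore step → pore fluxes and I_p (used by the next
step's membrane ODE) → pump evaluation → concentration update.  Ion flows
and concentrations are therefore computed alternately.

Time steps: dt = pulse_width/20 while the drive varies (0.05 ps at
0.5 THz), then geometric growth (factor 1.05) capped at 100× the stimulation
step and at half the explicit stability bound.  Long relaxation runs
(hundreds of ns) raise the cap factor to 500 (25 ps), still ~10³ below the
stability bound.  Self-convergence: halving the stimulation step moves the
pore-activation time and the peak averaged power by <5%.

Frequency sweeps use one *common absolute* step — the finest pulse width
across the compared frequencies — because the concentration changes (K⁺ in
particular, a near-cancellation of opposing fluxes ~30× smaller than the
Na⁺ change) are sensitive enough to discretization that per-frequency steps
would confound the comparison.  With the common step the 0.1–1.2 THz spread
is 0.15% (Na⁺) and ~4–5% (K⁺).

Recording decouples physics steps from output (default ~1000 frames/run).
Detectors: pore *activation* is the first time any angle's density exceeds
10× N₀ (threshold must exceed 1, since N starts at N₀); pump *closure* is
the first time the averaged |pump current| falls below a relative threshold
(default 10⁻⁴) of its post-stimulation peak and stays there for 1 ns.

## Default parameters

Geometry: R_cell = 3.3 μm, R_domain = 9.9 μm, d_mem = 5 nm, N_θ = 13,
N_r = 33 + 33.  Electrical: C_m = 10⁻² F/m², g₁ = 2 S/m², σᵢ = 0.455 S/m,
σₒ = 1.2 S/m, T = 310 K, V_rest = −70 mV (rat) / −85 mV (guinea pig).
Electroporation: α = 10⁹ m⁻²s⁻¹, V_ep = 0.258 V, N₀ = 1.5×10⁹ m⁻²,
r* = 0.51 nm, r_m = 0.80 nm, q_p = (r_m/r*)² (exponent configurable),
D_p = 5×10⁻¹⁴ m²/s, F_max = 0.70 nN/V², r_h = 0.97 nm, r_t = 0.31 nm,
β = 1.4×10⁻¹⁹ J, γ = 1.8×10⁻¹¹ J/m, σ′ = 2×10⁻² N/m, σ₀ = 10⁻⁶ N/m — the
standard asymptotic-electroporation literature set.  Ions (D in 10⁻⁹ m²/s,
hydrated radius in nm, cᵢ/cₒ in mol/m³): Na⁺ 1.33/0.358/12/145,
K⁺ 1.96/0.331/139/4, Ca²⁺ 0.79/0.412/10⁻⁴/2, Cl⁻ 2.03/0.332/10/110.

Pump constants are *literature-informed synthetic sets* (the study-specific
fitted tables are not published in accessible form): forward rate constants
of the Smith–Crampin family (k₁⁺ = 1050, k₂⁺ = 481, k₃⁺ = 2000,
k₄⁺ = 320 s⁻¹), backward constants set small so the cycle runs far from
reversal at physiological potentials (pump reversal lies well below
−200 mV), dissociation constants and voltage partitions chosen so the rat
I-V is monotone over −120…+60 mV with its main rise at positive potentials,
and the guinea-pig curve is narrower and shifted toward negative potentials
— the published qualitative contrast between the two cell types.  The
current scales F_c (6.0 and 2.0 ×10⁻¹² A·s) anchor peak whole-cell pump
currents at tens to ~150 pA, the magnitude of whole-cell measurements.
Both cycles show the over-large-voltage inhibition (current falls beyond
its peak near +0.4 V (rat) / +0.13 V (guinea pig)) that produces the
transient pump shutdown at the depolarized pole during stimulation.

## What the synthetic data emulate — and what they do not

`make_iv_dataset` emulates whole-cell voltage-clamp pump I-V measurements:
the cycle-model current plus Gaussian noise scaled to 5% of the maximum
current, which stands in for unreported experimental uncertainty.  It does
not emulate series-resistance artefacts, leak subtraction errors, or
run-down, so recovery results certify the fitting machinery on clean-model
data, not robustness to real voltage-clamp systematics.  Likewise the
coupled simulation is a deterministic continuum model: passing its tests
shows the implementation solves *this* model correctly at the stated
resolutions, not that the model captures molecular-scale pore stochastics
or protein-level THz resonances.

## Known limitations and deviations

- **Pump closure time.**  With the literature-default pore constants the
  depolarized pole porates much less than the hyperpolarized one (the
  resting potential adds to the induced voltage at θ = π and subtracts at
  θ = 0, and pore creation is exponential in V_m²), so the positive cap
  discharges slowly: the averaged pump current falls to 10⁻³ of its
  post-stimulation peak only near ~200 ns, and to the default 10⁻⁴ closure
  threshold beyond 400 ns — not at ~80 ns as published with the
  study-specific fitted constants, whose membrane voltage collapses within
  ~10 ns.  The closure-time test and acceptance value report this honestly.
- **Ca²⁺ fold change.**  The computed average intracellular Ca²⁺ reaches
  ~2.8× basal at 12.3 ns (coarse grid ~3.3×) versus the published "nearly
  two times": the same pore-population difference, plus the
  mid-membrane-mean flux discretization at the nearly emptied polar
  compartment, biases the influx high.
- Poration in this parameter regime is confined to the polar caps; models
  with stronger creation rates spread it over a broader angular band and
  discharge the membrane faster.
- The 3R Dirichlet outer boundary under-drives the induced voltage by ~2%
  (documented truncation; configurable via `R_domain`).
- No electro-osmotic water flux, pH dynamics, pore-interior PNP structure,
  hindrance factors, temperature dependence of the pump rate constants, or
  ATP/ADP turnover (ligand concentrations fixed).

## Problem sizes used in tests and acceptance

The test suite runs coupled simulations on a coarse grid (7 angles,
8+8 radial nodes) — ~10 s for the 12.3 ns reference run — and the
acceptance script at full resolution (13 angles, 33+33 radial nodes;
24 000 stimulation steps of 0.05 ps, relaxation steps growing to 5–25 ps).
The long relaxation run is taken to 241 ns, and the frequency sweep covers
all eight repetition frequencies at a common 0.021 ps step.  The whole
acceptance script completes in a few minutes on one core.
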