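# Methods

## Physical model

The system is a straight cylindrical channel (internal diameter 4 mm,
length 47 mm) cast from pHEMA hydrogel, through which a dilute aqueous
dispersion of polymer-coated iron-oxide nanoparticles is driven at a mean
velocity of a few mm/s.  The package models the dispersion as a Newtonian
fluid in steady laminar flow and the particles as passive Brownian tracers
that are removed irreversibly on first wall contact.  Erythrocyte
interactions, ligand–receptor binding, particle–particle forces, magnetic
body forces and non-Newtonian rheology are out of scope by design.

Key parameter defaults (SI internally; constructors convert mm/nm/g·mL⁻¹):

| parameter | default | unit | rationale |
|---|---|---|---|
| fluid density ρ | 5240 | kg·m⁻³ | the nanofluid density used for the flow computations; together with the defaults below it reproduces the tube Reynolds numbers 120.1/127.1 at 5.1/5.4 mm·s⁻¹ exactly, so it is retained verbatim even though it is close to solid magnetite and physically surprising for a dispersion |
| dynamic viscosity μ | 8.9 × 10⁻⁴ | Pa·s | water at 25 °C; not independently reported, but the unique value consistent with the Reynolds pair above — config-overridable |
| temperature T | 298.15 | K | room temperature |
| hydrodynamic diameters | 69 / 130 / 140 / 144 | nm | the four coated formulations (PDI 0.12–0.24) |
| mean inlet velocity | 5.1 / 5.4 | mm·s⁻¹ | the two simulated doses (4.12 g and 2.008 g Fe per 1 mL) |

Derived groups: Re = ρv̄D/μ ≈ 120–127 (laminar; the constructor rejects
Re ≥ 2100), Pe = v̄D/D_B ≈ 3–6 × 10⁶, Stokes–Einstein D_B = k_BT/(3πμd)
≈ 3.4–7.1 × 10⁻¹² m²·s⁻¹, entrance length L_e = 0.05·Re·D ≈ 24–25 mm.
The entrance-length correlation is the standard laminar textbook form,
chosen because no correlation is otherwise specified.  The inlet dose is
carried as a label only: all transport here is linear in concentration.

## Mesh

Structured cylindrical meshes n_axial × n_radial × n_circ with uniform
axial spacing and geometrically stretched radial spacing from axis to
wall.  The wall-adjacent cell height is `first_wall_spacing × diameter`;
the spacing value 3.0 × 10⁻⁴ is dimensionless in its source, and is
interpreted here as a diameter fraction (1.2 µm on the 4 mm tube) — a
0.3 mm absolute reading would be *coarser* than the bulk grid and
contradict the stated boundary-layer refinement.  The stretching ratio is
solved by bisection and capped at 3; infeasible spacing/count pairs raise
a configuration error.  The circumferential dimension is bookkeeping and
VTK export only: geometry and boundary conditions are axisymmetric, so the
solvers work in (r, z) — exact by symmetry.  Solvers collocate on
[axis, cell centres, wall] so the Dirichlet wall point is explicit.

## Velocity fields

Fully developed flow is the closed-form parabola.  Developing entry flow
solves the parabolized axial momentum equation
`u ∂u/∂z = −(1/ρ)dp/dz + ν(1/r)∂/∂r(r ∂u/∂r)` by implicit marching:
radial diffusion implicit (nonuniform 3-point stencil, exact for
quadratics), convection linearised about the upstream profile, and the
unknown pressure gradient eliminated at each station by enforcing the
discrete flux Q = v̄πR² exactly (superposition of two tridiagonal solves).
Radial velocity is neglected in the momentum balance; the scheme's
acceptance surface is profile/flux behaviour (uniform inlet, flux
conserved to <0.5%, Poiseuille within 1% L∞ of v̄ downstream), which it
meets with ~0.4% outlet error on the 97-cell radial grid.  Axial substeps
are refined 40× inside the entrance region.  The y+ ≤ 1 wall criterion
sometimes quoted for such meshes is a turbulence metric and is recorded
but not computed — the flow is laminar.

## Eulerian transport

The Graetz march `u(r,z) ∂c/∂z = D_B(1/r)∂/∂r(r ∂c/∂r)` uses
Crank–Nicolson in z with 10 backward-Euler startup steps (Rannacher
damping of the inlet-corner discontinuity), the same nonuniform radial
operator, c = 0 at the wall, symmetry at the axis.  The axial step starts
at 0.2·u_wall·h_wall²/D_B (the diffusion scale of the wall cell), grows
geometrically (ratio 1.02) and is capped at L/500; a step that would
underflow raises a step-control error.  Deposition is accumulated from the
one-sided wall gradient each step; the mass-conservation defect
(inlet − outlet − deposited)/inlet is reported in the diagnostics and is
~10⁻⁷ at study conditions (tolerance 10⁻³).  Concentrations are clipped
to [0, 1] after each solve step (CN overshoot is below 10⁻⁶ here).

Wall condition: deposit-on-contact is the perfectly absorbing Dirichlet
condition at r = R.  An optional finite-particle-radius variant
(absorbing surface at R − d/2) exists in the Lagrangian stage; its effect
at these sizes is ~10⁻⁵ relative and it is off by default.

Oracles: the slug-flow eigenseries (zeros of J₀ via scipy) and the
Gormley–Kennedy asymptote `5.50 h^{2/3} − 3.77 h`, valid for
h = D_B L/Q < 0.02.  The solver agrees with the eigenseries to 0.02% at
τ = 0.05 and with Gormley–Kennedy to 0.01% at study conditions.

## Lagrangian transport

Euler–Maruyama with isotropic Gaussian increments; the transverse position
is tracked in Cartesian (x, y), which avoids the spurious drift of naive
cylindrical updates and makes the axis trivially reflecting.  No
reflection at the wall — contact is absorption.  Inlet radii are
flux-weighted (p ∝ u(r)·r, inverse-CDF), matching the uniform-concentration
inlet of the Eulerian stage.  The default time step sets the RMS Brownian
step to half the wall-adjacent node gap; explicit steps violating
√(2D_BΔt) < gap are rejected.  Particles exceeding the step budget are
counted as "stuck", never as deposited.  At n = 10⁶ the Monte-Carlo loss
is statistically indistinguishable from the Eulerian value (z ≈ −0.7), and
the packaged cross-validation requires agreement within 3 binomial
standard errors at n = 10⁵.

## Experiment analysis

Velocity = L/t in cm·s⁻¹; mass loss % = 100(m_in − m_out)/m_in, with
m_out > m_in flagged as a data-quality error rather than clipped.
Trend fits are ordinary least squares in the family ladder
linear/quadratic/cubic/general-polynomial/power; the power family is fit
in log–log space (a nonlinear refinement was considered and rejected as
an undefined improvement over the simplest defensible reading).
"R" is the multiple correlation coefficient — the sign-preserving square
root of the coefficient of determination between fitted and observed
response; a zero-variance response yields a flagged degenerate result
instead of an exception so batch runs survive pathological inputs.
Replicates are averaged per condition before fitting (matching analyses
of per-condition averages with SD error bars).  The size-correlation
report prefers the linear family unless the quadratic improves R² by
more than 0.05.  Swelling ratio is 100(W_swollen − W_dry)/W_dry.

## Synthetic data

The generator emulates the replicate structure of the bench study:
4 formulations × 7 inlet amounts (2.008–5.24 g) × 3 replicates.  True
velocities follow a cubic-in-mass trend spanning the measured
0.47–0.58 cm·s⁻¹ band; true losses follow a quadratic-in-size trend
through the measured per-formulation averages (1.77/1.60/1.96/2.45% at
69/130/140/144 nm).  Replicate noise is Gaussian, truncated at the
physical bounds by resampling (clipping would bias the moments); default
SDs (0.02 cm·s⁻¹, 0.15 percentage points) are a few percent of the means,
consistent with the reported error bars.  What the generator does *not*
emulate: injection-pressure drift, pH chemistry, instrument error
structure — so round-trip test passes demonstrate the analysis pipeline's
correctness, not the field realism of any particular noise model.
Swelling series are rise–plateau–collapse curves (sin² rise to the peak,
20% plateau decline, zero after disintegration with a flag).

## The concentration-dependence caveat

Linear advection–diffusion with absorb-on-contact predicts a fractional
loss that is *independent* of inlet concentration, and at the study
parameters the prediction is ~0.1%.  Measured and previously computed
losses for the same geometry vary with dose and are 1–6%.  No mechanism in
the stated physics (no effective-diffusivity model, no concentration
coupling, no additional body force) produces that behaviour, so the
package deliberately does not tune anything toward those figures: it
reports its model's prediction next to the oracles and flags the gap.
Closing it would require physics beyond this baseline (wall interaction
energetics, hindered transport in the soft gel surface, multi-particle
effects), all of which are out of scope.

## Problem sizes and determinism

Default runs use the optimum 129 × 97 × 37 mesh (solver cost is governed
by the 97-cell radial grid and ~800 adaptive axial steps, well under a
second), 10⁴–10⁵ Lagrangian particles (seconds), and 50-seed ensembles for
statistical round-trip checks.  Every stochastic stage takes a mandatory
integer seed (numpy Generator); identical config + seed reproduces
byte-identical result files, with wall-clock metadata confined to the
manifest sidecars.

## Known limitations

* The parabolized entry-flow scheme neglects radial momentum transport;
  centreline development is slightly faster than a full Navier–Stokes
  solution, though the downstream state is exact.
* The Eulerian wall-gradient deposition integral uses a first-order
  one-sided difference; adequate because the wall cell (1.2 µm) is ~30×
  thinner than the concentration boundary layer.
* Discrete-step Brownian absorption misses sub-step wall excursions; at
  the default step this biases deposition by well under 1% of itself.
* Power-law fits are log–log OLS, which weights relative rather than
  absolute residuals.
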