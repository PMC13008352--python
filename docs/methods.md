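# Methods

## The physical picture

The cytoplasm is modelled as a biphasic poroelastic medium: a drained
elastic skeleton (Young's modulus `E`, Poisson ratio `nu`) saturated by
interstitial fluid that flows down pore-pressure gradients following
Darcy's law, `q = -k grad p`, with hydraulic permeability `k`
[um^2/(Pa s)]. Local deformation pressurises the fluid; stress relaxes as
fluid leaves the loaded region, at a rate set by the poroelastic diffusion
constant `D`. A thin (250 nm) membrane–cortex layer of much lower
permeability wraps the cell and controls exchange with the exterior.
Three in-silico experiments probe this picture: ramp–hold AFM indentation
of a cylindrical slab, fluid microinjection into a spread (elliptical-cap)
cell, and localised depressurisation of the two-layer cell through a
small sink.

## Governing equations and conventions

Small-strain linear Biot consolidation with Biot coefficient 1 and
incompressible constituents (every volume change is fluid exchange):

    div(sigma') - grad p = 0,     sigma' = 2 mu eps + lambda tr(eps) I
    d/dt div(u) + div(q) = 0,     q = -k grad p

`p` is pore pressure above ambient (positive in compression); effective
stress acts on the drained skeleton as `sigma' = sigma_total + p I`.
The experiments reach strains of order 10%, where a large-deformation
(porohyperelastic) description would differ quantitatively; the linear
model is retained because every quantitative result in this package is a
self-consistency recovery (the same forward model generates and fits the
data) and the qualitative spatial patterns of interest survive
linearisation. An initial uniform pressure `P_in` is treated as a
pre-stressed equilibrium (balanced in vivo by cortical tension and
osmosis, which are not modelled): the solver computes deviations from it
and reports totals, so a pressurised, undisturbed cell stays exactly at
rest.

`D` and `k` are interchangeable through the oedometric (confined
compression) modulus:

    D = k * M_oed,   M_oed = E (1 - nu) / ((1 + nu)(1 - 2 nu)).

Only the scaling `D ~ kE` is physically pinned; this specific convention
is applied consistently in both directions, so parameter recoveries are
convention-independent. Internal units are um, s, Pa, nN throughout
(1 m^2/(Pa s) = 1e12 um^2/(Pa s); 1.25e-13 m^2/(Pa s) = 0.125 um^2/(Pa s)).

## Discretisation

Axisymmetric meridian sections are meshed with structured 9-node
biquadratic quadrilaterals for displacement and geometry, with bilinear
pore pressure on the corner nodes (Taylor–Hood pairing, inf-sup stable,
the quadratic-displacement choice mirroring standard consolidation
elements). Radial grading refines the contact/pipette patch; an optional
geometric bias concentrates element rows under the loaded surface; the
cortex layer is always resolved by at least two rows through its 250 nm.
The elliptical cap is truncated at a 1 um rim so elements stay
well-shaped. Integration is 3x3 Gauss; the hoop strain `u_r / r` is
evaluated at Gauss points only, so the axis needs no special casing.

Time stepping is implicit backward Euler, monolithic in (u, p), with LU
factorisation reuse across equal step sizes. Grids ramp uniformly through
the loading phase, then grow geometrically with a cap on the maximum step
(the cap bounds the first-order time-discretisation error at late times).
Per step the solver records the maximum pore-pressure change and the
global continuity residual; the Terzaghi validation holds the residual
below 1e-8 and matches the closed-form consolidation series to <1%
relative L2 across `Tv` from 0.05 to 1.

### Boundary conditions per scenario

* **Indentation** (disk, default 20 x 20 um; indenter radius defaults to
  R = 2 um, matching a ~4 um contact diameter, and is configurable):
  no-slip base; free, drained (p = 0) top surface; the contact is the
  prescribed rigid-sphere penetration profile `u_z = -(delta - r^2/(2R))`
  over the geometric patch `a = sqrt(2 R delta)`, frictionless and
  impermeable. Prescribing the edge-continuous spherical profile rather
  than a uniform punch avoids a strong contact-edge singularity and gives
  <2% force change per mesh halving; a contact-inequality solver is out
  of scope. The reaction force is assembled from the residual at the
  constrained dofs.
* **Injection** (elliptical cap, 40 um diameter x 4.5 um): no-slip base;
  pipette patch (1 um radius) held at `P_app` ramped over 2 s; all other
  surfaces impermeable, because the ~2 s injection is fast compared with
  trans-membrane water exchange (tens of seconds). Probe displacements
  are read at the undeformed surface radii (small-strain consistency).
* **Depressurisation** (cap + 250 nm cortex): the pipette establishes a
  whole-cell fluidic connection, so the cortex layer is breached under
  the 1 um sink patch, which is held at `P_app < P_in`; the outer surface
  away from the sink is held at the reservoir pressure `P_in`,
  representing trans-membrane influx that keeps cell volume constant (no
  explicit osmotic model). The cortex diffusion constant `D1` then sets
  how far the depression reaches: at steady state the sink efflux and
  membrane influx balance to <1%.

Steady state is declared when the monitored field changes by <1% of its
maximum over the final 5% of the window; runs auto-extend once (doubled
horizon) if the test fails. Inference disables auto-extension so truth
data and fit candidates share one horizon.

## Estimators

* **Time lags** implement both threshold rules in use: an absolute 0.1 um
  displacement (experimental traces) and 10% of the steady-state
  displacement (simulations); the rule is always an explicit argument.
  Crossings are linearly interpolated between samples; a trace that never
  crosses returns `None`, distinct from a zero lag.
* **Darcy regression** forms `v_i = L_i / dt_i` and `g_i = dP_i / L_i`
  and fits `v = k g` through the origin (Darcy's law has no offset); the
  free-intercept r^2 is reported alongside for comparability with
  published fits.
* **The slow-phase relaxation time** `tau_p` is a single-exponential fit
  after a fixed phase split at 0.3 s (the upper bound of the fast phase);
  a fixed split is preferred to changepoint detection because the fast
  phase is unresolved at the 67–100 ms frame intervals, and the
  exponential form is the simplest consistent with diffusive
  equilibration.
* **Pore-size scaling** uses `xi/xi0 = (alpha + phi (alpha - 1))^{1/3}`
  with `t_p/t_p0 = (xi/xi0)^{-2}`. Note a convention wrinkle: for a 40%
  volume *decrease* the bracket [0.72, 0.77] quoted for these parameters
  requires `alpha = V/V0 = 0.6`; evaluating the formula at `alpha = 0.4`
  gives [0.53, 0.58]. The formula is implemented as printed and `alpha`
  is documented as the post-shock volume ratio; the discrepancy is
  flagged here rather than silently fixed.

**Known bias.** Applying the front estimator (`v ~ dx/dt`,
`gradP ~ dP/dx`) to the injection simulation's own lags overestimates the
solver's permeability by a factor ~2.1: the front-averaged gradient
`dP/dx` understates the local gradient driving the front. The estimate is
order-of-magnitude accurate, which is the level at which such estimates
should be read.

## Parameter inference

Both fits minimise the sum of squared relative residuals (each observable
group scaled by its own maximum), with `nu = 0.3` fixed and, for
injection, `P_eff` fixed at its measured value. Identifiability: under
displacement control the steady indentation profile is independent of
`E`, so the force-relaxation curve is required whenever `D` is free (its
amplitude pins `E`, its decay pins `D`); for injection the displacement
amplitude scales as `P_eff / E` and the lags pin `D`, so an error in
`P_eff` maps directly onto the fitted `E`. Stage 1 scans a 5x5 log-spaced
grid over the bounds; stage 2 is bounded Nelder–Mead in log-parameters,
restarted from its own optimum up to twice (a fresh simplex rescues the
occasional collapse in the shallow valley along `D`). Everything is
deterministic. Fitting uses a coarse forward model (~50–100 ms per solve);
an optional fine-mesh verification solve warns when observables shift
more than 5% under refinement.

## Ring tracking

Synthetic defocused beads are sums of Gaussian annuli (outermost at the
nominal radius, spacing at least 4 ring-widths so annuli stay resolved)
over a flat background with Gaussian noise. The tracker takes a
horizontal profile through the ring centre, averaged over a 3-px band (a
1-px line is noise-limited; the band width is configurable), finds the
first and last peaks on a lightly smoothed copy, then fits a Gaussian to
each peak on the raw profile; the radius is half the distance between
fitted centres. The centre defaults to the intensity centroid; centre
error is not corrected, only propagated into the radius uncertainty.
Radius maps to height through a linear piezo-step calibration, valid over
the limited defocus range used. Measured performance on synthetic frames:
bias < 0.1 px across radii 10–40 px, RMSE 0.07 px at 10%-of-contrast
noise, and 1–2 nm RMSE on tracked height ramps (20 nm is the asserted
bound).

## Synthetic data

The generators reproduce the statistical *structure* of the experiments —
biphasic traces with distance-dependent slow times and a sign switch at
6 um, Darcy-consistent pressure-step lags (`dt = dx^2/(k dP)`, with a
constant-front-speed alternative), hyperbolic-onset metaphase diameter
courses with 3 replicates per pressure, ring-image stacks — with defaults
of 5 nm additive noise on heights and 10–20% multiplicative noise on
lags. Amplitude-vs-distance defaults are order-of-magnitude placeholders
(the measured amplitude profiles exist only as figures). All randomness
flows from one explicit seeded generator; equal seeds give bitwise-equal
outputs, and at zero noise every planted parameter is recovered by its
estimator exactly. The generators do not emulate camera photophysics,
drift, or cell-to-cell variability beyond the stated noise, so passing
round trips demonstrate estimator correctness, not robustness to every
artefact of real recordings.

## Numerical limitations

* The pressure-Dirichlet/impermeable transition at the pipette or sink
  edge makes the boundary flux weakly singular: injection near-field
  observables converge at only ~4% per uniform mesh halving (local edge
  refinement does not remove it at practical sizes). Parameter recovery
  is unaffected because forward and inverse share one discretisation; the
  <2% halving criterion is met by the regular-field outputs (reaction
  force, column pressure fields).
* In the thick 20 x 20 um slab the steady linear-model surface
  displacement is downward at all radii. The observed down-near/up-far
  sign switch around 6 um appears once the layer is thin: indenting a
  4.5-um disk (the spread-cell thickness) forces conserved volume up
  through the surface, giving a steady crossover at ~6 um with ~10 nm
  uplift. The qualitative sign-change analysis therefore runs on the thin
  disk; parameter recovery keeps the thick slab.
* No surface-tension term is included, so the sub-0.3 s fast phase of the
  bead response (attributed to cortical tension) is outside the model;
  the solver addresses the slow, poroelastic phase only.

## Problem sizes

Validation columns use 40 quadratic elements over 10 um with ~450
geometric time steps; scenario meshes span ~300–3000 nodes; each
inference run takes 200–500 forward solves on the coarse mesh (tens of
seconds in total); Monte-Carlo suites use 50–200 seeds per estimator.
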