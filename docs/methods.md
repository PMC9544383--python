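# Methods

`biofilmflow` simulates how a bacterial biofilm deforms, recovers and
detaches under channel flow, using a two-way coupled CFD-DEM
(computational fluid dynamics - discrete element method) description:
every bacterium and every blob of extracellular polymeric substance
(EPS) is an individual spherical agent, and the surrounding fluid is a
continuum on a grid.  This note documents the model equations, the
parameter choices, the numerical methods, and the reduced desk-scale
study conditions under which the package's tests and acceptance script
run, including what those runs can and cannot say about full-scale
biofilms.

## 1. Model overview

The study has two decoupled stages.

**Growth (quasi-static, days).**  A colony is grown from a few founder
cells on the substratum under static conditions (default 5.3 days).
Cells grow at the Monod rate `mu = mu_max * S / (K_s + S)` with
multiplicative lognormal noise, divide at diameter 1.4 um into two
equal-volume daughters along a random axis, and excrete EPS shells as
discrete agents.  Agent diameters stay within 0.7-1.4 um.  Substrate is
well mixed (no transport gradients); detachment during growth is not
modeled.

**Flow (dynamic, milliseconds).**  The grown colony is exposed to
channel flow.  Each agent i obeys

    m_i dv_i/dt = f_contact,i + f_cohesion,i + f_fluid-particle,i

with Hookean spring-dashpot contacts, pairwise Hamaker sphere-sphere
cohesion, and drag + shear-lift coupling to the fluid.  The fluid obeys
the locally averaged incompressible Navier-Stokes equations

    div(eps_s U_s + eps_f U_f) = 0
    d(eps_f U_f)/dt + div(eps_f U_f U_f)
        = (1/rho_f)(-grad p + eps_f div R + F_fp)

where `eps_s` is the local solid volume fraction (`eps_f = 1 - eps_s`),
`U_s` the averaged particle velocity and `F_fp` the reaction force
density from the particles.  Only viscous stress is kept in R: the
channel Reynolds number (hydraulic diameter of the 30 x 50 um duct) is
3.75-15 over the 0.1-0.4 m/s driving range, far below any turbulence.

### Boundary conditions and driving

The channel (200 x 30 x 50 um at full scale) is cyclic in the
streamwise (x) and spanwise (y) directions, no-slip at the bottom wall
(a fixed layer of wall particles provides substratum roughness and
adhesion sites), and driven from the top.  Two driving modes exist
because a lid-driven description and an inlet-velocity description both
appear in the literature for this geometry; the quoted shear rates
(2000-8000 1/s) equal U/H, which is the lid-driven (Couette) value, so
Couette is the default.  An inlet/outflow mode (prescribed uniform
inflow, zero-gradient outflow, free-slip lid) is provided as an option.

Two experiment protocols:

* *steady flow*: constant driving speed U for 40 ms; detachment events
  are logged and the detachment rate coefficient -- detached volume over
  initial colony volume per millisecond -- is computed over the first
  14 ms;
* *deformation-recovery*: the driving speed ramps as `U(t) = a t` for
  3 ms (reaching 0.06/0.09/0.12 m/s for a = 20/30/40 m/s^2) and is then
  set to zero for 17 ms.  By default the fluid keeps evolving during
  relaxation and decays viscously; `freeze_fluid` implements the
  literal "flow stopped" reading (fields zeroed instantly).  The two
  differ only during the first ~H^2/nu ~ 1 ms of relaxation.

## 2. Forces

**Contact.**  Hookean normal spring `k_n * overlap` plus overlap-scaled
dashpots: the damping force is `gamma * m_eff * overlap * v_rel`, which
is the interpretation under which the published damping constants
(gamma_n = 1e13 m^-1 s^-1, gamma_t = 10 m^-1 s^-1) carry consistent
units.  The tangential spring accumulates shear displacement per
contact and is cleared on separation; no Coulomb cap is applied (no
friction coefficient is part of the parameter set), and rolling
friction and Hertzian contacts are out of scope.

**Cohesion.**  The sphere-sphere Hamaker attraction

    |F| = (A/6) * 64 ri^3 rj^3 (s + ri + rj)
          / [(s^2+2ri s+2rj s)^2 (s^2+2ri s+2rj s+4 ri rj)^2]

with surface separation s clamped at `s_min` when particles touch.  For
equal spheres at close approach this reduces to `A r / (12 s^2)` (the
package tests verify agreement within 1% for s < r/100).  Five pairwise
strengths are used (J): EPS-EPS 5e-18, bacteria-EPS 1.6e-18, EPS-wall
2.3e-18, bacteria-wall 2.3e-21, bacteria-bacteria 1.6e-21 -- EPS-driven
bonds three orders of magnitude stronger than purely bacterial ones.
Cohesion is cut off beyond a gap of `cohesion_cutoff_factor *
min(ri, rj)` (the force there is below 1e-6 of its contact value); the
clamp distance `s_min` is a free model parameter (1 nm default at full
scale) because the Hamaker form diverges at contact.  Note that `s_min`
effectively sets the bond strength and therefore the detachment
threshold of the assembly.

**Drag.**  Per particle, `f = Vp eps_f eps_s beta (U_f - u_p)` with
beta from the Syamlal-O'Brien terminal-velocity correlation (standard
coefficients, 0.8/2.65 branch crossover at eps_f = 0.85).  The eps_s
factors cancel against the correlation's own 1/eps_s, leaving a finite
per-particle force that reduces to ~0.96x Stokes drag (3 pi mu dp
|slip|) in the dilute low-Reynolds limit.

**Lift.**  `f = Cl (rho_f mu)^0.5 dp^2 (U_f - u_p) x omega /
|omega|^0.5` with Cl = 1.6 and omega the interpolated curl of the fluid
velocity; zero in irrotational flow.  Added-mass, Basset history and
Magnus forces are not modeled.

Gravity/buoyancy cancel exactly: agents have the carrier fluid's
density (1e3 kg/m^3).

## 3. Numerics

**DEM.**  Velocity-Verlet with one force evaluation per step; wall
particles are pinned; cyclic axes wrap.  The default step is
`0.05 sqrt(m_min / k_n)` (explicit spring stability), and `step_dem`
rejects steps above `0.1 sqrt(m_min / k_n)`.  Neighbor lists come from
a kd-tree (cyclic axes via the tree's periodic box; a cached static
tree for the immobile wall layer) with a 0.6 um skin, rebuilt when any
particle has moved half a skin.  Per-contact tangential history
survives list rebuilds by pair-key matching.  The drag term enters each
half-kick implicitly, (v + h C u_f/m)/(1 + h C/m), so the integration
is stable for arbitrarily large drag coefficients -- the drag response
time of a micron agent (~m/C ~ 5e-8 s) is otherwise close to the DEM
step.

**Fluid.**  MAC staggered grid (velocities on faces, pressure at cell
centers), first-order upwind advection, explicit viscous diffusion and
a first-order projection onto the mixture continuity constraint.  The
projection Poisson equation has constant coefficients (the correction
divides by the face fluid fraction), so it is factorised once per grid
(sparse LU) and reused; the discrete residual of
`div(eps_s U_s + eps_f U_f)` after a step is at direct-solver
precision (the suite requires < 1e-8 relative).  The lid and bottom
walls enter through ghost layers, which makes the linear Couette
profile and the discrete parabolic Poiseuille profile exact stationary
solutions up to O(h^2) wall placement error (~1/nz^2; 64 cells give
~0.06%, comfortably within the 1% acceptance band).  Step_fluid rejects
steps violating the advective CFL (0.5) or the explicit viscous bound.

**Coupling.**  Trilinear (cloud-in-cell) weights both ways, with two
conservative Jacobi diffusion sweeps regularising eps_s on the coarse
grid (cell sums are preserved exactly; the volume-conservation identity
Sum eps_s Vcell = Sum Vp is tested to machine precision).  One fluid
step interleaves with `dt_fluid/dt_dem` DEM sub-steps (100 at full
scale); drag coefficients and lift vectors are frozen at the start of
each fluid step, but the drag force tracks the evolving particle
velocity through the frozen coefficient.  On the fluid side the drag
reaction is deposited as an implicit relaxation sink
`u <- (u + dt K Up)/(1 + dt K)` rather than an explicit force: dense
cells have drag response times (~2.5e-7 s) far below the fluid step,
and the explicit form is violently unstable there.  The explicit
equal-and-opposite bookkeeping (`exchange_step`) remains the reference
implementation for the momentum-conservation identity and is tested to
machine precision.

**Cluster detection and events.**  Particles within a 50 nm surface
gap are bonded; connected components containing a wall particle are
"attached".  At 50 nm the Hamaker force has decayed by >10^3 from its
clamped contact value, a natural broken-bond scale.  A cluster is
counted as one detachment event the first time it loses wall
connectivity (re-attachment within the window is ignored; each particle
is counted once).  Events with fewer than 1000 particles are erosion,
1000 or more sloughing (the published partition leaves exactly 1000
unassigned; it is classified as sloughing so the partition is total).
Agents already loose at t = 0 (placement artifacts of stochastic
growth) are recorded as a pre-detached baseline, not as events, and
every experiment starts with a 0.2 ms quiescent settling phase so
contacts and bonds equilibrate before driving starts.  Detached debris
farther than 5 um from the attached colony is removed from the
simulation: with cyclic boundaries it would otherwise orbit the channel
and re-impact the colony, which a real channel with an outlet does not
allow.  Statistics are unaffected (events are recorded at detachment).

**Stress and strain.**  The global shear stress is the virial over the
attached colony,

    sigma_xz = (1/V) [ Sum_pairs (r_i - r_j)_x f_ij,z
                       + Sum_i m_i v_i,x v_i,z ],

with V the particle volume corrected by the colony porosity (an
envelope volume; the normalisation convention is not fixed by the
stress definition itself).  The kinetic term is negligible at these
speeds but kept by default.  The recorded sigma_xz flips the sign of
the raw (pressure-convention) virial so that forward, flow-direction
loading is positive.  The shear strain is the mean tilt of the
biofilm's leading edge measured on three spanwise planes (y = W/6, W/2,
5W/6; +-3 um slabs): the frontmost attached particle per 1 um height
bin defines the edge, a Theil-Sen line (median of pairwise slopes)
gives its angle from the wall-normal, and the undeformed reference
angle is subtracted.  Theil-Sen rather than least squares because the
surface is rough and discrete: when a single bin's leading particle
changes identity, an ordinary least-squares line can jump by ~0.2 rad,
while the median slope moves smoothly.  Detached debris and particles
displaced more than 15 um are excluded -- they no longer describe the
deforming colony.

Three further robustness layers protect the protocol summaries:
(i) every experiment begins with a 0.4 ms quiescent settling phase and
the experiment clock/reference re-zeroed afterwards; (ii) summaries
are computed on 9-sample moving averages of the stress/strain traces
(the edge estimator carries ~0.02 rad of particle-hop jitter), with the
apparent-modulus window restricted to strains between 0.02 and 0.1;
(iii) when the colony sloughs its front under load, the measured edge
belongs to a different body from that sample onward -- the raw strain
trace jumps discontinuously -- so cycle-integral observables
(dissipation, recovery) are evaluated on the trace truncated at the
first jump exceeding 0.15 rad between consecutive samples.

**Viscoelastic characterisation.**  The apparent shear modulus is the
through-origin slope of sigma_xz vs strain over loading samples with
strain < 0.1.  The one-term Prony shear relaxation modulus
`G(t) = G_eq + G1 exp(-t/tau)` is fitted through the hereditary
integral `sigma(t) = int G(t-s) dalpha/ds ds` evaluated on the measured
(piecewise-linear) strain history, jointly over traces at different
loading rates, each normalised by its peak stress; parameters are
log-transformed for positivity and fitted by Levenberg-Marquardt.  The
viscosity is `eta = G1 tau`.  Recovery is
`100 (alpha(t_load) - alpha(end)) / alpha(t_load)`; the hysteresis
energy density is the shoelace area of the closed (strain, stress)
loop, signed so a dissipative load-then-unload cycle is positive.

## 4. Desk-scale study conditions

Full-scale runs are not interactively reproducible: the published
stiffness (k_n = 1e3 N/m) on femtogram agents gives a stable DEM step
of ~2e-11 s, i.e. ~1e9 steps for one 20 ms experiment.  The package
therefore defines a reduced fixture (`desk_config`, `desk_biofilm`)
on which all trend tests and the acceptance script run:

* channel 50 x 20 x 25 um, fluid grid 10 x 4 x 5 (5 um cells, at least
  three particle diameters per cell as the volume-averaged coupling
  requires);
* colony of a few hundred agents (founders 4, growth 3.0e5 s);
* elastic constants scaled by 1e-7 (k_n = 1e-4 N/m), giving
  dt_dem = 4e-8 s, dt_fluid = 2e-6 s (50 sub-steps);
* cohesive strengths scaled by 4e-3 with s_min = 20 nm -- every
  pairwise ratio of the published cohesion table is preserved, so the
  EPS-vs-bacteria bond hierarchy that drives all EPS trends is intact;
* reduced protocol windows: steady exposure 4 ms (the detachment
  coefficient window equals the run length), ramp loading 1.5 ms plus
  4 ms relaxation;
* colonies for cross-yield comparisons are grown to a matched biofilm
  volume (1e-16 m^3) rather than a fixed time: at fixed time a higher
  EPS yield simply produces a larger colony, and colony size (lever arm
  in the shear profile) would confound every EPS comparison;
* sweep levels, chosen once so each sweep brackets the desk fixture's
  interesting regime: driving speeds 0.01/0.03/0.1 m/s for the
  detachment-vs-velocity sweep (above ~0.1 m/s the coefficient
  saturates against its window bound, the same saturating shape the
  full-scale velocity curve shows at its top end); EPS yields
  0.12/0.17/0.22 at the middle speed for the detachment-vs-EPS sweep;
  ramp accelerations 20/40/80 m/s^2 (peak speeds 0.03/0.06/0.12 m/s),
  spanning from comfortably sub-failure loading to the onset of
  colony failure.

The cohesion scaling is tied to the stiffness scaling: the bond force
at the clamp (~2e-12 N for EPS-EPS) then produces equilibrium overlaps
of ~20 nm (4% of a radius), and the cohesive stiffness at the clamp
(~2F/s_min) stays below the contact stiffness so the soft-sphere step
remains stable.  Consequences of the scaling: the desk colony's
detachment transition sits at driving speeds of order 0.005-0.2 m/s,
and stresses/moduli are of order 0.1-10 Pa.  Desk-scale results are
read as *trends* (detachment rate vs. velocity and EPS fraction,
modulus vs. loading rate and EPS fraction, hysteresis vs. peak
velocity), never as quantitative replications of the full-scale values.

What the desk fixture preserves: the cohesion hierarchy, the
fluid-structure interaction structure (shear gradient over the colony
height, shielding of the colony interior via the drag sink), the
erosion/sloughing classification machinery, and the viscoelastic
measurement chain.  What it does not preserve: absolute force/stress
scales, the full-scale erosion/sloughing balance (desk clusters are
small, so most desk events are erosion-classified), and absolute
detachment thresholds.

## 5. Growth calibration

The published kinetic constants live in supplementary material that is
not part of the main text; the growth model's observable surface here
is the mapping from EPS yield to EPS volume ratio and the colony
morphology.  The model uses a competitive yield split -- of the
substrate consumed, Y_eps becomes EPS COD and Y_tot - Y_eps biomass COD
-- plus a COD-to-volume conversion ratio c for EPS relative to biomass,
so the produced EPS-to-biomass volume ratio is
`kappa = c Y_eps / (Y_tot - Y_eps)`.  The two constants were calibrated
once against the published sweep endpoints (yield 0.12 -> 20% EPS,
yield 0.22 -> 51%), giving Y_tot = 0.38 and c = 0.84; the midpoint then
lands near 33%, matching the published mid-sweep value (~32%) without
being fitted to it.  Cells excrete their EPS shell when it exceeds 20%
of the cell volume *and* suffices to form an agent of at least the
minimum radius (0.35 um); a larger threshold would never trigger at low
yields because the shell-to-cell ratio saturates at kappa < 0.5.
Division at 1.4 um conserves parent volume exactly (tested).  Monod
defaults (mu_max 1.2e-5 1/s, K_s 3.5e-3, S 3e-2 kg/m^3) give roughly a
doubling per 16 h and a few-hundred-agent colony in the desk fixture's
growth window.

The generator emulates: stochastic size/division variability, an
EPS-enriched matrix interleaved with cells, colony-scale surface
roughness and porosity.  It does not emulate: substrate gradients and
the resulting mushroom morphologies, multiple species or functional
groups, EPS aging, or density differences between agent classes.
Passing trend tests on these colonies therefore demonstrate the
mechanics of a compact, randomly packed, EPS-bonded colony, not of
every real biofilm architecture.

### What the desk scaling cannot show: EPS stiffening

One published trend -- a higher apparent shear modulus for higher-EPS
biofilms -- does not survive the desk scaling, and the reason is
structural rather than statistical.  Small-strain stiffness in this
agent model comes from the contact springs, which are identical for
every agent type; EPS enters only through the cohesive bond strengths,
which control *failure* (detachment, yielding), not linear elasticity.
The desk stability scaling deliberately caps the cohesive stiffness at
the clamp below the contact stiffness (otherwise the soft-sphere step
is unstable), so bonded pairs sit in the clamped, constant-force region
of the Hamaker curve and contribute no stiffness at all.  Measured
across matched-volume colonies the apparent modulus is flat in the EPS
fraction at every loading rate, while the EPS effects on detachment
(where bond strength is what matters) come out clearly.  The
corresponding trend check is accordingly expected to fail at desk
scale and is reported as such, not weakened.

## 6. Known limitations

* The fluid solver is first-order in time and uses first-order upwind
  advection -- adequate for Re <= 15 channel flow, not for inertial
  regimes.
* `s_min` (unstated in the source parameter set) controls absolute
  detachment thresholds; only trends across conditions are meaningful
  without an experimental anchor for it.
* The Prony fit uses a single relaxation term; multi-term spectra are
  out of scope.
* Desk-scale erosion/sloughing counts are dominated by erosion because
  the colony itself is only a few hundred agents; the 1000-particle
  sloughing threshold is a full-scale notion.
* Quantities reported by the acceptance script at desk scale (moduli,
  detachment coefficients, hysteresis) are in the desk units/regime and
  are expected to differ from full-scale magnitudes.
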