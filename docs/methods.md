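# Methods

## The model

The package samples constrained Langevin dynamics

    dq/dt = M^-1 p
    dp/dt = F(q) - gamma p + sqrt(2 kB T gamma) M^1/2 eta(t) - G(q)^T lambda
    g(q) = 0,   G(q) M^-1 p = 0

for a system of N Cartesian degrees of freedom with diagonal mass matrix
M, holonomic distance constraints g_j(q) = |q_i - q_j|^2 - r0^2 (squared
distance, so the constraint function is smooth everywhere), friction
gamma and temperature T.  The target distribution is the constrained
Gibbs measure: the canonical density restricted to the constraint
manifold and its cotangent space.

The dynamics is split into three parts, each of which can be solved (or
approximated) while preserving both constraint classes:

* **A (geodesic drift)** — kinetic-energy-only motion on the manifold.
  Approximated by `n_inner` substeps, each a free drift followed by a
  SHAKE position projection (Gauss–Seidel sweeps of single Newton steps
  per constraint, corrections along `M^-1 grad g(q_ref)`) with the
  matching momentum correction `-G(q_ref)^T lambda / tau`, then a RATTLE
  momentum projection.  The substep is second-order accurate in the
  substep length against the exact geodesic and involves no force
  evaluation.
* **B (projected kick)** — `p <- p + h * Pi(q) F` with the cotangent
  projector `Pi = I - G^T (G M^-1 G^T)^-1 G M^-1`.
* **O (projected Ornstein–Uhlenbeck)** — exact in distribution for
  cotangent momenta:
  `p <- e^{-gamma h} p + sqrt(kB T (1 - e^{-2 gamma h})) Pi M^1/2 R`,
  a consequence of the projector identity
  `exp(alpha Pi) = I + (e^alpha - 1) Pi`.

Compositions: `gBAOAB` = B·A·O·A·B with half-length outer pieces,
`gOBABO` = O·B·A·B·O, `MEVME` = midpoint-Euler OU half-step, RATTLE
(constrained Verlet) step, midpoint-Euler OU half-step, and the
solvent–solute multiple-timestep scheme

    Bs(h/2) [Bp(h/2Kp) A(h/2Kp) O(h/Kp) A(h/2Kp) Bp(h/2Kp)]^Kp Bs(h/2)

where the force is partitioned U = U_ss + U_ps + U_pp and the expensive
solvent–solvent part is evaluated only on the outer step.  Because the
two kick operators commute exactly at fixed positions, `gBAOAB` on a
partitioned force field is *defined* as the Kp = 1 case of this
composition and shares its code path; with a shared noise stream the two
are bit-identical, which the test suite asserts.

Palindromic splittings of this family sample the constrained Gibbs
measure with O(dt^2) bias in long-run averages; the BAOAB ordering has a
much smaller prefactor than OBABO, and is exactly correct for
configurational averages of harmonic systems at any stepsize within
stability.  Both properties are verified empirically against quadrature
oracles rather than assumed.

## Units and numerical conventions

AKMA-style units: angstrom, amu, kcal/mol, kelvin; the internal time
unit `t* = sqrt(amu A^2 / (kcal/mol)) ~= 48.888 fs` makes `M^-1 p` a
velocity with no conversion factor.  User-facing times are fs/ps and
friction is given in ps^-1.  kB = 1.987204259e-3 kcal/mol/K.

Constraint tolerances: |g| <= 1e-8 A^2 (SHAKE, max 500 sweeps) and
|G M^-1 p| <= 1e-8 internal units.  A SHAKE sweep whose Newton
denominator vanishes (correction direction orthogonal to the current
gradient — the "no solution" fold of oblique projection) or whose
residual diverges aborts the whole step; the driver rolls back to the
last completed state and flags the record unstable.  There is no silent
stepsize adaptation, since that would corrupt fixed-stepsize bias
measurements.

The projector is never formed densely in production: the normal system
`(G M^-1 G^T) x = G M^-1 v` is solved per connected constraint cluster,
batched over clusters of identical shape (216 rigid waters = one batched
3x3 solve; an ensemble of circle replicas = one batched 1x1 solve).  A
dense-projector path is kept for small systems and tests; both agree to
1e-10.  Hot loops (the pairwise force kernel and the sequential
Gauss–Seidel SHAKE sweep) are JIT-compiled with numba when it is
importable, with vectorised numpy fallbacks defining the reference
semantics.

One global Gaussian stream per run, consumed in composition order (one
standard normal per degree of freedom per O substep, atoms in index
order).  gamma = 0 short-circuits the O step to an exact identity that
consumes no randoms, so deterministic-limit tests are exact.

Force reuse: the trailing kick's force is cached (keyed by position-array
identity) and reused by the next step's leading kick, giving exactly one
new full force evaluation per step in steady state; the driver asserts
this through force-call counters.

## Force field and truncation

Nonbonded interactions are Lennard-Jones (Lorentz–Berthelot combination)
plus Coulomb (332.0637 kcal mol^-1 A e^-2) under the minimum-image
convention, with bonded harmonic bonds and angles for the toy solute.
Rigid three-site water uses the standard TIP3P constants (r_OH 0.9572 A,
HOH 104.52 deg stored as the derived H–H distance, sigma_O 3.15061 A,
eps_O 0.1521 kcal/mol, q_O -0.834 e; hydrogens carry no LJ), imposed as
three distance constraints per molecule.

Truncation is *neutral-group shifted-potential*: pair inclusion at the
9 A cutoff is decided by the minimum-image distance between the pair's
charge-group reference sites (the oxygen for water; the atom itself for
free atoms), the same periodic image shift is applied to the site–site
displacement, and every included pair term has its value at r_c
subtracted.  Gating on neutral groups is essential: with atom-based
truncation, molecule pairs split at the cutoff leave non-neutral partial
charge sums whose O(1/r_c) terms deepen the mean potential energy of the
216-water box by roughly 30%.  With group gating the box equilibrates to
about -9.5 kcal/mol per molecule, in line with Ewald-quality reference
values for this water model.  Residual differences from any particular
reference code's smoothing scheme remain at the percent level and are
covered by the stated tolerance on the mean-energy check.  Forces are
the exact gradients of the shifted site terms; the small discontinuity
when a whole group crosses the cutoff is ignored, as is conventional for
group-truncated simulations (the thermostat absorbs it; deterministic
energy-conservation tests use systems with all interactions in range).

Pair evaluation is O(N^2) over a precomputed exclusion-filtered pair
list.  At the package's design scale (hundreds of atoms, box edge about
twice the cutoff) a Verlet neighbour list would exclude almost nothing
and is not implemented.

## Benchmark systems (what the generators emulate)

* `build_water_box(216, 18.643 A, 300 K)` reproduces the benchmark
  rigid-water box conditions: jittered cubic lattice, random molecular
  orientations, Maxwell–Boltzmann momenta with the centre-of-mass drift
  removed and a cotangent projection, 9 A cutoff, gamma = 1 ps^-1.
  Because the initial state is a lattice rather than a pre-equilibrated
  benchmark file, every measurement is preceded by 500 gentle steps at
  0.5 fs plus a few ps at the production stepsize.
* `build_circle_system` embeds a particle on a circle in 2D via one
  distance constraint to an infinite-mass anchor (inverse mass exactly
  zero, so the anchor never moves).  The angular Gibbs marginal is
  computable by trapezoid quadrature, giving an *exact* oracle for
  invariant-measure bias.  Replicas are independent (anchor, particle)
  pairs in one batched system, so ensemble sampling is vectorised.
  The cosine potential used for the bias ladder has amplitude 4 kcal/mol
  at kT = 1: deep enough that the smallest-rung bias of each scheme's
  measured observable is a many-sigma signal at desk-scale sampling,
  while the thermal drift per geodesic substep stays safely below the
  oblique-projection fold.
* `build_bead_solute_in_solvent` is a 4-bead chain with one frozen
  "heavy–H" bond and two stiff unconstrained harmonic angles
  (120 kcal/mol/rad^2) — the minimal carrier of the fast solute modes
  that motivate solvent–solute multiple timestepping — solvated in rigid
  waters with the solute/solvent partition populated.  It emulates only
  the integrator-relevant structure of a solvated biomolecule, not its
  chemistry: passing tests demonstrate the stability and splitting
  machinery, not force-field realism.
* `build_water_dimer` (two rigid waters, large cutoff, no box) has no
  truncation discontinuity anywhere in range and is the deterministic
  energy-conservation benchmark.

## Measurement choices

* Averages carry block-averaged standard errors (10 blocks by default),
  which inflate correctly for serially correlated series.
* The RDF normalises pair counts by the ideal-gas shell density so
  G(r) -> 1 at large r; intramolecular partners are excluded.
* Diffusion uses the Einstein relation MSD = 6 D t on unwrapped oxygen
  coordinates with all snapshot pairs at matching lag (multiple time
  origins), snapshots every ~1 ps, a fit window of 10–50% of the
  trajectory, and the conversion 1 A^2/ps = 10 x 1e-5 cm^2/s.  The
  standard error comes from the spread of per-molecule slopes.  No
  centre-of-mass correction is applied beyond the zero-momentum start,
  matching the convention of the reference measurements this mirrors.
* Free-energy profiles are -kT ln of a histogram density (72 bins by
  default), shifted to zero at the occupied minimum; the barrier is
  max - min over occupied bins in the caller's range; empty bins are
  masked.
* Autocorrelation fits a * exp(-t/tau) by unweighted least squares on
  lags up to the first zero crossing; a reference decay time gives the
  normalised ratio tau_ref / tau.
* The bias ladder runs each stepsize after discarding the opening
  fraction of the steps, measures the deviation of the long-run average
  from the quadrature value, flags unstable stepsizes instead of
  dropping them, and fits the log–log slope over the stable rungs.
  Several observables can be measured from the same trajectories.  On
  the circle the reduced mass matrix is constant, so g-BAOAB inherits
  the unconstrained scheme's near-total error cancellation for
  configurational averages: its <cos theta> bias sits below Monte-Carlo
  resolution at desk scale (decaying *faster* than any measurable
  second-order envelope), while its momentum variance shows the generic
  second-order bias cleanly; g-OBABO is the mirror image (exact
  momentum marginal, second-order configurational bias).  The shipped
  order measurement therefore fits each scheme's slope on the
  observable whose leading term survives, and compares the two schemes'
  accuracy on the configurational observable, where g-BAOAB's bias is
  several times the smaller at every stepsize.
* Water self-diffusion is measured with `remove_drift` enabled: the
  Langevin thermostat gives the system centre of mass its own random
  walk with D_com = kT/(M_total gamma) (~0.6e-5 cm^2/s for the
  216-water box at gamma = 1 ps^-1), which would otherwise inflate
  every single-molecule MSD; self-diffusion is reported in the fluid's
  rest frame, as diffusion tools conventionally do.

## Problem sizes used by the shipped checks

The shipped test suite and the acceptance script run scaled-down
versions of the headline experiments chosen for desk-scale hardware:
the 216-molecule box is equilibrated for ~10 ps and measured over 20 ps
(mean energy) and 100 ps (diffusion, one run per scheme rather than
five averaged 5 ns runs); the bias ladder uses 512 replicas times
4.2e4 steps per rung.  Statistical error bars are correspondingly larger
than the published ones, and the checks compare at matching tolerances.

## Limitations

* No Ewald/PME; absolute energies are truncation-scheme dependent.
* No SETTLE/LINCS; geodesics always go through iterative SHAKE/RATTLE,
  so very large drift per substep can hit the oblique-projection fold
  (the run aborts loudly; on the unit circle this caps the stepsize near
  0.3 internal time units).
* The MEVME comparison scheme is a best-effort reconstruction from its
  original description and is excluded from bit-exact guarantees.
* Kinetic-temperature readings are biased upward at large stepsizes
  (the BAOAB family is optimised for configurational, not kinetic,
  accuracy); instantaneous temperature is a diagnostic, not an
  observable of record.
* Orthorhombic boxes only; no pressure coupling; one temperature bath.
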