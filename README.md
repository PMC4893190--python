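# geomd

Geodesic splitting integrators for **constrained Langevin molecular
dynamics**: g-BAOAB, g-OBABO, MEVME and a solvent–solute
multiple-timestep g-BAOAB, together with the benchmark systems and
analysis machinery needed to verify their sampling accuracy against
exact oracles.

## The problem

Molecular dynamics with holonomic constraints (rigid waters, frozen
X–H bonds) samples the constrained canonical distribution

    rho(q, p) ∝ exp(-beta H(q,p)) Π_j delta[g_j(q)] Π_j delta[∇g_j(q)^T M^-1 p]

The classical route — interleaving unconstrained Langevin steps with
SHAKE/RATTLE projections — leaves a stepsize-dependent bias in every
long-run average and fails outright at large stepsizes.  The geodesic
approach instead splits the constrained dynamics into three parts, each
solved *on the manifold*:

* **A** — geodesic (force-free) drift, approximated by SHAKE/RATTLE
  substeps;
* **B** — the projected kick `p ← p + h Π F`, with
  `Π = I − G^T(G M^-1 G^T)^-1 G M^-1` the cotangent projector;
* **O** — the projected Ornstein–Uhlenbeck thermostat, solved exactly in
  distribution via `exp(αΠ) = I + (e^α − 1)Π`:
  `p ← e^{-γh} p + sqrt(kT(1 − e^{-2γh})) Π M^{1/2} R`.

The palindromic composition **B·A·O·A·B (g-BAOAB)** samples
configurational averages with a second-order, remarkably small bias —
rigid three-site water runs stably at 9 fs — and combining it with a
solvent–solute force split (cheap solute forces evaluated `Kp` times per
expensive solvent force) lifts the stepsize for solvated-solute systems
with stiff unconstrained modes to the same range.  This package is a
self-contained, tested implementation of that machinery for desk-scale
systems, with every accuracy claim checked against an independent
oracle: velocity-Verlet trajectories, closed-form projections,
quadrature Gibbs averages, and synthetic data with known ground truth.

## Worked example

Sampling bias of the two palindromic schemes on an exactly solvable
system — a particle on the unit circle with a cosine potential, whose
Gibbs averages are known by quadrature (`examples/03_bias_ladder.py`;
abridged output):

```text
quadrature <cos theta> = -0.863523,  exact <p^2> = 1
gBAOAB  cos dt=0.20  bias=+5.25e-04 +- 2.7e-04
gBAOAB  cos dt=0.28  bias=+1.79e-03 +- 1.4e-04
gBAOAB  p2  dt=0.20  bias=-3.58e-02 +- 1.7e-03
gBAOAB  p2  fitted order = +2.05
gOBABO  cos dt=0.20  bias=+6.76e-03 +- 2.4e-04
gOBABO  cos dt=0.28  bias=+1.27e-02 +- 1.7e-04
gOBABO  cos fitted order = +1.91
gOBABO  p2  dt=0.28  bias=+2.32e-05 +- 7.1e-04
```

The bias is the deviation of the long-run trajectory average from the
quadrature value.  Each scheme's bias decays at second order on the
observable where its leading error term survives — momenta for g-BAOAB,
positions for g-OBABO — and each is near-exact on the other: g-BAOAB's
configurational bias stays several times below g-OBABO's at every
stepsize, the ordering that makes it the scheme of choice for sampling
positions.  The other examples build a rigid-water box and print its
mean potential energy (`02`), thermalise a constrained dimer (`01`), and
show that three solute substeps stabilise a stiff-angle solute at an
outer stepsize where plain g-BAOAB blows up (`04`).

A thin CLI wraps the same library:

```bash
geomd build --system water_box --param n_molecules=27 --param box_edge=9.86
geomd run --config run.yaml --seed 1 --out traj.h5
geomd analyze --traj traj.h5 --what pe
geomd ladder --dts 0.14,0.2,0.28 --out ladder.csv
```

## Layout

| Path | Contents |
| --- | --- |
| `src/geomd/core.py` | units, state, thermostat, random stream |
| `src/geomd/constraints.py` | SHAKE/RATTLE, projector algebra, elementary flows |
| `src/geomd/forcefield.py` | LJ + Coulomb (group cutoff), bonded terms, partition |
| `src/geomd/integrators.py` | scheme compositions and the trajectory driver |
| `src/geomd/systems.py` | benchmark system builders (water box, circle, bead solute) |
| `src/geomd/analysis.py` | averages, RDF, diffusion, free energy, ACF, bias ladder |
| `src/geomd/io.py`, `cli.py` | YAML config, extended-XYZ, HDF5, CLI |
| `examples/` | one narrative script per capability |
| `docs/methods.md` | model, conventions, design choices, limitations |
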