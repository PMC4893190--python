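"""Deterministic builders for every benchmark system.

All systems are generated in memory from a seed -- no external data:

* a periodic box of rigid three-site (TIP3P) waters on a jittered
  lattice with random orientations;
* a particle on a circle (embedded in 2D with a radius constraint, the
  anchor pinned with infinite mass), whose Gibbs marginal over the angle
  is computable by 1D quadrature -- the exact oracle for
  invariant-measure bias measurements;
* a bead-spring solute (constrained "heavy-H" bond, stiff unconstrained
  harmonic angles -- the motivating fast mode of the solvent-solute
  splitting) solvated in rigid waters, with the solute/solvent partition
  populated;
* a two-molecule rigid water cluster (no box, interactions in range) for
  deterministic energy-conservation checks.

Momenta are drawn from the Maxwell-Boltzmann distribution, the total
momentum is removed, and the result is projected onto the cotangent
space, so every builder's output satisfies its constraints to 1e-10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    BOLTZMANN_KCAL_MOL_K,
    SystemState,
    RandomStream,
)
from .constraints import ConstraintSet, project_cotangent
from .forcefield import (
    HarmonicAngle,
    HarmonicBond,
    NonbondedParams,
    PairForceField,
    SoluteSolventPartition,
    TIP3P,
)

__all__ = [
    "PackingError",
    "SystemSpec",
    "HarmonicWell",
    "CirclePotential",
    "build_water_box",
    "build_water_dimer",
    "build_circle_system",
    "build_bead_solute_in_solvent",
    "build_harmonic_oscillator",
    "maxwell_boltzmann_momenta",
]


class PackingError(ValueError):
    """Generated configuration is unphysically dense."""


@dataclass
class SystemSpec:
    """A fully assembled benchmark system."""

    name: str
    state: SystemState
    constraints: ConstraintSet
    forcefield: object
    species: list
    temperature: float
    metadata: dict = field(default_factory=dict)

    @property
    def partition(self):
        return getattr(self.forcefield, "partition", None)


# ----------------------------------------------------------------------
# analytic toy force fields
# ----------------------------------------------------------------------
class HarmonicWell:
    """Isotropic harmonic trap U = 0.5 k |q - q0|^2 applied per atom
    (infinite-mass atoms feel no force)."""

    def __init__(self, k: float, center: float | np.ndarray = 0.0):
        self.k = k
        self.center = center
        self.partition = None
        self.call_counts = {"total": 0, "solvent": 0, "solute": 0}

    def energy_forces(self, state: SystemState):
        self.call_counts["total"] += 1
        d = state.q - self.center
        mobile = np.isfinite(state.masses)[:, None]
        d = np.where(mobile, d, 0.0)
        return 0.5 * self.k * float(np.sum(d * d)), -self.k * d


class CirclePotential:
    """Angular potential for the particle-on-a-circle system, written as
    a smooth function of the 2D ambient coordinates:

    * ``free``        U = 0
    * ``cosine``      U = A cos(theta) = A x / R
    * ``double_well`` U = (B/2)(1 - cos 2 theta) = (B/2)(1 - (x^2-y^2)/R^2),
      minima at theta = 0, pi and barrier height B at theta = +-pi/2.

    ``particle_mask`` selects the mobile particles (anchors feel no
    force).
    """

    KINDS = ("free", "cosine", "double_well")

    def __init__(self, kind: str, radius: float, amplitude: float = 1.0,
                 particle_mask: np.ndarray | None = None):
        if kind not in self.KINDS:
            raise ValueError(f"unknown circle potential {kind!r}")
        self.kind = kind
        self.radius = radius
        self.amplitude = amplitude
        self.particle_mask = particle_mask
        self.partition = None
        self.call_counts = {"total": 0, "solvent": 0, "solute": 0}

    def energy(self, theta: np.ndarray) -> np.ndarray:
        """U(theta) -- the quadrature oracle evaluates this directly."""
        if self.kind == "free":
            return np.zeros_like(theta)
        if self.kind == "cosine":
            return self.amplitude * np.cos(theta)
        return 0.5 * self.amplitude * (1.0 - np.cos(2.0 * theta))

    def energy_forces(self, state: SystemState):
        self.call_counts["total"] += 1
        q = state.q
        F = np.zeros_like(q)
        mask = (
            self.particle_mask
            if self.particle_mask is not None
            else np.isfinite(state.masses)
        )
        x = q[mask, 0]
        y = q[mask, 1]
        R = self.radius
        if self.kind == "free":
            U = 0.0
        elif self.kind == "cosine":
            U = float(np.sum(self.amplitude * x / R))
            F[mask, 0] = -self.amplitude / R
        else:
            B = self.amplitude
            U = float(np.sum(0.5 * B * (1.0 - (x * x - y * y) / R**2)))
            F[mask, 0] = B * x / R**2
            F[mask, 1] = -B * y / R**2
        return U, F


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------
def maxwell_boltzmann_momenta(
    masses: np.ndarray, kT: float, rng: RandomStream, n_dim: int = 3
) -> np.ndarray:
    """Momenta drawn from the Maxwell-Boltzmann distribution; pinned
    (infinite-mass) atoms receive zero momentum."""
    sqrtm = np.where(np.isfinite(masses), np.sqrt(masses), 0.0)
    return np.sqrt(kT) * sqrtm[:, None] * rng.normal((masses.size, n_dim))


def _remove_net_momentum(p: np.ndarray, masses: np.ndarray) -> np.ndarray:
    mobile = np.isfinite(masses)
    v_com = p[mobile].sum(axis=0) / masses[mobile].sum()
    p = p.copy()
    p[mobile] -= masses[mobile, None] * v_com
    return p


def _random_rotation(rng: RandomStream) -> np.ndarray:
    qv = rng.normal(4)
    qv /= np.linalg.norm(qv)
    w, x, y, z = qv
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _water_template() -> np.ndarray:
    """Sites of one rigid water in its molecular frame (O at origin)."""
    half = math.radians(TIP3P.angle_hoh_deg) / 2.0
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [TIP3P.r_oh * math.sin(half), 0.0, TIP3P.r_oh * math.cos(half)],
            [-TIP3P.r_oh * math.sin(half), 0.0, TIP3P.r_oh * math.cos(half)],
        ]
    )


def _water_arrays(n_molecules: int):
    sigma = np.tile([TIP3P.sigma_o, 0.0, 0.0], n_molecules)
    eps = np.tile([TIP3P.epsilon_o, 0.0, 0.0], n_molecules)
    charge = np.tile([TIP3P.charge_o, TIP3P.charge_h, TIP3P.charge_h], n_molecules)
    masses = np.tile([TIP3P.mass_o, TIP3P.mass_h, TIP3P.mass_h], n_molecules)
    species = ["O", "H", "H"] * n_molecules
    constraints = []
    exclusions = []
    # the oxygen anchors its molecule's neutral charge group: cutoff
    # inclusion is decided by O-O distance so molecules enter atomically
    group_ref = np.repeat(3 * np.arange(n_molecules), 3)
    for mol in range(n_molecules):
        o, h1, h2 = 3 * mol, 3 * mol + 1, 3 * mol + 2
        constraints += [
            (o, h1, TIP3P.r_oh),
            (o, h2, TIP3P.r_oh),
            (h1, h2, TIP3P.r_hh),
        ]
        exclusions += [(o, h1), (o, h2), (h1, h2)]
    return sigma, eps, charge, masses, species, constraints, exclusions, group_ref


def _project_initial(state: SystemState, cset: ConstraintSet) -> None:
    if cset.n_constraints:
        state.p = project_cotangent(state.p, state.q, state.masses, cset)
    state.p[~np.isfinite(state.masses)] = 0.0  # pinned atoms stay at rest


# ----------------------------------------------------------------------
# builders
# ----------------------------------------------------------------------
def build_water_box(
    n_molecules: int,
    box_edge: float,
    temperature: float = 300.0,
    seed: int = 0,
    cutoff: float = 9.0,
    jitter: float = 0.1,
) -> SystemSpec:
    """Rigid waters on a jittered cubic lattice with random orientations
    in a periodic box.

    Raises :class:`PackingError` if the resulting density puts two
    oxygens closer than 2 A (minimum image).
    """
    rng = RandomStream(seed)
    n_side = math.ceil(n_molecules ** (1.0 / 3.0))
    spacing = box_edge / n_side
    template = _water_template()
    sites = []
    for ix in range(n_side):
        for iy in range(n_side):
            for iz in range(n_side):
                sites.append((np.array([ix, iy, iz]) + 0.5) * spacing)
    sites = np.array(sites[:n_molecules])

    q = np.empty((3 * n_molecules, 3))
    for mol in range(n_molecules):
        center = sites[mol] + jitter * rng.normal(3)
        rot = _random_rotation(rng)
        q[3 * mol : 3 * mol + 3] = center + template @ rot.T

    box = np.full(3, float(box_edge))
    o_pos = q[::3]
    if n_molecules > 1:
        d = o_pos[:, None, :] - o_pos[None, :, :]
        d -= box * np.round(d / box)
        r = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(r, np.inf)
        if r.min() < 2.0:
            raise PackingError(
                f"minimum O-O distance {r.min():.2f} A < 2 A; box too dense"
            )

    sigma, eps, charge, masses, species, cons, excl, gref = _water_arrays(n_molecules)
    cset = ConstraintSet(cons)
    ff = PairForceField(
        NonbondedParams(sigma=sigma, epsilon=eps, charge=charge, cutoff=cutoff),
        exclusions=excl,
        group_ref=gref,
    )
    kT = BOLTZMANN_KCAL_MOL_K * temperature
    p = maxwell_boltzmann_momenta(masses, kT, rng)
    p = _remove_net_momentum(p, masses)
    state = SystemState(q=q, p=p, masses=masses, box=box)
    _project_initial(state, cset)
    return SystemSpec(
        name=f"water_box_{n_molecules}",
        state=state,
        constraints=cset,
        forcefield=ff,
        species=species,
        temperature=temperature,
        metadata={"n_molecules": n_molecules, "box_edge": box_edge, "cutoff": cutoff},
    )


def build_water_dimer(
    separation: float = 2.9,
    temperature: float = 300.0,
    seed: int = 0,
    cutoff: float = 50.0,
) -> SystemSpec:
    """Two rigid waters with all interactions in range (no box, large
    cutoff): no truncation discontinuity, suitable for deterministic
    energy-conservation checks."""
    rng = RandomStream(seed)
    template = _water_template()
    q = np.empty((6, 3))
    q[:3] = template
    rot = _random_rotation(rng)
    q[3:] = np.array([separation, 0.0, 0.0]) + template @ rot.T
    sigma, eps, charge, masses, species, cons, excl, gref = _water_arrays(2)
    cset = ConstraintSet(cons)
    ff = PairForceField(
        NonbondedParams(sigma=sigma, epsilon=eps, charge=charge, cutoff=cutoff),
        exclusions=excl,
        group_ref=gref,
    )
    kT = BOLTZMANN_KCAL_MOL_K * temperature
    p = maxwell_boltzmann_momenta(masses, kT, rng)
    p = _remove_net_momentum(p, masses)
    state = SystemState(q=q, p=p, masses=masses)
    _project_initial(state, cset)
    return SystemSpec(
        name="water_dimer",
        state=state,
        constraints=cset,
        forcefield=ff,
        species=species,
        temperature=temperature,
    )


def build_circle_system(
    radius: float = 1.0,
    potential_name: str = "cosine",
    temperature: float = 1.0 / BOLTZMANN_KCAL_MOL_K,
    amplitude: float = 1.0,
    n_replicas: int = 1,
    mass: float = 1.0,
    seed: int = 0,
) -> SystemSpec:
    """Particle(s) on a circle of given radius in 2D.

    Each replica is an independent (anchor, particle) pair sharing one
    distance constraint; the anchor is pinned at the origin with
    infinite mass.  The default temperature makes kT = 1 kcal/mol.
    Replicas make ensemble sampling a single batched system.
    """
    rng = RandomStream(seed)
    n = 2 * n_replicas
    q = np.zeros((n, 2))
    theta0 = 2.0 * np.pi * np.arange(n_replicas) / max(n_replicas, 1) + np.pi / 3
    q[1::2, 0] = radius * np.cos(theta0)
    q[1::2, 1] = radius * np.sin(theta0)
    masses = np.empty(n)
    masses[0::2] = np.inf
    masses[1::2] = mass
    cset = ConstraintSet([(2 * r, 2 * r + 1, radius) for r in range(n_replicas)])
    mask = np.zeros(n, dtype=bool)
    mask[1::2] = True
    ff = CirclePotential(potential_name, radius, amplitude, particle_mask=mask)
    kT = BOLTZMANN_KCAL_MOL_K * temperature
    p = maxwell_boltzmann_momenta(masses, kT, rng, n_dim=2)
    state = SystemState(q=q, p=p, masses=masses)
    _project_initial(state, cset)
    return SystemSpec(
        name=f"circle_{potential_name}",
        state=state,
        constraints=cset,
        forcefield=ff,
        species=["X"] * n,
        temperature=temperature,
        metadata={"radius": radius, "amplitude": amplitude, "n_replicas": n_replicas},
    )


def circle_angles(state: SystemState) -> np.ndarray:
    """Angles theta of the mobile particles of a circle system."""
    q = state.q[1::2]
    return np.arctan2(q[:, 1], q[:, 0])


def build_harmonic_oscillator(
    k: float = 1.0,
    mass: float = 1.0,
    kT: float = 1.0,
    n_replicas: int = 1,
    n_dim: int = 1,
    seed: int = 0,
) -> SystemSpec:
    """Independent harmonic oscillators (internal units: kT in kcal/mol,
    time in internal units), for exactness and bias oracles."""
    rng = RandomStream(seed)
    masses = np.full(n_replicas, float(mass))
    q = np.sqrt(kT / k) * rng.normal((n_replicas, n_dim))
    p = maxwell_boltzmann_momenta(masses, kT, rng, n_dim=n_dim)
    state = SystemState(q=q, p=p, masses=masses)
    return SystemSpec(
        name="harmonic_oscillator",
        state=state,
        constraints=ConstraintSet([]),
        forcefield=HarmonicWell(k),
        species=["X"] * n_replicas,
        temperature=kT / BOLTZMANN_KCAL_MOL_K,
        metadata={"k": k, "kT": kT},
    )


def build_bead_solute_in_solvent(
    n_waters: int,
    box_edge: float | None = None,
    temperature: float = 300.0,
    seed: int = 0,
    cutoff: float = 9.0,
    angle_k: float = 120.0,
    bond_k: float = 300.0,
) -> SystemSpec:
    """A 4-bead solute (constrained heavy-H bond, two stiff unconstrained
    harmonic angles) solvated by rigid waters.

    The stiff angles are the fast unconstrained modes the solvent-solute
    multiple-timestep composition is designed to stabilise.  With
    ``n_waters = 0`` an isolated solute (no box) is returned for
    stability-ladder experiments.
    """
    rng = RandomStream(seed)
    theta0 = math.radians(109.5)
    r_cc, r_ch = 1.53, 1.09
    # zig-zag chain in the xz plane
    sol_q = np.zeros((4, 3))
    direc = np.array(
        [math.sin(theta0 / 2.0), 0.0, math.cos(theta0 / 2.0)]
    )
    mirror = np.array([math.sin(theta0 / 2.0), 0.0, -math.cos(theta0 / 2.0)])
    sol_q[1] = sol_q[0] + r_cc * direc
    sol_q[2] = sol_q[1] + r_cc * mirror
    sol_q[3] = sol_q[2] + r_ch * direc
    sol_masses = np.array([12.011, 12.011, 12.011, 1.008])
    sol_sigma = np.array([3.4, 3.4, 3.4, 0.0])
    sol_eps = np.array([0.1, 0.1, 0.1, 0.0])
    sol_charge = np.array([0.15, -0.15, 0.15, -0.15])
    sol_species = ["C", "C", "C", "H"]
    bonds = [HarmonicBond(0, 1, bond_k, r_cc), HarmonicBond(1, 2, bond_k, r_cc)]
    angles = [
        HarmonicAngle(0, 1, 2, angle_k, theta0),
        HarmonicAngle(1, 2, 3, angle_k, theta0),
    ]
    cons = [(2, 3, r_ch)]  # the heavy-H bond is frozen
    # all intra-solute pairs excluded from the nonbonded sum
    excl = [(i, j) for i in range(4) for j in range(i + 1, 4)]

    if n_waters == 0:
        masses = sol_masses
        cset = ConstraintSet(cons)
        ff = PairForceField(
            NonbondedParams(
                sigma=sol_sigma, epsilon=sol_eps, charge=sol_charge, cutoff=cutoff
            ),
            bonds=bonds,
            angles=angles,
            exclusions=excl,
            partition=SoluteSolventPartition(
                solute_indices=np.arange(4), solvent_indices=np.arange(0)
            ),
        )
        kT = BOLTZMANN_KCAL_MOL_K * temperature
        p = maxwell_boltzmann_momenta(masses, kT, rng)
        p = _remove_net_momentum(p, masses)
        state = SystemState(q=sol_q.copy(), p=p, masses=masses)
        _project_initial(state, cset)
        return SystemSpec(
            name="bead_solute_isolated",
            state=state,
            constraints=cset,
            forcefield=ff,
            species=sol_species,
            temperature=temperature,
            metadata={"n_waters": 0},
        )

    if box_edge is None:
        raise ValueError("box_edge is required when n_waters > 0")
    box = np.full(3, float(box_edge))
    center = box / 2.0
    sol_q = sol_q - sol_q.mean(axis=0) + center

    n_side = math.ceil((n_waters + 8) ** (1.0 / 3.0))
    spacing = box_edge / n_side
    sites = []
    for ix in range(n_side):
        for iy in range(n_side):
            for iz in range(n_side):
                s = (np.array([ix, iy, iz]) + 0.5) * spacing
                if np.min(np.linalg.norm(sol_q - s, axis=1)) > 2.5:
                    sites.append(s)
    if len(sites) < n_waters:
        raise PackingError(
            f"only {len(sites)} lattice sites clear of the solute; "
            f"{n_waters} waters requested"
        )
    sites = np.array(sites[:n_waters])

    template = _water_template()
    wq = np.empty((3 * n_waters, 3))
    for mol in range(n_waters):
        c = sites[mol] + 0.1 * rng.normal(3)
        rot = _random_rotation(rng)
        wq[3 * mol : 3 * mol + 3] = c + template @ rot.T

    wsigma, weps, wcharge, wmasses, wspecies, wcons, wexcl, wgref = _water_arrays(n_waters)
    off = 4
    q = np.vstack([sol_q, wq])
    masses = np.concatenate([sol_masses, wmasses])
    sigma = np.concatenate([sol_sigma, wsigma])
    eps = np.concatenate([sol_eps, weps])
    charge = np.concatenate([sol_charge, wcharge])
    species = sol_species + wspecies
    cons = cons + [(i + off, j + off, r) for i, j, r in wcons]
    excl = excl + [(i + off, j + off) for i, j in wexcl]
    gref = np.concatenate([np.arange(4), wgref + off])
    cset = ConstraintSet(cons)
    ff = PairForceField(
        NonbondedParams(sigma=sigma, epsilon=eps, charge=charge, cutoff=cutoff),
        bonds=bonds,
        angles=angles,
        exclusions=excl,
        group_ref=gref,
        partition=SoluteSolventPartition(
            solute_indices=np.arange(4),
            solvent_indices=np.arange(4, 4 + 3 * n_waters),
        ),
    )
    kT = BOLTZMANN_KCAL_MOL_K * temperature
    p = maxwell_boltzmann_momenta(masses, kT, rng)
    p = _remove_net_momentum(p, masses)
    state = SystemState(q=q, p=p, masses=masses, box=box)
    _project_initial(state, cset)
    return SystemSpec(
        name=f"bead_solute_{n_waters}w",
        state=state,
        constraints=cset,
        forcefield=ff,
        species=species,
        temperature=temperature,
        metadata={"n_waters": n_waters, "box_edge": box_edge, "cutoff": cutoff},
    )
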