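"""Domain types and the unit system shared by the whole package.

Unit system (AKMA-style)
------------------------
Lengths are in angstrom, masses in amu, energies in kcal/mol and
temperatures in kelvin.  The internal time unit ``t*`` is chosen so that
``M^{-1} p`` is a velocity with no conversion factor, i.e.

    t* = sqrt(amu * A^2 / (kcal/mol)) ~= 48.8882 fs.

All user-facing times are femtoseconds or picoseconds; conversion happens
only at the I/O boundary.  With this choice ``p^2 / (2 m)`` is directly a
kcal/mol energy and the Boltzmann constant is the single dimensional
constant the integrators need.

Momenta (not velocities) are the stored conjugate variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BOLTZMANN_KCAL_MOL_K",
    "FS_PER_INTERNAL",
    "PS_PER_INTERNAL",
    "AKMA",
    "UnitSystem",
    "SystemState",
    "ThermostatParams",
    "RandomStream",
    "DegenerateSystemError",
    "kinetic_energy",
    "instantaneous_temperature",
    "fs_to_internal",
    "internal_to_fs",
    "ps_to_internal",
    "internal_to_ps",
]

#: Boltzmann constant, kcal mol^-1 K^-1 (package constant, exact by fiat).
BOLTZMANN_KCAL_MOL_K = 1.987204259e-3

_AVOGADRO = 6.02214076e23
_AMU_KG = 1.66053906660e-27
_KCAL_J = 4184.0

#: femtoseconds per internal (AKMA) time unit: sqrt(amu A^2 / (kcal/mol)).
FS_PER_INTERNAL = 1.0e15 * math.sqrt(_AMU_KG * 1.0e-20 / (_KCAL_J / _AVOGADRO))
PS_PER_INTERNAL = FS_PER_INTERNAL * 1.0e-3


def fs_to_internal(t_fs: float) -> float:
    return t_fs / FS_PER_INTERNAL


def internal_to_fs(t: float) -> float:
    return t * FS_PER_INTERNAL


def ps_to_internal(t_ps: float) -> float:
    return t_ps / PS_PER_INTERNAL


def internal_to_ps(t: float) -> float:
    return t * PS_PER_INTERNAL


@dataclass(frozen=True)
class UnitSystem:
    """Record of the unit conventions in force throughout the package."""

    length: str = "angstrom"
    mass: str = "amu"
    energy: str = "kcal/mol"
    temperature: str = "kelvin"
    time_io: str = "fs"
    fs_per_internal_time: float = FS_PER_INTERNAL
    boltzmann_constant: float = BOLTZMANN_KCAL_MOL_K


#: The single unit system used by the package.
AKMA = UnitSystem()


class DegenerateSystemError(ValueError):
    """Raised when a system has no free degrees of freedom."""


@dataclass
class SystemState:
    """Phase-space point (q, p) of a particle system.

    ``q`` and ``p`` have shape ``(n_atoms, n_dim)``; ``masses`` has shape
    ``(n_atoms,)`` and may contain ``np.inf`` for pinned (immobile) atoms,
    whose inverse mass is treated as exactly zero.  ``box`` is either
    ``None`` (no periodicity) or the three orthorhombic edge lengths in
    angstrom.  ``time`` is the simulation clock in internal time units.

    Positions are never wrapped during dynamics: the minimum-image
    convention is applied inside force and distance computations only, so
    constrained groups never straddle a boundary and mean squared
    displacements can be read off directly.
    """

    q: np.ndarray
    p: np.ndarray
    masses: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.q = np.ascontiguousarray(self.q, dtype=float)
        self.p = np.ascontiguousarray(self.p, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.q.ndim != 2 or self.q.shape != self.p.shape:
            raise ValueError("q and p must both have shape (n_atoms, n_dim)")
        if self.masses.shape != (self.q.shape[0],):
            raise ValueError("masses must have shape (n_atoms,)")
        if not np.all(self.masses > 0):
            raise ValueError("masses must be strictly positive")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or not np.all(self.box > 0):
                raise ValueError("box must be three positive edge lengths")

    @property
    def n_atoms(self) -> int:
        return self.q.shape[0]

    @property
    def n_dim(self) -> int:
        return self.q.shape[1]

    @property
    def inv_masses(self) -> np.ndarray:
        """Per-atom inverse masses; exactly zero for pinned atoms."""
        with np.errstate(divide="ignore"):
            inv = 1.0 / self.masses
        inv[~np.isfinite(self.masses)] = 0.0
        return inv

    @property
    def n_free_dof(self) -> int:
        """Number of mobile degrees of freedom (pinned atoms excluded)."""
        return int(np.isfinite(self.masses).sum()) * self.n_dim

    @property
    def time_fs(self) -> float:
        return internal_to_fs(self.time)

    def copy(self) -> "SystemState":
        return SystemState(
            q=self.q.copy(),
            p=self.p.copy(),
            masses=self.masses,
            box=None if self.box is None else self.box.copy(),
            time=self.time,
        )


@dataclass(frozen=True)
class ThermostatParams:
    """Langevin thermostat parameters.

    ``gamma`` is the friction in inverse internal time units (use
    :meth:`from_ps` to specify it in the conventional ps^-1);
    ``temperature`` is in kelvin.
    """

    gamma: float
    temperature: float

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @classmethod
    def from_ps(cls, gamma_ps: float, temperature: float) -> "ThermostatParams":
        """Build from a friction given in ps^-1 (the usual convention)."""
        return cls(gamma=gamma_ps * PS_PER_INTERNAL, temperature=temperature)

    @property
    def kT(self) -> float:
        """Thermal energy k_B T in kcal/mol."""
        return BOLTZMANN_KCAL_MOL_K * self.temperature


@dataclass
class RandomStream:
    """Single Gaussian stream with a documented, fixed draw order.

    Every stochastic substep draws exactly the standard normals it needs
    via :meth:`normal`, in composition order.  Within one draw the layout
    is C order over ``(atom index, cartesian component)``.  Two runs with
    the same seed and the same sequence of calls therefore produce
    bit-identical variates, which is what makes the Kp=1 multiple-timestep
    scheme replay the plain g-BAOAB stream exactly.
    """

    seed: int
    _gen: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._gen = np.random.Generator(np.random.PCG64(self.seed))

    def normal(self, shape) -> np.ndarray:
        return self._gen.standard_normal(shape)

    def uniform(self, low: float, high: float, shape) -> np.ndarray:
        return self._gen.uniform(low, high, shape)


def kinetic_energy(state: SystemState) -> float:
    """Kinetic energy 0.5 * sum_i p_i^2 / m_i in kcal/mol."""
    return 0.5 * float(np.sum(state.p**2 * state.inv_masses[:, None]))


def instantaneous_temperature(state: SystemState, n_constraints: int = 0) -> float:
    """Kinetic temperature 2 KE / (N_dof k_B) in kelvin.

    ``N_dof`` is the number of mobile degrees of freedom minus the number
    of holonomic constraints.
    """
    n_dof = state.n_free_dof - n_constraints
    if n_dof <= 0:
        raise DegenerateSystemError(
            f"no free degrees of freedom ({state.n_free_dof} dof, "
            f"{n_constraints} constraints)"
        )
    return 2.0 * kinetic_energy(state) / (n_dof * BOLTZMANN_KCAL_MOL_K)
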