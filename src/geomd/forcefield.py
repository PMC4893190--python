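"""Potential energy and forces.

Nonbonded interactions are Lennard-Jones plus Coulomb under the
minimum-image convention, truncated at a cutoff ``r_c`` with the
*shifted-potential* scheme: each pair term has its value at ``r_c``
subtracted so U(r_c) = 0 (forces are unchanged by the shift).  Absolute
energies therefore carry a systematic truncation offset relative to codes
using other smoothing schemes; see docs/methods.md.

Bonded terms are harmonic bonds and harmonic angles (the toy-solute
terms).  The solvent-solute partition U = U_ss + U_ps + U_pp needed by
the multiple-timestep integrator is exposed as two force routines:
solvent-solvent pairs only, and everything involving the solute (plus all
bonded terms).  Their sum equals the unpartitioned total.

Pair evaluation is O(N^2) vectorised over a precomputed pair list with
topological exclusions; at the few-hundred-atom scale this package
targets, that is both the simplest and the fastest portable choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .core import SystemState

__all__ = [
    "COULOMB_CONSTANT",
    "NonbondedParams",
    "WaterModelParams",
    "TIP3P",
    "SoluteSolventPartition",
    "HarmonicBond",
    "HarmonicAngle",
    "PairForceField",
    "SingularityError",
    "GeometryError",
    "nonbonded_energy_forces",
    "bonded_energy_forces",
    "partitioned_forces",
]

#: Coulomb constant in kcal mol^-1 A e^-2.
COULOMB_CONSTANT = 332.0637


class SingularityError(ValueError):
    """Two interaction sites are (numerically) on top of each other."""


class GeometryError(ValueError):
    """Degenerate bonded geometry (e.g. collinear angle triplet)."""


@dataclass(frozen=True)
class NonbondedParams:
    """Per-site nonbonded parameters and the truncation settings."""

    sigma: np.ndarray  # (n,) A
    epsilon: np.ndarray  # (n,) kcal/mol
    charge: np.ndarray  # (n,) e
    cutoff: float  # A
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if np.any(np.asarray(self.sigma) < 0) or np.any(np.asarray(self.epsilon) < 0):
            raise ValueError("sigma and epsilon must be non-negative")


@dataclass(frozen=True)
class WaterModelParams:
    """Rigid three-site water constants (standard TIP3P values)."""

    r_oh: float = 0.9572  # A
    angle_hoh_deg: float = 104.52
    sigma_o: float = 3.15061  # A
    epsilon_o: float = 0.1521  # kcal/mol
    charge_o: float = -0.834  # e
    charge_h: float = 0.417  # e
    mass_o: float = 15.9994  # amu
    mass_h: float = 1.008  # amu

    @property
    def r_hh(self) -> float:
        """Derived H-H distance 2 r_OH sin(angle/2)."""
        return 2.0 * self.r_oh * math.sin(math.radians(self.angle_hoh_deg) / 2.0)


TIP3P = WaterModelParams()


@dataclass(frozen=True)
class SoluteSolventPartition:
    solute_indices: np.ndarray
    solvent_indices: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.solute_indices, dtype=np.intp)
        w = np.asarray(self.solvent_indices, dtype=np.intp)
        object.__setattr__(self, "solute_indices", s)
        object.__setattr__(self, "solvent_indices", w)
        if np.intersect1d(s, w).size:
            raise ValueError("solute and solvent index sets overlap")

    def validate_covering(self, n_atoms: int) -> None:
        union = np.union1d(self.solute_indices, self.solvent_indices)
        if union.size != n_atoms or (union != np.arange(n_atoms)).any():
            raise ValueError("partition must cover all atom indices exactly")


@dataclass(frozen=True)
class HarmonicBond:
    i: int
    j: int
    k: float  # kcal/mol/A^2
    r0: float  # A


@dataclass(frozen=True)
class HarmonicAngle:
    i: int
    j: int  # central atom
    k_atom: int
    k_theta: float  # kcal/mol/rad^2
    theta0: float  # rad


# ----------------------------------------------------------------------
# kernels
# ----------------------------------------------------------------------
def _pair_energy_forces(q, box, pi, pj, ri, rj, sig2, eps, kqq, rc):
    """LJ + Coulomb over an explicit pair list, shifted potential.

    Cutoff inclusion is gated on the minimum-image distance between the
    group reference sites (ri, rj); the same image shift is applied to
    the site-site displacement (neutral-group truncation).
    """
    n, dim = q.shape
    U = 0.0
    F = np.zeros_like(q)
    if pi.size == 0:
        return U, F
    if _kernels.HAVE_NUMBA and pi.size >= 256:
        use_box = box is not None
        box_arr = (
            np.asarray(box, dtype=float) if use_box else np.ones(dim, dtype=float)
        )
        U, status = _kernels.pair_energy_forces(
            q,
            use_box,
            box_arr,
            np.ascontiguousarray(pi, dtype=np.int64),
            np.ascontiguousarray(pj, dtype=np.int64),
            np.ascontiguousarray(ri, dtype=np.int64),
            np.ascontiguousarray(rj, dtype=np.int64),
            sig2,
            eps,
            kqq,
            rc,
            F,
        )
        if status == 1:
            raise SingularityError("overlapping nonbonded sites (r < 1e-6 A)")
        return U, F
    dref = q[ri] - q[rj]
    shift = np.zeros_like(dref)
    if box is not None:
        shift = -box * np.round(dref / box)
        dref = dref + shift
    gr2 = np.einsum("md,md->m", dref, dref)
    sel = np.flatnonzero(gr2 < rc * rc)
    if sel.size == 0:
        return U, F
    dq = q[pi[sel]] - q[pj[sel]] + shift[sel]
    r2 = np.einsum("md,md->m", dq, dq)
    if r2.min() < 1e-12:
        raise SingularityError("overlapping nonbonded sites (r < 1e-6 A)")
    sig2 = sig2[sel]
    eps = eps[sel]
    kqq = kqq[sel]
    inv_r2 = 1.0 / r2
    fmag = np.zeros(sel.size)  # force factor: F_i = fmag * dq

    lj = eps > 0.0
    if np.any(lj):
        s6 = (sig2[lj] * inv_r2[lj]) ** 3
        s12 = s6 * s6
        sc6 = (sig2[lj] / (rc * rc)) ** 3
        U += float(np.sum(4.0 * eps[lj] * (s12 - s6 - (sc6 * sc6 - sc6))))
        fmag[lj] += 24.0 * eps[lj] * (2.0 * s12 - s6) * inv_r2[lj]

    coul = kqq != 0.0
    if np.any(coul):
        inv_r = np.sqrt(inv_r2[coul])
        U += float(np.sum(kqq[coul] * (inv_r - 1.0 / rc)))
        fmag[coul] += kqq[coul] * inv_r * inv_r2[coul]

    fvec = fmag[:, None] * dq
    for d in range(dim):
        F[:, d] += np.bincount(pi[sel], weights=fvec[:, d], minlength=n)
        F[:, d] -= np.bincount(pj[sel], weights=fvec[:, d], minlength=n)
    return U, F


def _bond_energy_forces(q, bi, bj, bk, br0):
    U = 0.0
    F = np.zeros_like(q)
    if bi.size == 0:
        return U, F
    dq = q[bi] - q[bj]
    r = np.sqrt(np.einsum("md,md->m", dq, dq))
    dev = r - br0
    U = float(np.sum(0.5 * bk * dev**2))
    fac = (-bk * dev / r)[:, None] * dq
    np.add.at(F, bi, fac)
    np.subtract.at(F, bj, fac)
    return U, F


def _angle_energy_forces(q, ci, cj, ck, kth, th0):
    U = 0.0
    F = np.zeros_like(q)
    if ci.size == 0:
        return U, F
    u = q[ci] - q[cj]
    v = q[ck] - q[cj]
    nu = np.sqrt(np.einsum("md,md->m", u, u))
    nv = np.sqrt(np.einsum("md,md->m", v, v))
    cosq = np.einsum("md,md->m", u, v) / (nu * nv)
    cosq = np.clip(cosq, -1.0, 1.0)
    sinq = np.sqrt(1.0 - cosq**2)
    if np.any(sinq < 1e-8):
        raise GeometryError("collinear angle triplet (sin theta < 1e-8)")
    theta = np.arccos(cosq)
    dev = theta - th0
    U = float(np.sum(0.5 * kth * dev**2))
    uhat = u / nu[:, None]
    vhat = v / nv[:, None]
    coeff = (kth * dev / sinq)[:, None]
    fi = coeff * (vhat - cosq[:, None] * uhat) / nu[:, None]
    fk = coeff * (uhat - cosq[:, None] * vhat) / nv[:, None]
    np.add.at(F, ci, fi)
    np.add.at(F, ck, fk)
    np.subtract.at(F, cj, fi + fk)
    return U, F


# ----------------------------------------------------------------------
# model
# ----------------------------------------------------------------------
class PairForceField:
    """LJ + Coulomb + harmonic bonded force field with optional
    solvent-solute partition.

    Parameters
    ----------
    nonbonded : NonbondedParams
    bonds, angles : harmonic bonded terms (solute terms)
    exclusions : iterable of (i, j)
        Pairs excluded from the nonbonded sum (intramolecular pairs,
        constrained bonds, bonded 1-2/1-3 neighbours).
    partition : SoluteSolventPartition or None

    Combination rules are Lorentz-Berthelot (arithmetic sigma, geometric
    epsilon); a site with epsilon = 0 carries no LJ interaction.

    ``call_counts`` tracks force evaluations by kind ("total",
    "solvent", "solute") for cost accounting.
    """

    def __init__(self, nonbonded, bonds=(), angles=(), exclusions=(), partition=None,
                 group_ref=None):
        self.nonbonded = nonbonded
        self.bonds = list(bonds)
        self.angles = list(angles)
        self.partition = partition
        n = len(np.asarray(nonbonded.sigma))
        self.n_atoms = n
        if partition is not None:
            partition.validate_covering(n)
        if group_ref is None:
            group_ref = np.arange(n, dtype=np.intp)
        self.group_ref = np.asarray(group_ref, dtype=np.intp)
        if self.group_ref.shape != (n,):
            raise ValueError("group_ref must give one reference atom per atom")

        iu, ju = np.triu_indices(n, 1)
        excl = set()
        for i, j in exclusions:
            excl.add((min(i, j), max(i, j)))
        if excl:
            keep = np.array(
                [(i, j) not in excl for i, j in zip(iu, ju)], dtype=bool
            )
            iu, ju = iu[keep], ju[keep]
        self._pi, self._pj = iu, ju
        self._ri = self.group_ref[iu]
        self._rj = self.group_ref[ju]
        sig = np.asarray(nonbonded.sigma, dtype=float)
        eps = np.asarray(nonbonded.epsilon, dtype=float)
        chg = np.asarray(nonbonded.charge, dtype=float)
        self._sig2 = (0.5 * (sig[iu] + sig[ju])) ** 2
        self._eps = np.sqrt(eps[iu] * eps[ju])
        self._kqq = nonbonded.coulomb_constant * chg[iu] * chg[ju]

        if partition is not None:
            solute = np.zeros(n, dtype=bool)
            solute[partition.solute_indices] = True
            inv = solute[iu] | solute[ju]
            self._ss_sel = np.flatnonzero(~inv)
            self._sol_sel = np.flatnonzero(inv)

        self._bi = np.array([b.i for b in self.bonds], dtype=np.intp)
        self._bj = np.array([b.j for b in self.bonds], dtype=np.intp)
        self._bk = np.array([b.k for b in self.bonds], dtype=float)
        self._br0 = np.array([b.r0 for b in self.bonds], dtype=float)
        self._ci = np.array([a.i for a in self.angles], dtype=np.intp)
        self._cj = np.array([a.j for a in self.angles], dtype=np.intp)
        self._ck = np.array([a.k_atom for a in self.angles], dtype=np.intp)
        self._kth = np.array([a.k_theta for a in self.angles], dtype=float)
        self._th0 = np.array([a.theta0 for a in self.angles], dtype=float)

        self.call_counts = {"total": 0, "solvent": 0, "solute": 0}

    # -- full force -----------------------------------------------------
    def energy_forces(self, state: SystemState):
        self.call_counts["total"] += 1
        U, F = self._nonbonded_subset(state, slice(None))
        Ub, Fb = self._bonded(state.q)
        return U + Ub, F + Fb

    # -- partitioned forces --------------------------------------------
    def solvent_energy_forces(self, state: SystemState):
        """Solvent-solvent nonbonded terms only (U_ss)."""
        self._require_partition()
        self.call_counts["solvent"] += 1
        return self._nonbonded_subset(state, self._ss_sel)

    def solute_energy_forces(self, state: SystemState):
        """All terms involving the solute (U_pp + U_ps) plus every bonded
        term."""
        self._require_partition()
        self.call_counts["solute"] += 1
        U, F = self._nonbonded_subset(state, self._sol_sel)
        Ub, Fb = self._bonded(state.q)
        return U + Ub, F + Fb

    def pair_counts(self):
        """(solvent-solvent, solute-involving) nonbonded pair counts."""
        self._require_partition()
        return int(self._ss_sel.size), int(self._sol_sel.size)

    # -- helpers --------------------------------------------------------
    def _require_partition(self):
        if self.partition is None:
            raise ValueError("force field has no solute/solvent partition")

    def _nonbonded_subset(self, state, sel):
        return _pair_energy_forces(
            state.q,
            state.box,
            self._pi[sel],
            self._pj[sel],
            self._ri[sel],
            self._rj[sel],
            self._sig2[sel],
            self._eps[sel],
            self._kqq[sel],
            self.nonbonded.cutoff,
        )

    def _bonded(self, q):
        U1, F1 = _bond_energy_forces(q, self._bi, self._bj, self._bk, self._br0)
        U2, F2 = _angle_energy_forces(q, self._ci, self._cj, self._ck, self._kth, self._th0)
        return U1 + U2, F1 + F2


# ----------------------------------------------------------------------
# functional wrappers (operation-level API)
# ----------------------------------------------------------------------
def nonbonded_energy_forces(state: SystemState, ff: PairForceField):
    """Nonbonded LJ+Coulomb energy and forces only."""
    return ff._nonbonded_subset(state, slice(None))


def bonded_energy_forces(state: SystemState, ff: PairForceField):
    """Harmonic bond + angle energy and forces only."""
    return ff._bonded(state.q)


def partitioned_forces(state: SystemState, ff: PairForceField):
    """(U_ss, F_ss), (U_solute, F_solute); the two force fields sum to
    the unpartitioned total to 1e-10."""
    return ff.solvent_energy_forces(state), ff.solute_energy_forces(state)
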