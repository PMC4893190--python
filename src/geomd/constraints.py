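"""Holonomic distance constraints and the constrained elementary flows.

A constrained Langevin step is composed from three pieces, each of which
preserves the constraint manifold ``g(q) = 0`` and the cotangency
condition ``G(q) M^{-1} p = 0``:

* the geodesic drift (kinetic energy only), approximated by a sequence of
  free drifts followed by SHAKE position projection and RATTLE momentum
  projection;
* the projected kick ``p <- p + h * Pi F`` with the cotangent projector
  ``Pi = I - G^T (G M^{-1} G^T)^{-1} G M^{-1}``;
* the constrained Ornstein-Uhlenbeck step, whose weak solution follows
  from ``exp(alpha Pi) = I + (e^alpha - 1) Pi`` (Rodrigues' formula for a
  projector), reducing for cotangent momenta to

      p(h) = e^{-gamma h} p(0)
             + sqrt(kT (1 - e^{-2 gamma h})) Pi M^{1/2} R.

Constraint convention: ``g_ij(q) = |q_i - q_j|^2 - r0^2`` (squared
distance, smooth everywhere); tolerances are on this squared residual.

Production code never forms ``Pi`` densely.  Constraints are grouped into
connected clusters (e.g. one rigid water = 3 constraints on 3 atoms) and
the m x m normal system is solved per cluster, batched over all clusters
of identical shape in a single numpy call.  A dense path is retained for
small-system tests; both must agree to 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import _kernels
from .core import SystemState, ThermostatParams, RandomStream

__all__ = [
    "TOL_G",
    "TOL_P",
    "ConstraintSet",
    "ProjectionResult",
    "DegenerateConstraintError",
    "ConstraintFailureError",
    "cotangent_projector",
    "projector_exponential",
    "rattle_momentum_project",
    "shake_position_project",
    "project_cotangent",
    "geodesic_flow_step",
    "projected_kick",
    "constrained_ou_step",
]

#: default tolerance on the squared-distance constraint residual (A^2)
TOL_G = 1.0e-8
#: default tolerance on the cotangency residual G M^-1 p (internal units)
TOL_P = 1.0e-8

_SHAKE_MAX_ITER = 500


class DegenerateConstraintError(np.linalg.LinAlgError):
    """Constraint Jacobian is rank deficient (G M^-1 G^T singular)."""


class ConstraintFailureError(RuntimeError):
    """SHAKE projection failed: no solution reachable along the
    reference gradients (or the iteration diverged).  The step must be
    aborted, never silently continued."""

    def __init__(self, message: str, worst_residual: float = np.nan):
        super().__init__(message)
        self.worst_residual = worst_residual


@dataclass
class ProjectionResult:
    projected: np.ndarray
    multipliers: np.ndarray
    iterations: int
    converged: bool


class ConstraintSet:
    """A list of pairwise distance constraints.

    Parameters
    ----------
    pairs : sequence of (i, j, r0)
        Atom index pairs with target distances in angstrom.
    """

    def __init__(self, pairs):
        triples = [(int(i), int(j), float(r)) for i, j, r in pairs]
        seen = set()
        for i, j, r in triples:
            if i == j:
                raise ValueError(f"constraint pairs an atom with itself: {i}")
            if r <= 0:
                raise ValueError(f"non-positive target distance for ({i},{j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate constraint pair {key}")
            seen.add(key)
        self.ai = np.array([t[0] for t in triples], dtype=np.intp)
        self.aj = np.array([t[1] for t in triples], dtype=np.intp)
        self.r0 = np.array([t[2] for t in triples], dtype=float)
        self.r0sq = self.r0**2
        self._colors = self._edge_coloring()
        self._groups_topo = self._cluster_groups()
        self._coef_cache: dict[int, tuple[np.ndarray, list[np.ndarray]]] = {}

    # ------------------------------------------------------------------
    # basic evaluation
    # ------------------------------------------------------------------
    @property
    def n_constraints(self) -> int:
        return self.ai.size

    def evaluate(self, q: np.ndarray) -> np.ndarray:
        """Residuals g_j(q) = |q_i - q_j|^2 - r0^2 (shape (m,))."""
        d = q[self.ai] - q[self.aj]
        return np.einsum("md,md->m", d, d) - self.r0sq

    def jacobian(self, q: np.ndarray) -> np.ndarray:
        """Dense Jacobian G(q) of shape (m, n_atoms * n_dim).

        Intended for small-system tests and oracles; production paths use
        the clustered solve instead.
        """
        n_atoms, n_dim = q.shape
        G = np.zeros((self.n_constraints, n_atoms * n_dim))
        d = 2.0 * (q[self.ai] - q[self.aj])
        for a in range(self.n_constraints):
            i, j = self.ai[a], self.aj[a]
            G[a, i * n_dim : (i + 1) * n_dim] = d[a]
            G[a, j * n_dim : (j + 1) * n_dim] = -d[a]
        return G

    def cotangency_residual(self, state: SystemState) -> float:
        """max_j |grad g_j . M^{-1} p|."""
        if self.n_constraints == 0:
            return 0.0
        invm = state.inv_masses
        v = state.p * invm[:, None]
        d = 2.0 * (state.q[self.ai] - state.q[self.aj])
        return float(np.abs(np.einsum("md,md->m", d, v[self.ai] - v[self.aj])).max())

    def max_residual(self, q: np.ndarray) -> float:
        if self.n_constraints == 0:
            return 0.0
        return float(np.abs(self.evaluate(q)).max())

    # ------------------------------------------------------------------
    # topology precomputation
    # ------------------------------------------------------------------
    def _edge_coloring(self):
        """Greedy colouring so constraints in one colour share no atom.

        Within a SHAKE sweep, each colour is updated as one vectorised
        Newton step; colours are visited sequentially (Gauss-Seidel
        across colours, exact parallelism within a colour).
        """
        m = self.n_constraints
        atom_colors: dict[int, set[int]] = {}
        color_of = np.zeros(m, dtype=int)
        for a in range(m):
            used = atom_colors.setdefault(self.ai[a], set()) | atom_colors.setdefault(
                self.aj[a], set()
            )
            c = 0
            while c in used:
                c += 1
            color_of[a] = c
            atom_colors[self.ai[a]].add(c)
            atom_colors[self.aj[a]].add(c)
        ncolors = int(color_of.max()) + 1 if m else 0
        return [np.flatnonzero(color_of == c) for c in range(ncolors)]

    def _cluster_groups(self):
        """Group constraints into connected clusters, then bucket clusters
        by constraint count so each bucket solves one batched k x k system."""
        m = self.n_constraints
        if m == 0:
            return []
        atoms = np.unique(np.concatenate([self.ai, self.aj]))
        remap = {a: k for k, a in enumerate(atoms)}
        ri = np.array([remap[a] for a in self.ai])
        rj = np.array([remap[a] for a in self.aj])
        adj = coo_matrix(
            (np.ones(m), (ri, rj)), shape=(atoms.size, atoms.size)
        )
        _, comp = connected_components(adj, directed=False)
        cluster_of = comp[ri]  # component of constraint = component of its atoms
        groups = []
        by_size: dict[int, list[np.ndarray]] = {}
        for c in np.unique(cluster_of):
            idx = np.flatnonzero(cluster_of == c)
            by_size.setdefault(idx.size, []).append(idx)
        for k, clusters in sorted(by_size.items()):
            cons = np.array(clusters, dtype=np.intp)  # (ncl, k)
            groups.append(cons)
        return groups

    def _coefficients(self, masses: np.ndarray):
        """Static coefficient tensors C[c,a,b] with
        A = G M^-1 G^T = 4 * C * (dq_a . dq_b), cached per masses array."""
        key = id(masses)
        hit = self._coef_cache.get(key)
        if hit is not None and hit[0] is masses:
            return hit[1]
        with np.errstate(divide="ignore"):
            invm = 1.0 / masses
        invm = np.where(np.isfinite(masses), invm, 0.0)
        tensors = []
        for cons in self._groups_topo:
            I = self.ai[cons]  # (ncl, k)
            J = self.aj[cons]
            C = (
                (I[:, :, None] == I[:, None, :]) * invm[I][:, :, None]
                + (J[:, :, None] == J[:, None, :]) * invm[J][:, :, None]
                - (I[:, :, None] == J[:, None, :]) * invm[I][:, :, None]
                - (J[:, :, None] == I[:, None, :]) * invm[J][:, :, None]
            )
            tensors.append(C)
        self._coef_cache = {key: (masses, (invm, tensors))}
        return invm, tensors


# ----------------------------------------------------------------------
# dense projector algebra (small systems, oracles)
# ----------------------------------------------------------------------
def cotangent_projector(G: np.ndarray, masses_dof: np.ndarray) -> np.ndarray:
    """Dense cotangent projector Pi = I - G^T (G M^-1 G^T)^-1 G M^-1.

    ``masses_dof`` is the per-degree-of-freedom mass vector (length N).
    Raises :class:`DegenerateConstraintError` if the constraints are rank
    deficient.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    N = G.shape[1]
    if G.shape[0] == 0:
        return np.eye(N)
    with np.errstate(divide="ignore"):
        invm = 1.0 / np.asarray(masses_dof, dtype=float)
    invm = np.where(np.isfinite(masses_dof), invm, 0.0)
    GD = G * invm[None, :]
    S = GD @ G.T
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e12:
        raise DegenerateConstraintError(
            f"G M^-1 G^T is (near-)singular, cond={cond:.3g}"
        )
    X = scipy.linalg.solve(S, GD, assume_a="sym")
    return np.eye(N) - G.T @ X


def projector_exponential(alpha: float, Pi: np.ndarray) -> np.ndarray:
    """exp(alpha * Pi) = I + (e^alpha - 1) Pi for a projector Pi."""
    Pi = np.asarray(Pi, dtype=float)
    return np.eye(Pi.shape[0]) + np.expm1(alpha) * Pi


def rattle_momentum_project(
    p: np.ndarray, G: np.ndarray, masses_dof: np.ndarray
) -> ProjectionResult:
    """Orthogonal (M^-1-metric) projection of momenta onto the cotangent
    space: p' = Pi p, returned with the multipliers mu solving
    (G M^-1 G^T) mu = G M^-1 p.  Dense path for small systems."""
    G = np.atleast_2d(np.asarray(G, dtype=float))
    p = np.asarray(p, dtype=float)
    if G.shape[0] == 0:
        return ProjectionResult(p.copy(), np.zeros(0), 1, True)
    with np.errstate(divide="ignore"):
        invm = 1.0 / np.asarray(masses_dof, dtype=float)
    invm = np.where(np.isfinite(masses_dof), invm, 0.0)
    S = (G * invm[None, :]) @ G.T
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e12:
        raise DegenerateConstraintError(
            f"G M^-1 G^T is (near-)singular, cond={cond:.3g}"
        )
    mu = scipy.linalg.solve(S, G @ (invm * p), assume_a="sym")
    return ProjectionResult(p - G.T @ mu, mu, 1, True)


# ----------------------------------------------------------------------
# clustered projector action (production path)
# ----------------------------------------------------------------------
def project_cotangent(
    v: np.ndarray,
    q: np.ndarray,
    masses: np.ndarray,
    constraints: ConstraintSet,
    return_multipliers: bool = False,
):
    """Apply the cotangent projector: returns Pi(q) v.

    ``v`` has shape (n_atoms, n_dim).  The m x m normal system is solved
    per connected constraint cluster (batched over clusters of equal
    size); the result agrees with the dense projector to 1e-10.
    """
    if constraints.n_constraints == 0:
        return (v.copy(), np.zeros(0)) if return_multipliers else v.copy()
    invm, tensors = constraints._coefficients(masses)
    out = v.copy()
    vi = v * invm[:, None]
    mults = np.zeros(constraints.n_constraints) if return_multipliers else None
    for cons, C in zip(constraints._groups_topo, tensors):
        I = constraints.ai[cons]
        J = constraints.aj[cons]
        dq = q[I] - q[J]  # (ncl, k, dim)
        A = 4.0 * C * np.einsum("ckd,cld->ckl", dq, dq)
        rhs = 2.0 * np.einsum("ckd,ckd->ck", dq, vi[I] - vi[J])
        try:
            x = np.linalg.solve(A, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:
            raise DegenerateConstraintError(str(exc)) from exc
        corr = 2.0 * dq * x[..., None]
        dim = v.shape[1]
        np.subtract.at(out, I.ravel(), corr.reshape(-1, dim))
        np.add.at(out, J.ravel(), corr.reshape(-1, dim))
        if mults is not None:
            mults[cons.ravel()] = x.ravel()
    if return_multipliers:
        return out, mults
    return out


# ----------------------------------------------------------------------
# SHAKE position projection
# ----------------------------------------------------------------------
def shake_position_project(
    q_unc: np.ndarray,
    q_ref: np.ndarray,
    constraints: ConstraintSet,
    masses: np.ndarray,
    tol: float = TOL_G,
    max_iter: int = _SHAKE_MAX_ITER,
) -> ProjectionResult:
    """Return the unconstrained proposal to the manifold by oblique
    projection along M^-1 grad g(q_ref).

    Gauss-Seidel sweeps of single Newton steps per constraint (the
    classic iteration), vectorised over non-overlapping constraint
    colours.  Raises :class:`ConstraintFailureError` when the projection
    equation is insoluble (the correction direction loses its projection
    onto the current gradient) or the iteration fails to converge --
    aborting the step is mandatory, the caller must not continue.
    """
    m = constraints.n_constraints
    if m == 0:
        return ProjectionResult(q_unc.copy(), np.zeros(0), 0, True)
    with np.errstate(divide="ignore"):
        invm = 1.0 / masses
    invm = np.where(np.isfinite(masses), invm, 0.0)

    q = q_unc.copy()
    lam = np.zeros(m)
    res0 = constraints.max_residual(q)
    if res0 <= tol:
        return ProjectionResult(q, lam, 0, True)

    dref = q_ref[constraints.ai] - q_ref[constraints.aj]  # (m, dim)

    if _kernels.HAVE_NUMBA:
        refscale = np.einsum("md,md->m", dref, dref)
        lam, sweeps, status = _kernels.shake_sweeps(
            q,
            np.ascontiguousarray(constraints.ai, dtype=np.int64),
            np.ascontiguousarray(constraints.aj, dtype=np.int64),
            constraints.r0sq,
            np.ascontiguousarray(dref),
            refscale,
            invm,
            tol,
            max_iter,
            res0,
        )
        if status == 0:
            return ProjectionResult(q, lam, sweeps, True)
        res = constraints.max_residual(q)
        if status == 2:
            raise ConstraintFailureError(
                "SHAKE projection insoluble: correction direction "
                "orthogonal to current constraint gradient",
                worst_residual=res,
            )
        if status == 3:
            raise ConstraintFailureError(
                f"SHAKE diverged: residual {res:.3g} from initial {res0:.3g}",
                worst_residual=res,
            )
        raise ConstraintFailureError(
            f"SHAKE failed to converge in {max_iter} sweeps "
            f"(residual {res:.3g}, tol {tol:.3g})",
            worst_residual=res,
        )

    prev = np.inf
    for sweep in range(1, max_iter + 1):
        for idx in constraints._colors:
            i = constraints.ai[idx]
            j = constraints.aj[idx]
            d = q[i] - q[j]
            g = np.einsum("md,md->m", d, d) - constraints.r0sq[idx]
            denom = 4.0 * np.einsum("md,md->m", d, dref[idx]) * (invm[i] + invm[j])
            scale = np.einsum("md,md->m", dref[idx], dref[idx]) * (invm[i] + invm[j])
            if np.any(np.abs(denom) <= 1e-8 * scale):
                raise ConstraintFailureError(
                    "SHAKE projection insoluble: correction direction "
                    "orthogonal to current constraint gradient",
                    worst_residual=float(np.abs(g).max()),
                )
            dlam = g / denom
            lam[idx] += dlam
            step = 2.0 * dlam[:, None] * dref[idx]
            q[i] -= invm[i, None] * step
            q[j] += invm[j, None] * step
        res = constraints.max_residual(q)
        if not np.isfinite(res) or res > 1e3 * (res0 + 1.0):
            raise ConstraintFailureError(
                f"SHAKE diverged: residual {res:.3g} from initial {res0:.3g}",
                worst_residual=res,
            )
        if res <= tol:
            return ProjectionResult(q, lam, sweep, True)
        prev = res
    raise ConstraintFailureError(
        f"SHAKE failed to converge in {max_iter} sweeps "
        f"(residual {prev:.3g}, tol {tol:.3g})",
        worst_residual=prev,
    )


# ----------------------------------------------------------------------
# elementary constrained flows
# ----------------------------------------------------------------------
def geodesic_flow_step(
    state: SystemState,
    h: float,
    constraints: ConstraintSet | None,
    n_inner: int = 1,
    tol: float = TOL_G,
) -> SystemState:
    """Approximate the geodesic (kinetic-only) flow for time h.

    Performs ``n_inner`` substeps of size ``h / n_inner``; each is a free
    drift, a SHAKE position projection with the matching momentum
    correction, and a RATTLE momentum projection.  No force evaluation
    occurs.  Kinetic energy is conserved to O((h/n_inner)^2) per substep
    and the endpoint converges to the exact geodesic at second order.
    """
    new = state.copy()
    if constraints is None or constraints.n_constraints == 0:
        new.q += h * new.p * new.inv_masses[:, None]
        new.time += h
        return new
    invm = new.inv_masses
    tau = h / n_inner
    for _ in range(n_inner):
        q_ref = new.q
        q_unc = q_ref + tau * new.p * invm[:, None]
        result = shake_position_project(
            q_unc, q_ref, constraints, new.masses, tol=tol
        )
        # momentum update consistent with the constrained drift:
        # q_new = q_ref + tau M^-1 (p - G(q_ref)^T lam / tau)
        dref = q_ref[constraints.ai] - q_ref[constraints.aj]
        corr = (2.0 / tau) * result.multipliers[:, None] * dref
        p = new.p.copy()
        np.subtract.at(p, constraints.ai, corr)
        np.add.at(p, constraints.aj, corr)
        new.q = result.projected
        new.p = project_cotangent(p, new.q, new.masses, constraints)
    new.time += h
    return new


def projected_kick(
    state: SystemState,
    h: float,
    force: np.ndarray,
    constraints: ConstraintSet | None = None,
) -> SystemState:
    """Constrained impulse: p <- p + h * Pi(q) F; positions unchanged.

    The returned state shares the (unmodified) position array with the
    input, which lets integrators detect by identity that a cached force
    is still valid.  Elementary flows never mutate input arrays in place.
    """
    if constraints is None or constraints.n_constraints == 0:
        p = state.p + h * force
    else:
        p = state.p + h * project_cotangent(force, state.q, state.masses, constraints)
    return SystemState(
        q=state.q, p=p, masses=state.masses, box=state.box, time=state.time
    )


def constrained_ou_step(
    state: SystemState,
    h: float,
    thermostat: ThermostatParams,
    rng: RandomStream,
    constraints: ConstraintSet | None = None,
) -> SystemState:
    """Weak solution of the projected Ornstein-Uhlenbeck process.

    For cotangent momenta the update is
    ``p <- e^{-gamma h} p + sqrt(kT (1 - e^{-2 gamma h})) Pi M^{1/2} R``
    with R standard normal, drawn for every atom in index order (xyz
    fastest).  ``gamma = 0`` is an exact identity and consumes no
    Gaussians, so deterministic-limit tests are exact.
    """
    if thermostat.gamma == 0.0:
        return SystemState(
            q=state.q, p=state.p, masses=state.masses, box=state.box, time=state.time
        )
    c = np.exp(-thermostat.gamma * h)
    sigma = np.sqrt(thermostat.kT * (1.0 - c * c))
    R = rng.normal(state.p.shape)
    sqrtm = np.where(np.isfinite(state.masses), np.sqrt(state.masses), 0.0)
    noise = sqrtm[:, None] * R
    if constraints is not None and constraints.n_constraints > 0:
        noise = project_cotangent(noise, state.q, state.masses, constraints)
    p = c * state.p + sigma * noise
    return SystemState(
        q=state.q, p=p, masses=state.masses, box=state.box, time=state.time
    )
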