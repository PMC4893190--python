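"""Splitting-scheme integrators for constrained Langevin dynamics.

The named schemes compose the elementary constrained flows of
:mod:`geomd.constraints`:

* ``gBAOAB``   -- B(h/2) A(h/2) O(h) A(h/2) B(h/2), each A piece resolved
  by ``n_inner`` SHAKE/RATTLE geodesic substeps;
* ``gOBABO``   -- O(h/2) B(h/2) A(h) B(h/2) O(h/2) (geodesic version of
  the Bussi-Parinello splitting);
* ``MEVME``    -- midpoint-Euler OU half-step, constrained (RATTLE)
  Verlet step, midpoint-Euler OU half-step (best-effort reimplementation
  of the Midpoint-Euler-Verlet-Midpoint-Euler scheme);
* ``gBAOAB-RESPA`` -- the solvent-solute multiple-timestep composition
  Bs(h/2) [Bp(h/2Kp) A(h/2Kp) O(h/Kp) A(h/2Kp) Bp(h/2Kp)]^Kp Bs(h/2).

Force reuse: the force evaluated for a step's trailing kick is cached and
reused by the next step's leading kick (positions do not move across the
step boundary), so every scheme makes exactly one new full force
evaluation per step in steady state.  Cache validity is tracked by array
identity of the position vector, which elementary flows share when they
leave positions untouched.

On a partitioned force field, ``gBAOAB`` *is* the Kp=1 case of the RESPA
composition (the two kick operators commute exactly at fixed positions),
implemented as a single shared code path; with a shared noise stream the
Kp=1 multiple-timestep scheme is therefore bit-identical to g-BAOAB.

Noise draw order is fixed by the composition string: each O substep
draws one standard normal per degree of freedom, atoms in index order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    SystemState,
    ThermostatParams,
    RandomStream,
    fs_to_internal,
    kinetic_energy,
)
from .constraints import (
    ConstraintSet,
    ConstraintFailureError,
    geodesic_flow_step,
    projected_kick,
    constrained_ou_step,
    project_cotangent,
    shake_position_project,
)
from .trajectory import TrajectoryRecord

__all__ = [
    "SCHEME_CODES",
    "SplittingScheme",
    "ForceCache",
    "g_baoab_step",
    "g_obabo_step",
    "mevme_step",
    "respa_gbaoab_step",
    "rattle_verlet_step",
    "make_step_function",
    "run_trajectory",
]

SCHEME_CODES = ("gBAOAB", "gOBABO", "MEVME", "gBAOAB-RESPA")


@dataclass(frozen=True)
class SplittingScheme:
    """An ordered splitting composition with its stepsizes.

    ``dt`` is the outer stepsize in internal time units (use
    :meth:`from_fs` for femtoseconds), ``n_inner`` the number of geodesic
    (SHAKE/RATTLE) substeps per A piece and ``kp`` the number of solute
    substeps of the multiple-timestep composition.
    """

    code: str
    dt: float
    n_inner: int = 1
    kp: int = 1

    def __post_init__(self):
        if self.code not in SCHEME_CODES:
            raise ValueError(f"unknown scheme code {self.code!r}; known: {SCHEME_CODES}")
        if self.dt <= 0:
            raise ValueError("stepsize must be positive")
        if self.n_inner < 1 or self.kp < 1:
            raise ValueError("n_inner and kp must be >= 1")

    @classmethod
    def from_fs(cls, code: str, dt_fs: float, n_inner: int = 1, kp: int = 1):
        return cls(code=code, dt=fs_to_internal(dt_fs), n_inner=n_inner, kp=kp)

    @property
    def dt_fs(self) -> float:
        from .core import internal_to_fs

        return internal_to_fs(self.dt)


@dataclass
class ForceCache:
    """Force reuse across the step boundary, keyed by position-array
    identity."""

    q: np.ndarray | None = None
    U: float | None = None
    F: np.ndarray | None = None
    # partitioned entries
    U_ss: float | None = None
    F_ss: np.ndarray | None = None
    U_p: float | None = None
    F_p: np.ndarray | None = None

    def valid_for(self, state: SystemState) -> bool:
        return self.q is not None and self.q is state.q

    @property
    def last_potential(self) -> float | None:
        if self.U is not None:
            return self.U
        if self.U_ss is not None and self.U_p is not None:
            return self.U_ss + self.U_p
        return None


def _total_force(state, forcefield, cache):
    if cache is not None and cache.valid_for(state) and cache.F is not None:
        return cache.U, cache.F
    return forcefield.energy_forces(state)


# ----------------------------------------------------------------------
# one-step maps
# ----------------------------------------------------------------------
def g_baoab_step(
    state: SystemState,
    scheme: SplittingScheme,
    forcefield,
    thermostat: ThermostatParams,
    rng: RandomStream,
    constraints: ConstraintSet | None = None,
    cache: ForceCache | None = None,
) -> SystemState:
    """One g-BAOAB step: B(h/2) A(h/2) O(h) A(h/2) B(h/2).

    On a force field carrying a solvent-solute partition this runs the
    Kp=1 multiple-timestep composition (same code path, identical in
    exact and floating-point arithmetic).
    """
    if getattr(forcefield, "partition", None) is not None:
        return _respa_core(state, scheme, 1, forcefield, thermostat, rng, constraints, cache)
    h = scheme.dt
    U, F = _total_force(state, forcefield, cache)
    s = projected_kick(state, 0.5 * h, F, constraints)
    s = geodesic_flow_step(s, 0.5 * h, constraints, scheme.n_inner)
    s = constrained_ou_step(s, h, thermostat, rng, constraints)
    s = geodesic_flow_step(s, 0.5 * h, constraints, scheme.n_inner)
    U, F = forcefield.energy_forces(s)
    s = projected_kick(s, 0.5 * h, F, constraints)
    if cache is not None:
        cache.q, cache.U, cache.F = s.q, U, F
    return s


def g_obabo_step(
    state: SystemState,
    scheme: SplittingScheme,
    forcefield,
    thermostat: ThermostatParams,
    rng: RandomStream,
    constraints: ConstraintSet | None = None,
    cache: ForceCache | None = None,
) -> SystemState:
    """One g-OBABO step: O(h/2) B(h/2) A(h) B(h/2) O(h/2)."""
    h = scheme.dt
    s = constrained_ou_step(state, 0.5 * h, thermostat, rng, constraints)
    U, F = _total_force(s, forcefield, cache)
    s = projected_kick(s, 0.5 * h, F, constraints)
    s = geodesic_flow_step(s, h, constraints, scheme.n_inner)
    U, F = forcefield.energy_forces(s)
    s = projected_kick(s, 0.5 * h, F, constraints)
    s = constrained_ou_step(s, 0.5 * h, thermostat, rng, constraints)
    if cache is not None:
        cache.q, cache.U, cache.F = s.q, U, F
    return s


def rattle_verlet_step(
    state: SystemState,
    h: float,
    forcefield,
    constraints: ConstraintSet | None = None,
    cache: ForceCache | None = None,
) -> SystemState:
    """One deterministic RATTLE step (constrained velocity Verlet):
    half kick, SHAKE-projected drift with the matching momentum
    correction, half kick, RATTLE momentum projection."""
    U, F = _total_force(state, forcefield, cache)
    invm = state.inv_masses
    p_half = state.p + 0.5 * h * F
    q_ref = state.q
    q_unc = q_ref + h * p_half * invm[:, None]
    if constraints is not None and constraints.n_constraints > 0:
        res = shake_position_project(q_unc, q_ref, constraints, state.masses)
        q_new = res.projected
        corr = (2.0 / h) * res.multipliers[:, None] * (
            q_ref[constraints.ai] - q_ref[constraints.aj]
        )
        p_half = p_half.copy()
        np.subtract.at(p_half, constraints.ai, corr)
        np.add.at(p_half, constraints.aj, corr)
    else:
        q_new = q_unc
    mid = SystemState(
        q=q_new, p=p_half, masses=state.masses, box=state.box, time=state.time + h
    )
    U2, F2 = forcefield.energy_forces(mid)
    p1 = p_half + 0.5 * h * F2
    if constraints is not None and constraints.n_constraints > 0:
        p1 = project_cotangent(p1, q_new, state.masses, constraints)
    out = SystemState(
        q=q_new, p=p1, masses=state.masses, box=state.box, time=state.time + h
    )
    if cache is not None:
        cache.q, cache.U, cache.F = out.q, U2, F2
    return out


def _midpoint_euler_ou(state, h, thermostat, rng, constraints):
    """Implicit-midpoint Euler step of the projected OU process over h;
    identity (no draws) at gamma = 0."""
    if thermostat.gamma == 0.0:
        return state
    a = 0.5 * thermostat.gamma * h
    R = rng.normal(state.p.shape)
    sqrtm = np.where(np.isfinite(state.masses), np.sqrt(state.masses), 0.0)
    noise = sqrtm[:, None] * R
    if constraints is not None and constraints.n_constraints > 0:
        noise = project_cotangent(noise, state.q, state.masses, constraints)
    sigma = np.sqrt(2.0 * thermostat.kT * thermostat.gamma * h)
    p = ((1.0 - a) * state.p + sigma * noise) / (1.0 + a)
    return SystemState(
        q=state.q, p=p, masses=state.masses, box=state.box, time=state.time
    )


def mevme_step(
    state: SystemState,
    scheme: SplittingScheme,
    forcefield,
    thermostat: ThermostatParams,
    rng: RandomStream,
    constraints: ConstraintSet | None = None,
    cache: ForceCache | None = None,
) -> SystemState:
    """One MEVME step: midpoint-Euler OU half-step, RATTLE Verlet step,
    midpoint-Euler OU half-step.  At gamma = 0 this is exactly one RATTLE
    step."""
    h = scheme.dt
    s = _midpoint_euler_ou(state, 0.5 * h, thermostat, rng, constraints)
    s = rattle_verlet_step(s, h, forcefield, constraints, cache)
    s = _midpoint_euler_ou(s, 0.5 * h, thermostat, rng, constraints)
    if cache is not None:
        cache.q = s.q
    return s


def _respa_core(state, scheme, kp, forcefield, thermostat, rng, constraints, cache):
    h = scheme.dt
    hk = h / kp
    if cache is not None and cache.valid_for(state) and cache.F_ss is not None:
        U_ss, F_ss = cache.U_ss, cache.F_ss
        have_p = cache.F_p is not None
        U_p, F_p = (cache.U_p, cache.F_p) if have_p else (None, None)
    else:
        U_ss, F_ss = forcefield.solvent_energy_forces(state)
        have_p = False
        U_p = F_p = None
    s = projected_kick(state, 0.5 * h, F_ss, constraints)
    for k in range(kp):
        if not (k == 0 and have_p):
            U_p, F_p = forcefield.solute_energy_forces(s)
        s = projected_kick(s, 0.5 * hk, F_p, constraints)
        s = geodesic_flow_step(s, 0.5 * hk, constraints, scheme.n_inner)
        s = constrained_ou_step(s, hk, thermostat, rng, constraints)
        s = geodesic_flow_step(s, 0.5 * hk, constraints, scheme.n_inner)
        U_p, F_p = forcefield.solute_energy_forces(s)
        s = projected_kick(s, 0.5 * hk, F_p, constraints)
    U_ss, F_ss = forcefield.solvent_energy_forces(s)
    s = projected_kick(s, 0.5 * h, F_ss, constraints)
    if cache is not None:
        cache.q = s.q
        cache.U = cache.F = None
        cache.U_ss, cache.F_ss = U_ss, F_ss
        cache.U_p, cache.F_p = U_p, F_p
    return s


def respa_gbaoab_step(
    state: SystemState,
    scheme: SplittingScheme,
    forcefield,
    thermostat: ThermostatParams,
    rng: RandomStream,
    constraints: ConstraintSet | None = None,
    cache: ForceCache | None = None,
) -> SystemState:
    """One solvent-solute multiple-timestep g-BAOAB step with
    ``scheme.kp`` inner solute cycles.  Requires a partitioned force
    field; with ``kp = 1`` and a shared noise stream the output is
    bit-identical to :func:`g_baoab_step`."""
    return _respa_core(
        state, scheme, scheme.kp, forcefield, thermostat, rng, constraints, cache
    )


_STEP_FUNCTIONS = {
    "gBAOAB": g_baoab_step,
    "gOBABO": g_obabo_step,
    "MEVME": mevme_step,
    "gBAOAB-RESPA": respa_gbaoab_step,
}


def make_step_function(code: str):
    return _STEP_FUNCTIONS[code]


# ----------------------------------------------------------------------
# driver
# ----------------------------------------------------------------------
def run_trajectory(
    initial: SystemState,
    scheme: SplittingScheme,
    forcefield,
    thermostat: ThermostatParams,
    n_steps: int,
    rng: RandomStream | int,
    constraints: ConstraintSet | None = None,
    observers: dict | None = None,
    snapshot_stride: int = 0,
    energy_stride: int = 1,
    observer_stride: int = 1,
    blowup_energy: float = 1.0e8,
    metadata: dict | None = None,
) -> TrajectoryRecord:
    """Advance ``n_steps`` and collect a :class:`TrajectoryRecord`.

    ``snapshot_stride = 0`` stores only the initial snapshot.
    ``observers`` maps names to callables ``f(state) -> float`` sampled
    every ``observer_stride`` steps.  A constraint failure or an energy
    blow-up aborts the run: the record is flagged unstable, the last
    completed state is kept (the failing step is rolled back), and the
    partial record is returned.  Runs are deterministic given the seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = RandomStream(int(rng))
    step = _STEP_FUNCTIONS[scheme.code]
    cache = ForceCache()
    record = TrajectoryRecord(metadata=dict(metadata or {}))
    record.metadata.setdefault("scheme", scheme.code)
    record.metadata.setdefault("dt_fs", scheme.dt_fs)
    record.metadata.setdefault("n_inner", scheme.n_inner)
    record.metadata.setdefault("kp", scheme.kp)
    record.metadata.setdefault("seed", rng.seed)
    if observers:
        for name in observers:
            record.observables.setdefault(name, [])

    state = initial
    partitioned = getattr(forcefield, "partition", None) is not None
    if partitioned and scheme.code in ("gBAOAB", "gBAOAB-RESPA"):
        U_ss, F_ss = forcefield.solvent_energy_forces(state)
        U_p, F_p = forcefield.solute_energy_forces(state)
        U0 = U_ss + U_p
        cache.q = state.q
        cache.U_ss, cache.F_ss = U_ss, F_ss
        cache.U_p, cache.F_p = U_p, F_p
    else:
        U0, F0 = forcefield.energy_forces(state)
        cache.q, cache.U, cache.F = state.q, U0, F0

    def _sample(state, U):
        record.times.append(state.time)
        record.potential_energies.append(U)
        record.kinetic_energies.append(kinetic_energy(state))
        if constraints is not None:
            record.residual_g.append(constraints.max_residual(state.q))
            record.residual_p.append(constraints.cotangency_residual(state))

    _sample(state, U0)
    record.snapshot_times.append(state.time)
    record.snapshots.append(state.q.copy())
    if observers:
        for name, f in observers.items():
            record.observables[name].append(f(state))

    for n in range(1, n_steps + 1):
        try:
            state = step(state, scheme, forcefield, thermostat, rng, constraints, cache)
        except ConstraintFailureError as exc:
            record.unstable = True
            record.abort_reason = f"constraint failure at step {n}: {exc}"
            break
        ke = kinetic_energy(state)
        U = cache.last_potential
        if not np.isfinite(ke) or ke > blowup_energy or (
            U is not None and (not np.isfinite(U) or abs(U) > blowup_energy)
        ):
            record.unstable = True
            record.abort_reason = f"energy blow-up at step {n}"
            break
        record.n_steps_completed = n
        if energy_stride and n % energy_stride == 0:
            _sample(state, U if U is not None else np.nan)
        if snapshot_stride and n % snapshot_stride == 0:
            record.snapshot_times.append(state.time)
            record.snapshots.append(state.q.copy())
        if observers and n % observer_stride == 0:
            for name, f in observers.items():
                record.observables[name].append(f(state))
    record.final_state = state
    return record
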