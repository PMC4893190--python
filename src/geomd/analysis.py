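"""Observables and estimators: averages with block-averaged error bars,
radial distribution functions, diffusion from mean squared displacement,
free-energy profiles and barrier heights, autocorrelation decay, and the
invariant-measure bias-vs-stepsize harness.

Units at the interface: times in ps, distances in angstrom, diffusion
coefficients in 1e-5 cm^2 s^-1 (the conventional unit for water
self-diffusion).  The single conversion constant is

    1 A^2 / ps = 10 x 1e-5 cm^2 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .core import (
    BOLTZMANN_KCAL_MOL_K,
    RandomStream,
    ThermostatParams,
    internal_to_ps,
)
from .integrators import SplittingScheme, run_trajectory
from .systems import SystemSpec, circle_angles
from .trajectory import TrajectoryRecord

__all__ = [
    "ANG2_PER_PS_IN_1E5_CM2_PER_S",
    "EstimateWithError",
    "InsufficientDataError",
    "block_average",
    "mean_potential_energy",
    "radial_distribution",
    "diffusion_from_msd",
    "free_energy_profile",
    "autocorrelation_decay",
    "exact_circle_average",
    "bias_ladder",
    "harmonic_stability_limit_fs",
    "BiasLadderRow",
]

#: conversion A^2/ps -> 1e-5 cm^2/s (1 A^2/ps = 1e-16 cm^2 / 1e-12 s).
ANG2_PER_PS_IN_1E5_CM2_PER_S = 10.0

_SPEED_OF_LIGHT_CM_S = 2.99792458e10


class InsufficientDataError(ValueError):
    pass


@dataclass
class EstimateWithError:
    value: float
    standard_error: float
    method: str = ""

    def __post_init__(self):
        if self.standard_error < 0:
            raise ValueError("standard error must be non-negative")


def block_average(series: np.ndarray, n_blocks: int = 10) -> EstimateWithError:
    """Mean with a block-averaged standard error (guards against serial
    correlation that a naive SE would ignore)."""
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < 2 * n_blocks or n_blocks < 2:
        raise InsufficientDataError(
            f"need at least {2 * n_blocks} samples for {n_blocks} blocks, got {n}"
        )
    usable = n - (n % n_blocks)
    blocks = series[:usable].reshape(n_blocks, -1).mean(axis=1)
    se = blocks.std(ddof=1) / math.sqrt(n_blocks)
    return EstimateWithError(
        float(series.mean()), float(se), method=f"block-{n_blocks}"
    )


def mean_potential_energy(
    record: TrajectoryRecord, equilibration_cut: int = 0, n_blocks: int = 10
) -> EstimateWithError:
    """Time-averaged potential energy after discarding the first
    ``equilibration_cut`` samples."""
    series = record.potential_array[equilibration_cut:]
    if series.size == 0:
        raise InsufficientDataError("record shorter than the equilibration cut")
    return block_average(series, n_blocks=n_blocks)


# ----------------------------------------------------------------------
# radial distribution function
# ----------------------------------------------------------------------
def radial_distribution(
    frames: np.ndarray,
    box: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    bin_width: float = 0.05,
    r_max: float | None = None,
    exclude_pairs=None,
):
    """Pair correlation G(r) between two site sets under periodic minimum
    image, normalised by the ideal-gas shell density so G -> 1 at large r.

    ``frames``: array (n_frames, n_atoms, 3) of (possibly unwrapped)
    positions.  ``exclude_pairs``: iterable of (a, b) global index pairs
    to omit (e.g. intramolecular partners).  Returns (r_centers, g).
    """
    box = np.asarray(box, dtype=float)
    if r_max is None:
        r_max = float(box.min()) / 2.0
    if r_max > box.min() / 2.0 + 1e-9:
        raise ValueError("r_max must not exceed half the smallest box edge")
    idx_a = np.asarray(idx_a, dtype=np.intp)
    idx_b = np.asarray(idx_b, dtype=np.intp)
    ai, bi = np.meshgrid(idx_a, idx_b, indexing="ij")
    ai, bi = ai.ravel(), bi.ravel()
    keep = ai != bi
    if exclude_pairs is not None:
        excl = {(min(a, b), max(a, b)) for a, b in exclude_pairs}
        keep &= np.array(
            [(min(a, b), max(a, b)) not in excl for a, b in zip(ai, bi)]
        )
    ai, bi = ai[keep], bi[keep]
    n_pairs = ai.size
    if n_pairs == 0:
        raise ValueError("no pairs to correlate")

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(edges.size - 1)
    frames = np.asarray(frames)
    for q in frames:
        d = q[ai] - q[bi]
        d -= box * np.round(d / box)
        r = np.sqrt((d * d).sum(axis=1))
        hist += np.histogram(r, bins=edges)[0]
    volume = float(np.prod(box))
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    # each counted (ordered) pair contributes density n_pairs / V
    ideal = shell * n_pairs / volume * len(frames)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, hist / ideal


# ----------------------------------------------------------------------
# diffusion from MSD
# ----------------------------------------------------------------------
def diffusion_from_msd(
    frames: np.ndarray,
    snapshot_times_ps: np.ndarray,
    atom_indices: np.ndarray | None = None,
    fit_window: tuple[float, float] | None = None,
    remove_drift: bool = False,
) -> EstimateWithError:
    """Self-diffusion coefficient from the Einstein relation
    MSD(t) = 6 D t, in 1e-5 cm^2 s^-1.

    Uses all snapshot pairs at matching lag (multiple time origins) on
    unwrapped coordinates.  The standard error comes from the spread of
    per-particle slope estimates.  ``fit_window`` is (t_min, t_max) in
    ps; default is [10%, 50%] of the trajectory length.

    ``remove_drift`` subtracts the per-frame mean position of the
    selected atoms before computing displacements.  Under a Langevin
    thermostat the system's centre of mass performs its own random walk
    with D_com = kT / (M_total gamma), which contaminates single-particle
    MSDs; self-diffusion is conventionally measured in the fluid's rest
    frame.
    """
    frames = np.asarray(frames, dtype=float)
    t = np.asarray(snapshot_times_ps, dtype=float)
    if atom_indices is not None:
        frames = frames[:, np.asarray(atom_indices, dtype=np.intp), :]
    if remove_drift:
        frames = frames - frames.mean(axis=1, keepdims=True)
    n_frames = frames.shape[0]
    if n_frames < 4:
        raise InsufficientDataError("need at least 4 snapshots for an MSD fit")
    dt = t[1] - t[0]
    total = t[-1] - t[0]
    if fit_window is None:
        fit_window = (0.1 * total, 0.5 * total)
    lags = np.arange(1, n_frames)
    lag_times = lags * dt
    sel = (lag_times >= fit_window[0]) & (lag_times <= fit_window[1])
    if sel.sum() < 3:
        raise InsufficientDataError("fit window shorter than 3 MSD points")
    lags = lags[sel]
    lag_times = lag_times[sel]

    n_atoms = frames.shape[1]
    msd_per_atom = np.empty((lags.size, n_atoms))
    for k, lag in enumerate(lags):
        disp = frames[lag:] - frames[:-lag]
        msd_per_atom[k] = (disp**2).sum(axis=2).mean(axis=0)
    # per-atom least-squares slope through the origin-free linear fit
    A = np.vstack([lag_times, np.ones_like(lag_times)]).T
    coef, *_ = np.linalg.lstsq(A, msd_per_atom, rcond=None)
    d_per_atom = coef[0] / 6.0 * ANG2_PER_PS_IN_1E5_CM2_PER_S
    value = float(d_per_atom.mean())
    se = float(d_per_atom.std(ddof=1) / math.sqrt(n_atoms)) if n_atoms > 1 else 0.0
    return EstimateWithError(value, se, method="msd-multi-origin")


def msd_curve(frames: np.ndarray, snapshot_times_ps: np.ndarray):
    """Full MSD(t) curve over all lags (diagnostic for non-diffusive
    regimes)."""
    frames = np.asarray(frames, dtype=float)
    t = np.asarray(snapshot_times_ps, dtype=float)
    n_frames = frames.shape[0]
    lags = np.arange(1, n_frames)
    msd = np.empty(lags.size)
    for k, lag in enumerate(lags):
        disp = frames[lag:] - frames[:-lag]
        msd[k] = (disp**2).sum(axis=2).mean()
    return lags * (t[1] - t[0]), msd


# ----------------------------------------------------------------------
# free energy profiles
# ----------------------------------------------------------------------
def free_energy_profile(
    angle_series: np.ndarray,
    n_bins: int = 72,
    temperature: float = 300.0,
    angle_range: tuple[float, float] = (-np.pi, np.pi),
    barrier_range: tuple[float, float] | None = None,
):
    """F(theta) = -kT ln rho(theta) from a histogram, shifted so the
    occupied minimum is zero, plus the barrier (max - min of F) over
    ``barrier_range``.

    Empty bins are masked (NaN) with a warning flag; the barrier is
    computed on occupied bins only.  Returns (bin_centers, F, barrier).
    """
    series = np.asarray(angle_series, dtype=float)
    if series.size < 10 * n_bins:
        raise InsufficientDataError(
            f"need at least {10 * n_bins} samples for {n_bins} bins"
        )
    hist, edges = np.histogram(series, bins=n_bins, range=angle_range, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    kT = BOLTZMANN_KCAL_MOL_K * temperature
    with np.errstate(divide="ignore"):
        F = -kT * np.log(hist)
    F[~np.isfinite(F)] = np.nan
    F = F - np.nanmin(F)
    if barrier_range is None:
        barrier_range = angle_range
    sel = (centers >= barrier_range[0]) & (centers <= barrier_range[1])
    occupied = sel & np.isfinite(F)
    if not occupied.any():
        raise InsufficientDataError("no occupied bins in the barrier range")
    barrier = float(np.nanmax(F[occupied]) - np.nanmin(F[occupied]))
    return centers, F, barrier


# ----------------------------------------------------------------------
# autocorrelation decay
# ----------------------------------------------------------------------
@dataclass
class AcfFit:
    tau: float
    amplitude: float
    converged: bool
    lags: np.ndarray = field(repr=False, default=None)
    acf: np.ndarray = field(repr=False, default=None)

    def ratio_to(self, tau_reference: float) -> float:
        """Normalised decay rate tau_ref / tau (1 = matches reference)."""
        return tau_reference / self.tau


def autocorrelation_decay(series: np.ndarray, dt: float, max_lag: int) -> AcfFit:
    """Empirical autocorrelation up to ``max_lag`` and an unweighted
    least-squares fit to a * exp(-t / tau) on lags up to the first zero
    crossing.  A non-decaying fit is returned flagged unconverged."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    n = x.size
    if n <= max_lag:
        raise InsufficientDataError("series shorter than max_lag")
    var = np.dot(x, x) / n
    if var == 0:
        raise InsufficientDataError("constant series has no autocorrelation")
    acf = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        acf[lag] = np.dot(x[: n - lag], x[lag:]) / (n * var)
    crossings = np.flatnonzero(acf < 0)
    cut = int(crossings[0]) if crossings.size else max_lag + 1
    cut = max(cut, 3)
    lags = np.arange(cut) * dt
    y = acf[:cut]
    try:
        popt, _ = scipy.optimize.curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau),
            lags,
            y,
            p0=(1.0, max(lags[-1] / 2.0, dt)),
            maxfev=5000,
        )
        a, tau = popt
        ok = np.isfinite(tau) and tau > 0
    except RuntimeError:
        a, tau, ok = np.nan, np.nan, False
    return AcfFit(
        tau=float(tau), amplitude=float(a), converged=bool(ok),
        lags=np.arange(max_lag + 1) * dt, acf=acf,
    )


# ----------------------------------------------------------------------
# invariant-measure bias harness
# ----------------------------------------------------------------------
def exact_circle_average(
    potential, beta: float, observable, n_points: int = 10000
) -> float:
    """Quadrature (trapezoid) average of ``observable(theta)`` under the
    Gibbs density ~ exp(-beta U(theta)) on the circle."""
    theta = np.linspace(-np.pi, np.pi, n_points + 1)
    w = np.exp(-beta * potential.energy(theta))
    f = observable(theta)
    num = np.trapezoid(w * f, theta)
    den = np.trapezoid(w, theta)
    return float(num / den)


@dataclass
class BiasLadderRow:
    dt: float
    bias: float
    standard_error: float
    stable: bool


def _fit_order(rows):
    good = [r for r in rows if r.stable and abs(r.bias) > 0]
    if len(good) >= 2:
        x = np.log([r.dt for r in good])
        y = np.log([abs(r.bias) for r in good])
        return float(np.polyfit(x, y, 1)[0])
    return np.nan


def bias_ladder(
    build_system,
    scheme_code: str,
    stepsizes,
    observable,
    exact_value,
    n_steps: int,
    gamma: float = 1.0,
    n_inner: int = 1,
    n_equil: int | None = None,
    seed: int = 0,
):
    """Measure the invariant-measure bias of a scheme over a stepsize
    ladder.

    ``build_system(seed)`` must return a :class:`SystemSpec`;
    ``observable(state) -> array`` returns per-replica samples (or a
    mapping of named observables, with ``exact_value`` a matching
    mapping -- all observables are measured from the same trajectories).
    Each stepsize is run for ``n_steps`` (after ``n_equil`` discarded
    steps, default n_steps // 5); the bias is the deviation of the
    long-run sample average from the exact (quadrature) value, with a
    block-averaged SE.  Unstable runs are flagged, never silently
    dropped.

    Returns (rows, fitted_order): the log-log slope of |bias| vs dt over
    the stable rows.  For a mapping of observables both returns are
    mappings keyed the same way.
    """
    single = callable(observable)
    obs_map = {"obs": observable} if single else dict(observable)
    exact_map = {"obs": exact_value} if single else dict(exact_value)
    if n_equil is None:
        n_equil = n_steps // 5
    rows = {name: [] for name in obs_map}
    for i, dt in enumerate(stepsizes):
        spec = build_system(seed + 1000 * i)
        thermo = ThermostatParams(gamma=gamma, temperature=spec.temperature)
        scheme = SplittingScheme(code=scheme_code, dt=float(dt), n_inner=n_inner)
        observers = {
            name: (lambda s, f=f: float(f(s).mean())) for name, f in obs_map.items()
        }
        record = run_trajectory(
            spec.state,
            scheme,
            spec.forcefield,
            thermo,
            n_steps + n_equil,
            rng=RandomStream(seed + 17 * i + 1),
            constraints=spec.constraints,
            observers=observers,
            energy_stride=0,
        )
        for name in obs_map:
            if record.unstable:
                rows[name].append(BiasLadderRow(float(dt), np.nan, np.nan, False))
                continue
            series = record.observable_array(name)[1 + n_equil :]
            est = block_average(series, n_blocks=10)
            rows[name].append(
                BiasLadderRow(
                    float(dt), est.value - exact_map[name], est.standard_error, True
                )
            )
    orders = {name: _fit_order(r) for name, r in rows.items()}
    if single:
        return rows["obs"], orders["obs"]
    return rows, orders


def harmonic_stability_limit_fs(wavenumber_cm: float) -> float:
    """Stepsize stability bound 2/omega of a harmonic mode given its
    spectroscopic wavenumber (cm^-1), in femtoseconds."""
    omega = 2.0 * np.pi * _SPEED_OF_LIGHT_CM_S * wavenumber_cm  # rad/s
    return 2.0 / omega * 1.0e15
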