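"""Hot inner loops, JIT-compiled with numba when available.

The numpy implementations in :mod:`geomd.forcefield` and
:mod:`geomd.constraints` remain the reference semantics; these kernels
compute the same quantities (pairwise LJ+Coulomb accumulation, the
sequential Gauss-Seidel SHAKE sweep) in compiled loops.  When numba is
not importable the callers fall back to the vectorised numpy paths.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def pair_energy_forces(q, use_box, box, pi, pj, ri, rj, sig2, eps, kqq, rc, F):
    """LJ + Coulomb with shifted potential over an explicit pair list.

    Inclusion is gated on the minimum-image distance between the pair's
    *group reference sites* (ri, rj), and the same periodic image shift
    is applied to the site-site displacement, so neutral charge groups
    (e.g. whole water molecules) enter or leave the cutoff atomically.
    For free atoms the reference site is the atom itself and this reduces
    to the plain atom-based cutoff.

    Accumulates forces into F (must be zeroed by the caller).  Returns
    (U, status) with status 1 when two sites overlap (r < 1e-6 A).
    """
    U = 0.0
    rc2 = rc * rc
    inv_rc = 1.0 / rc
    ndim = q.shape[1]
    d = np.empty(ndim)
    shift = np.empty(ndim)
    for m in range(pi.shape[0]):
        i = pi[m]
        j = pj[m]
        gr2 = 0.0
        for k in range(ndim):
            dd = q[ri[m], k] - q[rj[m], k]
            s = 0.0
            if use_box:
                s = -box[k] * np.rint(dd / box[k])
                dd += s
            shift[k] = s
            gr2 += dd * dd
        if gr2 >= rc2:
            continue
        r2 = 0.0
        for k in range(ndim):
            dd = q[i, k] - q[j, k] + shift[k]
            d[k] = dd
            r2 += dd * dd
        if r2 < 1e-12:
            return U, 1
        fmag = 0.0
        if eps[m] > 0.0:
            s2 = sig2[m] / r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            sc6 = (sig2[m] / rc2) ** 3
            U += 4.0 * eps[m] * (s12 - s6 - (sc6 * sc6 - sc6))
            fmag += 24.0 * eps[m] * (2.0 * s12 - s6) / r2
        if kqq[m] != 0.0:
            r = np.sqrt(r2)
            U += kqq[m] * (1.0 / r - inv_rc)
            fmag += kqq[m] / (r2 * r)
        for k in range(ndim):
            fk = fmag * d[k]
            F[i, k] += fk
            F[j, k] -= fk
    return U, 0


@njit(cache=False)
def shake_sweeps(q, ai, aj, r0sq, dref, refscale, invm, tol, max_iter, res0):
    """Gauss-Seidel SHAKE: sequential single-Newton steps per constraint.

    Modifies q in place.  Returns (lam, sweeps, status) with status
    0 = converged, 1 = max_iter exceeded, 2 = insoluble projection
    (correction direction orthogonal to the current gradient),
    3 = diverged.
    """
    m = ai.shape[0]
    ndim = q.shape[1]
    lam = np.zeros(m)
    for sweep in range(1, max_iter + 1):
        for a in range(m):
            i = ai[a]
            j = aj[a]
            g = -r0sq[a]
            dot = 0.0
            for k in range(ndim):
                dd = q[i, k] - q[j, k]
                g += dd * dd
                dot += dd * dref[a, k]
            w = invm[i] + invm[j]
            denom = 4.0 * dot * w
            if abs(denom) <= 1e-8 * refscale[a] * w:
                return lam, sweep, 2
            dl = g / denom
            lam[a] += dl
            for k in range(ndim):
                s = 2.0 * dl * dref[a, k]
                q[i, k] -= invm[i] * s
                q[j, k] += invm[j] * s
        maxres = 0.0
        for a in range(m):
            i = ai[a]
            j = aj[a]
            g = -r0sq[a]
            for k in range(ndim):
                dd = q[i, k] - q[j, k]
                g += dd * dd
            ag = abs(g)
            if ag > maxres:
                maxres = ag
        if not np.isfinite(maxres) or maxres > 1e3 * (res0 + 1.0):
            return lam, sweep, 3
        if maxres <= tol:
            return lam, sweep, 0
    return lam, max_iter, 1
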