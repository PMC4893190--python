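"""Invariant-measure bias of g-BAOAB vs g-OBABO on an exactly solvable
system.

A particle on a circle with U = A cos(theta) has Gibbs averages
computable by quadrature, so the sampling bias of a scheme -- the
deviation of its long-run trajectory average from the exact value -- can
be measured directly, as a function of stepsize.

Two observables are tracked from the same trajectories: the
configurational <cos theta> and the momentum variance <p^2> (exact
value kT).  The two schemes are near-perfect mirror images: g-OBABO's
configurational bias decays at second order with a large prefactor
while its momentum marginal is essentially exact; g-BAOAB's momentum
bias decays at second order while its configurational bias is many
times smaller than g-OBABO's at every stepsize -- the property that
makes it the scheme of choice for sampling positions.
"""

import numpy as np

from geomd import build_circle_system, circle_angles
from geomd.analysis import bias_ladder, exact_circle_average

AMPLITUDE = 4.0
ff = build_circle_system(potential_name="cosine", amplitude=AMPLITUDE).forcefield
exact = {
    "cos": exact_circle_average(ff, beta=1.0, observable=np.cos),
    "p2": 1.0,  # kT per cotangent degree of freedom
}
observables = {
    "cos": lambda st: np.cos(circle_angles(st)),
    "p2": lambda st: (st.p[1::2] ** 2).sum(axis=1),
}
print(f"quadrature <cos theta> = {exact['cos']:.6f},  exact <p^2> = 1")

for code, n_inner in (("gBAOAB", 1), ("gOBABO", 2)):
    rows, orders = bias_ladder(
        lambda s: build_circle_system(
            potential_name="cosine", amplitude=AMPLITUDE, n_replicas=256, seed=s
        ),
        code, [0.14, 0.20, 0.28], observables, exact,
        n_steps=20000, gamma=1.0, n_inner=n_inner, seed=0,
    )
    for name in ("cos", "p2"):
        for r in rows[name]:
            print(f"{code}  {name:3s} dt={r.dt:.2f}  "
                  f"bias={r.bias:+.2e} +- {r.standard_error:.1e}")
        print(f"{code}  {name:3s} fitted order = {orders[name]:+.2f}")
print("A fitted order near 2 marks the observable where the scheme's")
print("leading bias term survives; the tiny biases elsewhere are the")
print("cancellations each scheme is prized for.")
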