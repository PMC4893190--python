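"""Sampling a rigid dimer in a harmonic trap with g-BAOAB.

Builds the smallest constrained system there is -- two atoms with a
frozen bond inside an isotropic harmonic well -- runs constrained
Langevin dynamics, and prints the kinetic temperature and the worst
constraint residual.  The temperature should fluctuate around the
thermostat target (with 6 - 1 = 5 free degrees of freedom) and the
residual should stay at the SHAKE tolerance, ~1e-8 A^2.
"""

import numpy as np

from geomd import (
    ConstraintSet,
    RandomStream,
    SplittingScheme,
    SystemState,
    ThermostatParams,
    HarmonicWell,
    instantaneous_temperature,
    project_cotangent,
    run_trajectory,
)

q = np.array([[0.0, 0.0, 0.0], [1.1, 0.0, 0.0]])
masses = np.array([12.0, 1.0])
cset = ConstraintSet([(0, 1, 1.1)])

rng = np.random.default_rng(0)
p = project_cotangent(rng.normal(size=(2, 3)), q, masses, cset)
state = SystemState(q=q, p=p, masses=masses)

scheme = SplittingScheme.from_fs("gBAOAB", 1.0)  # 1 fs steps
thermo = ThermostatParams.from_ps(1.0, 300.0)  # gamma = 1/ps, 300 K

record = run_trajectory(
    state, scheme, HarmonicWell(k=2.0), thermo, 100_000,
    rng=RandomStream(1), constraints=cset,
)

temps = 2.0 * record.kinetic_array / (5 * 1.987204259e-3)
print(f"mean kinetic temperature : {temps[5000:].mean():7.1f} K  (target 300 K)")
print(f"worst |g| residual       : {record.max_residual_g:.2e} A^2")
print("The mean sits near 300 K (a few kelvin of statistical scatter is")
print("expected at this run length) -- equipartition on the constrained")
print("ensemble; the residual shows the bond length never drifts.")
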