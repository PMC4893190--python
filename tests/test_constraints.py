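"""Projector algebra, SHAKE/RATTLE projections, and the elementary
constrained flows, checked against independent linear-algebra and
closed-form oracles."""

import numpy as np
import pytest

from geomd.core import SystemState, ThermostatParams, RandomStream
from geomd.constraints import (
    ConstraintFailureError,
    ConstraintSet,
    DegenerateConstraintError,
    constrained_ou_step,
    cotangent_projector,
    geodesic_flow_step,
    project_cotangent,
    projected_kick,
    projector_exponential,
    rattle_momentum_project,
    shake_position_project,
)


def random_full_rank_G(rng, m, n):
    while True:
        G = rng.normal(size=(m, n))
        if np.linalg.matrix_rank(G) == m:
            return G


def projector_oracle(G, masses):
    """Pi via an explicit pseudo-inverse (independent of the solve path):
    Pi = I - G^T pinv(G M^-1 G^T) G M^-1."""
    invm = 1.0 / masses
    S = (G * invm) @ G.T
    return np.eye(G.shape[1]) - G.T @ np.linalg.pinv(S) @ (G * invm)


def series_expm(A, terms=30):
    out = np.eye(A.shape[0])
    term = np.eye(A.shape[0])
    for k in range(1, terms):
        term = term @ A / k
        out = out + term
    return out


class TestCotangentProjector:
    def test_no_constraints_is_identity(self):
        assert np.array_equal(
            cotangent_projector(np.zeros((0, 6)), np.ones(6)), np.eye(6)
        )

    def test_single_axis_constraint_unit_masses(self):
        # G = e1^T with equal unit masses: Pi = I - e1 e1^T
        G = np.zeros((1, 4))
        G[0, 0] = 1.0
        Pi = cotangent_projector(G, np.ones(4))
        expected = np.eye(4)
        expected[0, 0] = 0.0
        assert np.allclose(Pi, expected, atol=1e-14)

    @pytest.mark.parametrize("m,n", [(1, 4), (3, 9), (5, 12)])
    def test_agrees_with_pseudo_inverse_oracle(self, m, n):
        rng = np.random.default_rng(m * 100 + n)
        for _ in range(5):
            G = random_full_rank_G(rng, m, n)
            masses = rng.uniform(0.5, 20.0, n)
            Pi = cotangent_projector(G, masses)
            assert np.abs(Pi - projector_oracle(G, masses)).max() < 1e-10

    def test_projector_identities_over_random_jacobians(self):
        """Pi^2 = Pi and G M^-1 Pi = 0 for 100 random constraint Jacobians."""
        rng = np.random.default_rng(2024)
        for trial in range(100):
            m = rng.integers(1, 5)
            n = int(rng.integers(m + 1, 12))
            G = random_full_rank_G(rng, int(m), n)
            masses = rng.uniform(0.5, 20.0, n)
            Pi = cotangent_projector(G, masses)
            assert np.abs(Pi @ Pi - Pi).max() < 1e-10
            assert np.abs((G / masses) @ Pi).max() < 1e-10

    def test_symmetric_in_inverse_mass_inner_product(self):
        rng = np.random.default_rng(5)
        G = random_full_rank_G(rng, 3, 9)
        masses = rng.uniform(0.5, 20.0, 9)
        Pi = cotangent_projector(G, masses)
        Minv = np.diag(1.0 / masses)
        assert np.abs(Minv @ Pi - Pi.T @ Minv).max() < 1e-10

    def test_rank_deficient_raises(self):
        G = np.ones((2, 5))  # duplicated row
        with pytest.raises(DegenerateConstraintError):
            cotangent_projector(G, np.ones(5))


class TestProjectorExponential:
    def test_alpha_zero_is_identity(self):
        Pi = np.eye(3)
        assert np.allclose(projector_exponential(0.0, Pi), np.eye(3), atol=1e-15)

    def test_full_rank_projector_scales(self):
        assert np.allclose(
            projector_exponential(0.7, np.eye(4)), np.exp(0.7) * np.eye(4), rtol=1e-14
        )

    def test_matches_series_oracle(self):
        rng = np.random.default_rng(11)
        G = random_full_rank_G(rng, 2, 7)
        Pi = cotangent_projector(G, rng.uniform(0.5, 5.0, 7))
        alpha = -0.3
        assert np.abs(projector_exponential(alpha, Pi) - series_expm(alpha * Pi)).max() < 1e-12

    def test_semigroup_property(self):
        rng = np.random.default_rng(12)
        G = random_full_rank_G(rng, 3, 8)
        Pi = cotangent_projector(G, rng.uniform(0.5, 5.0, 8))
        a1, a2 = 0.4, -1.1
        lhs = projector_exponential(a1 + a2, Pi)
        rhs = projector_exponential(a1, Pi) @ projector_exponential(a2, Pi)
        assert np.abs(lhs - rhs).max() < 1e-10


class TestRattleMomentumProjection:
    def test_fixed_point(self):
        rng = np.random.default_rng(3)
        G = random_full_rank_G(rng, 2, 6)
        masses = rng.uniform(0.5, 5.0, 6)
        Pi = cotangent_projector(G, masses)
        p = Pi @ rng.normal(size=6)  # already cotangent
        res = rattle_momentum_project(p, G, masses)
        assert np.abs(res.projected - p).max() < 1e-12

    def test_two_body_bond_closed_form(self):
        # equal masses, bond along x, p = (+a, -a) along the bond:
        # the bond-axis relative momentum is removed, transverse kept.
        q = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        cset = ConstraintSet([(0, 1, 1.0)])
        G = cset.jacobian(q)
        masses_dof = np.ones(6)
        a = 0.7
        p = np.array([a, 0.3, 0.0, -a, 0.5, 0.0])
        res = rattle_momentum_project(p, G, masses_dof)
        # hand solution: G row = (-2,0,0,+2,0,0), so G M^-1 p = -4a,
        # G M^-1 G^T = 8, mu = -a/2, p' = p - G^T mu
        expected = p.copy()
        expected[0] = 0.0
        expected[3] = 0.0
        assert np.allclose(res.projected, expected, atol=1e-12)
        assert res.multipliers[0] == pytest.approx(-a / 2.0, abs=1e-12)

    def test_matches_dense_projector_and_idempotent(self):
        rng = np.random.default_rng(9)
        G = random_full_rank_G(rng, 3, 9)
        masses = rng.uniform(0.5, 5.0, 9)
        p = rng.normal(size=9)
        Pi = cotangent_projector(G, masses)
        res = rattle_momentum_project(p, G, masses)
        assert np.abs(res.projected - Pi @ p).max() < 1e-10
        twice = rattle_momentum_project(res.projected, G, masses)
        assert np.abs(twice.projected - res.projected).max() < 1e-12


class TestClusteredProjection:
    """The production (per-cluster batched solve) path must agree with
    the dense projector."""

    @pytest.mark.parametrize("topology", ["waters", "chain", "mixed"])
    def test_matches_dense_path(self, topology):
        rng = np.random.default_rng(hash(topology) % 2**31)
        if topology == "waters":
            pairs = []
            for mol in range(5):
                o, h1, h2 = 3 * mol, 3 * mol + 1, 3 * mol + 2
                pairs += [(o, h1, 1.0), (o, h2, 1.0), (h1, h2, 1.5)]
            n = 15
        elif topology == "chain":
            pairs = [(i, i + 1, 1.2) for i in range(7)]
            n = 8
        else:
            pairs = [(0, 1, 1.0), (2, 3, 1.1), (2, 4, 0.9), (5, 6, 1.3), (6, 7, 1.0), (7, 5, 1.2)]
            n = 8
        cset = ConstraintSet(pairs)
        q = rng.normal(size=(n, 3)) * 2.0
        masses = rng.uniform(0.5, 16.0, n)
        v = rng.normal(size=(n, 3))
        out = project_cotangent(v, q, masses, cset)
        G = cset.jacobian(q)
        Pi = cotangent_projector(G, np.repeat(masses, 3))
        assert np.abs(out.ravel() - Pi @ v.ravel()).max() < 1e-10


class TestShake:
    def two_body(self, stretch):
        q_ref = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        q_unc = np.array([[0.0, 0, 0], [stretch, 0, 0]])
        return q_ref, q_unc, ConstraintSet([(0, 1, 1.0)])

    def test_already_on_manifold_returns_input(self):
        q_ref, _, cset = self.two_body(1.0)
        res = shake_position_project(q_ref.copy(), q_ref, cset, np.ones(2))
        assert res.iterations <= 1
        assert np.abs(res.projected - q_ref).max() < 1e-12
        assert np.abs(res.multipliers).max() < 1e-12

    @pytest.mark.parametrize("stretch", [1.05, 1.2, 0.85])
    def test_two_body_matches_scalar_quadratic_oracle(self, stretch):
        """1D bond stretched by s: the single multiplier solves a scalar
        quadratic |s - 4*lam*dref|^2 = 1 (equal unit masses)."""
        q_ref, q_unc, cset = self.two_body(stretch)
        res = shake_position_project(q_unc, q_ref, cset, np.ones(2), tol=1e-12)
        assert res.converged
        # oracle: with corrections q1 += 2 lam dref, q0 -= ... net bond
        # change 4 lam dref along x; solve (s - 4 lam)^2 = 1, root near s
        lam_oracle = np.roots([16.0, -8.0 * stretch, stretch**2 - 1.0])
        lam_oracle = lam_oracle[np.argmin(np.abs(lam_oracle))]
        assert res.multipliers[0] == pytest.approx(lam_oracle, abs=1e-6)
        d = res.projected[1] - res.projected[0]
        assert np.dot(d, d) == pytest.approx(1.0, abs=1e-10)

    def test_infeasible_projection_raises(self):
        """Proposal displaced perpendicular past the fold: correcting
        along the reference gradient can never restore the bond."""
        q_ref = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        # displace particle 1 sideways: bond vector now orthogonal to the
        # reference gradient, the Newton denominator vanishes
        q_unc = np.array([[0.0, 0.0, 0.0], [0.0, 2.5, 0.0]])
        cset = ConstraintSet([(0, 1, 1.0)])
        with pytest.raises(ConstraintFailureError):
            shake_position_project(q_unc, q_ref, cset, np.ones(2))

    def test_water_cluster_converges_to_tolerance(self):
        rng = np.random.default_rng(21)
        from geomd.systems import build_water_box

        spec = build_water_box(8, 8.0, seed=3)
        q_ref = spec.state.q
        q_unc = q_ref + 0.05 * rng.normal(size=q_ref.shape)
        res = shake_position_project(q_unc, q_ref, spec.constraints, spec.state.masses)
        assert res.converged
        assert spec.constraints.max_residual(res.projected) <= 1e-8

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError):
            ConstraintSet([(0, 1, 1.0), (1, 0, 1.2)])


def circle_state(radius=2.0, speed=1.5, mass=1.0):
    """Anchor (pinned) + particle on a circle, tangential momentum."""
    q = np.array([[0.0, 0.0], [radius, 0.0]])
    p = np.array([[0.0, 0.0], [0.0, mass * speed]])
    masses = np.array([np.inf, mass])
    state = SystemState(q=q, p=p, masses=masses)
    return state, ConstraintSet([(0, 1, radius)])


class TestGeodesicFlow:
    def test_zero_momentum_is_identity(self):
        state, cset = circle_state(speed=0.0)
        out = geodesic_flow_step(state, 0.3, cset, n_inner=4)
        assert np.array_equal(out.q, state.q)
        assert np.abs(out.p).max() == 0.0

    def test_circle_rotation_oracle(self):
        """The exact geodesic on a circle is rotation by v h / R."""
        R, v, h = 2.0, 1.5, 0.5
        state, cset = circle_state(radius=R, speed=v)
        out = geodesic_flow_step(state, h, cset, n_inner=64)
        phi = v * h / R
        exact = np.array([R * np.cos(phi), R * np.sin(phi)])
        err = np.linalg.norm(out.q[1] - exact)
        assert err < 5.0 * (h / 64) ** 2

    def test_second_order_convergence_ladder(self):
        """Doubling n_inner cuts the endpoint error ~4x over >= 4 levels."""
        R, v, h = 2.0, 1.5, 0.8
        phi = v * h / R
        exact = np.array([R * np.cos(phi), R * np.sin(phi)])
        errors = []
        for n_inner in [4, 8, 16, 32, 64]:
            state, cset = circle_state(radius=R, speed=v)
            out = geodesic_flow_step(state, h, cset, n_inner=n_inner)
            errors.append(np.linalg.norm(out.q[1] - exact))
        rates = np.log2(np.array(errors[:-1]) / np.array(errors[1:]))
        assert np.all(rates > 1.7), f"observed rates {rates}"

    def test_kinetic_energy_conserved_on_circle(self):
        from geomd.core import kinetic_energy

        state, cset = circle_state(radius=2.0, speed=1.5)
        ke0 = kinetic_energy(state)
        out = geodesic_flow_step(state, 0.5, cset, n_inner=32)
        assert kinetic_energy(out) == pytest.approx(ke0, rel=1e-6)


class TestProjectedKick:
    def test_zero_force_identity(self):
        state, cset = circle_state()
        out = projected_kick(state, 0.1, np.zeros_like(state.p), cset)
        assert np.array_equal(out.p, state.p)
        assert out.q is state.q  # positions shared, untouched

    def test_force_along_constraint_gradient_annihilated(self):
        # central force along the bond of a 2-body dimer leaves p alone
        q = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        p = np.zeros((2, 3))
        state = SystemState(q=q, p=p, masses=np.ones(2))
        cset = ConstraintSet([(0, 1, 1.0)])
        F = np.array([[-3.0, 0, 0], [3.0, 0, 0]])  # pulls atoms apart
        out = projected_kick(state, 0.2, F, cset)
        assert np.abs(out.p).max() < 1e-12

    def test_no_constraints_is_plain_kick(self):
        state = SystemState(q=np.zeros((2, 3)), p=np.zeros((2, 3)), masses=np.ones(2))
        F = np.arange(6.0).reshape(2, 3)
        out = projected_kick(state, 0.5, F, None)
        assert np.allclose(out.p, 0.5 * F)


class TestConstrainedOU:
    def test_gamma_zero_identity_consumes_no_randoms(self):
        state, cset = circle_state()
        rng = RandomStream(1)
        thermo = ThermostatParams(gamma=0.0, temperature=300.0)
        out = constrained_ou_step(state, 0.7, thermo, rng, cset)
        assert np.array_equal(out.p, state.p)
        # stream untouched: next draw equals a fresh stream's first draw
        assert np.array_equal(rng.normal((4,)), RandomStream(1).normal((4,)))

    def test_unconstrained_moments(self):
        """Mean e^{-gamma h} p0 and variance kT m (1 - e^{-2 gamma h})
        over 1e5 independent applications (replicated atoms)."""
        n = 100_000
        m, kT, gamma, h = 2.0, 0.8, 1.3, 0.45
        p0 = 1.7
        state = SystemState(
            q=np.zeros((n, 1)), p=np.full((n, 1), p0), masses=np.full(n, m)
        )
        thermo = ThermostatParams(gamma=gamma, temperature=kT / 1.987204259e-3)
        out = constrained_ou_step(state, h, thermo, RandomStream(4), None)
        c = np.exp(-gamma * h)
        var = kT * m * (1 - c * c)
        se_mean = np.sqrt(var / n)
        assert abs(out.p.mean() - c * p0) < 4 * se_mean
        se_var = var * np.sqrt(2.0 / n)
        assert abs(out.p.var() - var) < 4 * se_var

    def test_stationary_covariance_matches_projected_oracle(self):
        """gamma h >> 1: empirical covariance -> kT Pi M Pi^T for a
        2-body bond, via 1e5 replicated dimers."""
        n_rep = 100_000
        kT = 0.9
        masses_pair = np.array([1.0, 3.0])
        q_pair = np.array([[0.0, 0.0], [1.0, 0.0]])
        q = np.tile(q_pair, (n_rep, 1))
        masses = np.tile(masses_pair, n_rep)
        state = SystemState(q=q, p=np.zeros_like(q), masses=masses)
        cset = ConstraintSet([(2 * r, 2 * r + 1, 1.0) for r in range(n_rep)])
        thermo = ThermostatParams(gamma=50.0, temperature=kT / 1.987204259e-3)
        out = constrained_ou_step(state, 1.0, thermo, RandomStream(8), cset)
        samples = out.p.reshape(n_rep, 4)
        cov = np.cov(samples.T)
        G = ConstraintSet([(0, 1, 1.0)]).jacobian(q_pair)
        Pi = cotangent_projector(G, np.repeat(masses_pair, 2))
        M = np.diag(np.repeat(masses_pair, 2))
        target = kT * Pi @ M @ Pi.T
        scale = np.abs(target).max()
        assert np.abs(cov - target).max() < 5 * scale * np.sqrt(2.0 / n_rep) + 0.01 * scale


class TestManifoldPreservationInvariant:
    def test_flows_keep_residuals_below_tolerance(self):
        from geomd.systems import build_water_box

        spec = build_water_box(8, 8.0, seed=5)
        state = spec.state
        cset = spec.constraints
        thermo = ThermostatParams.from_ps(1.0, 300.0)
        rng = RandomStream(2)
        for op in range(20):
            state = geodesic_flow_step(state, 0.02, cset, n_inner=1)
            F = np.zeros_like(state.q)
            state = projected_kick(state, 0.02, F, cset)
            state = constrained_ou_step(state, 0.02, thermo, rng, cset)
            assert cset.max_residual(state.q) <= 1e-8
            assert cset.cotangency_residual(state) <= 1e-8


# ---------------------------------------------------------------------
# property-based checks (hypothesis, derandomised)
# ---------------------------------------------------------------------
from hypothesis import given, settings, strategies as st


@st.composite
def jacobian_and_masses(draw):
    m = draw(st.integers(min_value=1, max_value=4))
    n = draw(st.integers(min_value=m + 2, max_value=12))
    seed = draw(st.integers(min_value=0, max_value=2**16))
    rng = np.random.default_rng(seed)
    G = rng.normal(size=(m, n))
    # reject near-degenerate draws; the API contract requires full rank
    sv = np.linalg.svd(G, compute_uv=False)
    if sv[-1] < 1e-3:
        G = G + np.eye(m, n)
    masses = rng.uniform(0.5, 20.0, n)
    return G, masses


class TestProjectorProperties:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(jacobian_and_masses())
    def test_projector_is_idempotent_and_annihilates_gradients(self, gm):
        G, masses = gm
        Pi = cotangent_projector(G, masses)
        assert np.abs(Pi @ Pi - Pi).max() < 1e-9
        assert np.abs((G / masses) @ Pi).max() < 1e-9

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(jacobian_and_masses(), st.floats(-2.0, 2.0), st.floats(-2.0, 2.0))
    def test_projector_exponential_semigroup(self, gm, a1, a2):
        G, masses = gm
        Pi = cotangent_projector(G, masses)
        lhs = projector_exponential(a1 + a2, Pi)
        rhs = projector_exponential(a1, Pi) @ projector_exponential(a2, Pi)
        assert np.abs(lhs - rhs).max() < 1e-9

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(jacobian_and_masses())
    def test_momentum_projection_is_idempotent(self, gm):
        G, masses = gm
        rng = np.random.default_rng(1)
        p = rng.normal(size=G.shape[1])
        once = rattle_momentum_project(p, G, masses).projected
        twice = rattle_momentum_project(once, G, masses).projected
        assert np.abs(twice - once).max() < 1e-9
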