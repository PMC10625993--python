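import numpy as np
import pytest

from tcflow.mesh import generate_channel_mesh_2d
from tcflow.stabilization import (MeshMotion, StabilizationSettings,
                                  l2_norm_field, nu_c, omega_ale,
                                  omega_global, tau_supg_conventional,
                                  tau_supg_present)


def _random_spd(rng, d=2, scale=10.0):
    B = rng.normal(size=(d, d)) * scale
    return B.T @ B + 0.1 * np.eye(d)


class TestTau:
    def test_transient_term_only(self):
        assert tau_supg_conventional(2.0, np.zeros(2), np.eye(2), 0.0) == 1.0
        assert tau_supg_conventional(0.2, np.zeros(2), np.eye(2), 0.0) \
            == pytest.approx(0.1)

    def test_worked_values(self):
        t = tau_supg_conventional(0.01, np.array([1.0, 0.0]),
                                  np.diag([100.0, 100.0]), 0.01, 3.0)
        # (40000 + 100 + 6)^(-1/2)
        assert t == pytest.approx(40106.0**-0.5, rel=1e-12)
        assert t == pytest.approx(4.9934e-3, rel=1e-4)
        tp = tau_supg_present(10.0, np.array([1.0, 0.0]),
                              np.diag([100.0, 100.0]), 0.01, 3.0)
        assert tp == pytest.approx(206.0**-0.5, rel=1e-12)

    def test_identity_with_omega_2_over_dt_bitwise(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            dt = 10.0 ** rng.uniform(-5, 0)
            u = rng.normal(size=2) * 10 ** rng.uniform(-2, 2)
            G = _random_spd(rng, 2, 10 ** rng.uniform(-1, 2))
            nu = 10.0 ** rng.uniform(-4, 0)
            a = tau_supg_conventional(dt, u, G, nu)
            b = tau_supg_present(2.0 / dt, u, G, nu)
            assert a == b  # bitwise

    def test_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            dt = 10.0 ** rng.uniform(-4, 0)
            u = rng.normal(size=2) * 5
            G = _random_spd(rng)
            nu = 10.0 ** rng.uniform(-4, -1)
            assert 0 < tau_supg_conventional(dt, u, G, nu) <= dt / 2
            om = 10.0 ** rng.uniform(-1, 3)
            assert tau_supg_present(om, u, G, nu) <= 1.0 / om

    def test_monotone_decreasing_in_each_term(self):
        u = np.array([1.0, 0.5])
        G = np.diag([50.0, 80.0])
        base = tau_supg_present(5.0, u, G, 0.05)
        assert tau_supg_present(10.0, u, G, 0.05) < base
        assert tau_supg_present(5.0, 2 * u, G, 0.05) < base
        assert tau_supg_present(5.0, u, G, 0.1) < base

    def test_homogeneity_in_omega(self):
        G = np.eye(2)
        t1 = tau_supg_present(3.0, np.zeros(2), G, 0.0)
        t2 = tau_supg_present(6.0, np.zeros(2), G, 0.0)
        assert t1 == pytest.approx(2 * t2, rel=1e-14)

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            tau_supg_present(0.0, np.zeros(2), np.eye(2), 0.0)

    def test_time_unit_scaling(self):
        """tau carries seconds: scaling u, omega and nu by k scales tau by
        1/k (pure change of time unit at fixed geometry)."""
        rng = np.random.default_rng(2)
        u, G, nu, om, k = rng.normal(size=2), _random_spd(rng), 0.03, 4.0, 7.0
        t1 = tau_supg_present(om, u, G, nu)
        t2 = tau_supg_present(k * om, k * u, G, k * nu)
        assert t2 == pytest.approx(t1 / k, rel=1e-13)


class TestNuC:
    def test_values(self):
        tau = 40106.0**-0.5
        assert nu_c(np.diag([100.0, 100.0]), tau) \
            == pytest.approx(1.0 / (200 * tau))
        assert nu_c(np.array([[1.0]]), 1.0) == 1.0

    def test_monotone_in_tau(self):
        G = np.diag([3.0, 4.0])
        v = [nu_c(G, t) for t in (1.0, 0.1, 0.01)]
        assert v[0] < v[1] < v[2]

    def test_invalid(self):
        with pytest.raises(ValueError):
            nu_c(np.diag([1.0, 1.0]), 0.0)


class TestOmega:
    settings = StabilizationSettings(dt=0.1)

    def test_proportional_fields_exact(self):
        mesh = generate_channel_mesh_2d(1, 1, 3, 3, perturb=0.2)
        rng = np.random.default_rng(0)
        u = rng.normal(size=(mesh.n_nodes, 2))
        assert omega_global(u, 3.5 * u, mesh, self.settings) \
            == pytest.approx(3.5, abs=1e-13)

    def test_steady_limit_zero(self):
        mesh = generate_channel_mesh_2d(1, 1, 2, 2)
        u = np.ones((mesh.n_nodes, 2))
        assert omega_global(u, np.zeros_like(u), mesh, self.settings) == 0.0

    def test_matches_p1_mass_matrix_oracle(self):
        """The Gauss-rule L2 norm equals the closed-form P1 mass-matrix
        value int N_a N_b = V (1 + delta_ab)/((d+1)(d+2))."""
        mesh = generate_channel_mesh_2d(1, 1, 1, 2)
        rng = np.random.default_rng(5)
        f = rng.normal(size=(mesh.n_nodes, 2))
        acc = 0.0
        from tcflow.mesh import element_volumes
        vol = element_volumes(mesh)
        for e, el in enumerate(mesh.elements):
            fe = f[el]
            acc += vol[e] / 12.0 * (np.sum(fe * fe) + np.sum(fe.sum(0)**2))
        assert l2_norm_field(f, mesh) == pytest.approx(np.sqrt(acc),
                                                       rel=1e-12)

    def test_refinement_invariant_for_p1_field(self):
        def field(mesh):
            x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
            return np.stack([1 + 2 * x - y, 0.5 * x + y], axis=1)

        m1 = generate_channel_mesh_2d(2, 1, 4, 2)
        m2 = generate_channel_mesh_2d(2, 1, 8, 4)
        s = StabilizationSettings(dt=0.1)
        o1 = omega_global(field(m1), 2 * field(m1), m1, s)
        o2 = omega_global(field(m2), 2 * field(m2), m2, s)
        assert o1 == pytest.approx(o2, abs=1e-12)

    def test_first_step_and_quiescent_guards(self):
        mesh = generate_channel_mesh_2d(1, 1, 2, 2)
        u = np.zeros((mesh.n_nodes, 2))
        s = StabilizationSettings(dt=0.05)
        assert omega_global(u, u, mesh, s, is_first_step=True) == 40.0
        assert omega_global(u, u, mesh, s) == 40.0  # ||u|| below epsilon_u


class TestOmegaALE:
    settings = StabilizationSettings(dt=0.1)

    def _mesh_fields(self):
        mesh = generate_channel_mesh_2d(1, 1, 3, 2, perturb=0.15)
        rng = np.random.default_rng(9)
        u = rng.normal(size=(mesh.n_nodes, 2))
        a = rng.normal(size=(mesh.n_nodes, 2))
        return mesh, u, a

    def test_zero_mesh_velocity_reduces_to_global(self):
        mesh, u, a = self._mesh_fields()
        mot = MeshMotion(np.zeros_like(u))
        assert omega_ale(u, a, mot, mesh, self.settings) \
            == omega_global(u, a, mesh, self.settings)

    def test_galilean_invariance(self):
        mesh, u, a = self._mesh_fields()
        uhat = np.tile([0.3, -0.2], (mesh.n_nodes, 1))
        c = np.array([5.0, -7.0])
        o1 = omega_ale(u, a, MeshMotion(uhat), mesh, self.settings)
        o2 = omega_ale(u + c, a, MeshMotion(uhat + c), mesh, self.settings)
        assert o1 == pytest.approx(o2, abs=1e-12)

    def test_zero_relative_velocity_guard(self):
        mesh, u, a = self._mesh_fields()
        assert omega_ale(u, a, MeshMotion(u.copy()), mesh, self.settings) \
            == 2.0 / self.settings.dt

    def test_shape_mismatch(self):
        mesh, u, a = self._mesh_fields()
        with pytest.raises(ValueError):
            omega_ale(u, a, MeshMotion(np.zeros((3, 2))), mesh, self.settings)
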