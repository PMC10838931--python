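"""Forward models: sphere fitting, the conducting-sphere closed form and
the corrected single-shell lead field."""

import numpy as np
import pytest

from opmlesion import (
    ConductorModel,
    LeadField,
    SourceSpace,
    fit_sphere,
    make_icosphere,
    normal_oriented_sources,
    single_shell_leadfield,
    sphere_leadfield,
)
from opmlesion.forward import _sarvas_field


@pytest.fixture(scope="module")
def random_sources():
    rng = np.random.default_rng(0)
    pos = rng.normal(size=(40, 3))
    pos = 60.0 * pos / np.linalg.norm(pos, axis=1, keepdims=True)
    pos *= rng.uniform(0.5, 1.0, size=(40, 1))
    ori = rng.normal(size=(40, 3))
    ori /= np.linalg.norm(ori, axis=1, keepdims=True)
    return SourceSpace(pos, ori)


@pytest.fixture(scope="module")
def sphere_mesh():
    return make_icosphere(3, 80.0)


class TestFitSphere:
    def test_exact_recovery(self, sphere_mesh):
        model = fit_sphere(sphere_mesh)
        assert np.allclose(model.center, 0.0, atol=1e-9)
        assert model.radius == pytest.approx(80.0, abs=1e-9)

    def test_translated_sphere(self):
        m = make_icosphere(2, 50.0)
        shifted = type(m)(m.vertices + np.array([10.0, 0.0, 0.0]), m.faces)
        model = fit_sphere(shifted)
        assert np.allclose(model.center, [10.0, 0.0, 0.0], atol=1e-9)

    def test_bumpy_cortex_residual(self, head_small):
        model = fit_sphere(head_small.cortex)
        r = np.linalg.norm(head_small.cortex.vertices - model.center, axis=1)
        rms = np.sqrt(np.mean((r - model.radius) ** 2))
        assert rms < 0.1 * model.radius


class TestSphereModel:
    def test_silent_sources(self, array_small):
        sphere = ConductorModel(kind="sphere", center=np.zeros(3), radius=85.0)
        src = SourceSpace(
            np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 50.0]]),
            np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),  # centre, radial
        )
        L = sphere_leadfield(array_small, src, sphere)
        assert np.all(np.abs(L.matrix) < 1e-12)

    def test_radius_independence_and_sign_linearity(self, array_small, random_sources):
        c = np.zeros(3)
        L1 = sphere_leadfield(
            array_small, random_sources, ConductorModel("sphere", c, 80.0)
        )
        L2 = sphere_leadfield(
            array_small, random_sources, ConductorModel("sphere", c, 120.0)
        )
        assert np.allclose(L1.matrix, L2.matrix, atol=1e-12)
        flipped = SourceSpace(random_sources.positions, -random_sources.orientations)
        L3 = sphere_leadfield(
            array_small, flipped, ConductorModel("sphere", c, 80.0)
        )
        assert np.allclose(L3.matrix, -L1.matrix, atol=1e-12)

    def test_against_potential_gradient_oracle(self, array_small):
        """The closed-form field must equal -mu0 grad U with U the
        analytic magnetic scalar potential (numerical differentiation)."""

        def potential(r, r0, q):
            a = np.linalg.norm(r - r0)
            rn = np.linalg.norm(r)
            F = a * (rn * a + rn**2 - r0 @ r)
            return -(np.cross(q, r0) @ r) / (4.0 * np.pi * F)

        r0 = np.array([0.030, 0.0, 0.040])
        q = np.array([0.0, 1.0, 0.0])
        eps = 1e-7
        for ch in (0, 5, 11):
            r_s = array_small.channel_positions[ch] * 1e-3
            n_s = array_small.channel_orientations[ch]
            grad = np.array(
                [
                    (potential(r_s + eps * e, r0, q) - potential(r_s - eps * e, r0, q))
                    / (2 * eps)
                    for e in np.eye(3)
                ]
            )
            oracle = -(4.0 * np.pi * 1e-7) * grad @ n_s * 1e15 * 1e-9
            sphere = ConductorModel("sphere", np.zeros(3), 85.0)
            src = SourceSpace(r0[None, :] * 1e3, q[None, :])
            L = sphere_leadfield(array_small, src, sphere)
            assert L.matrix[ch, 0] == pytest.approx(oracle, rel=1e-8)

    def test_radial_component_equals_primary(self):
        """Volume currents in a sphere contribute no radial field, so the
        radial component must equal the infinite-medium primary field."""
        r_s = np.array([[0.0, 0.02, 0.10]])
        r0 = np.array([[0.03, 0.0, 0.04]])
        q = np.array([[0.0, 1.0, 0.0]])
        B = _sarvas_field(r_s, r0, q)[0, 0] * 1e-7
        Bp = 1e-7 * np.cross(q[0], r_s[0] - r0[0]) / np.linalg.norm(r_s[0] - r0[0]) ** 3
        rhat = r_s[0] / np.linalg.norm(r_s[0])
        assert B @ rhat == pytest.approx(Bp @ rhat, rel=1e-10)

    def test_source_outside_sphere_rejected(self, array_small):
        sphere = ConductorModel("sphere", np.zeros(3), 50.0)
        src = SourceSpace(np.array([[0.0, 0.0, 60.0]]), np.array([[1.0, 0.0, 0.0]]))
        with pytest.raises(ValueError):
            sphere_leadfield(array_small, src, sphere)

    def test_field_scale_sanity(self, array_small):
        """A 10 nA*m tangential dipole ~25 mm under a sensor gives a field
        in the 10-1000 fT range."""
        pos = array_small.positions[0]
        dirn = pos / np.linalg.norm(pos)
        src_pos = pos - 25.0 * dirn
        tang = np.cross(dirn, [0.0, 0.0, 1.0])
        tang /= np.linalg.norm(tang)
        src = SourceSpace(src_pos[None, :], tang[None, :])
        L = sphere_leadfield(
            array_small, src, ConductorModel("sphere", np.zeros(3), 85.0)
        )
        peak = 10.0 * np.abs(L.matrix).max()
        assert 10.0 < peak < 1000.0


class TestSingleShell:
    def test_sphere_limit(self, array_small, random_sources, sphere_mesh):
        """On an exactly spherical shell the corrected model must match
        the closed-form sphere solution to <1% relative Frobenius."""
        L_sphere = sphere_leadfield(
            array_small, random_sources, ConductorModel("sphere", np.zeros(3), 80.0)
        )
        shell = ConductorModel(kind="shell", mesh=sphere_mesh, order=10)
        L_shell = single_shell_leadfield(array_small, random_sources, shell)
        rel = np.linalg.norm(L_shell.matrix - L_sphere.matrix) / np.linalg.norm(
            L_sphere.matrix
        )
        assert rel < 0.01

    def test_residual_monotone_in_order(self, array_small, random_sources, sphere_mesh):
        res = []
        for order in (6, 8, 10):
            shell = ConductorModel(kind="shell", mesh=sphere_mesh, order=order)
            L = single_shell_leadfield(array_small, random_sources, shell)
            res.append(L.boundary_residual)
        assert res[0] > res[1] > res[2]

    def test_orientation_linearity(self, array_small, sphere_mesh):
        rng = np.random.default_rng(3)
        pos = np.array([[20.0, -10.0, 30.0]])
        q1 = np.array([[1.0, 0.0, 0.0]])
        q2 = np.array([[0.0, 1.0, 0.0]])
        mix = (q1 + q2) / np.linalg.norm(q1 + q2)
        shell = ConductorModel(kind="shell", mesh=sphere_mesh, order=8)
        g1 = single_shell_leadfield(array_small, SourceSpace(pos, q1), shell).matrix
        g2 = single_shell_leadfield(array_small, SourceSpace(pos, q2), shell).matrix
        gm = single_shell_leadfield(array_small, SourceSpace(pos, mix), shell).matrix
        assert np.allclose(gm, (g1 + g2) / np.sqrt(2.0), atol=1e-12)

    def test_min_order_guard(self, sphere_mesh):
        with pytest.raises(ValueError):
            ConductorModel(kind="shell", mesh=sphere_mesh, order=4)


class TestSourceSpace:
    def test_normal_oriented_sources(self):
        cortex = make_icosphere(2, 70.0)
        src = normal_oriented_sources(cortex)
        assert len(src) == cortex.n_vertices
        rad = src.positions / np.linalg.norm(src.positions, axis=1, keepdims=True)
        # area-weighted discrete normals deviate from exact radial by
        # O(1e-5) on an icosphere ring; they must still be outward radial
        assert np.all(np.sum(src.orientations * rad, axis=1) > 1.0 - 1e-4)

    def test_leadfield_hdf5_round_trip(self, leadfield_small, tmp_path):
        path = tmp_path / "lf.h5"
        leadfield_small.save(path)
        back = LeadField.load(path)
        assert np.array_equal(back.matrix, leadfield_small.matrix)
        assert back.channel_names == leadfield_small.channel_names
        assert np.array_equal(
            back.sources.positions, leadfield_small.sources.positions
        )
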