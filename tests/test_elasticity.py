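"""Stiffness, assembly, solve, and resultant-growth decomposition."""

import numpy as np
import pytest

from morphocanvas import (
    ConstraintSet,
    ElasticMaterial,
    assemble_elastic_system,
    build_flat_sheet,
    decompose_growth,
    independent_stiffness_components,
    isotropic_stiffness,
    positive_definiteness_boundary,
    solve_displacements,
)
from morphocanvas.elasticity import deformation_energy
from morphocanvas.errors import ConstraintError, ParameterError
from morphocanvas.growth import GrowthSpec, assemble_specified_growth


class TestIsotropicStiffness:
    def test_zero_poisson(self):
        C = isotropic_stiffness(ElasticMaterial(1.0, 0.0))
        assert C[0, 0] == 2.0 and C[0, 1] == 0.0 and C[3, 3] == 1.0

    def test_default_poisson(self):
        C = isotropic_stiffness(ElasticMaterial(1.0, 0.3))
        assert abs(C[0, 0] - 3.5) < 1e-12
        assert abs(C[0, 1] - 1.5) < 1e-12
        assert C[3, 3] == 1.0

    def test_half_poisson_degenerate(self):
        with pytest.raises(ParameterError):
            ElasticMaterial(1.0, 0.5)

    def test_positive_definite_below_half(self):
        C = isotropic_stiffness(ElasticMaterial(2.0, 0.45))
        assert np.all(np.linalg.eigvalsh(C) > 0)

    def test_symmetry_component_count(self):
        assert independent_stiffness_components() == 21

    def test_pd_boundary_at_half(self):
        assert abs(positive_definiteness_boundary() - 0.5) <= 1e-9


def _wedge_oracle_K(coords, C):
    """Independent dense-quadrature element stiffness: complex-step shape
    derivatives and a Duffy-mapped 6x6x6 Gauss grid."""

    def shapes(xi, eta, zeta):
        lam = [1 - xi - eta, xi, eta]
        return np.array(
            [lam[i] * 0.5 * (1 - zeta) for i in range(3)]
            + [lam[i] * 0.5 * (1 + zeta) for i in range(3)]
        )

    h = 1e-20

    def dshapes(xi, eta, zeta):
        cols = []
        for k in range(3):
            args = [xi + 0j, eta + 0j, zeta + 0j]
            args[k] += 1j * h
            cols.append(np.imag(shapes(*args)) / h)
        return np.array(cols).T  # (6, 3)

    gp, gw = np.polynomial.legendre.leggauss(6)
    K = np.zeros((18, 18))
    for za, zw in zip(gp, gw):
        for ua, uw in zip(gp, gw):
            for va, vw in zip(gp, gw):
                u, v = (ua + 1) / 2, (va + 1) / 2
                xi, eta = u * (1 - v), v
                w = uw * vw * zw * (1 - v) / 4.0  # Duffy jacobian
                dN = dshapes(xi, eta, za)
                J = coords.T @ dN
                dNdx = dN @ np.linalg.inv(J)
                B = np.zeros((6, 18))
                for node in range(6):
                    c = 3 * node
                    B[0, c] = dNdx[node, 0]
                    B[1, c + 1] = dNdx[node, 1]
                    B[2, c + 2] = dNdx[node, 2]
                    B[3, c + 1] = dNdx[node, 2]
                    B[3, c + 2] = dNdx[node, 1]
                    B[4, c] = dNdx[node, 2]
                    B[4, c + 2] = dNdx[node, 0]
                    B[5, c] = dNdx[node, 1]
                    B[5, c + 1] = dNdx[node, 0]
                K += w * np.linalg.det(J) * B.T @ C @ B
    return K


class TestAssembly:
    def test_zero_growth_zero_force(self, sheet4, stiffness):
        sys_ = assemble_elastic_system(sheet4, stiffness, None, None)
        assert np.all(sys_.f == 0.0)

    def test_single_wedge_matches_dense_oracle(self, single_wedge, stiffness):
        sys_ = assemble_elastic_system(single_wedge, stiffness, None, None)
        K = sys_.K.toarray()
        coords = np.vstack([single_wedge.pos_a, single_wedge.pos_b])
        Ko = _wedge_oracle_K(coords, stiffness)
        assert np.abs(K - Ko).max() < 1e-10

    def test_unconstrained_nullity_is_six(self, stiffness):
        c = build_flat_sheet(2, 2, 1.0, 0.1, 0.0)
        sys_ = assemble_elastic_system(c, stiffness, None, None)
        ev = np.linalg.eigvalsh(sys_.K.toarray())
        scale = ev.max()
        assert np.sum(np.abs(ev) < 1e-10 * scale) == 6

    def test_symmetry(self, sheet4, stiffness):
        sys_ = assemble_elastic_system(sheet4, stiffness, None, None)
        d = sys_.K - sys_.K.T
        assert abs(d).max() < 1e-12

    def test_conflicting_constraints_rejected(self, sheet4):
        cons = ConstraintSet()
        cons.fix_vertices(sheet4, [0], axes=2, surfaces="a")
        cons.add_flatness(sheet4, [0])
        with pytest.raises(ConstraintError):
            cons.validate(sheet4)


class TestSolve:
    def test_zero_force_zero_displacement(self, sheet4, stiffness):
        sys_ = assemble_elastic_system(sheet4, stiffness, None, None)
        u = solve_displacements(sys_, tol=1e-8)
        assert np.all(u == 0.0)

    def test_uniform_isotropic_growth_is_pure_scaling(self, sheet10, stiffness):
        g = 0.05
        spec = GrowthSpec.zeros(sheet10.n_elements)
        for name in ("kpar_a", "kpar_b", "kper_a", "kper_b", "kthick"):
            getattr(spec, name)[:] = 1.0
        layers = assemble_specified_growth(sheet10, spec, None, g)
        sys_ = assemble_elastic_system(sheet10, stiffness, layers, None)
        u = solve_displacements(sys_, tol=1e-9)
        P = np.vstack([sheet10.pos_a, sheet10.pos_b])
        expect = g * (P - P.mean(axis=0))
        assert np.abs(u - expect).max() < 1e-9

    @pytest.mark.parametrize("method", ["minres", "cgs", "direct"])
    def test_solvers_agree_on_tiny_mesh(self, stiffness, method):
        c = build_flat_sheet(1, 1, 1.0, 0.2, 0.0)  # 24 dofs
        spec = GrowthSpec.zeros(c.n_elements)
        spec.kpar_a[:] = 1.0
        spec.kper_b[:] = -0.5
        layers = assemble_specified_growth(c, spec, None, 0.05)
        sys_ = assemble_elastic_system(c, stiffness, layers, None)
        tol = 1e-10
        u = solve_displacements(sys_, tol=tol, method=method)
        # dense least-squares oracle with the same rigid-mode projection
        from morphocanvas.elasticity import _rigid_modes

        uo = np.linalg.lstsq(sys_.K.toarray(), sys_.f, rcond=None)[0]
        M = _rigid_modes(c)
        Q, _ = np.linalg.qr(M.T)
        uo -= Q @ (Q.T @ uo)
        assert np.abs(u.ravel() - uo).max() < 1e-8

    def test_stiffness_scale_invariance(self, sheet4, stiffness):
        spec = GrowthSpec.zeros(sheet4.n_elements)
        spec.kpar_a[:] = 1.0
        layers = assemble_specified_growth(sheet4, spec, None, 0.05)
        u1 = solve_displacements(
            assemble_elastic_system(sheet4, stiffness, layers, None), tol=1e-10
        )
        u2 = solve_displacements(
            assemble_elastic_system(sheet4, 1e3 * stiffness, layers, None), tol=1e-10
        )
        assert np.abs(u1 - u2).max() < 1e-8

    def test_poisson_weak_sensitivity_for_growth(self, sheet4):
        # displacements from smooth incompatible growth depend only weakly
        # on nu (compatible growth would be exactly nu-independent)
        spec = GrowthSpec.from_vertex_fields(
            sheet4, kpar_a=sheet4.midplane[:, 0], kper_a=sheet4.midplane[:, 0]
        )
        layers = assemble_specified_growth(sheet4, spec, None, 0.05)
        us = {}
        for nu in (0.2, 0.4):
            C = isotropic_stiffness(ElasticMaterial(1.0, nu))
            us[nu] = solve_displacements(
                assemble_elastic_system(sheet4, C, layers, None), tol=1e-10
            )
        scale = np.abs(us[0.4]).max()
        assert np.abs(us[0.2] - us[0.4]).max() < 0.05 * scale

    def test_patch_uniform_strain_reproduced_exactly(self, sheet4, stiffness):
        # any uniform (compatible) specified strain is realised with
        # negligible residual on single- and multi-element meshes
        eps0 = np.array([[0.02, 0.005, 0.0], [0.005, -0.01, 0.0], [0.0, 0.0, 0.015]])
        layers = np.broadcast_to(eps0, (sheet4.n_elements, 2, 3, 3)).copy()
        sys_ = assemble_elastic_system(sheet4, stiffness, layers, None)
        u = solve_displacements(sys_, tol=1e-12)
        res = decompose_growth(sheet4, u)
        assert np.abs(res.strain - eps0).max() < 1e-10

    def test_equilibrium_minimises_energy(self, stiffness):
        c = build_flat_sheet(2, 2, 1.0, 0.15, 0.0)
        rng = np.random.default_rng(1)
        spec = GrowthSpec.zeros(c.n_elements)
        spec.kpar_a[:] = rng.random(c.n_elements)
        spec.kper_b[:] = rng.random(c.n_elements)
        layers = assemble_specified_growth(c, spec, None, 0.08)
        sys_ = assemble_elastic_system(c, stiffness, layers, None)
        u = solve_displacements(sys_, tol=1e-12)
        e0 = deformation_energy(c, stiffness, u, layers)
        for _ in range(10):
            du = 1e-3 * rng.standard_normal(u.shape)
            assert deformation_energy(c, stiffness, u + du, layers) >= e0 - 1e-14


class TestDecomposeGrowth:
    def test_infinitesimal_rotation_is_pure_vorticity(self, sheet4):
        w = np.array([0.0, 0.0, 1e-3])
        P = np.vstack([sheet4.pos_a, sheet4.pos_b])
        u = np.cross(np.broadcast_to(w, P.shape), P - P.mean(axis=0))
        res = decompose_growth(sheet4, u)
        assert np.abs(res.strain).max() < 1e-12
        assert np.abs(res.rotation_vectors() - w).max() < 1e-12

    def test_uniaxial_stretch_field(self, sheet4):
        g = 0.03
        P = np.vstack([sheet4.pos_a, sheet4.pos_b])
        u = np.zeros_like(P)
        u[:, 1] = g * P[:, 1]
        res = decompose_growth(sheet4, u)
        assert np.abs(res.strain - np.diag([0.0, g, 0.0])).max() < 1e-12
        assert np.abs(res.vorticity).max() < 1e-12

    def test_random_affine_gradient_recovered(self, sheet4):
        rng = np.random.default_rng(2)
        G = 0.01 * rng.standard_normal((3, 3))
        P = np.vstack([sheet4.pos_a, sheet4.pos_b])
        u = P @ G.T
        res = decompose_growth(sheet4, u)
        assert np.abs(res.grad - G).max() < 1e-13
        assert np.abs(res.strain + res.vorticity - res.grad).max() < 1e-15

    def test_principal_growth_eigenpairs(self, sheet4):
        g = 0.02
        P = np.vstack([sheet4.pos_a, sheet4.pos_b])
        u = np.zeros_like(P)
        u[:, 0] = g * P[:, 1]
        u[:, 1] = g * P[:, 0]  # pure shear
        res = decompose_growth(sheet4, u)
        evals, _ = res.principal_growth()
        assert np.abs(evals[:, 0] + g).max() < 1e-12
        assert np.abs(evals[:, 2] - g).max() < 1e-12
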