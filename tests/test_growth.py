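"""Specified growth tensor assembly and local frames."""

import numpy as np
import pytest

from morphocanvas import PolarityMode, PolarityState
from morphocanvas.errors import ModelError
from morphocanvas.growth import GAUSS_ZETA, GrowthSpec, assemble_specified_growth, local_frame


def _external_polarity(canvas, direction):
    from morphocanvas import update_polarity

    s = PolarityState.blank(canvas.n_elements)
    s.mode[:] = int(PolarityMode.EXTERNAL)
    s.external_direction = np.asarray(direction, dtype=float)
    return update_polarity(canvas, s)


class TestLocalFrame:
    def test_flat_element_axis_aligned(self, single_wedge):
        pol = _external_polarity(single_wedge, (0.0, 1.0, 0.0))
        u, v, n = local_frame(single_wedge, 0, pol)
        assert np.allclose(u, [0, 1, 0])
        assert np.allclose(np.abs(n), [0, 0, 1])
        assert np.allclose(np.cross(u, v), -n) or np.allclose(np.cross(u, v), n)

    def test_orthonormality_random_elements(self, sheet10):
        rng = np.random.default_rng(0)
        pol = _external_polarity(sheet10, rng.standard_normal(3))
        for e in rng.choice(sheet10.n_elements, 10, replace=False):
            u, v, n = local_frame(sheet10, int(e), pol)
            G = np.array([u, v, n])
            assert np.abs(G @ G.T - np.eye(3)).max() < 1e-12

    def test_frame_rotates_with_element(self, single_wedge):
        from scipy.spatial.transform import Rotation

        pol = _external_polarity(single_wedge, (1.0, 1.0, 0.0))
        u0, v0, n0 = local_frame(single_wedge, 0, pol)
        R = Rotation.from_rotvec([0.3, -0.2, 0.5]).as_matrix()
        rot = single_wedge.copy()
        rot.pos_a = rot.pos_a @ R.T
        rot.pos_b = rot.pos_b @ R.T
        polR = PolarityState.blank(1)
        polR.mode[:] = int(PolarityMode.FROZEN)
        polR.axis[0] = R @ u0
        u1, v1, n1 = local_frame(rot, 0, polR)
        for a0, a1 in ((u0, u1), (v0, v1), (n0, n1)):
            assert np.abs(R @ a0 - a1).max() < 1e-12


class TestSpecifiedGrowth:
    def test_uniaxial_tensor_in_lab_frame(self, single_wedge):
        pol = _external_polarity(single_wedge, (0.0, 1.0, 0.0))
        spec = GrowthSpec.zeros(1)
        spec.kpar_a[:] = spec.kpar_b[:] = 1.0
        layers = assemble_specified_growth(single_wedge, spec, pol, 0.1)
        for layer in range(2):
            assert np.abs(layers[0, layer] - np.diag([0.0, 0.1, 0.0])).max() < 1e-12

    def test_per_surface_difference_separates_layers(self, single_wedge):
        pol = _external_polarity(single_wedge, (0.0, 1.0, 0.0))
        spec = GrowthSpec.zeros(1)
        spec.kpar_a[:] = 1.0
        spec.kpar_b[:] = -1.0  # shrink one side, expand the other
        layers = assemble_specified_growth(single_wedge, spec, pol, 0.1)
        assert layers[0, 0, 1, 1] > 0 > layers[0, 1, 1, 1]
        assert not np.allclose(layers[0, 0], layers[0, 1])

    def test_trace_identity(self, sheet10):
        rng = np.random.default_rng(2)
        pol = _external_polarity(sheet10, (1.0, 0.3, 0.0))
        spec = GrowthSpec(
            rng.standard_normal(sheet10.n_elements),
            rng.standard_normal(sheet10.n_elements),
            rng.standard_normal(sheet10.n_elements),
            rng.standard_normal(sheet10.n_elements),
            rng.standard_normal(sheet10.n_elements),
        )
        dt = 0.07
        layers = assemble_specified_growth(sheet10, spec, pol, dt)
        for li, zeta in enumerate(GAUSS_ZETA):
            wa, wb = 0.5 * (1 - zeta), 0.5 * (1 + zeta)
            expect = dt * (
                wa * spec.kpar_a + wb * spec.kpar_b
                + wa * spec.kper_a + wb * spec.kper_b
                + spec.kthick
            )
            tr = np.trace(layers[:, li], axis1=1, axis2=2)
            assert np.abs(tr - expect).max() < 1e-12

    def test_quarter_turn_swaps_eigenvalues(self, single_wedge):
        spec = GrowthSpec.zeros(1)
        spec.kpar_a[:] = spec.kpar_b[:] = 2.0
        spec.kper_a[:] = spec.kper_b[:] = 0.5
        a = assemble_specified_growth(
            single_wedge, spec, _external_polarity(single_wedge, (0, 1, 0)), 0.1
        )
        b = assemble_specified_growth(
            single_wedge, spec, _external_polarity(single_wedge, (1, 0, 0)), 0.1
        )
        assert abs(a[0, 0, 1, 1] - b[0, 0, 0, 0]) < 1e-12
        assert abs(a[0, 0, 0, 0] - b[0, 0, 1, 1]) < 1e-12

    def test_axiality_negating_axis_changes_nothing(self, sheet10):
        rng = np.random.default_rng(3)
        pol = _external_polarity(sheet10, (0.7, 0.7, 0.0))
        spec = GrowthSpec(
            rng.random(sheet10.n_elements), rng.random(sheet10.n_elements),
            rng.random(sheet10.n_elements), rng.random(sheet10.n_elements),
            rng.random(sheet10.n_elements),
        )
        a = assemble_specified_growth(sheet10, spec, pol, 0.1)
        flipped = pol.copy()
        flipped.axis = -flipped.axis
        b = assemble_specified_growth(sheet10, spec, flipped, 0.1)
        assert np.abs(a - b).max() < 1e-14

    def test_isotropic_fallback_uses_mean(self, single_wedge):
        spec = GrowthSpec.zeros(1)
        spec.kpar_a[:] = spec.kpar_b[:] = 2.0
        layers = assemble_specified_growth(single_wedge, spec, None, 0.1)
        # mean of (2, 0) = 1 in both in-plane directions
        assert abs(layers[0, 0, 0, 0] - 0.1) < 1e-12
        assert abs(layers[0, 0, 1, 1] - 0.1) < 1e-12

    def test_non_finite_rate_rejected(self, single_wedge):
        spec = GrowthSpec.zeros(1)
        spec.kpar_a[0] = np.nan
        with pytest.raises(ModelError):
            assemble_specified_growth(single_wedge, spec, None, 0.1)

    def test_normal_is_always_an_eigenvector(self, sheet10):
        rng = np.random.default_rng(4)
        pol = _external_polarity(sheet10, (0.2, 1.0, 0.0))
        spec = GrowthSpec(
            rng.random(sheet10.n_elements), rng.random(sheet10.n_elements),
            rng.random(sheet10.n_elements), rng.random(sheet10.n_elements),
            rng.random(sheet10.n_elements),
        )
        layers = assemble_specified_growth(sheet10, spec, pol, 0.1)
        normals = sheet10.triangle_normals()
        res = np.einsum("elij,ej->eli", layers, normals)
        expect = (0.1 * spec.kthick)[:, None, None] * normals[:, None, :]
        assert np.abs(res - expect).max() < 1e-12
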