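"""Factor fields, promotion/inhibition, polarity, thresholds, hooks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphocanvas import (
    FactorField,
    PolarityMode,
    PolarityState,
    apply_threshold_rule,
    compute_pol_gradient,
    inh,
    pro,
    update_polarity,
)
from morphocanvas.canvas import build_flat_sheet
from morphocanvas.errors import ContractViolation, DomainError, ParameterError
from morphocanvas.factors import run_interaction
from morphocanvas.growth import GrowthSpec, assemble_specified_growth


class TestProInh:
    def test_values_at_zero(self):
        for k in (0.0, 1.0, 1e6):
            assert pro(k, 0.0) == 1.0
            assert inh(k, 0.0) == 1.0

    def test_adopted_closed_forms(self):
        assert pro(2.0, 0.5) == 2.0
        assert inh(2.0, 0.5) == 0.5

    def test_reciprocal_composition(self):
        x = np.linspace(0, 5, 11)
        assert np.allclose(pro(3.0, x) * inh(3.0, x), 1.0)

    def test_order_independence(self):
        x1 = np.array([0.1, 2.0])
        x2 = np.array([3.0, 0.5])
        z = np.array([1.5, 0.7])
        a = z * pro(1.0, x1) * pro(2.0, x2)
        b = z * pro(2.0, x2) * pro(1.0, x1)
        assert np.array_equal(a, b)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            pro(1.0, np.array([-0.1]))
        with pytest.raises(DomainError):
            inh(-1.0, np.array([0.1]))

    @settings(max_examples=50, derandomize=True)
    @given(
        k=st.floats(0.0, 1e6),
        x=st.floats(0.0, 1e-9),
    )
    def test_limits_near_zero(self, k, x):
        assert abs(pro(k, x) - 1.0) <= k * x + 1e-15
        assert abs(inh(k, x) - 1.0) <= k * x + 1e-15

    @settings(max_examples=50, derandomize=True)
    @given(x=st.lists(st.floats(0.0, 100.0), min_size=2, max_size=6))
    def test_monotonicity(self, x):
        x = np.sort(np.asarray(x))
        assert np.all(np.diff(pro(2.0, x)) >= 0)
        assert np.all(np.diff(inh(2.0, x)) <= 0)


class TestFactorField:
    def test_identity_cannot_diffuse(self):
        with pytest.raises(ParameterError):
            FactorField("a", "identity", np.zeros(3), D=1.0)

    def test_identity_never_dilutable(self):
        f = FactorField("a", "identity", np.zeros(3), dilutable=True)
        assert not f.dilutable

    def test_unknown_kind(self):
        with pytest.raises(ParameterError):
            FactorField("a", "mystery", np.zeros(3))


class TestPolGradient:
    def test_linear_field_exact(self, sheet10):
        pol = FactorField("POL", "signalling", sheet10.midplane[:, 1].copy(), D=1.0)
        g = compute_pol_gradient(sheet10, pol)
        assert np.abs(g - np.array([0.0, 1.0, 0.0])).max() < 1e-12

    def test_constant_field_zero_gradient(self, sheet10):
        pol = FactorField("POL", "signalling", np.ones(sheet10.n_vertices), D=1.0)
        g = compute_pol_gradient(sheet10, pol)
        assert np.abs(g).max() == 0.0

    def test_identity_factor_rejected(self, sheet10):
        f = FactorField("g", "identity", np.ones(sheet10.n_vertices))
        with pytest.raises(ParameterError):
            compute_pol_gradient(sheet10, f)

    def test_gradient_converges_under_refinement(self):
        # smooth field sin(pi x) cos(pi y): elementwise P1 gradient error -> 0
        errs = []
        for n in (8, 16, 32):
            c = build_flat_sheet(n, n, 1.0, 0.1, 0.0)
            mp = c.midplane
            pol = FactorField(
                "POL", "signalling", np.sin(np.pi * mp[:, 0]) * np.cos(np.pi * mp[:, 1]), D=1.0
            )
            g = compute_pol_gradient(c, pol)
            cen = mp[c.triangles].mean(axis=1)
            exact = np.stack(
                [
                    np.pi * np.cos(np.pi * cen[:, 0]) * np.cos(np.pi * cen[:, 1]),
                    -np.pi * np.sin(np.pi * cen[:, 0]) * np.sin(np.pi * cen[:, 1]),
                    np.zeros(len(cen)),
                ],
                axis=1,
            )
            errs.append(np.sqrt(np.mean(np.sum((g - exact) ** 2, axis=1))))
        assert errs[1] < 0.6 * errs[0]
        assert errs[2] < 0.6 * errs[1]


class TestPolarityUpdate:
    def test_frozen_axis_convects_with_rigid_rotation(self, sheet10):
        state = PolarityState.blank(sheet10.n_elements)
        state.mode[:] = int(PolarityMode.FROZEN)
        state.axis[:] = [0.0, 1.0, 0.0]
        th = np.pi / 2
        R = np.array(
            [[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0.0, 0.0, 1.0]]
        )
        rotated = sheet10.copy()
        rotated.pos_a = rotated.pos_a @ R.T
        rotated.pos_b = rotated.pos_b @ R.T
        F = np.broadcast_to(R, (sheet10.n_elements, 3, 3))
        new = update_polarity(rotated, state, deformation_gradients=F)
        assert np.abs(new.axis - np.array([-1.0, 0.0, 0.0])).max() < 1e-9

    def test_shallow_gradient_absent_policy_gives_isotropy(self, sheet10):
        state = PolarityState.blank(sheet10.n_elements)
        state.mode[:] = int(PolarityMode.LIVE)
        state.gradient_threshold = 1e-3
        state.shallow_policy = "absent"
        grads = np.full((sheet10.n_elements, 3), 1e-6)
        new = update_polarity(sheet10, state, grads)
        assert np.all(new.mode == int(PolarityMode.ABSENT))
        spec = GrowthSpec.zeros(sheet10.n_elements)
        spec.kpar_a[:] = spec.kpar_b[:] = 2.0
        layers = assemble_specified_growth(sheet10, spec, new, 0.1)
        # in-plane isotropic: xx and yy strains equal
        assert np.allclose(layers[:, 0, 0, 0], layers[:, 0, 1, 1])

    def test_external_mode_projects_lab_axis(self, sheet10):
        state = PolarityState.blank(sheet10.n_elements)
        state.mode[:] = int(PolarityMode.EXTERNAL)
        state.external_direction = np.array([0.0, 1.0, 0.0])
        new = update_polarity(sheet10, state)
        assert np.abs(new.axis - np.array([0.0, 1.0, 0.0])).max() < 1e-12

    def test_axis_stays_in_plane_and_unit(self, sheet10):
        rng = np.random.default_rng(1)
        pol = FactorField("POL", "signalling", rng.random(sheet10.n_vertices), D=1.0)
        state = PolarityState.blank(sheet10.n_elements)
        state.mode[:] = int(PolarityMode.LIVE)
        g = compute_pol_gradient(sheet10, pol)
        new = update_polarity(sheet10, state, g)
        normals = sheet10.triangle_normals()
        live = new.mode == int(PolarityMode.LIVE)
        assert np.abs(np.einsum("ij,ij->i", new.axis[live], normals[live])).max() < 1e-9
        assert np.abs(np.linalg.norm(new.axis[live], axis=1) - 1.0).max() < 1e-12


class TestThresholdRule:
    def test_no_activation_above_threshold(self):
        ident = np.zeros(5)
        out = apply_threshold_rule(np.full(5, 2.0), 1.0, ident)
        assert np.array_equal(out, ident)

    def test_latching(self):
        ident = np.zeros(3)
        out = apply_threshold_rule(np.array([0.1, 2.0, 2.0]), 1.0, ident)
        assert np.array_equal(out, [1.0, 0.0, 0.0])
        # field recovers but the identity stays on
        out2 = apply_threshold_rule(np.array([5.0, 5.0, 5.0]), 1.0, out)
        assert np.array_equal(out2, [1.0, 0.0, 0.0])

    def test_minus_infinity_never_activates(self):
        out = apply_threshold_rule(np.zeros(4), -np.inf, np.zeros(4))
        assert np.array_equal(out, np.zeros(4))


class TestInteractionHook:
    def _state(self, sheet10):
        from morphocanvas.simulation import SimState

        return SimState(
            canvas=sheet10,
            fields={"g": FactorField("g", "identity", np.ones(sheet10.n_vertices))},
            polarity=PolarityState.blank(sheet10.n_elements),
        )

    def test_null_hook_is_noop(self, sheet10):
        s = self._state(sheet10)
        run_interaction(None, s)
        assert all(np.all(v == 0) for v in s.rates.values())

    def test_hook_sets_rates(self, sheet10):
        s = self._state(sheet10)
        run_interaction(lambda st: st.set_rates(kpar=1.0), s)
        assert np.all(s.rates["kpar_a"] == 1.0)
        assert np.all(s.rates["kper_a"] == 0.0)

    def test_geometry_mutation_rejected(self, sheet10):
        s = self._state(sheet10)

        def bad(st):
            st.canvas.pos_a[0, 0] += 1.0

        with pytest.raises(ContractViolation):
            run_interaction(bad, s)
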