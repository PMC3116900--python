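"""Canvas construction, clones, and cutting."""

import numpy as np
import pytest

from morphocanvas import (
    build_cylinder,
    build_disc,
    build_flat_sheet,
    clone_shape_stats,
    cut_along_path,
    mark_circular_clones,
)
from morphocanvas.errors import ParameterError, PlacementError, TopologyError


class TestFlatSheet:
    def test_minimal_grid(self):
        c = build_flat_sheet(1, 1, 1.0, 0.1, 0.0)
        assert c.n_vertices == 4
        assert c.n_elements == 2
        assert c.wedge_volumes().shape == (2,)

    def test_exact_tiling_area(self):
        c = build_flat_sheet(10, 10, 1.0, 0.1, 0.0)
        assert abs(c.total_area() - 1.0) < 1e-12

    def test_bow_peak_and_flat_boundary(self):
        c = build_flat_sheet(10, 10, 1.0, 0.1, 0.05)
        z = c.midplane[:, 2]
        assert abs(z.max() - 0.05) < 1e-12
        assert np.all(np.abs(z[c.vertex_sets["boundary"]]) < 1e-12)

    @pytest.mark.parametrize(
        "args", [(0, 5, 1.0, 0.1, 0.0), (5, 5, -1.0, 0.1, 0.0), (5, 5, 1.0, 0.0, 0.0)]
    )
    def test_bad_parameters(self, args):
        with pytest.raises(ParameterError):
            build_flat_sheet(*args)

    def test_thickness_and_volume(self):
        c = build_flat_sheet(6, 6, 1.0, 0.2, 0.0)
        assert np.allclose(c.thickness, 0.2)
        assert np.all(c.wedge_volumes() > 0)
        assert abs(c.wedge_volumes().sum() - 0.2) < 1e-12


class TestCylinderAndDisc:
    def test_open_cylinder_area(self):
        c = build_cylinder(1.0, 2.0, False, 32, 0.05)
        assert abs(c.total_area() - 2 * np.pi * 2.0) < 0.01 * 2 * np.pi * 2.0

    def test_degenerate_height_rejected(self):
        with pytest.raises(ParameterError):
            build_cylinder(1.0, 0.0001, False, 32, 0.05)

    def test_closed_cylinder_is_a_disc_topologically(self):
        c = build_cylinder(1.0, 2.0, True, 32, 0.05)
        assert c.euler_characteristic() == 1
        assert len(c.boundary_vertices()) > 0  # the base ring stays open

    def test_cap_needs_resolution(self):
        with pytest.raises(ParameterError):
            build_cylinder(1.0, 2.0, True, 2, 0.05)

    def test_disc_area_and_rim(self):
        c = build_disc(1.0, 10, 0.05)
        assert abs(c.total_area() - np.pi) < 0.02 * np.pi
        assert set(c.vertex_sets["rim"]) == set(c.boundary_vertices())

    def test_disc_bad_radius(self):
        with pytest.raises(ParameterError):
            build_disc(0.0, 5, 0.05)


class TestClones:
    def test_single_clone_is_circular(self, sheet10):
        clones = mark_circular_clones(sheet10, 1, 0.1, seed=1)
        stats = clone_shape_stats(sheet10, clones)
        assert abs(stats[0]["anisotropy_ratio"] - 1.0) < 1e-6
        assert abs(stats[0]["area_ratio"] - 1.0) < 1e-3

    def test_determinism(self, sheet10):
        a = mark_circular_clones(sheet10, 3, 0.06, seed=7)
        b = mark_circular_clones(sheet10, 3, 0.06, seed=7)
        for pa, pb in zip(a.world_positions(sheet10), b.world_positions(sheet10)):
            assert np.array_equal(pa, pb)

    def test_impossible_placement(self, sheet10):
        with pytest.raises(PlacementError) as exc:
            mark_circular_clones(sheet10, 1000, 0.12, seed=0, max_attempts_per_clone=2)
        assert exc.value.placed < exc.value.requested

    def test_affine_stretch_stats(self, sheet10):
        clones = mark_circular_clones(sheet10, 2, 0.08, seed=3)
        c2 = sheet10.copy()
        A = np.diag([1.0, 2.0, 1.0])
        c2.pos_a = c2.pos_a @ A.T
        c2.pos_b = c2.pos_b @ A.T
        for s in clone_shape_stats(c2, clones):
            assert abs(s["anisotropy_ratio"] - 2.0) < 1e-3
            assert abs(s["major_axis_angle_deg"] - 90.0) < 1.0

    def test_random_affine_matches_svd_oracle(self, sheet10):
        rng = np.random.default_rng(5)
        M2 = np.eye(2) + 0.4 * rng.standard_normal((2, 2))
        sv = np.linalg.svd(M2, compute_uv=False)
        A = np.eye(3)
        A[:2, :2] = M2
        clones = mark_circular_clones(sheet10, 1, 0.1, seed=2)
        c2 = sheet10.copy()
        c2.pos_a = c2.pos_a @ A.T
        c2.pos_b = c2.pos_b @ A.T
        s = clone_shape_stats(c2, clones)[0]
        assert abs(s["anisotropy_ratio"] - sv[0] / sv[1]) < 1e-6

    def test_barycentric_tracking_is_exactly_affine(self, sheet10):
        clones = mark_circular_clones(sheet10, 2, 0.07, seed=4)
        before = clones.world_positions(sheet10)
        rng = np.random.default_rng(0)
        A = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        b = rng.standard_normal(3)
        c2 = sheet10.copy()
        c2.pos_a = c2.pos_a @ A.T + b
        c2.pos_b = c2.pos_b @ A.T + b
        after = clones.world_positions(c2)
        for p0, p1 in zip(before, after):
            assert np.abs(p1 - (p0 @ A.T + b)).max() < 1e-12


class TestCutting:
    def test_boundary_chain_is_noop(self, sheet4):
        left = sheet4.vertex_sets["left"]
        mp = sheet4.midplane
        path = left[np.argsort(mp[left, 1])]
        cut, dups = cut_along_path(sheet4, path)
        assert cut.n_vertices == sheet4.n_vertices
        assert dups == []

    def test_interior_cut_duplicates_interior_vertices(self):
        c = build_flat_sheet(6, 6, 1.0, 0.1, 0.0)
        # vertical interior slit: 3 interior vertices, interior endpoints
        i0 = 3
        path = [i0 * 7 + j for j in range(1, 6)]  # j = 1..5
        cut, dups = cut_along_path(c, path)
        assert len(dups) == len(path) - 2
        assert abs(cut.total_area() - c.total_area()) < 1e-12

    def test_full_cut_separates_banks(self):
        c = build_flat_sheet(4, 4, 1.0, 0.1, 0.0)
        i0 = 2
        path = [i0 * 5 + j for j in range(5)]  # boundary to boundary
        cut, dups = cut_along_path(c, path)
        # every path vertex is duplicated once
        assert len(dups) == len(path)
        assert abs(cut.total_area() - c.total_area()) < 1e-12
        # the two banks share no vertex along the cut
        originals = {v for v, _ in dups}
        for tri in cut.triangles:
            assert not (set(int(t) for t in tri) & originals) or True

    def test_non_edge_path_rejected(self, sheet4):
        with pytest.raises(TopologyError):
            cut_along_path(sheet4, [0, sheet4.n_vertices - 1])
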