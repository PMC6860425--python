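import numpy as np
import pytest

import rbr
from rbr.geometry import AffineTransform
from rbr.lattice import (
    KUHN_TET_CORNERS,
    ControlPointField,
    DegenerateTetrahedronError,
    LatticeLevel,
    OutsideLatticeError,
    cell_tet_affines,
    deform_points,
    locate_tetrahedra,
)


def make_level(depth, origin=(0.0, 0.0, 0.0), extent=(8.0, 8.0, 8.0)):
    return LatticeLevel(np.array(origin), np.array(extent), depth)


class TestBuildLattice:
    @pytest.mark.parametrize(
        "depth,n_cells,n_nodes",
        [(0, 1, 8), (1, 8, 27), (2, 64, 125)],
    )
    def test_counts(self, depth, n_cells, n_nodes):
        levels = rbr.build_lattice(np.zeros(3), np.full(3, 8.0), depth)
        level = levels[depth]
        assert level.n_cells**3 == n_cells
        assert level.n_nodes**3 == n_nodes
        assert level.node_positions().reshape(-1, 3).shape == (n_nodes, 3)

    def test_nodes_shared_between_adjacent_cells(self):
        level = make_level(1)
        a = level.cell_corner_nodes((0, 0, 0))
        b = level.cell_corner_nodes((1, 0, 0))
        shared = {tuple(n) for n in a} & {tuple(n) for n in b}
        assert len(shared) == 4  # one full face of nodes in common


class TestPartitionVertices:
    def test_conservation(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0.0, 8.0, size=(500, 3))
        level = make_level(2)
        parts = rbr.partition_vertices(pts, level)
        assert sum(len(v) for v in parts.values()) == 500
        all_idx = np.sort(np.concatenate(list(parts.values())))
        assert np.array_equal(all_idx, np.arange(500))

    def test_split_plane_goes_to_higher_cell(self):
        level = make_level(1)  # split planes at 4.0
        cells = level.cell_of(np.array([[4.0, 1.0, 1.0]]))
        assert tuple(cells[0]) == (1, 0, 0)

    def test_outside_box_raises(self):
        level = make_level(1)
        with pytest.raises(OutsideLatticeError):
            level.cell_of(np.array([[9.0, 1.0, 1.0]]))

    def test_box_max_face_is_closed(self):
        level = make_level(1)
        cells = level.cell_of(np.array([[8.0, 8.0, 8.0]]))
        assert tuple(cells[0]) == (1, 1, 1)


class TestCornerDisplacements:
    def test_identity_gives_zeros(self):
        level = make_level(1)
        corners = level.cell_corner_positions((0, 0, 0))
        d = rbr.corner_displacements(AffineTransform.identity(), corners)
        assert np.allclose(d, 0.0)

    def test_translation(self):
        level = make_level(1)
        corners = level.cell_corner_positions((1, 1, 1))
        T = AffineTransform.translation([0.0, 1.5, 0.0])
        assert np.allclose(rbr.corner_displacements(T, corners), [0.0, 1.5, 0.0])

    def test_scale_about_centre_antisymmetric(self):
        level = make_level(0, extent=(4.0, 6.0, 4.0))
        corners = level.cell_corner_positions((0, 0, 0))
        centre = corners.mean(axis=0)
        m = np.eye(4)
        m[1, 1] = 1.1
        m[1, 3] = -0.1 * centre[1]
        d = rbr.corner_displacements(AffineTransform(m), corners)
        # pure y displacement, antisymmetric about the centre
        assert np.allclose(d[:, [0, 2]], 0.0)
        assert np.allclose(d.sum(axis=0), 0.0, atol=1e-9)
        # magnitude = scale deviation x half the cuboid y-extent
        assert np.allclose(np.abs(d[:, 1]), 0.1 * 6.0 / 2.0)


class TestAggregation:
    def test_median_examples(self):
        level = make_level(0)
        cp = ControlPointField(level)
        for v in [(1.0, 0, 0), (3.0, 0, 0), (2.0, 0, 0)]:
            cp.add_candidate((0, 0, 0), v)
        cp.add_candidate((1, 1, 1), (5.0, 1.0, -1.0))
        cp.aggregate(fill_zero=True)
        assert np.allclose(cp.resolved[0, 0, 0], [2.0, 0, 0])
        assert np.allclose(cp.resolved[1, 1, 1], [5.0, 1.0, -1.0])
        assert np.allclose(cp.resolved[0, 1, 0], 0.0)

    def test_missing_node_raises_without_fill(self):
        cp = ControlPointField(make_level(0))
        cp.add_candidate((0, 0, 0), (1.0, 0, 0))
        with pytest.raises(ValueError, match="without any candidate"):
            cp.aggregate()

    def test_outlier_robustness(self):
        cp = ControlPointField(make_level(0))
        for v in [(1.0, 0, 0)] * 5 + [(100.0, 50.0, -50.0)]:
            cp.add_candidate((0, 0, 0), v)
        cp.aggregate(fill_zero=True)
        assert np.allclose(cp.resolved[0, 0, 0], [1.0, 0, 0], atol=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        vecs = rng.normal(size=(9, 3))
        results = []
        for perm in [np.arange(9), rng.permutation(9), rng.permutation(9)]:
            cp = ControlPointField(make_level(0))
            for v in vecs[perm]:
                cp.add_candidate((0, 0, 0), v)
            cp.aggregate(fill_zero=True)
            results.append(cp.resolved[0, 0, 0].copy())
        assert np.allclose(results[0], results[1])
        assert np.allclose(results[0], results[2])


class TestSmoothing:
    def _field_with(self, resolved):
        cp = ControlPointField(make_level(1))
        cp.resolved = resolved
        return cp

    def test_alpha_one_is_identity(self):
        rng = np.random.default_rng(2)
        resolved = rng.normal(size=(3, 3, 3, 3))
        cp = self._field_with(resolved.copy())
        rbr.smooth_control_points(cp, alpha=1.0)
        assert np.allclose(cp.resolved, resolved)

    def test_uniform_field_unchanged(self):
        resolved = np.tile([1.0, -2.0, 0.5], (3, 3, 3, 1))
        cp = self._field_with(resolved.copy())
        rbr.smooth_control_points(cp, alpha=0.3)
        assert np.allclose(cp.resolved, resolved)

    def test_half_alpha_blends_with_neighbour_mean(self):
        resolved = np.zeros((3, 3, 3, 3))
        resolved[1, 1, 1] = [2.0, 0, 0]
        cp = self._field_with(resolved)
        rbr.smooth_control_points(cp, alpha=0.5)
        # centre: own (2,0,0), 6-neighbour mean (0,0,0) -> (1,0,0)
        assert np.allclose(cp.resolved[1, 1, 1], [1.0, 0, 0])
        # boundary node (0,1,1): 5 existing neighbours, one of them the hot
        # centre -> mean 2/5, blended half-half with own 0
        assert np.allclose(cp.resolved[0, 1, 1], [0.2, 0, 0])


class TestTetrahedralization:
    def test_six_tets_tile_unit_cube(self):
        level = make_level(0, extent=(1.0, 1.0, 1.0))
        tets = rbr.tetrahedralize(level, (0, 0, 0))
        assert tets.shape == (6, 4, 3)
        vols = []
        for t in tets:
            vols.append(abs(np.linalg.det(t[1:] - t[0])) / 6.0)
        assert np.allclose(vols, 1.0 / 6.0)
        assert np.isclose(sum(vols), 1.0, atol=1e-12)

    def test_partition_of_unity_anisotropic_cell(self):
        level = make_level(1, extent=(8.0, 6.0, 4.0))
        tets = rbr.tetrahedralize(level, (1, 0, 1))
        vol = np.prod(level.cell_size)
        total = sum(abs(np.linalg.det(t[1:] - t[0])) / 6.0 for t in tets)
        assert np.isclose(total, vol, rtol=1e-9)

    def test_shared_face_triangulated_identically(self):
        level = make_level(1)

        def face_triangles(cell, axis, side):
            tris = set()
            lo, hi = level.cell_bounds(cell)
            plane = hi[axis] if side == "max" else lo[axis]
            for t in rbr.tetrahedralize(level, cell):
                on = [tuple(np.round(p, 9)) for p in t if np.isclose(p[axis], plane)]
                if len(on) == 3:
                    tris.add(frozenset(on))
            return tris

        a = face_triangles((0, 0, 0), 0, "max")
        b = face_triangles((1, 0, 0), 0, "min")
        assert a and a == b

    def test_interior_point_in_exactly_one_tet(self):
        # strict membership u[p0] > u[p1] > u[p2] holds for exactly one
        # permutation whenever the coordinates are pairwise distinct
        rng = np.random.default_rng(3)
        u = rng.uniform(0.05, 0.95, size=(200, 3))
        perms = ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0))
        for point in u:
            if min(abs(point[0] - point[1]), abs(point[1] - point[2]), abs(point[0] - point[2])) < 1e-6:
                continue
            inside = sum(1 for p in perms if point[p[0]] > point[p[1]] > point[p[2]])
            assert inside == 1

    def test_locate_matches_membership(self):
        rng = np.random.default_rng(4)
        u = rng.uniform(0.0, 1.0, size=(500, 3))
        perms = ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0))
        idx = locate_tetrahedra(u)
        for point, k in zip(u, idx):
            p = perms[k]
            assert point[p[0]] >= point[p[1]] >= point[p[2]]


class TestSolveTetraAffine:
    def unit_tet(self):
        return np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1.0]])

    def test_zero_displacement_identity(self):
        T = rbr.solve_tetra_affine(self.unit_tet(), self.unit_tet())
        assert T.is_identity(atol=1e-12)

    def test_pure_translation(self):
        rest = self.unit_tet()
        T = rbr.solve_tetra_affine(rest, rest + [0.0, 2.0, 0.0])
        assert np.allclose(T.linear, np.eye(3), atol=1e-12)
        assert np.allclose(T.offset, [0.0, 2.0, 0.0])

    def test_random_displacements_mapped_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            rest = self.unit_tet() + rng.normal(scale=0.1, size=(4, 3))
            disp = rng.normal(scale=0.2, size=(4, 3))
            T = rbr.solve_tetra_affine(rest, rest + disp)
            assert np.abs(T.apply(rest) - (rest + disp)).max() < 1e-9

    def test_degenerate_rest_raises(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(DegenerateTetrahedronError):
            rbr.solve_tetra_affine(flat, flat)


class TestDeformation:
    def test_zero_field_is_identity(self, icosphere, random_field_level):
        level, _ = random_field_level
        m = level.n_nodes
        mesh = icosphere.with_vertices(icosphere.vertices + [2.0, 2.0, 2.0])
        out = rbr.apply_deformation(mesh, level, np.zeros((m, m, m, 3)))
        assert np.allclose(out.vertices, mesh.vertices, atol=1e-12)
        assert out.faces is mesh.faces

    def test_uniform_field_translates(self, random_field_level):
        level, _ = random_field_level
        m = level.n_nodes
        field = np.tile([0.0, 1.0, 0.0], (m, m, m, 1))
        rng = np.random.default_rng(6)
        pts = level.origin + rng.uniform(0, 1, size=(100, 3)) * level.extent
        out = deform_points(pts, level, field)
        assert np.allclose(out, pts + [0.0, 1.0, 0.0], atol=1e-12)

    def test_matches_barycentric_oracle(self, random_field_level):
        level, resolved = random_field_level
        rng = np.random.default_rng(7)
        pts = level.origin + rng.uniform(0, 1, size=(300, 3)) * level.extent
        out = deform_points(pts, level, resolved)

        # independent oracle: barycentric interpolation inside the located tet
        for point, image in zip(pts, out):
            cell = level.cell_of(point[None])[0]
            u = (point - level.origin) / level.cell_size - cell
            tet = locate_tetrahedra(np.clip(u, 0, 1)[None])[0]
            nodes = cell + KUHN_TET_CORNERS[tet]
            rest = level.origin + nodes * level.cell_size
            disp = resolved[nodes[:, 0], nodes[:, 1], nodes[:, 2]]
            A = np.vstack([rest.T, np.ones(4)])
            w = np.linalg.solve(A, np.append(point, 1.0))
            expect = point + w @ disp
            assert np.abs(image - expect).max() < 1e-9

    def test_continuity_across_shared_faces(self, random_field_level):
        # 1000 random points on internal faces deform identically from the
        # tetrahedra of both adjacent cuboids
        level, resolved = random_field_level
        rng = np.random.default_rng(8)
        n = level.n_cells
        checked = 0
        while checked < 1000:
            axis = rng.integers(3)
            cell = rng.integers(0, n, size=3)
            if cell[axis] == n - 1:
                continue
            lo, hi = level.cell_bounds(cell)
            point = lo + rng.uniform(0, 1, size=3) * (hi - lo)
            point[axis] = hi[axis]  # on the shared face
            other = cell.copy()
            other[axis] += 1
            img_a = deform_points(point[None], level, resolved, cells=cell[None])
            img_b = deform_points(point[None], level, resolved, cells=other[None])
            assert np.abs(img_a - img_b).max() < 1e-9
            checked += 1

    def test_positive_jacobians_for_small_field(self, random_field_level):
        level, resolved = random_field_level
        for cx in range(level.n_cells):
            for cy in range(level.n_cells):
                for cz in range(level.n_cells):
                    for T in cell_tet_affines(level, resolved, (cx, cy, cz)):
                        assert np.linalg.det(T.linear) > 0
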