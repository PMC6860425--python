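"""Recursive cuboid lattice and topology-preserving mesh deformation.

At depth ``d`` the registration bounding box is partitioned into ``2^d``
cuboids per axis.  Each cuboid's eight corners are control points shared with
the adjacent cuboids; every local registration deposits a candidate
displacement vector at each corner of its cuboid, the candidates are reduced
by a componentwise median, optionally relaxed toward the mean of the
6-connected neighbouring nodes, and the resolved node displacements are turned
into a continuous piecewise-affine warp by splitting every cuboid into six
tetrahedra (Kuhn subdivision along the common main diagonal) and solving the
exactly determined 4-point affine system per tetrahedron.  Because adjacent
cuboids split their shared face with the same diagonal, the per-tetrahedron
affines agree on shared faces and the warp is globally continuous.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .geometry import AffineTransform


class OutsideLatticeError(ValueError):
    """A point lies outside the lattice bounding box."""


class DegenerateTetrahedronError(ValueError):
    """Rest tetrahedron has (near-)zero signed volume."""


# corner order: binary (x, y, z) offsets, x slowest
UNIT_CORNERS = np.array(
    [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=np.int64
)

# Kuhn subdivision: one tetrahedron per permutation of the axes, all sharing
# the main diagonal (0,0,0)-(1,1,1).  Tet for permutation p is the region
# u[p0] >= u[p1] >= u[p2]; its corners walk the cube edges in that order.
KUHN_PERMS = tuple(itertools.permutations((0, 1, 2)))


def _tet_unit_corners(perm) -> np.ndarray:
    e = np.eye(3, dtype=np.int64)
    c0 = np.zeros(3, dtype=np.int64)
    c1 = e[perm[0]]
    c2 = e[perm[0]] + e[perm[1]]
    c3 = np.ones(3, dtype=np.int64)
    return np.stack([c0, c1, c2, c3])


KUHN_TET_CORNERS = np.stack([_tet_unit_corners(p) for p in KUHN_PERMS])  # (6,4,3)

# lookup: encoded descending argsort order -> Kuhn tetrahedron index
_PERM_LOOKUP = np.full(27, -1, dtype=np.int64)
for _i, _p in enumerate(KUHN_PERMS):
    _PERM_LOOKUP[_p[0] * 9 + _p[1] * 3 + _p[2]] = _i


@dataclass(frozen=True)
class LatticeLevel:
    """The ``2^depth``-per-axis cuboid partition of a bounding box."""

    origin: np.ndarray  # (3,) world mm, min corner
    extent: np.ndarray  # (3,) world mm, full box size
    depth: int

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "extent", np.asarray(self.extent, dtype=float))
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if np.any(self.extent <= 0):
            raise ValueError("bounding box must be non-empty")

    @property
    def n_cells(self) -> int:
        """Cuboids per axis."""
        return 2**self.depth

    @property
    def n_nodes(self) -> int:
        """Control points per axis."""
        return self.n_cells + 1

    @property
    def cell_size(self) -> np.ndarray:
        return self.extent / self.n_cells

    def node_positions(self) -> np.ndarray:
        """(m, m, m, 3) world positions of the control-point grid."""
        m = self.n_nodes
        idx = np.stack(
            np.meshgrid(np.arange(m), np.arange(m), np.arange(m), indexing="ij"),
            axis=-1,
        ).astype(float)
        return self.origin + idx * self.cell_size

    def cell_of(self, points: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        """(K, 3) integer cuboid indices containing each point.

        Half-open rule: a point exactly on an internal split plane belongs to
        the higher-index cuboid; the box's max faces are closed.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        lo, hi = self.origin, self.origin + self.extent
        if np.any(p < lo - atol) or np.any(p > hi + atol):
            raise OutsideLatticeError("point outside the lattice bounding box")
        idx = np.floor((p - lo) / self.cell_size).astype(np.int64)
        return np.clip(idx, 0, self.n_cells - 1)

    def cell_bounds(self, cell) -> tuple[np.ndarray, np.ndarray]:
        cell = np.asarray(cell, dtype=float)
        lo = self.origin + cell * self.cell_size
        return lo, lo + self.cell_size

    def cell_corner_nodes(self, cell) -> np.ndarray:
        """(8, 3) node indices of a cuboid's corners (shared between cells)."""
        return np.asarray(cell, dtype=np.int64) + UNIT_CORNERS

    def cell_corner_positions(self, cell) -> np.ndarray:
        return self.origin + self.cell_corner_nodes(cell) * self.cell_size

    def cell_flat(self, cells: np.ndarray) -> np.ndarray:
        c = np.atleast_2d(cells)
        n = self.n_cells
        return (c[:, 0] * n + c[:, 1]) * n + c[:, 2]


def build_lattice(
    lo: np.ndarray, hi: np.ndarray, max_depth: int
) -> list[LatticeLevel]:
    """Lattice levels for depths 0..max_depth over one bounding box."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    return [LatticeLevel(lo, hi - lo, d) for d in range(max_depth + 1)]


def partition_vertices(vertices: np.ndarray, level: LatticeLevel) -> dict:
    """Map flat cuboid index -> vertex index array (exactly one per vertex)."""
    cells = level.cell_of(vertices)
    flat = level.cell_flat(cells)
    order = np.argsort(flat, kind="stable")
    out: dict[int, np.ndarray] = {}
    for key, grp in itertools.groupby(order, key=lambda i: flat[i]):
        out[int(key)] = np.fromiter(grp, dtype=np.int64)
    return out


def corner_displacements(
    transform: AffineTransform, corner_positions: np.ndarray
) -> np.ndarray:
    """Displacement T.p - p at each of a cuboid's 8 corner positions."""
    return transform.apply(corner_positions) - corner_positions


class ControlPointField:
    """Candidate displacement lists and the resolved field on one level.

    Nodes shared by adjacent cuboids are stored once (identified by their
    integer grid index), which is what guarantees continuity of the warp.
    """

    def __init__(self, level: LatticeLevel):
        self.level = level
        self._candidates: dict[tuple[int, int, int], list] = defaultdict(list)
        self.resolved: np.ndarray | None = None  # (m, m, m, 3)

    def add_candidate(self, node, vector) -> None:
        self._candidates[tuple(int(i) for i in node)].append(
            np.asarray(vector, dtype=float)
        )

    def add_cell_candidates(self, cell, vectors: np.ndarray) -> None:
        """Deposit one displacement vector at each of a cuboid's 8 corners."""
        nodes = self.level.cell_corner_nodes(cell)
        vectors = np.asarray(vectors, dtype=float)
        for node, vec in zip(nodes, vectors):
            self.add_candidate(node, vec)

    def candidates(self, node) -> list:
        return self._candidates[tuple(int(i) for i in node)]

    def aggregate(self, fill_zero: bool = False) -> np.ndarray:
        """Componentwise median of each node's candidate list.

        With ``fill_zero`` nodes that received no candidates resolve to zero
        displacement (used by the driver: cells without any vertices cast no
        vote, and lattice nodes surrounded only by empty space stay put).
        Otherwise a node without candidates is an error.
        """
        m = self.level.n_nodes
        resolved = np.zeros((m, m, m, 3))
        seen = np.zeros((m, m, m), dtype=bool)
        for node, vecs in self._candidates.items():
            resolved[node] = np.median(np.asarray(vecs), axis=0)
            seen[node] = True
        if not fill_zero and not seen.all():
            raise ValueError("control point without any candidate displacement")
        self.resolved = resolved
        return resolved


def _neighbour_mean(grid: np.ndarray) -> np.ndarray:
    """Mean over existing 6-connected neighbours of each lattice node."""
    acc = np.zeros_like(grid)
    cnt = np.zeros(grid.shape[:3])
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        acc[tuple(sl_lo)] += grid[tuple(sl_hi)]
        cnt[tuple(sl_lo)] += 1
        acc[tuple(sl_hi)] += grid[tuple(sl_lo)]
        cnt[tuple(sl_hi)] += 1
    return acc / cnt[..., None]


def smooth_control_points(
    field: ControlPointField, alpha: float, iterations: int = 1
) -> np.ndarray:
    """Relax resolved displacements toward their neighbourhood mean.

    Synchronous update  d <- alpha * d + (1 - alpha) * M(x)  where M(x) is the
    mean of the 6-connected neighbouring nodes (boundary nodes average over
    the neighbours that exist).  alpha = 1 keeps pure local matching.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if field.resolved is None:
        raise ValueError("aggregate() must run before smoothing")
    out = field.resolved
    for _ in range(iterations):
        out = alpha * out + (1.0 - alpha) * _neighbour_mean(out)
    field.resolved = out
    return out


def tetrahedralize(level: LatticeLevel, cell) -> np.ndarray:
    """(6, 4, 3) rest corner positions of a cuboid's Kuhn tetrahedra."""
    lo, _ = level.cell_bounds(cell)
    return lo + KUHN_TET_CORNERS * level.cell_size


def solve_tetra_affine(rest: np.ndarray, displaced: np.ndarray) -> AffineTransform:
    """The unique affine mapping 4 rest corners onto 4 displaced corners.

    With four non-coplanar points the homogeneous system T R = D is exactly
    determined; adjacent tetrahedra sharing a face therefore agree on that
    face, which a least-squares 8-corner fit would not guarantee.
    """
    rest = np.asarray(rest, dtype=float)
    displaced = np.asarray(displaced, dtype=float)
    if rest.shape != (4, 3) or displaced.shape != (4, 3):
        raise ValueError("rest and displaced must be (4, 3)")
    R = np.vstack([rest.T, np.ones(4)])
    scale = max(np.abs(rest).max(), 1.0)
    if abs(np.linalg.det(R)) < 1e-12 * scale**3:
        raise DegenerateTetrahedronError("rest tetrahedron is degenerate")
    D = np.vstack([displaced.T, np.ones(4)])
    T = D @ np.linalg.inv(R)
    T[3] = (0.0, 0.0, 0.0, 1.0)
    return AffineTransform(T)


def locate_tetrahedra(unit_coords: np.ndarray) -> np.ndarray:
    """Kuhn tetrahedron index (0..5) containing each unit-cube point.

    Membership in tet ``perm`` is u[p0] >= u[p1] >= u[p2]; ties on a shared
    face resolve by stable descending argsort, and either choice yields the
    same image because adjacent tetra affines agree there.
    """
    u = np.atleast_2d(unit_coords)
    order = np.argsort(-u, axis=1, kind="stable")
    code = order[:, 0] * 9 + order[:, 1] * 3 + order[:, 2]
    return _PERM_LOOKUP[code]


def cell_tet_affines(
    level: LatticeLevel, resolved: np.ndarray, cell
) -> list[AffineTransform]:
    """The six tetrahedron affines of one cuboid under a resolved field."""
    cell = np.asarray(cell, dtype=np.int64)
    out = []
    for t in range(6):
        nodes = cell + KUHN_TET_CORNERS[t]
        rest = level.origin + nodes * level.cell_size
        disp = resolved[nodes[:, 0], nodes[:, 1], nodes[:, 2]]
        out.append(solve_tetra_affine(rest, rest + disp))
    return out


def deform_points(
    points: np.ndarray,
    level: LatticeLevel,
    resolved: np.ndarray,
    cells: np.ndarray | None = None,
) -> np.ndarray:
    """Apply the piecewise-affine warp of a resolved field to points.

    Each point is transformed by the affine of the Kuhn tetrahedron containing
    it within its cuboid.  ``cells`` overrides point location (used to verify
    continuity from both sides of a shared face).
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if cells is None:
        cells = level.cell_of(p)
    else:
        cells = np.atleast_2d(np.asarray(cells, dtype=np.int64))
        if len(cells) == 1 and len(p) > 1:
            cells = np.repeat(cells, len(p), axis=0)
    u = (p - level.origin) / level.cell_size - cells
    u = np.clip(u, 0.0, 1.0)  # guard float fuzz on cell faces
    tet = locate_tetrahedra(u)
    key = level.cell_flat(cells) * 6 + tet
    out = np.empty_like(p)
    for k in np.unique(key):
        sel = key == k
        cell = cells[np.argmax(sel)]
        t = int(k % 6)
        nodes = cell + KUHN_TET_CORNERS[t]
        rest = level.origin + nodes * level.cell_size
        disp = resolved[nodes[:, 0], nodes[:, 1], nodes[:, 2]]
        T = solve_tetra_affine(rest, rest + disp)
        out[sel] = T.apply(p[sel])
    return out


def apply_deformation(mesh, level: LatticeLevel, resolved: np.ndarray):
    """Deformed copy of a mesh; faces are shared unchanged."""
    return mesh.with_vertices(deform_points(mesh.vertices, level, resolved))
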