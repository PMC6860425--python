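"""Surface meshes, intensity volumes and affine transforms.

All registration math runs in world millimetres.  A :class:`Volume` carries a
NIfTI-style voxel-to-world affine (0-based voxel indices); intensity lookups at
non-integer voxel coordinates use trilinear interpolation.  A
:class:`SurfaceMesh` is the triangulated grey--white boundary being deformed;
downstream laminar analysis requires it to stay a topological sphere, so the
topology report computed here is re-checked after every deformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates


class TopologyError(ValueError):
    """A mesh violates the closed two-manifold requirement."""


@dataclass(frozen=True)
class TopologyReport:
    """Connectivity summary of a triangle mesh."""

    is_closed: bool
    is_manifold: bool
    euler_characteristic: int
    n_vertices: int
    n_edges: int
    n_faces: int
    n_flipped_faces: int

    @property
    def is_sphere(self) -> bool:
        """Closed orientable 2-manifold with the topology of a sphere."""
        return self.is_closed and self.is_manifold and self.euler_characteristic == 2


class SurfaceMesh:
    """Triangulated surface: vertices in world mm plus 0-based face indices.

    Parameters
    ----------
    vertices : (N, 3) array_like
        Vertex positions in world millimetres.
    faces : (M, 3) array_like
        Vertex index triples.  Consistent counter-clockwise winding (seen from
        outside) makes :meth:`vertex_normals` point outward.
    validate : bool
        Run the cheap structural checks (index range, degenerate faces).
        Full manifoldness is checked separately by :meth:`check_topology`.
    """

    def __init__(self, vertices, faces, validate: bool = True):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64)
        self._normals: np.ndarray | None = None
        if validate:
            self._validate()

    # -- construction / basic structure -------------------------------------

    def _validate(self) -> None:
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (M, 3)")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face indices out of range")
            distinct = (
                (self.faces[:, 0] != self.faces[:, 1])
                & (self.faces[:, 1] != self.faces[:, 2])
                & (self.faces[:, 0] != self.faces[:, 2])
            )
            if not distinct.all():
                raise ValueError("degenerate faces (repeated vertex index)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        """New mesh with moved vertices; the face array is shared unchanged."""
        out = SurfaceMesh.__new__(SurfaceMesh)
        out.vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        out.faces = self.faces
        out._normals = None
        if out.vertices.shape != self.vertices.shape:
            raise ValueError("vertex array shape must be preserved")
        return out

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    # -- normals -------------------------------------------------------------

    @property
    def vertex_normals(self) -> np.ndarray:
        """Outward per-vertex unit normals (area-weighted incident faces)."""
        if self._normals is None:
            self._normals = vertex_normals(self)
        return self._normals

    # -- orientation & topology ----------------------------------------------

    def signed_volume(self) -> float:
        """Signed enclosed volume; positive for outward-wound closed meshes."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def oriented(self) -> "SurfaceMesh":
        """Return a copy with outward winding (signed-volume test).

        Winding is fixed at load time: if the mesh encloses negative volume
        (i.e. the majority of faces disagree with the outward convention) all
        faces are flipped.
        """
        if self.signed_volume() < 0:
            return SurfaceMesh(self.vertices, self.faces[:, ::-1])
        return self

    def check_topology(self) -> TopologyReport:
        return check_topology(self)


def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex outward unit normals.

    Area-weighted average of incident face normals under the mesh's face
    winding.  Raises :class:`TopologyError` if any vertex has a vanishing
    normal (incident faces cancel), which indicates a non-manifold
    configuration for the meshes this package works with.
    """
    v, f = mesh.vertices, mesh.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    fn = np.cross(b - a, c - a)  # magnitude = 2 * face area
    acc = np.zeros_like(v)
    for k in range(3):
        np.add.at(acc, f[:, k], fn)
    norms = np.linalg.norm(acc, axis=1)
    if np.any(norms < 1e-300):
        raise TopologyError("vertex with vanishing accumulated normal")
    return acc / norms[:, None]


def check_topology(mesh: SurfaceMesh) -> TopologyReport:
    """Connectivity report: closedness, manifoldness, Euler characteristic.

    ``n_flipped_faces`` counts faces whose winding disagrees with the majority
    orientation: on a consistently wound mesh every directed edge occurs once,
    so a flipped face shows up through duplicated directed edges.
    """
    f = mesh.faces
    directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    _, und_counts = np.unique(und, axis=0, return_counts=True)
    is_manifold = bool((und_counts <= 2).all())
    is_closed = bool((und_counts == 2).all())
    n_edges = len(und_counts)

    _, inv, dir_counts = np.unique(
        directed, axis=0, return_inverse=True, return_counts=True
    )
    dup = (dir_counts[inv] >= 2).reshape(3, len(f))
    n_flipped = int((dup.sum(axis=0) >= 2).sum())
    # dup counts both members of a duplicated pair; with majority-correct
    # winding the flipped face triggers all three of its edges while each
    # correct neighbour triggers only one.
    return TopologyReport(
        is_closed=is_closed,
        is_manifold=is_manifold,
        euler_characteristic=mesh.n_vertices - n_edges + mesh.n_faces,
        n_vertices=mesh.n_vertices,
        n_edges=n_edges,
        n_faces=mesh.n_faces,
        n_flipped_faces=n_flipped,
    )


class AffineTransform:
    """4x4 homogeneous transform acting on world-mm column vectors."""

    __slots__ = ("matrix",)

    def __init__(self, matrix):
        m = np.asarray(matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("last row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-300:
            raise ValueError("affine matrix is singular")
        m = m.copy()
        m[3] = (0.0, 0.0, 0.0, 1.0)
        self.matrix = m

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def translation(cls, t) -> "AffineTransform":
        m = np.eye(4)
        m[:3, 3] = t
        return cls(m)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def offset(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return p @ self.linear.T + self.offset

    def transform_normals(self, normals: np.ndarray) -> np.ndarray:
        """Transform unit normals (inverse-transpose rule, renormalised)."""
        n = np.atleast_2d(np.asarray(normals, dtype=np.float64))
        out = n @ np.linalg.inv(self.linear)
        return out / np.linalg.norm(out, axis=1, keepdims=True)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Transform applying ``other`` first, then ``self``."""
        return AffineTransform(self.matrix @ other.matrix)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def is_identity(self, atol: float = 1e-12) -> bool:
        return np.allclose(self.matrix, np.eye(4), atol=atol)

    def __repr__(self) -> str:  # pragma: no cover
        return f"AffineTransform(\n{self.matrix!r})"


class Volume:
    """3-D scalar intensity grid with a voxel-index-to-world-mm affine."""

    def __init__(self, data, affine):
        self.data = np.ascontiguousarray(data, dtype=np.float64)
        self.affine = np.asarray(affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-300:
            raise ValueError("affine is singular")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be strictly positive")
        self._inv_affine = np.linalg.inv(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """mm per voxel along each index axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return p @ self._inv_affine[:3, :3].T + self._inv_affine[:3, 3]

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        i = np.atleast_2d(np.asarray(indices, dtype=np.float64))
        return i @ self.affine[:3, :3].T + self.affine[:3, 3]

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of world points whose voxel coordinates lie on-grid."""
        v = self.world_to_voxel(points)
        hi = np.array(self.shape) - 1
        return np.all((v >= 0) & (v <= hi), axis=1)

    def sample(self, points: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Trilinear intensity at world points; ``fill`` outside the grid."""
        v = self.world_to_voxel(points)
        return map_coordinates(self.data, v.T, order=1, mode="constant", cval=fill)

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box of the voxel-centre grid."""
        n = np.array(self.shape) - 1
        corners = np.array(
            [[i, j, k] for i in (0, n[0]) for j in (0, n[1]) for k in (0, n[2])],
            dtype=float,
        )
        w = self.voxel_to_world(corners)
        return w.min(axis=0), w.max(axis=0)


def world_to_voxel(volume: Volume, points: np.ndarray) -> np.ndarray:
    """Continuous voxel coordinates of world-mm points."""
    return volume.world_to_voxel(points)
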