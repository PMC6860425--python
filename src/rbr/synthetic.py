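"""Synthetic gold standards: phantom anatomy, rendered volumes, distortions.

The validation design emulated here: render a volume with distinct
white/grey/CSF intensities from a known grey--white boundary surface, displace
that surface along one axis by a smooth field-map-like voxel displacement map
(cubic-root tapered, so displacements are pushed away from zero into a bimodal
distribution), then ask the registration to find its way back.  Because the
true surface is known exactly, residual statistics are exact.

The phantom is a gyrified sphere (radial sinusoidal perturbation of an
icosphere) rather than a brain atlas so that everything is generated in
memory; it is star-shaped by construction, hence free of self-intersections,
and trivially a topological sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.interpolate import RegularGridInterpolator

from .geometry import SurfaceMesh, Volume

_AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


@dataclass
class PhantomSpec:
    """Gyrified-sphere phantom: geometry, tissue intensities, sampling.

    The grey--white boundary is the perturbed sphere
    ``r(u) = radius + amplitude * sin(f u_x) sin(f u_y) sin(f u_z)`` over unit
    directions u; the rendered volume is white inside it, grey in a shell of
    ``grey_thickness`` outside, CSF beyond, plus optional Gaussian noise.
    Intensities default to a T2*-like ordering (grey brightest).

    The default fold wavelength (~2 pi radius / frequency ~ 12.6 mm) puts
    folds inside every quarter-box cuboid, so local boundary fits see
    normals at many orientations, as they do on real cortex; without folds,
    patches whose normals are perpendicular to the distortion axis carry no
    information about displacement along it.  The matching amplitude keeps
    the fold-crest curvature radius near 3 mm, comparable to a gyral crown;
    much sharper crests put the boundary's own curvature inside the sampling
    projection and bias the contrast optimum.
    """

    radius: float = 28.0
    gyrification_amplitude: float = 1.2
    gyrification_frequency: float = 14.0
    subdivisions: int = 5
    white_intensity: float = 50.0
    grey_intensity: float = 150.0
    csf_intensity: float = 80.0
    grey_thickness: float = 3.0
    noise_sd: float = 0.0
    voxel_size: float = 0.9
    margin_voxels: int = 3
    seed: int = 0

    def __post_init__(self):
        if not self.radius > self.grey_thickness > 0:
            raise ValueError("need radius > grey_thickness > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.gyrification_amplitude < 0:
            raise ValueError("gyrification amplitude must be >= 0")
        if self.gyrification_amplitude >= 0.5 * self.radius:
            # steep radial folds start to approach self-intersection of the
            # offset grey shell; refuse rather than render a broken phantom
            raise ValueError("gyrification amplitude too large for the radius")


def _radial_perturbation(spec: PhantomSpec, unit_dirs: np.ndarray) -> np.ndarray:
    f = spec.gyrification_frequency
    u = unit_dirs
    return spec.gyrification_amplitude * (
        np.sin(f * u[..., 0]) * np.sin(f * u[..., 1]) * np.sin(f * u[..., 2])
    )


def make_phantom(spec: PhantomSpec) -> tuple[SurfaceMesh, Volume]:
    """Phantom boundary mesh plus the volume rendered from it.

    The boundary passes exactly through the white/grey intensity step: a voxel
    centre at radial distance rho in direction u is white when
    ``rho <= radius + amplitude * g(u)``.
    """
    ico = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
    u = np.asarray(ico.vertices, dtype=float)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = spec.radius + _radial_perturbation(spec, u)
    mesh = SurfaceMesh(u * r[:, None], np.asarray(ico.faces)).oriented()

    half = (
        spec.radius
        + spec.gyrification_amplitude
        + spec.grey_thickness
        + spec.margin_voxels * spec.voxel_size
    )
    n = int(np.ceil(2 * half / spec.voxel_size)) + 1
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    affine[:3, 3] = -0.5 * (n - 1) * spec.voxel_size  # grid centred on origin

    ax = affine[0, 3] + spec.voxel_size * np.arange(n)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    rho = np.sqrt(X**2 + Y**2 + Z**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.stack([X, Y, Z], axis=-1) / np.where(rho == 0, 1.0, rho)[..., None]
    rb = spec.radius + _radial_perturbation(spec, dirs)
    data = np.full((n, n, n), spec.csf_intensity)
    data[rho <= rb + spec.grey_thickness] = spec.grey_intensity
    data[rho <= rb] = spec.white_intensity
    volume = Volume(data, affine)
    if spec.noise_sd > 0:
        volume = salt_volume(volume, spec.noise_sd, spec.seed)
    return mesh, volume


@dataclass
class DistortionSpec:
    """Smooth field-map-like displacement along one axis.

    Seeded Gaussian values on a coarse control grid are interpolated
    trilinearly over the volume; with ``taper`` the values pass through a
    signed cubic root (pushing mass away from zero, as when tapering a
    measured voxel displacement map), and the whole field is rescaled so the
    mean absolute displacement over the mesh vertices equals
    ``target_mean_abs`` mm.

    The default control spacing gives the field only a couple of lobes
    across the phantom, mirroring how a B0 field map varies over a head:
    smoothly, at a scale much larger than the finest registration cuboid.
    The cubic root still introduces steep transitions wherever the
    underlying field crosses zero — displacement structure there is locally
    too sharp for any smooth lattice to invert, exactly as for a tapered
    measured displacement map.
    """

    axis: str | int = "y"
    control_spacing: float = 60.0
    amplitude: float = 1.0
    taper: bool = True
    target_mean_abs: float | None = 2.56
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.axis not in _AXES:
            raise ValueError("axis must be one of x, y, z")
        if self.target_mean_abs is not None and self.target_mean_abs < 0:
            raise ValueError("target_mean_abs must be >= 0")

    @property
    def axis_index(self) -> int:
        return _AXES[self.axis]


@dataclass
class DisplacementField:
    """Scalar displacement (mm) along one axis, on a volume grid."""

    volume: Volume
    axis: int

    def sample(self, points: np.ndarray) -> np.ndarray:
        return self.volume.sample(points, fill=0.0)


def make_distortion(
    spec: DistortionSpec,
    volume: Volume,
    mesh: SurfaceMesh | None = None,
) -> DisplacementField:
    """Voxel-displacement-map-like field over a volume's grid.

    Calibration to ``target_mean_abs`` needs the mesh whose vertices define
    the average; without a mesh the raw (tapered) field is returned.
    """
    lo, hi = volume.world_bounds()
    shape = volume.shape
    rng = np.random.default_rng(spec.seed)

    if spec.amplitude == 0:
        values = np.zeros(shape)
    else:
        axes_ctrl = []
        n_ctrl = []
        for a in range(3):
            # control nodes delimit round(extent / spacing) >= 1 intervals
            k = max(2, int(np.round((hi[a] - lo[a]) / spec.control_spacing)) + 1)
            axes_ctrl.append(np.linspace(lo[a], hi[a], k))
            n_ctrl.append(k)
        ctrl = rng.normal(0.0, spec.amplitude, size=tuple(n_ctrl))
        interp = RegularGridInterpolator(
            axes_ctrl, ctrl, method="linear", bounds_error=False, fill_value=0.0
        )
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        world = volume.voxel_to_world(idx)
        values = interp(world).reshape(shape)
        if spec.taper:
            values = np.cbrt(values)
        if spec.target_mean_abs is not None and mesh is not None:
            probe = Volume(values, volume.affine)
            m = float(np.abs(probe.sample(mesh.vertices)).mean())
            values = values * (spec.target_mean_abs / m) if m > 0 else values * 0.0

    return DisplacementField(Volume(values, volume.affine), spec.axis_index)


def distort_mesh(mesh: SurfaceMesh, field: DisplacementField) -> SurfaceMesh:
    """Move each vertex by the field value at its position, along the axis."""
    delta = field.sample(mesh.vertices)
    v = mesh.vertices.copy()
    v[:, field.axis] += delta
    return mesh.with_vertices(v)


def salt_volume(volume: Volume, noise_sd: float, seed: int) -> Volume:
    """Copy of a volume with seeded additive Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return Volume(volume.data.copy(), volume.affine)
    rng = np.random.default_rng(seed)
    return Volume(
        volume.data + rng.normal(0.0, noise_sd, size=volume.shape), volume.affine
    )


@dataclass
class GoldStandard:
    """A complete recovery experiment: truth, distorted start, target volume."""

    truth: SurfaceMesh
    distorted: SurfaceMesh
    volume: Volume
    field: DisplacementField


def make_gold_standard(
    phantom: PhantomSpec, distortion: DistortionSpec
) -> GoldStandard:
    """Phantom + rendered volume + calibrated distortion + displaced surface."""
    mesh, volume = make_phantom(phantom)
    fld = make_distortion(distortion, volume, mesh)
    return GoldStandard(
        truth=mesh, distorted=distort_mesh(mesh, fld), volume=volume, field=fld
    )
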