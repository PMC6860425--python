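"""Recursion controller for recursive boundary registration (RBR).

One *depth pass* partitions the mesh vertices over the ``2^d``-per-axis
cuboids, fits a constrained affine per cuboid (and per each of its six
half-split subregions, for robustness), deposits the implied corner
displacements on the shared control points, takes the componentwise median
per node, relaxes the field toward neighbouring nodes, and warps the mesh
through the per-tetrahedron affines.  Regions with too few vertices fall back
to the identity and contribute zero displacement vectors, so low-contrast or
empty territory defaults to "no change".  Depths run from the whole-box scale
downward until a cuboid edge falls below a minimum size in voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bbr import BbrParams, DofSpec, LocalFit, fit_local_transform
from .geometry import SurfaceMesh, Volume
from .lattice import (
    ControlPointField,
    LatticeLevel,
    apply_deformation,
    cell_tet_affines,
    corner_displacements,
    partition_vertices,
    smooth_control_points,
)


class DisjointInputsError(ValueError):
    """Mesh and volume bounding boxes do not intersect."""


@dataclass
class RbrConfig:
    """All tunables of a recursive boundary registration run.

    dof : degrees of freedom fitted per region; default translation + scale
        along y (the phase-encoding axis).
    alpha : balance between local matching (1) and lattice smoothness (0)
        in the control-point relaxation; default 0.9 favours specificity.
    min_voxel_size : recursion stops once a cuboid edge would span fewer
        voxels than this on any axis (default 4).
    min_vertices : regions with fewer vertices fall back to the identity
        (default 100).
    max_depth : optional hard cap on the recursion depth.
    bbr : boundary sampling / cost parameters.
    projection_schedule : optional per-depth boundary projection distances in
        mm (depth d uses entry d, the last entry repeating beyond the list;
        the linear initialisation uses the first entry).  Long projections at
        coarse depths give capture range for multi-millimetre residuals;
        projections just over one voxel at fine depths keep the cost
        sensitive to sub-voxel misplacement.  None uses
        ``bbr.projection_distance`` at every depth.
    pass_plan : optional explicit sequence of (depth, projection_mm) pairs
        overriding the automatic largest-to-smallest sweep.  Repeating a
        depth with descending projections walks residuals down through the
        cost's sensitivity annulus; passes whose cuboids would fall below
        ``min_voxel_size`` are skipped.
    init_linear : run a whole-mesh linear BBR before the recursion.
    init_dof : "rigid" (6 DoF), "affine9" (translation+rotation+scale), or
        "dof" to restrict the initialisation to the same axes as the local
        fits.  With a purely phase-encoding-axis distortion a free rotation
        can lower the cost by sliding the surface tangentially along itself
        — invisible to any boundary cost, but pure error in the vertex
        correspondence — so axis-matched initialisation is preferred when
        the distortion axis is known.
    smooth_iterations : how many times the control-point relaxation runs.
    nm_maxiter : optional cap on simplex iterations per local fit.
    min_cost_improvement : a region's fitted transform is only accepted if
        it lowers the cost by at least this much; sub-threshold gains (on
        already-registered data they are below 1e-5) reflect discretisation
        bias and optimizer flat-valley drift, so the region defaults to "no
        change" instead.
    seed : reserved for stochastic extensions (restarts); the default
        pipeline is fully deterministic.
    """

    dof: DofSpec = field(default_factory=DofSpec)
    alpha: float = 0.9
    min_voxel_size: float = 4.0
    min_vertices: int = 100
    max_depth: int | None = None
    bbr: BbrParams = field(default_factory=BbrParams)
    projection_schedule: tuple[float, ...] | None = None
    pass_plan: tuple[tuple[int, float], ...] | None = None
    init_linear: bool = True
    init_dof: str = "rigid"
    smooth_iterations: int = 1
    nm_maxiter: int | None = None
    min_cost_improvement: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.min_vertices < 4:
            raise ValueError("min_vertices must be >= 4")
        if self.min_voxel_size < 1:
            raise ValueError("min_voxel_size must be >= 1")
        if self.init_dof not in ("rigid", "affine9", "dof"):
            raise ValueError("init_dof must be 'rigid', 'affine9' or 'dof'")
        if self.pass_plan is not None:
            plan = tuple((int(d), float(p)) for d, p in self.pass_plan)
            if any(d < 0 or p <= 0 for d, p in plan):
                raise ValueError("pass_plan needs depth >= 0 and projection > 0")
            self.pass_plan = plan
        if self.projection_schedule is not None:
            sched = tuple(float(p) for p in self.projection_schedule)
            if not sched or any(p <= 0 for p in sched):
                raise ValueError("projection_schedule entries must be > 0")
            self.projection_schedule = sched

    def bbr_at_depth(self, depth: int) -> BbrParams:
        """Sampling parameters for one depth (projection schedule applied)."""
        if self.projection_schedule is None:
            return self.bbr
        sched = self.projection_schedule
        proj = sched[min(depth, len(sched) - 1)]
        return replace(self.bbr, projection_distance=proj)

    # coarse-to-fine projection ladder, in units of the largest voxel edge
    _PROJECTION_LADDER = (2.8, 2.0, 1.55, 1.25)

    @classmethod
    def scheduled_for_voxel(cls, voxel_size_mm: float, **kwargs) -> "RbrConfig":
        """Config with a voxel-scaled coarse-to-fine projection schedule.

        Depth 0 samples at 2.8 voxels (capture range for multi-mm residuals),
        tapering to 1.25 voxels at depth >= 3 (sub-voxel sensitivity while
        both samples still reach pure tissue past the partial-volume band).
        """
        sched = tuple(r * float(voxel_size_mm) for r in cls._PROJECTION_LADDER)
        kwargs.setdefault("projection_schedule", sched)
        return cls(**kwargs)

    @classmethod
    def for_noiseless_contrast(cls, voxel_size_mm: float, **kwargs) -> "RbrConfig":
        """Config tuned for noiseless, high-contrast (synthetic) volumes.

        On ideal rendered data the percent contrast across the boundary is an
        order of magnitude larger than in vivo and there is no noise to
        dither the saturating non-linearity, so the reference slope of 0.5
        leaves the cost exactly flat around the optimum; a slope of 0.03
        keeps the tanh in its sensitive zone (slope * Q ~ 3 at the boundary).
        The pass plan starts at quarter-box cuboids (a global axis-matched
        linear fit replaces the coarser depths, whose long-range corner
        extrapolations inject shape error that finer passes cannot observe)
        and repeats the finest admissible depth with projections descending
        from 1.55 to 1.05 voxels, tracking residuals down through the cost's
        partial-volume sensitivity band.
        """
        v = float(voxel_size_mm)
        # the linear-init projection matches the first ladder rung: longer
        # projections reach the grey/CSF edge of a ~3 mm shell (projection +
        # partial-volume band), whose opposite-signed gradient biases the
        # global fit toward compressing the surface
        kwargs.setdefault("bbr", BbrParams(projection_distance=1.55 * v, slope=0.03))
        kwargs.setdefault(
            "pass_plan",
            (
                (2, 1.55 * v),
                (2, 1.55 * v),
                (3, 1.55 * v),
                (3, 1.25 * v),
                (3, 1.05 * v),
            ),
        )
        kwargs.setdefault("init_dof", "dof")
        return cls(**kwargs)


@dataclass
class RegionFit:
    """One fitted region (full cuboid or one of its six half-splits)."""

    label: str  # "full", "x-", "x+", "y-", ...
    n_vertices: int
    fit: LocalFit


_SPLIT_LABELS = ("x-", "x+", "y-", "y+", "z-", "z+")


def fit_neighbourhood(
    volume: Volume,
    vertices: np.ndarray,
    normals: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
    cfg: RbrConfig,
    bbr_params: BbrParams | None = None,
) -> list[RegionFit]:
    """Fit the full vertex set of a cuboid plus its six half-splits.

    Splitting the cuboid in two along each axis yields six subregions whose
    independent fits feed extra candidates to the corner medians, damping the
    influence of any single misregistration.  Regions below
    ``cfg.min_vertices`` are omitted.
    """
    lo, hi = bounds
    mid = 0.5 * (np.asarray(lo) + np.asarray(hi))
    regions: list[tuple[str, np.ndarray]] = [
        ("full", np.arange(len(vertices)))
    ]
    for axis, ax_name in enumerate("xyz"):
        below = vertices[:, axis] < mid[axis]
        regions.append((f"{ax_name}-", np.flatnonzero(below)))
        regions.append((f"{ax_name}+", np.flatnonzero(~below)))

    out: list[RegionFit] = []
    for label, idx in regions:
        if len(idx) < cfg.min_vertices:
            continue
        pos = vertices[idx]
        dof = replace(cfg.dof, pivot=pos.mean(axis=0))
        fit = fit_local_transform(
            volume, pos, normals[idx], dof,
            bbr_params if bbr_params is not None else cfg.bbr,
            maxiter=cfg.nm_maxiter,
            min_improvement=cfg.min_cost_improvement,
        )
        out.append(RegionFit(label, len(idx), fit))
    return out


def depth_pass(
    volume: Volume,
    mesh: SurfaceMesh,
    level: LatticeLevel,
    cfg: RbrConfig,
):
    """Run one recursion depth; returns (deformed mesh, field, log dict)."""
    normals = mesh.vertex_normals
    parts = partition_vertices(mesh.vertices, level)
    bbr_params = cfg.bbr_at_depth(level.depth)
    cp = ControlPointField(level)
    n = level.n_cells
    n_fitted = n_identity = n_regions = n_nonconv = 0
    costs_before: list[float] = []
    costs_after: list[float] = []
    occupied_cells = []

    for cx in range(n):
        for cy in range(n):
            for cz in range(n):
                cell = np.array([cx, cy, cz])
                flat = int(level.cell_flat(cell[None])[0])
                idx = parts.get(flat)
                corners = level.cell_corner_positions(cell)
                records: list[RegionFit] = []
                if idx is not None and len(idx) >= cfg.min_vertices:
                    records = fit_neighbourhood(
                        volume,
                        mesh.vertices[idx],
                        normals[idx],
                        level.cell_bounds(cell),
                        cfg,
                        bbr_params=bbr_params,
                    )
                if idx is None or len(idx) == 0:
                    # cells without vertices cast no vote: zeros from empty
                    # space would systematically dilute the median at the
                    # outward-facing nodes of every surface-crossing cell
                    continue
                occupied_cells.append(cell)
                if not records:
                    # identity fallback for low-information regions that do
                    # hold vertices: the median sees "no change"
                    cp.add_cell_candidates(cell, np.zeros((8, 3)))
                    n_identity += 1
                    continue
                n_fitted += 1
                for rec in records:
                    n_regions += 1
                    if not rec.fit.converged:
                        n_nonconv += 1
                    if np.isfinite(rec.fit.cost_initial):
                        costs_before.append(rec.fit.cost_initial)
                        costs_after.append(rec.fit.cost_final)
                    cp.add_cell_candidates(
                        cell, corner_displacements(rec.fit.transform, corners)
                    )

    cp.aggregate(fill_zero=True)
    smooth_control_points(cp, cfg.alpha, cfg.smooth_iterations)
    new_mesh = apply_deformation(mesh, level, cp.resolved)

    n_negative_jacobian = 0
    for cell in occupied_cells:
        for T in cell_tet_affines(level, cp.resolved, cell):
            if np.linalg.det(T.linear) <= 0:
                n_negative_jacobian += 1

    moved = np.linalg.norm(new_mesh.vertices - mesh.vertices, axis=1)
    log = {
        "depth": level.depth,
        "n_cells": n**3,
        "n_fitted_cells": n_fitted,
        "n_identity_cells": n_identity,
        "n_regions": n_regions,
        "n_nonconverged": n_nonconv,
        "mean_cost_before": float(np.mean(costs_before)) if costs_before else None,
        "mean_cost_after": float(np.mean(costs_after)) if costs_after else None,
        "mean_abs_displacement": float(moved.mean()),
        "max_abs_displacement": float(moved.max()),
        "n_negative_jacobian": n_negative_jacobian,
    }
    return new_mesh, cp, log


@dataclass
class RbrRunResult:
    """Raw output of :func:`rbr`: final mesh, per-depth fields and logs."""

    mesh: SurfaceMesh
    initial_mesh: SurfaceMesh
    linear_fit: LocalFit | None
    fields: list[ControlPointField]
    depth_logs: list[dict]
    intermediate_vertices: list[np.ndarray] | None = None


def _boxes_intersect(a_lo, a_hi, b_lo, b_hi) -> bool:
    return bool(np.all(a_lo <= b_hi) and np.all(b_lo <= a_hi))


def rbr(
    volume: Volume,
    mesh: SurfaceMesh,
    cfg: RbrConfig | None = None,
    keep_intermediate: bool = False,
) -> RbrRunResult:
    """Recursive boundary registration of a surface mesh to a volume.

    Optionally initialises with a whole-mesh linear BBR, then runs depth
    passes from ``d = 0`` until a cuboid edge would span fewer than
    ``cfg.min_voxel_size`` voxels on any axis (or ``cfg.max_depth`` is hit).
    Only vertex positions change; the face array is returned untouched.
    """
    if cfg is None:
        cfg = RbrConfig()
    m_lo, m_hi = mesh.bounding_box()
    v_lo, v_hi = volume.world_bounds()
    if not _boxes_intersect(m_lo, m_hi, v_lo, v_hi):
        raise DisjointInputsError("mesh and volume bounding boxes do not overlap")

    current = mesh
    linear_fit = None
    if cfg.init_linear:
        pivot = current.vertices.mean(axis=0)
        if cfg.init_dof == "rigid":
            dof = DofSpec.rigid(pivot=pivot)
        elif cfg.init_dof == "affine9":
            dof = DofSpec.affine9(pivot=pivot)
        else:  # "dof": axis-matched to the local fits
            dof = replace(cfg.dof, pivot=pivot)
        linear_fit = fit_local_transform(
            volume,
            current.vertices,
            current.vertex_normals,
            dof,
            cfg.bbr_at_depth(0),
            maxiter=cfg.nm_maxiter,
            min_improvement=cfg.min_cost_improvement,
        )
        current = current.with_vertices(linear_fit.transform.apply(current.vertices))

    fields: list[ControlPointField] = []
    logs: list[dict] = []
    inter: list[np.ndarray] | None = [] if keep_intermediate else None
    pad = float(volume.voxel_size.max())

    def admissible(depth: int, lo, hi) -> bool:
        return not np.any((hi - lo) / 2**depth / volume.voxel_size < cfg.min_voxel_size)

    if cfg.pass_plan is not None:
        plan: list[tuple[int, float | None]] = list(cfg.pass_plan)
    else:
        plan = []
        d = 0
        while cfg.max_depth is None or d <= cfg.max_depth:
            lo, hi = mesh.bounding_box()
            if not admissible(d, lo - pad, hi + pad):
                break
            plan.append((d, None))
            d += 1

    for d, proj in plan:
        if cfg.max_depth is not None and d > cfg.max_depth:
            continue
        lo, hi = current.bounding_box()
        lo = lo - pad
        hi = hi + pad
        if not admissible(d, lo, hi):
            continue
        pass_cfg = cfg if proj is None else replace(
            cfg, projection_schedule=None, bbr=replace(cfg.bbr, projection_distance=proj)
        )
        level = LatticeLevel(lo, hi - lo, d)
        current, cp, log = depth_pass(volume, current, level, pass_cfg)
        log["projection_distance"] = (
            proj if proj is not None else cfg.bbr_at_depth(d).projection_distance
        )
        fields.append(cp)
        logs.append(log)
        if inter is not None:
            inter.append(current.vertices.copy())

    return RbrRunResult(
        mesh=current,
        initial_mesh=mesh,
        linear_fit=linear_fit,
        fields=fields,
        depth_logs=logs,
        intermediate_vertices=inter,
    )
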