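"""Model/Results front end over the recursive registration driver."""

from __future__ import annotations

import numpy as np

from .driver import RbrConfig, RbrRunResult, rbr
from .geometry import SurfaceMesh, TopologyReport, Volume
from .metrics import DisplacementReport, average_absolute_distance, displacement_report


class RecursiveBoundaryRegistration:
    """Recursive boundary registration of a cortical surface to a volume.

    Parameters
    ----------
    volume : Volume
        Registration target (e.g. a mean EPI), with voxel-to-world affine.
    surface : SurfaceMesh
        Grey--white boundary mesh in the same world coordinates.  The caller
        is responsible for a consistent affine convention (scanner RAS vs
        surface RAS); this package never guesses.
    config : RbrConfig, optional
        Degrees of freedom, thresholds and cost parameters.

    Examples
    --------
    >>> model = RecursiveBoundaryRegistration(volume, surface)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, volume: Volume, surface: SurfaceMesh, config: RbrConfig | None = None):
        self.volume = volume
        self.surface = surface.oriented()
        self.config = config if config is not None else RbrConfig()

    @classmethod
    def from_files(cls, volume_path, surface_path, config: RbrConfig | None = None):
        from .io import read_surface, read_volume

        return cls(read_volume(volume_path), read_surface(surface_path), config)

    def fit(self, keep_intermediate: bool = False) -> "RBRResults":
        run = rbr(self.volume, self.surface, self.config, keep_intermediate)
        return RBRResults(self, run)


class RBRResults:
    """Registered surface plus per-depth diagnostics of an RBR fit."""

    def __init__(self, model: RecursiveBoundaryRegistration, run: RbrRunResult):
        self.model = model
        self._run = run

    # -- estimates -----------------------------------------------------------

    @property
    def surface_(self) -> SurfaceMesh:
        """The registered (deformed) surface."""
        return self._run.mesh

    mesh = surface_

    @property
    def surface_initial(self) -> SurfaceMesh:
        return self._run.initial_mesh

    @property
    def fields(self):
        """Per-depth resolved control-point fields."""
        return self._run.fields

    @property
    def depth_logs(self) -> list[dict]:
        return self._run.depth_logs

    @property
    def linear_fit(self):
        return self._run.linear_fit

    @property
    def intermediate_vertices(self):
        return self._run.intermediate_vertices

    # -- diagnostics ---------------------------------------------------------

    def displacement_report(self, reference: SurfaceMesh | None = None, axis="y") -> DisplacementReport:
        """Residuals of the registered surface against a reference.

        Default reference is the model's input surface (i.e. how far the
        registration moved the mesh); pass a ground-truth mesh to measure
        recovery error.
        """
        ref = reference if reference is not None else self.surface_initial
        return displacement_report(ref, self.surface_, axis=axis)

    def aad(self, reference: SurfaceMesh | None = None) -> float:
        ref = reference if reference is not None else self.surface_initial
        return average_absolute_distance(ref, self.surface_)

    def check_topology(self) -> TopologyReport:
        return self.surface_.check_topology()

    @property
    def n_negative_jacobians(self) -> int:
        return int(sum(log["n_negative_jacobian"] for log in self.depth_logs))

    def to_manifest(self) -> dict:
        """Serializable per-depth summary for run manifests."""
        out = {
            "n_vertices": self.surface_.n_vertices,
            "n_faces": self.surface_.n_faces,
            "depths": self.depth_logs,
            "aad_vs_input_mm": self.aad(),
            "n_negative_jacobians": self.n_negative_jacobians,
        }
        if self.linear_fit is not None:
            out["linear_init"] = {
                "converged": bool(self.linear_fit.converged),
                "cost_initial": float(self.linear_fit.cost_initial),
                "cost_final": float(self.linear_fit.cost_final),
            }
        topo = self.check_topology()
        out["topology"] = {
            "is_sphere": topo.is_sphere,
            "euler_characteristic": topo.euler_characteristic,
        }
        return out

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-style text table)."""
        lines = []
        w = 66
        lines.append("Recursive Boundary Registration Results".center(w))
        lines.append("=" * w)
        lines.append(f"{'No. vertices:':<26}{self.surface_.n_vertices:>12}")
        lines.append(f"{'No. faces:':<26}{self.surface_.n_faces:>12}")
        vs = self.model.volume.voxel_size
        lines.append(
            f"{'Volume shape / voxel mm:':<26}"
            f"{str(self.model.volume.shape):>16}  "
            f"({vs[0]:.2f}, {vs[1]:.2f}, {vs[2]:.2f})"
        )
        cfg = self.model.config
        lines.append(f"{'DoF:':<26}{'+'.join(cfg.dof.labels):>12}")
        lines.append(f"{'alpha:':<26}{cfg.alpha:>12.2f}")
        if self.linear_fit is not None:
            lines.append(
                f"{'Linear init cost:':<26}"
                f"{self.linear_fit.cost_initial:>12.4f} -> {self.linear_fit.cost_final:.4f}"
            )
        lines.append("-" * w)
        lines.append(
            f"{'depth':>5} {'cells':>6} {'fitted':>6} {'ident':>6} "
            f"{'nconv':>6} {'negJ':>5} {'mean|d| mm':>11}"
        )
        for log in self.depth_logs:
            lines.append(
                f"{log['depth']:>5} {log['n_cells']:>6} {log['n_fitted_cells']:>6} "
                f"{log['n_identity_cells']:>6} {log['n_nonconverged']:>6} "
                f"{log['n_negative_jacobian']:>5} {log['mean_abs_displacement']:>11.4f}"
            )
        lines.append("-" * w)
        topo = self.check_topology()
        lines.append(
            f"{'Topology (out):':<26}"
            f"euler={topo.euler_characteristic}, closed={topo.is_closed}"
        )
        lines.append(f"{'Total movement (AAD mm):':<26}{self.aad():>12.4f}")
        lines.append("=" * w)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<RBRResults: {self.surface_.n_vertices} vertices, "
            f"{len(self.depth_logs)} depth passes>"
        )
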