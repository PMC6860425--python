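"""Readers/writers: FreeSurfer surfaces, plain-text meshes, NIfTI volumes,
YAML configuration and JSON run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .bbr import BbrParams, DofSpec
from .driver import RbrConfig
from .geometry import SurfaceMesh, Volume
from .lattice import ControlPointField


class FormatError(ValueError):
    """Unreadable or unsupported file content."""


TEXT_SUFFIXES = {".txt", ".asc", ".mesh"}


def _is_text_format(path: Path, fmt: str | None) -> bool:
    if fmt is not None:
        return fmt == "text"
    return path.suffix.lower() in TEXT_SUFFIXES


def read_surface(path, fmt: str | None = None) -> SurfaceMesh:
    """Read a surface; FreeSurfer binary triangle format or plain text.

    The format is inferred from the suffix (``.txt``/``.asc``/``.mesh`` are
    text) unless ``fmt`` ("freesurfer" or "text") is given.  Winding is
    repaired to outward at load time via the signed-volume test.
    """
    path = Path(path)
    if _is_text_format(path, fmt):
        return _read_text_surface(path).oriented()
    try:
        vertices, faces = nib.freesurfer.read_geometry(str(path))
    except Exception as exc:  # bad magic / truncation
        raise FormatError(f"cannot read FreeSurfer surface {path}: {exc}") from exc
    return SurfaceMesh(vertices, faces).oriented()


def write_surface(mesh: SurfaceMesh, path, fmt: str | None = None) -> None:
    path = Path(path)
    if _is_text_format(path, fmt):
        _write_text_surface(mesh, path)
    else:
        nib.freesurfer.write_geometry(str(path), mesh.vertices, mesh.faces)


def _read_text_surface(path: Path) -> SurfaceMesh:
    with open(path) as fh:
        lines = [ln for ln in (l.split("#")[0].strip() for l in fh) if ln]
    if not lines:
        raise FormatError(f"{path}: empty mesh file")
    try:
        nv, nf = (int(x) for x in lines[0].split())
        if len(lines) != 1 + nv + nf:
            raise ValueError(f"expected {1 + nv + nf} lines, found {len(lines)}")
        vertices = np.array([[float(x) for x in ln.split()] for ln in lines[1 : 1 + nv]])
        faces = np.array([[int(x) for x in ln.split()] for ln in lines[1 + nv :]])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed text mesh ({exc})") from exc
    return SurfaceMesh(vertices, faces)


def _write_text_surface(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# vertex/face surface mesh\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces}\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"{f[0]} {f[1]} {f[2]}\n")


def read_volume(path) -> Volume:
    """Read a NIfTI volume (plain or gzipped)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    try:
        data = data.astype(np.float64)
    except (TypeError, ValueError) as exc:
        code = img.header.get("datatype", "?")
        raise FormatError(f"{path}: unsupported datatype (code {code})") from exc
    return Volume(data, img.affine)


def write_volume(volume: Volume, path) -> None:
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), volume.affine), str(path))


def write_field_nifti(field: ControlPointField, path) -> None:
    """Resolved control-point displacements as a 4-D NIfTI (3 components)."""
    if field.resolved is None:
        raise ValueError("field has no resolved displacements")
    level = field.level
    affine = np.eye(4)
    affine[:3, :3] = np.diag(level.cell_size)
    affine[:3, 3] = level.origin
    nib.save(nib.Nifti1Image(field.resolved.astype(np.float32), affine), str(path))


def write_field_table(field: ControlPointField, path) -> None:
    """Resolved control points as a plain-text table for inspection."""
    if field.resolved is None:
        raise ValueError("field has no resolved displacements")
    level = field.level
    pos = level.node_positions()
    with open(Path(path), "w") as fh:
        fh.write("# i j k x_mm y_mm z_mm dx_mm dy_mm dz_mm\n")
        m = level.n_nodes
        for i in range(m):
            for j in range(m):
                for k in range(m):
                    p = pos[i, j, k]
                    d = field.resolved[i, j, k]
                    fh.write(
                        f"{i} {j} {k} "
                        f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g} "
                        f"{d[0]:.6g} {d[1]:.6g} {d[2]:.6g}\n"
                    )


# -- configuration -----------------------------------------------------------


def _axis_mask(value) -> tuple[bool, bool, bool]:
    """Accept [true,false,...] lists or compact axis strings like "y" / "xz"."""
    if isinstance(value, str):
        return tuple(ax in value.lower() for ax in "xyz")
    mask = tuple(bool(v) for v in value)
    if len(mask) != 3:
        raise FormatError("axis mask must have three entries")
    return mask


def config_from_dict(d: dict) -> RbrConfig:
    d = dict(d or {})
    dof_kwargs = {}
    for key in ("translation", "rotation", "scale"):
        if key in d:
            dof_kwargs[key] = _axis_mask(d.pop(key))
    bbr_kwargs = {}
    for key in ("projection_distance", "slope", "offset", "contrast_sign", "fill_value"):
        if key in d:
            bbr_kwargs[key] = d.pop(key)
    extra = {}
    if d.get("projection_schedule") is not None:
        extra["projection_schedule"] = tuple(float(p) for p in d.pop("projection_schedule"))
    else:
        d.pop("projection_schedule", None)
    if d.get("pass_plan") is not None:
        extra["pass_plan"] = tuple((int(dp), float(p)) for dp, p in d.pop("pass_plan"))
    else:
        d.pop("pass_plan", None)
    known = {
        "alpha",
        "min_voxel_size",
        "min_vertices",
        "max_depth",
        "init_linear",
        "init_dof",
        "smooth_iterations",
        "nm_maxiter",
        "seed",
    }
    unknown = set(d) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return RbrConfig(
        dof=DofSpec(**dof_kwargs) if dof_kwargs else DofSpec(),
        bbr=BbrParams(**bbr_kwargs),
        **extra,
        **d,
    )


def load_config(path) -> RbrConfig:
    """RbrConfig from a flat key/value YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def config_to_dict(cfg: RbrConfig) -> dict:
    return {
        "translation": list(cfg.dof.translation),
        "rotation": list(cfg.dof.rotation),
        "scale": list(cfg.dof.scale),
        "alpha": cfg.alpha,
        "projection_schedule": (
            list(cfg.projection_schedule) if cfg.projection_schedule else None
        ),
        "pass_plan": (
            [list(x) for x in cfg.pass_plan] if cfg.pass_plan else None
        ),
        "min_voxel_size": cfg.min_voxel_size,
        "min_vertices": cfg.min_vertices,
        "max_depth": cfg.max_depth,
        "init_linear": cfg.init_linear,
        "init_dof": cfg.init_dof,
        "smooth_iterations": cfg.smooth_iterations,
        "nm_maxiter": cfg.nm_maxiter,
        "seed": cfg.seed,
        "projection_distance": cfg.bbr.projection_distance,
        "slope": cfg.bbr.slope,
        "offset": cfg.bbr.offset,
        "contrast_sign": cfg.bbr.contrast_sign,
        "fill_value": cfg.bbr.fill_value,
    }


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, cfg: RbrConfig, inputs: dict, summary: dict) -> None:
    """JSON run manifest: config snapshot, input hashes, per-depth summary."""
    from . import __version__

    manifest = {
        "software": {"name": "rbr", "version": __version__},
        "config": config_to_dict(cfg),
        "inputs": {k: {"path": str(p), "sha256": file_sha256(p)} for k, p in inputs.items()},
        "summary": summary,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
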