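"""Reading and writing TIFF stacks, label volumes and result tables.

Voxel sizes are stored ImageJ-style: the XY pixel size in the TIFF
resolution tags and the Z spacing in the ImageJ metadata ``spacing`` field,
all in μm.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .grid import LabelVolume, VoxelGrid


def write_stack(path: str | Path, grid: VoxelGrid | LabelVolume) -> None:
    """Write a 3D stack as a multi-page TIFF with voxel size metadata."""
    arr = grid.values if isinstance(grid, VoxelGrid) else grid.labels
    vx, vy, vz = grid.voxel_size
    if np.issubdtype(arr.dtype, np.integer):
        out = arr.astype(np.int32 if arr.max() >= 2**16 else np.uint16)
    else:
        out = arr.astype(np.float32)
    tifffile.imwrite(
        str(path),
        out,
        imagej=True,
        photometric="minisblack",
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
    )


def _read_voxel_size(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    try:
        page = tif.pages[0]
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        vx = xres[1] / xres[0]
        vy = yres[1] / yres[0]
        meta = tif.imagej_metadata or {}
        vz = float(meta.get("spacing", 0.0))
        if vx > 0 and vy > 0 and vz > 0:
            return (float(vx), float(vy), vz)
    except (KeyError, ZeroDivisionError, TypeError):
        pass
    return None


def read_stack(
    path: str | Path, voxel_size: tuple[float, float, float] | None = None
) -> VoxelGrid:
    """Read a multi-page TIFF as a :class:`VoxelGrid`.

    ``voxel_size`` overrides any metadata; an error is raised when neither
    is available.
    """
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        meta_vs = _read_voxel_size(tif)
    vs = voxel_size or meta_vs
    if vs is None:
        raise ValueError(f"{path}: no voxel size in metadata; pass voxel_size explicitly")
    return VoxelGrid(arr, vs)


def read_labels(
    path: str | Path, voxel_size: tuple[float, float, float] | None = None
) -> LabelVolume:
    grid = read_stack(path, voxel_size)
    return LabelVolume(np.asarray(grid.values, dtype=np.int32), grid.voxel_size, grid.origin)


def write_mesh_ply(path: str | Path, mesh, vertex_signal: np.ndarray | None = None) -> None:
    """Export a cell-complex mesh as PLY (optionally with a per-vertex scalar)."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    if vertex_signal is not None:
        sig = np.clip(np.asarray(vertex_signal, dtype=float), 0, None)
        peak = sig.max() if sig.max() > 0 else 1.0
        grey = (255 * sig / peak).astype(np.uint8)
        tm.visual.vertex_colors = np.stack([grey, grey, grey, np.full_like(grey, 255)], axis=1)
    tm.export(str(path))


def write_params_json(path: str | Path, params: dict) -> None:
    """Persist run parameters for provenance."""
    Path(path).write_text(json.dumps(params, indent=2, sort_keys=True, default=str) + "\n")
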