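"""Voxel-grid containers for image stacks and label volumes.

Arrays are stored in ``(z, y, x)`` index order, the convention used by
confocal z-stacks and by :mod:`tifffile` / :mod:`scikit-image`.  All
user-facing physical quantities (voxel size, origin, coordinates) are in
micrometres and ordered ``(x, y, z)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Label value reserved for background / outside-tissue voxels and for the
#: outer (tissue-to-mountant) surface in interface tables.
EXTERIOR = 0


def _check_voxel_size(voxel_size: tuple[float, float, float]) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size must be three positive lengths (μm), got {voxel_size!r}")
    return vs


@dataclass
class VoxelGrid:
    """A 3D scalar image with physical voxel dimensions.

    Parameters
    ----------
    values
        Scalar array indexed ``[z, y, x]``.
    voxel_size
        Voxel edge lengths ``(x, y, z)`` in μm.
    origin
        Physical position ``(x, y, z)`` of the corner of voxel ``[0, 0, 0]``, μm.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("VoxelGrid requires a 3D array of shape >= (2, 2, 2)")
        self.voxel_size = _check_voxel_size(self.voxel_size)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # (z, y, x)

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        vx, vy, vz = self.voxel_size
        return (vz, vy, vx)

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size ``(x, y, z)`` of the stack in μm."""
        nz, ny, nx = self.values.shape
        vx, vy, vz = self.voxel_size
        return (nx * vx, ny * vy, nz * vz)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical center coordinates along each axis: arrays (x, y, z)."""
        nz, ny, nx = self.values.shape
        vx, vy, vz = self.voxel_size
        ox, oy, oz = self.origin
        x = ox + (np.arange(nx) + 0.5) * vx
        y = oy + (np.arange(ny) + 0.5) * vy
        z = oz + (np.arange(nz) + 0.5) * vz
        return x, y, z

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(values, self.voxel_size, self.origin)


@dataclass
class LabelVolume:
    """A 3D integer image assigning each voxel to a cell (0 = background)."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_ids: frozenset[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume requires a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        self.voxel_size = _check_voxel_size(self.voxel_size)
        self.origin = tuple(float(v) for v in self.origin)
        if self.label_ids is None:
            ids = np.unique(self.labels)
            self.label_ids = frozenset(int(i) for i in ids if i != EXTERIOR)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def extent(self) -> tuple[float, float, float]:
        nz, ny, nx = self.labels.shape
        vx, vy, vz = self.voxel_size
        return (nx * vx, ny * vy, nz * vz)

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        vx, vy, vz = self.voxel_size
        return (vz, vy, vx)

    @property
    def n_cells(self) -> int:
        return len(self.label_ids)

    def as_grid(self) -> VoxelGrid:
        return VoxelGrid(self.labels, self.voxel_size, self.origin)
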