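"""3D cell segmentation from the cell-wall channel.

The wall stain outlines cells as bright ridges around dark interiors.
Segmentation follows the classic scheme for such images: an isotropic
Gaussian blur in physical units, automatic seeding from low-intensity
regions (cell interiors), and marker-based watershed flooding of the wall
intensity landscape.  The region connected to the stack border through low
signal is the mountant outside the root and becomes background (label 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import relabel_sequential, watershed

from .grid import LabelVolume, VoxelGrid


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the blur + autoseeded-watershed segmentation.

    blur_radius : Gaussian sigma in μm applied to the wall channel (0.5).
    seed_threshold_quantile : intensity quantile below which voxels are
        considered interior/background and seed the watershed.
    min_cell_voxels : labels smaller than this are merged into their
        largest-contact neighbour after the watershed.
    """

    blur_radius: float = 0.5
    seed_threshold_quantile: float = 0.5
    min_cell_voxels: int = 64
    background_level: float = 0.0

    def __post_init__(self):
        if self.blur_radius < 0:
            raise ValueError("blur_radius must be >= 0")
        if not 0 < self.seed_threshold_quantile < 1:
            raise ValueError("seed_threshold_quantile must be in (0, 1)")


def gaussian_blur(stack: VoxelGrid, radius: float) -> VoxelGrid:
    """Isotropic Gaussian smoothing with sigma = ``radius`` μm.

    The sigma is converted per axis into voxel units, so anisotropic stacks
    are blurred isotropically in physical space.  ``radius = 0`` returns the
    input unchanged.
    """
    if radius < 0:
        raise ValueError("blur radius must be >= 0")
    if radius == 0:
        return stack
    sigma_vox = [radius / s for s in stack.spacing_zyx]
    dtype = stack.values.dtype if stack.values.dtype == np.float64 else np.float32
    return stack.with_values(
        ndimage.gaussian_filter(
            np.asarray(stack.values, dtype=dtype), sigma=sigma_vox, truncate=6.0
        )
    )


def autoseeded_watershed(
    blurred: VoxelGrid, params: SegmentationParams | None = None
) -> LabelVolume:
    """Segment cells by flooding the blurred wall intensity from auto-seeds.

    Seeds are the 26-connected components of voxels whose intensity lies
    below the ``seed_threshold_quantile`` of the stack; components touching
    the stack border are pooled into a single background seed, whose basin
    is set to 0 after flooding.  Remaining labels are renumbered from 1.
    """
    params = params or SegmentationParams()
    vals = np.asarray(blurred.values)
    thr = np.quantile(vals, params.seed_threshold_quantile)
    low = vals < thr
    if not low.any():
        # flat background at exactly the quantile (e.g. noise-free stacks)
        low = vals <= thr
    seeds, n_seeds = ndimage.label(low, structure=np.ones((3, 3, 3), dtype=bool))
    if n_seeds == 0:
        raise ValueError("no cells detected: no low-intensity seed regions found")

    border = np.zeros(vals.shape, dtype=bool)
    border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
    border_ids = np.unique(seeds[border & low])
    border_ids = border_ids[border_ids > 0]
    bg_marker = 0
    if border_ids.size:
        bg_marker = n_seeds + 1
        seeds[np.isin(seeds, border_ids)] = bg_marker
    if not np.any((seeds > 0) & (seeds != bg_marker)):
        raise ValueError("no cells detected: all seed regions touch the stack border")

    flooded = watershed(vals, markers=seeds)
    if bg_marker:
        flooded[flooded == bg_marker] = 0
    relabeled, _, _ = relabel_sequential(flooded)
    return LabelVolume(relabeled.astype(np.int32), blurred.voxel_size, blurred.origin)


def filter_small_labels(labels: LabelVolume, min_cell_voxels: int) -> LabelVolume:
    """Merge labels below ``min_cell_voxels`` into their largest-contact
    neighbour (background if they touch no other label), then renumber.

    Replaces the interactive manual proofreading step of the original
    workflow with a deterministic size-based cleanup.
    """
    lab = labels.labels.copy()
    if min_cell_voxels <= 0:
        return labels
    counts = np.bincount(lab.ravel())
    small = [i for i in range(1, counts.size) if 0 < counts[i] < min_cell_voxels]
    struct = np.zeros((3, 3, 3), dtype=bool)
    struct[1, 1, :] = struct[1, :, 1] = struct[:, 1, 1] = True  # 6-connectivity
    # absorb smallest first so chains of fragments collapse onto real cells
    for lid in sorted(small, key=lambda i: counts[i]):
        mask = lab == lid
        if not mask.any():
            continue
        ring = ndimage.binary_dilation(mask, structure=struct) & ~mask
        neigh = lab[ring]
        neigh = neigh[neigh != lid]
        contact = np.bincount(neigh[neigh > 0])
        lab[mask] = int(np.argmax(contact)) if contact.size and contact.max() > 0 else 0
    relabeled, _, _ = relabel_sequential(lab)
    return LabelVolume(relabeled.astype(np.int32), labels.voxel_size, labels.origin)


def segment_cells(
    wall: VoxelGrid, params: SegmentationParams | None = None
) -> LabelVolume:
    """Full segmentation: blur -> autoseeded watershed -> small-label cleanup."""
    params = params or SegmentationParams()
    blurred = gaussian_blur(wall, params.blur_radius)
    labels = autoseeded_watershed(blurred, params)
    return filter_small_labels(labels, params.min_cell_voxels)
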