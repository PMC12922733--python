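"""Cell-type (layer) annotation and interface orientation classification.

Roots are radially organised: concentric cell layers (epidermis, cortex,
endodermis, ...) wrap a central axis.  Cells are therefore annotated in a
cylindrical coordinate system anchored on the estimated organ axis — axial
position ``s``, radial distance ``r`` and azimuth ``theta`` of each cell
centroid — and assigned to layers by clustering their radial distances.
Interfaces are classified by the direction of their mean surface normal in
the local cylindrical frame: apical-basal (transverse walls between axially
stacked cells), radial (walls between layers) or circumferential (walls
between neighbours of the same ring).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .grid import EXTERIOR, LabelVolume
from .meshing import Interface, SurfaceMesh

#: separator used in interaction-class names, e.g. "cortex–endodermis"
CLASS_SEPARATOR = "–"

#: layer name given to cells inner to the innermost named layer
INNER_CORE = "inner_core"

#: orientation class names
APICAL_BASAL = "apical_basal"
RADIAL = "radial"
CIRCUMFERENTIAL = "circumferential"
UNCLASSIFIED = "unclassified"

DEFAULT_LAYERS = ("epidermis", "cortex", "endodermis", "core")


@dataclass
class RootAxis:
    """The organ axis: a point, a unit direction, and the anisotropy of the
    foreground around it (principal-axis length ratio)."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    anisotropy: float

    def cylindrical(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cylindrical coordinates (s, r, theta) of Cartesian points (n, 3)."""
        pts = np.atleast_2d(points) - self.axis_point
        s = pts @ self.axis_direction
        perp = pts - s[:, None] * self.axis_direction
        r = np.linalg.norm(perp, axis=1)
        # orthonormal frame perpendicular to the axis for the azimuth
        e1, e2 = _perp_frame(self.axis_direction)
        theta = np.arctan2(perp @ e2, perp @ e1)
        return s, r, theta


def _perp_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, axis)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(axis, e1)


@dataclass
class CellRecord:
    """Per-cell annotation: geometry plus assigned layer."""

    label: int
    centroid: np.ndarray
    volume: float
    s: float = np.nan
    r: float = np.nan
    theta: float = np.nan
    layer_name: str = ""
    layer_index: int = -1


def compute_cell_records(labels: LabelVolume) -> list[CellRecord]:
    """Centroid (μm) and volume (μm³) of every labelled cell."""
    lab = labels.labels
    ids = sorted(labels.label_ids)
    centroids = ndimage.center_of_mass(np.ones_like(lab), lab, ids)
    counts = np.bincount(lab.ravel(), minlength=max(ids) + 1)
    vz, vy, vx = labels.spacing_zyx
    vox_vol = vx * vy * vz
    origin = np.asarray(labels.origin)
    out = []
    for lid, com in zip(ids, centroids):
        cz, cy, cx = com
        centroid = origin + np.array(
            [(cx + 0.5) * vx, (cy + 0.5) * vy, (cz + 0.5) * vz]
        )
        out.append(
            CellRecord(label=lid, centroid=centroid, volume=float(counts[lid] * vox_vol))
        )
    return out


def estimate_root_axis(
    labels: LabelVolume, min_anisotropy: float = 1.5, max_points: int = 200_000
) -> RootAxis:
    """Estimate the organ axis as the first principal direction of the
    foreground voxel cloud.

    The sign is chosen so axial position increases with z.  Raises when the
    foreground shows no dominant direction (principal-axis length ratio
    below ``min_anisotropy``), e.g. for a spherical object.
    """
    zz, yy, xx = np.nonzero(labels.labels)
    if len(zz) < 10:
        raise ValueError("too few foreground voxels to estimate an axis")
    if len(zz) > max_points:
        step = len(zz) // max_points
        zz, yy, xx = zz[::step], yy[::step], xx[::step]
    vz, vy, vx = labels.spacing_zyx
    ox, oy, oz = labels.origin
    pts = np.stack(
        [ox + (xx + 0.5) * vx, oy + (yy + 0.5) * vy, oz + (zz + 0.5) * vz], axis=1
    )
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    evals, evecs = np.linalg.eigh(cov)
    aniso = float(np.sqrt(evals[-1] / max(evals[-2], 1e-12)))
    if aniso < min_anisotropy:
        raise ValueError(
            f"no dominant axis: anisotropy {aniso:.2f} < {min_anisotropy}"
        )
    direction = evecs[:, -1]
    if direction[2] < 0 or (direction[2] == 0 and direction[np.argmax(np.abs(direction))] < 0):
        direction = -direction
    return RootAxis(axis_point=center, axis_direction=direction, anisotropy=aniso)


def assign_cell_layers(
    cells: list[CellRecord],
    axis: RootAxis,
    layer_names: tuple[str, ...] = DEFAULT_LAYERS,
    n_bands: int | None = None,
) -> list[CellRecord]:
    """Assign each cell to a concentric layer by gap-clustering radial
    distances.

    Cells are sorted by radial distance ``r`` and split into ``n_bands``
    groups at the largest gaps of the sorted sequence (1-D gap clustering,
    invariant to uniform scaling).  The outermost band is ``layer_names[0]``
    and so on inward; bands beyond the named layers are labelled
    ``inner_core`` (pass ``n_bands > len(layer_names)`` when the sample
    contains unnamed inner tissue).
    """
    if not layer_names:
        raise ValueError("layer_names must not be empty")
    k = n_bands if n_bands is not None else len(layer_names)
    if k < len(layer_names):
        raise ValueError("n_bands must be >= len(layer_names)")
    if len(cells) < k:
        raise ValueError(f"fewer cells ({len(cells)}) than layers ({k})")
    coords = np.stack([c.centroid for c in cells])
    s, r, theta = axis.cylindrical(coords)
    order = np.argsort(r)[::-1]  # outermost first
    r_sorted = r[order]
    gaps = r_sorted[:-1] - r_sorted[1:]
    cut_positions = np.sort(np.argsort(gaps)[::-1][: k - 1]) + 1 if k > 1 else []
    band = np.zeros(len(cells), dtype=int)
    start = 0
    for bi, cut in enumerate(list(cut_positions) + [len(cells)]):
        band[order[start:cut]] = bi
        start = cut
    out = []
    for c, bi, si, ri, ti in zip(cells, band, s, r, theta):
        if bi < len(layer_names):
            name, li = layer_names[bi], bi
        else:
            name, li = INNER_CORE, bi
        out.append(replace(c, s=float(si), r=float(ri), theta=float(ti),
                           layer_name=name, layer_index=int(li)))
    return out


def classify_interface_orientation(
    interface: Interface,
    mesh: SurfaceMesh,
    axis: RootAxis,
    tie_margin: float = 0.05,
) -> str:
    """Orientation class from the patch's mean normal in the local
    cylindrical frame.

    The area-weighted mean unit normal (consistently oriented from cell_a to
    cell_b) is compared against the axial, radial and circumferential unit
    vectors at the patch centroid; the largest absolute component wins.
    When the top two components differ by less than ``tie_margin`` the
    interface is left unclassified (and excluded from class statistics).
    """
    n_hat = mesh.patch_normal(interface.tri_idx)
    centroid = mesh.patch_centroid(interface.tri_idx)
    a_hat = axis.axis_direction
    rel = centroid - axis.axis_point
    rel_perp = rel - (rel @ a_hat) * a_hat
    nrm = np.linalg.norm(rel_perp)
    if nrm < 1e-9:
        # patch centred on the axis: radial direction undefined; the wall can
        # still be classified if it is clearly transverse
        r_hat = np.zeros(3)
    else:
        r_hat = rel_perp / nrm
    c_hat = np.cross(a_hat, r_hat)
    comps = np.abs([n_hat @ a_hat, n_hat @ r_hat, n_hat @ c_hat])
    names = (APICAL_BASAL, RADIAL, CIRCUMFERENTIAL)
    top, second = np.sort(comps)[::-1][:2]
    if top - second < tie_margin:
        return UNCLASSIFIED
    return names[int(np.argmax(comps))]


def name_interaction_class(
    interface: Interface, cells_by_label: dict[int, CellRecord]
) -> str:
    """Layer-pair name of an interface, e.g. "cortex–endodermis".

    Names are ordered alphabetically so (a, b) and (b, a) agree; same-layer
    pairs collapse to the single layer name; the outer surface is named
    "exterior".
    """
    labels = [l for l in interface.pair if l != EXTERIOR]
    if len(labels) < 2:
        return "exterior"
    names = []
    for lid in labels:
        cell = cells_by_label.get(lid)
        if cell is None or not cell.layer_name:
            raise ValueError(f"cell {lid} has no layer annotation")
        names.append(cell.layer_name)
    if names[0] == names[1]:
        return names[0]
    return CLASS_SEPARATOR.join(sorted(names))


def annotate_interfaces(
    interfaces: list[Interface],
    mesh: SurfaceMesh,
    axis: RootAxis,
    cells: list[CellRecord],
    tie_margin: float = 0.05,
) -> list[Interface]:
    """Fill orientation_class and interaction_class of every interface."""
    by_label = {c.label: c for c in cells}
    for ifc in interfaces:
        ifc.interaction_class = name_interaction_class(ifc, by_label)
        if ifc.is_exterior:
            ifc.orientation_class = UNCLASSIFIED
        else:
            ifc.orientation_class = classify_interface_orientation(
                ifc, mesh, axis, tie_margin
            )
    return interfaces
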