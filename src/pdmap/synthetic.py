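"""Synthetic dual-channel root stacks with known geometry and pit-field truth.

The generator emulates a radially layered, straight cylindrical root segment
aligned with the z axis: concentric cell layers (e.g. epidermis, cortex,
endodermis) are divided into angular sectors and axial segments, giving a
label volume whose cell walls are analytic cylindrical-sector surfaces.  Two
fluorescence channels are rendered from it: a cell-wall stain (bright walls)
and a plasmodesmata-marker channel with punctate pit-field spots placed on
the cell-cell walls by a Poisson or Thomas (clustered) point process.

Because every wall is an analytic surface, the generator provides exact
ground truth — cell identities, layers, interface classes, interface areas
and spot counts/positions — against which segmentation, meshing, annotation
and quantification can be validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import EXTERIOR, LabelVolume, VoxelGrid

TWO_PI = 2.0 * np.pi

APICAL_BASAL = "apical_basal"
RADIAL = "radial"
CIRCUMFERENTIAL = "circumferential"
EXTERIOR_CLASS = "exterior"

DEFAULT_LAYER_NAMES = ("epidermis", "cortex", "endodermis", "core")


@dataclass(frozen=True)
class RootGeometryParams:
    """Geometry of the synthetic root: concentric layers of sector cells.

    ``layer_radii`` are the outer radii of each layer (μm), strictly
    decreasing inward; the innermost layer extends to the axis.  Each layer
    is split into ``cells_per_ring`` angular sectors and into axial segments
    of nominal length ``axial_cell_length`` (the stack is divided into
    ``floor(extent_z / axial_cell_length)`` equal segments, at least one).
    The default is a four-band meristem-like geometry: epidermis, cortex and
    endodermis rings of eight cells around a single-cell vascular core
    (using one core cell per axial segment avoids the degenerate many-wedge
    junction a sectored innermost band would create on the axis).
    """

    layer_radii: tuple[float, ...] = (20.0, 13.5, 7.5, 3.5)
    cells_per_ring: tuple[int, ...] = (8, 8, 8, 1)
    axial_cell_length: tuple[float, ...] = (16.0, 16.0, 16.0, 16.0)
    stack_extent: tuple[float, float, float] = (46.0, 46.0, 64.0)
    voxel_size: tuple[float, float, float] = (0.25, 0.25, 0.25)
    angular_offset: tuple[float, ...] | None = None
    layer_names: tuple[str, ...] = DEFAULT_LAYER_NAMES
    axis_orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        n = len(self.layer_radii)
        radii = tuple(float(r) for r in self.layer_radii)
        if n == 0 or any(r <= 0 for r in radii):
            raise ValueError("layer_radii must be positive")
        if any(radii[i + 1] >= radii[i] for i in range(n - 1)):
            raise ValueError("layer_radii must be strictly decreasing inward")
        if len(self.cells_per_ring) != n or any(c < 1 for c in self.cells_per_ring):
            raise ValueError("cells_per_ring needs one integer >= 1 per layer")
        ax = self.axial_cell_length
        if np.isscalar(ax):
            ax = (float(ax),) * n
        if len(ax) != n or any(a <= 0 for a in ax):
            raise ValueError("axial_cell_length needs one positive length per layer")
        object.__setattr__(self, "axial_cell_length", tuple(float(a) for a in ax))
        object.__setattr__(self, "layer_radii", radii)
        object.__setattr__(self, "cells_per_ring", tuple(int(c) for c in self.cells_per_ring))
        if any(e <= 0 for e in self.stack_extent) or any(v <= 0 for v in self.voxel_size):
            raise ValueError("stack extent and voxel size must be positive")
        off = self.angular_offset
        if off is None:
            off = (0.0,) * n
        if np.isscalar(off):
            off = (float(off),) * n
        if len(off) != n:
            raise ValueError("angular_offset needs one value per layer")
        object.__setattr__(self, "angular_offset", tuple(float(o) for o in off))
        if len(self.layer_names) < n:
            names = tuple(self.layer_names) + tuple(
                f"layer{i}" for i in range(len(self.layer_names), n)
            )
            object.__setattr__(self, "layer_names", names)
        else:
            object.__setattr__(self, "layer_names", tuple(self.layer_names[:n]))
        axis = np.asarray(self.axis_orientation, dtype=float)
        if not np.allclose(axis / np.linalg.norm(axis), [0.0, 0.0, 1.0]):
            raise NotImplementedError("only a z-aligned root axis is supported")
        if max(radii) * 2 > min(self.stack_extent[0], self.stack_extent[1]):
            raise ValueError("outer radius does not fit inside the stack extent")
        self._check_resolvable()

    # -- derived geometry ------------------------------------------------
    @property
    def n_layers(self) -> int:
        return len(self.layer_radii)

    def inner_radius(self, layer: int) -> float:
        return self.layer_radii[layer + 1] if layer + 1 < self.n_layers else 0.0

    def n_axial(self, layer: int) -> int:
        return max(1, int(self.stack_extent[2] / self.axial_cell_length[layer] + 1e-9))

    def axial_length(self, layer: int) -> float:
        return self.stack_extent[2] / self.n_axial(layer)

    def sector_width(self, layer: int) -> float:
        return TWO_PI / self.cells_per_ring[layer]

    def n_cells(self) -> int:
        return sum(self.cells_per_ring[i] * self.n_axial(i) for i in range(self.n_layers))

    def _check_resolvable(self) -> None:
        dims = []
        for i in range(self.n_layers):
            dims.append(self.layer_radii[i] - self.inner_radius(i))
            dims.append(self.axial_length(i))
            if self.cells_per_ring[i] > 1:
                r_mid = 0.5 * (self.layer_radii[i] + self.inner_radius(i))
                dims.append(self.sector_width(i) * r_mid)
        if max(self.voxel_size) > min(dims):
            raise ValueError(
                "unresolvable geometry: voxel size exceeds the smallest cell dimension"
            )

    def label_of(self, layer: int, sector: int, axial: int) -> int:
        base = 1
        for i in range(layer):
            base += self.cells_per_ring[i] * self.n_axial(i)
        return base + sector * self.n_axial(layer) + axial


@dataclass(frozen=True)
class PitFieldParams:
    """Pit-field placement statistics on cell-cell interfaces.

    ``rate_per_area`` gives the expected spot count per μm² for each
    interface orientation class.  In ``thomas`` mode spots arise from a
    parent-offspring cluster process with parent intensity
    ``parents_per_area`` (derived as rate / offspring_per_parent when None,
    so both modes share the same expected count), mean ``offspring_per_parent``
    spots per parent and in-plane dispersion ``cluster_sigma``.  Spots are
    rendered as 3D Gaussians of width ``spot_sigma_psf`` (the optical PSF
    stand-in) and height ``spot_amplitude`` over additive Gaussian noise.
    """

    rate_per_area: dict = field(
        default_factory=lambda: {APICAL_BASAL: 0.08, RADIAL: 0.02, CIRCUMFERENTIAL: 0.02}
    )
    cluster_mode: str = "uniform"
    parents_per_area: float | None = None
    offspring_per_parent: float = 10.0
    cluster_sigma: float = 1.2
    spot_sigma_psf: float = 0.2
    spot_amplitude: float = 1.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.cluster_mode not in ("uniform", "thomas"):
            raise ValueError(f"unknown cluster_mode {self.cluster_mode!r}")
        if any(v < 0 for v in self.rate_per_area.values()):
            raise ValueError("rates must be >= 0")
        for name in ("cluster_sigma", "spot_sigma_psf", "spot_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cluster_mode == "thomas" and self.offspring_per_parent <= 0:
            raise ValueError("offspring_per_parent must be > 0 in thomas mode")


@dataclass
class GroundTruthTable:
    """Analytic ground truth: cells, interfaces and (after placement) spots."""

    cells: pd.DataFrame
    interfaces: pd.DataFrame
    spots: pd.DataFrame | None = None

    def cell_interfaces(self) -> pd.DataFrame:
        """Cell-cell rows only (exterior surface excluded)."""
        ifc = self.interfaces
        keep = (ifc["cell_a"] != EXTERIOR) & (ifc["cell_b"] != EXTERIOR)
        return ifc[keep].reset_index(drop=True)

    def to_csv(self, cells_path, interfaces_path, spots_path=None) -> None:
        self.cells.to_csv(cells_path, index=False)
        self.interfaces.to_csv(interfaces_path, index=False)
        if spots_path is not None and self.spots is not None:
            self.spots.to_csv(spots_path, index=False)


# ---------------------------------------------------------------------------
# label volume
# ---------------------------------------------------------------------------

def generate_label_volume(geometry: RootGeometryParams) -> LabelVolume:
    """Rasterize the analytic root geometry into a cell label volume.

    Deterministic: each voxel center inside the outermost radius is mapped
    to (layer band, angular sector, axial segment); outside voxels are 0.
    """
    g = geometry
    ex, ey, ez = g.stack_extent
    vx, vy, vz = g.voxel_size
    nx, ny, nz = (max(2, int(round(e / v))) for e, v in zip(g.stack_extent, g.voxel_size))
    x = (np.arange(nx) + 0.5) * vx - ex / 2.0
    y = (np.arange(ny) + 0.5) * vy - ey / 2.0
    z = (np.arange(nz) + 0.5) * vz
    X = x[None, None, :]
    Y = y[None, :, None]
    R = np.sqrt(X**2 + Y**2)
    theta = np.mod(np.arctan2(Y, X), TWO_PI)

    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    # descending radii -> band index: band i is [inner_radius(i), radii[i])
    edges = np.array(list(g.layer_radii[::-1]))  # ascending
    band_asc = np.digitize(R, edges, right=False)  # 0 -> innermost region
    layer_idx = g.n_layers - 1 - (band_asc - 0)  # ascending index -> layer index
    inside = R < g.layer_radii[0]
    for li in range(g.n_layers):
        sel2d = inside & (layer_idx == li)  # (1, ny, nx) broadcast over z later
        if not sel2d.any():
            continue
        width = g.sector_width(li)
        sector = np.floor(np.mod(theta - g.angular_offset[li], TWO_PI) / width).astype(int)
        sector = np.clip(sector, 0, g.cells_per_ring[li] - 1)
        n_ax = g.n_axial(li)
        axial = np.minimum((z / (ez / n_ax)).astype(int), n_ax - 1)  # (nz,)
        base = g.label_of(li, 0, 0)
        lab2d = base + sector * n_ax  # (1, ny, nx)
        vol = np.where(sel2d, lab2d, 0)  # broadcastable 2D plane labels
        labels += vol.astype(np.int32) + (axial[:, None, None] * (vol > 0)).astype(np.int32)
    return LabelVolume(labels, g.voxel_size)


# ---------------------------------------------------------------------------
# ground truth enumeration
# ---------------------------------------------------------------------------

def _arc_overlaps(lo: float, hi: float, g: RootGeometryParams, layer: int):
    """Intersect the arc [lo, hi) with every sector of ``layer`` (wraparound)."""
    width = g.sector_width(layer)
    out = []
    for j in range(g.cells_per_ring[layer]):
        a0 = g.angular_offset[layer] + j * width
        for shift in (-TWO_PI, 0.0, TWO_PI):
            s0, s1 = a0 + shift, a0 + width + shift
            o0, o1 = max(lo, s0), min(hi, s1)
            if o1 - o0 > 1e-12:
                out.append((j, o1 - o0))
    return out


def _interval_overlap(a0, a1, b0, b1) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def build_ground_truth(geometry: RootGeometryParams) -> GroundTruthTable:
    """Enumerate all cells and interfaces with analytic areas and classes."""
    g = geometry
    ez = g.stack_extent[2]
    cells = []
    for li in range(g.n_layers):
        r_out, r_in = g.layer_radii[li], g.inner_radius(li)
        width, lz, n_ax = g.sector_width(li), g.axial_length(li), g.n_axial(li)
        if r_out > r_in:
            r_bar = (2.0 / 3.0) * (r_out**3 - r_in**3) / (r_out**2 - r_in**2)
        else:  # pragma: no cover - excluded by validation
            r_bar = r_out
        for j in range(g.cells_per_ring[li]):
            th_mid = g.angular_offset[li] + (j + 0.5) * width
            # full-ring single cell: centroid on the axis
            cx = r_bar * np.cos(th_mid) if g.cells_per_ring[li] > 1 else 0.0
            cy = r_bar * np.sin(th_mid) if g.cells_per_ring[li] > 1 else 0.0
            for k in range(n_ax):
                cells.append(
                    dict(
                        label=g.label_of(li, j, k),
                        layer=g.layer_names[li],
                        layer_index=li,
                        sector_index=j,
                        axial_index=k,
                        centroid_x=cx + g.stack_extent[0] / 2,
                        centroid_y=cy + g.stack_extent[1] / 2,
                        centroid_z=(k + 0.5) * lz,
                        volume_um3=width / 2 * (r_out**2 - r_in**2) * lz,
                    )
                )
    cells_df = pd.DataFrame(cells)

    rows = []

    def add(cell_a, cell_b, cls, area, **geom):
        a, b = (cell_a, cell_b) if cell_a < cell_b else (cell_b, cell_a)
        base = dict(
            r_in=np.nan, r_out=np.nan, theta0=np.nan, theta1=np.nan,
            z0=np.nan, z1=np.nan, r_wall=np.nan, theta_wall=np.nan, z_wall=np.nan,
        )
        base.update(geom)
        rows.append(dict(cell_a=a, cell_b=b, **{"class": cls}, area_um2=area, **base))

    for li in range(g.n_layers):
        r_out, r_in = g.layer_radii[li], g.inner_radius(li)
        width, lz, n_ax = g.sector_width(li), g.axial_length(li), g.n_axial(li)
        n_sec = g.cells_per_ring[li]
        ab_area = width / 2 * (r_out**2 - r_in**2)
        circ_area = (r_out - r_in) * lz
        for j in range(n_sec):
            th0 = g.angular_offset[li] + j * width
            for k in range(n_ax):
                me = g.label_of(li, j, k)
                # apical-basal wall to the next axial segment
                if k + 1 < n_ax:
                    add(me, g.label_of(li, j, k + 1), APICAL_BASAL, ab_area,
                        r_in=r_in, r_out=r_out, theta0=th0, theta1=th0 + width,
                        z_wall=(k + 1) * lz)
                # circumferential wall to the next sector (wraparound); with
                # exactly two sectors the pair shares both planar walls
                if n_sec >= 3 or (n_sec == 2 and j == 0):
                    nb = g.label_of(li, (j + 1) % n_sec, k)
                    add(me, nb, CIRCUMFERENTIAL, circ_area,
                        r_in=r_in, r_out=r_out, z0=k * lz, z1=(k + 1) * lz,
                        theta_wall=th0 + width)
                    if n_sec == 2:
                        add(me, nb, CIRCUMFERENTIAL, circ_area,
                            r_in=r_in, r_out=r_out, z0=k * lz, z1=(k + 1) * lz,
                            theta_wall=g.angular_offset[li])
        # radial wall between this layer and the next inward at radius r_in
        if li + 1 < g.n_layers:
            lz_in, n_ax_in = g.axial_length(li + 1), g.n_axial(li + 1)
            for j in range(n_sec):
                th0 = g.angular_offset[li] + j * width
                for j2, dth in _arc_overlaps(th0, th0 + width, g, li + 1):
                    for k in range(n_ax):
                        za0, za1 = k * lz, (k + 1) * lz
                        for k2 in range(n_ax_in):
                            dz = _interval_overlap(za0, za1, k2 * lz_in, (k2 + 1) * lz_in)
                            if dz <= 1e-12 or dth * r_in * dz <= 1e-12:
                                continue
                            lo = max(th0, g.angular_offset[li + 1] + j2 * g.sector_width(li + 1))
                            add(g.label_of(li, j, k), g.label_of(li + 1, j2, k2),
                                RADIAL, r_in * dth * dz,
                                r_wall=r_in, theta0=lo, theta1=lo + dth,
                                z0=max(za0, k2 * lz_in), z1=max(za0, k2 * lz_in) + dz)

    # exterior surface: outer side wall of layer 0 plus z-end caps of all cells
    ext_area: dict[int, float] = {}
    for c in cells:
        li = c["layer_index"]
        area = 0.0
        if li == 0:
            area += g.layer_radii[0] * g.sector_width(0) * g.axial_length(0)
        n_ax = g.n_axial(li)
        cap = g.sector_width(li) / 2 * (g.layer_radii[li] ** 2 - g.inner_radius(li) ** 2)
        if c["axial_index"] == 0:
            area += cap
        if c["axial_index"] == n_ax - 1:
            area += cap
        if area > 0:
            ext_area[c["label"]] = ext_area.get(c["label"], 0.0) + area
    for lab, area in ext_area.items():
        add(EXTERIOR, lab, EXTERIOR_CLASS, area)

    # duplicate (cell_a, cell_b, class) rows (e.g. split circumferential walls
    # between two sectors) are summed: one interface per adjacent pair
    ifc = pd.DataFrame(rows)
    agg = {c: "first" for c in ifc.columns if c not in ("cell_a", "cell_b", "class", "area_um2")}
    agg["area_um2"] = "sum"
    ifc = (
        ifc.groupby(["cell_a", "cell_b", "class"], as_index=False)
        .agg(agg)
        .sort_values(["cell_a", "cell_b"])
        .reset_index(drop=True)
    )
    ifc["interface_id"] = np.arange(len(ifc))
    return GroundTruthTable(cells=cells_df, interfaces=ifc)


# ---------------------------------------------------------------------------
# wall channel
# ---------------------------------------------------------------------------

def render_wall_channel(
    labels: LabelVolume,
    wall_thickness: float = 1.0,
    blur_sigma: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> VoxelGrid:
    """Render a cell-wall-stain channel: bright on label boundaries.

    Boundary voxels (label differs from a 6-neighbour, or a labelled voxel
    on the outer tissue surface) get intensity 1, thickened to
    ``wall_thickness`` by a Euclidean distance threshold, then blurred with
    ``blur_sigma`` (μm) and corrupted with seeded additive Gaussian noise.
    """
    lab = labels.labels
    bound = np.zeros(lab.shape, dtype=bool)
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(0, -1)
        sl_b[ax] = slice(1, None)
        d = lab[tuple(sl_a)] != lab[tuple(sl_b)]
        bound[tuple(sl_a)] |= d
        bound[tuple(sl_b)] |= d
    # tissue cut open at the stack faces still shows a stained outer wall
    for ax in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[ax] = edge
            bound[tuple(sl)] = True
        sl[ax] = slice(None)
    bound &= lab > 0  # outside-of-root background stays dark

    spacing = labels.voxel_size[::-1]  # (z, y, x)
    extra = max(0.0, wall_thickness / 2.0 - min(labels.voxel_size) / 2.0)
    if extra > 0 and bound.any():
        dist = ndimage.distance_transform_edt(~bound, sampling=spacing)
        wall = (dist <= extra).astype(np.float32)
    else:
        wall = bound.astype(np.float32)
    if blur_sigma > 0:
        wall = ndimage.gaussian_filter(wall, sigma=[blur_sigma / s for s in spacing])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        wall = wall + rng.normal(0.0, noise_sd, size=wall.shape).astype(np.float32)
    return VoxelGrid(wall, labels.voxel_size)


# ---------------------------------------------------------------------------
# pit-field placement
# ---------------------------------------------------------------------------

def _sample_on_interface(row, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` points uniformly (by area) on one analytic wall patch."""
    cls = row["class"]
    if cls == APICAL_BASAL:
        u = rng.uniform(size=n)
        r = np.sqrt(u * (row.r_out**2 - row.r_in**2) + row.r_in**2)
        th = rng.uniform(row.theta0, row.theta1, size=n)
        return np.column_stack([r * np.cos(th), r * np.sin(th), np.full(n, row.z_wall)])
    if cls == RADIAL:
        th = rng.uniform(row.theta0, row.theta1, size=n)
        z = rng.uniform(row.z0, row.z1, size=n)
        return np.column_stack([row.r_wall * np.cos(th), row.r_wall * np.sin(th), z])
    if cls == CIRCUMFERENTIAL:
        r = rng.uniform(row.r_in, row.r_out, size=n)
        z = rng.uniform(row.z0, row.z1, size=n)
        return np.column_stack([r * np.cos(row.theta_wall), r * np.sin(row.theta_wall), z])
    raise ValueError(f"cannot place spots on interface class {cls!r}")


def _thomas_points(row, rate: float, params: PitFieldParams, rng) -> np.ndarray:
    """Parent-offspring clustered points on one wall patch."""
    area = row.area_um2
    lam_parent = (
        params.parents_per_area
        if params.parents_per_area is not None
        else rate / params.offspring_per_parent
    )
    n_par = rng.poisson(lam_parent * area)
    if n_par == 0:
        return np.empty((0, 3))
    parents = _sample_on_interface(row, n_par, rng)
    pts = []
    for p in parents:
        n_off = rng.poisson(params.offspring_per_parent)
        if n_off == 0:
            continue
        disp = rng.normal(0.0, params.cluster_sigma, size=(n_off, 2))
        pts.append(_displace_in_plane(row, p, disp))
    return np.vstack(pts) if pts else np.empty((0, 3))


def _displace_in_plane(row, point: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Move ``point`` by 2D tangent offsets, clipped to the patch bounds."""
    cls = row["class"]
    x, y, z = point
    if cls == APICAL_BASAL:
        r = np.hypot(x, y)
        th = np.arctan2(y, x)
        r2 = np.clip(r + disp[:, 0], row.r_in, row.r_out)
        th2 = np.clip(th + disp[:, 1] / max(r, 1e-6), row.theta0, row.theta1)
        return np.column_stack([r2 * np.cos(th2), r2 * np.sin(th2), np.full(len(disp), z)])
    if cls == RADIAL:
        th = np.arctan2(y, x)
        th2 = np.clip(th + disp[:, 0] / row.r_wall, row.theta0, row.theta1)
        z2 = np.clip(z + disp[:, 1], row.z0, row.z1)
        return np.column_stack([row.r_wall * np.cos(th2), row.r_wall * np.sin(th2), z2])
    r = np.hypot(x, y)
    r2 = np.clip(r + disp[:, 0], row.r_in, row.r_out)
    z2 = np.clip(z + disp[:, 1], row.z0, row.z1)
    return np.column_stack(
        [r2 * np.cos(row.theta_wall), r2 * np.sin(row.theta_wall), z2]
    )


def _render_spots(shape_zyx, voxel_size, centers_xyz, sigma, amplitude) -> np.ndarray:
    """Accumulate isotropic 3D Gaussian spots into a stack."""
    img = np.zeros(shape_zyx, dtype=np.float32)
    if len(centers_xyz) == 0 or amplitude == 0:
        return img
    vx, vy, vz = voxel_size
    nz, ny, nx = shape_zyx
    half = 3.5 * sigma
    for cx, cy, cz in centers_xyz:
        ix0, ix1 = max(0, int((cx - half) / vx)), min(nx, int((cx + half) / vx) + 1)
        iy0, iy1 = max(0, int((cy - half) / vy)), min(ny, int((cy + half) / vy) + 1)
        iz0, iz1 = max(0, int((cz - half) / vz)), min(nz, int((cz + half) / vz) + 1)
        if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
            continue
        gx = (np.arange(ix0, ix1) + 0.5) * vx - cx
        gy = (np.arange(iy0, iy1) + 0.5) * vy - cy
        gz = (np.arange(iz0, iz1) + 0.5) * vz - cz
        d2 = (
            gz[:, None, None] ** 2 + gy[None, :, None] ** 2 + gx[None, None, :] ** 2
        )
        img[iz0:iz1, iy0:iy1, ix0:ix1] += amplitude * np.exp(-d2 / (2 * sigma**2))
    return img


def place_pit_fields(
    labels: LabelVolume, truth: GroundTruthTable, params: PitFieldParams
) -> tuple[VoxelGrid, GroundTruthTable]:
    """Place pit-field spots on every cell-cell interface and render them.

    Per interface the spot count is Poisson(rate × area) in ``uniform`` mode,
    or arises from a Thomas parent-offspring process with the same expected
    count in ``thomas`` mode.  Each spot is attributed to its generating
    interface in the returned truth table even when its rendered Gaussian
    support bleeds onto neighbouring walls.
    """
    rng = np.random.default_rng(params.seed)
    ifc = truth.interfaces.copy()
    cc = ifc["class"] != EXTERIOR_CLASS
    missing = set(ifc.loc[cc, "class"]) - set(params.rate_per_area)
    if missing:
        raise ValueError(f"rate_per_area missing interface classes: {sorted(missing)}")

    # offset the patch coordinates: truth geometry is centred on the axis,
    # the stack is centred at (extent_x/2, extent_y/2)
    ox = labels.extent[0] / 2.0
    oy = labels.extent[1] / 2.0

    all_pts, counts, spot_iface = [], np.zeros(len(ifc), dtype=int), []
    for idx, row in ifc.iterrows():
        if row["class"] == EXTERIOR_CLASS:
            continue
        rate = params.rate_per_area[row["class"]]
        if rate == 0:
            continue
        if params.cluster_mode == "thomas":
            pts = _thomas_points(row, rate, params, rng)
        else:
            n = rng.poisson(rate * row.area_um2)
            pts = _sample_on_interface(row, n, rng) if n else np.empty((0, 3))
        counts[idx] = len(pts)
        if len(pts):
            pts = pts + np.array([ox, oy, 0.0])
            all_pts.append(pts)
            spot_iface.extend([row.interface_id] * len(pts))

    centers = np.vstack(all_pts) if all_pts else np.empty((0, 3))
    img = _render_spots(labels.shape, labels.voxel_size, centers, params.spot_sigma_psf,
                        params.spot_amplitude)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape).astype(np.float32)

    ifc["true_count"] = counts
    ifc["cluster_mode"] = np.where(cc, params.cluster_mode, "")
    spots = pd.DataFrame(
        dict(
            x=centers[:, 0] if len(centers) else [],
            y=centers[:, 1] if len(centers) else [],
            z=centers[:, 2] if len(centers) else [],
            interface_id=spot_iface,
        )
    )
    return VoxelGrid(img, labels.voxel_size), GroundTruthTable(truth.cells, ifc, spots)


# ---------------------------------------------------------------------------
# convenience bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSample:
    labels: LabelVolume
    wall: VoxelGrid
    pd_channel: VoxelGrid
    truth: GroundTruthTable
    geometry: RootGeometryParams
    pit_params: PitFieldParams


def simulate_root(
    geometry: RootGeometryParams | None = None,
    pit_params: PitFieldParams | None = None,
    wall_thickness: float = 1.0,
    wall_blur_sigma: float = 0.2,
    wall_noise_sd: float = 0.0,
    seed: int | None = None,
) -> SyntheticSample:
    """Generate a full synthetic sample: labels, wall and PD channels, truth."""
    geometry = geometry or RootGeometryParams()
    pit_params = pit_params or PitFieldParams()
    if seed is not None:
        pit_params = replace(pit_params, seed=seed)
    labels = generate_label_volume(geometry)
    truth = build_ground_truth(geometry)
    wall = render_wall_channel(
        labels, wall_thickness, wall_blur_sigma, wall_noise_sd,
        seed=(pit_params.seed + 1) if seed is None else seed + 1,
    )
    pd_channel, truth = place_pit_fields(labels, truth, pit_params)
    return SyntheticSample(labels, wall, pd_channel, truth, geometry, pit_params)
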