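"""End-to-end orchestration: stacks in, per-interface metric table out.

The stages mirror the imaging workflow: segment cells from the wall stain
(or accept a given label volume), estimate the root axis and annotate cell
layers, mesh the cell surfaces and extract interfaces at the abundance
resolution (and a finer one for spatial statistics), project and binarise
the pit-field marker, and quantify every retained interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotation import (
    DEFAULT_LAYERS,
    annotate_interfaces,
    assign_cell_layers,
    compute_cell_records,
    estimate_root_axis,
)
from .grid import LabelVolume, VoxelGrid
from .meshing import (
    MIN_INTERFACE_AREA,
    MeshParams,
    build_meshes,
    extract_interfaces,
    filter_interfaces,
)
from .projection import ProjectionParams, project_and_binarize
from .quantify import quantify_sample
from .segmentation import SegmentationParams, segment_cells


@dataclass
class PipelineParams:
    """Everything tunable along the pipeline, with the workflow defaults:
    0.5 μm blur, cube size 0.5 (0.2 for Moran's I), 10 smooth passes,
    ±0.5 μm projection band, 3 μm² interface filter."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    mesh_coarse: MeshParams = field(default_factory=lambda: MeshParams(cube_size=0.5))
    mesh_fine: MeshParams = field(default_factory=lambda: MeshParams(cube_size=0.2))
    projection: ProjectionParams = field(default_factory=ProjectionParams)
    layer_names: tuple[str, ...] = DEFAULT_LAYERS
    n_bands: int | None = None
    min_interface_area: float = MIN_INTERFACE_AREA
    compute_morans: bool = True


@dataclass
class PipelineResult:
    table: pd.DataFrame
    labels: LabelVolume
    cells: list
    axis: object
    mesh_coarse: object
    interfaces_coarse: list
    signal_coarse: object


def run_pipeline(
    pd_stack: VoxelGrid,
    wall_stack: VoxelGrid | None = None,
    labels: LabelVolume | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the full quantification on one sample.

    Provide either a raw ``wall_stack`` (segmented here) or a pre-computed
    ``labels`` volume.  Returns the per-interface table plus the
    intermediate objects for export or inspection.
    """
    params = params or PipelineParams()
    if labels is None:
        if wall_stack is None:
            raise ValueError("need either wall_stack or labels")
        labels = segment_cells(wall_stack, params.segmentation)

    axis = estimate_root_axis(labels)
    cells = assign_cell_layers(
        compute_cell_records(labels), axis, params.layer_names, params.n_bands
    )
    layer_of_cell = {c.label: c.layer_index for c in cells}

    mesh_c = build_meshes(labels, params.mesh_coarse)
    ifcs_c = filter_interfaces(
        extract_interfaces(mesh_c), params.min_interface_area
    )
    annotate_interfaces(ifcs_c, mesh_c, axis, cells)
    sig_c = project_and_binarize(
        mesh_c, pd_stack, ifcs_c, layer_of_cell, params.projection
    )

    mesh_f = ifcs_f = sig_f = None
    if params.compute_morans:
        mesh_f = build_meshes(labels, params.mesh_fine)
        ifcs_f = extract_interfaces(mesh_f)
        sig_f = project_and_binarize(
            mesh_f, pd_stack, ifcs_f, layer_of_cell, params.projection
        )

    table = quantify_sample(
        mesh_c, ifcs_c, sig_c, mesh_f, ifcs_f, sig_f,
        min_area=params.min_interface_area,
    )
    return PipelineResult(
        table=table,
        labels=labels,
        cells=cells,
        axis=axis,
        mesh_coarse=mesh_c,
        interfaces_coarse=ifcs_c,
        signal_coarse=sig_c,
    )
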