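"""Full quantification: project the marker channel and measure every wall.

Runs the complete chain — layer annotation, meshing at 0.5 μm (abundance)
and 0.2 μm (spatial statistics), ±0.5 μm max-projection of the marker,
trim + binarisation — and prints the per-class summary of % Total Signal,
% Signal Density and Moran's I.
"""

from pdmap import (
    PipelineParams,
    PitFieldParams,
    ProjectionParams,
    RootGeometryParams,
    run_pipeline,
    simulate_root,
)

sample = simulate_root(
    RootGeometryParams(
        layer_radii=(12.0, 8.0, 4.5, 2.2),
        cells_per_ring=(6, 6, 6, 1),
        axial_cell_length=(11.0,) * 4,
        stack_extent=(28.0, 28.0, 44.0),
        voxel_size=(0.25,) * 3,
    ),
    PitFieldParams(seed=4),  # default class rates 4:1:1 (apical-basal high)
)

# synthetic stacks carry no depth attenuation, so depth compensation is off
params = PipelineParams(projection=ProjectionParams(base_trim=0.2, layer_decay=1.0))
result = run_pipeline(sample.pd_channel, labels=sample.labels, params=params)

table = result.table
print(f"{len(table)} interfaces quantified "
      f"(% Total Signal sums to {table.pct_total_signal.sum():.6f})")
print("\nmean per orientation class:")
print(
    table.groupby("orientation_class")[
        ["pct_total_signal", "pct_signal_density", "area_um2", "morans_I"]
    ].mean().round(3)
)
# Apical-basal walls should lead % Total Signal (the generator placed 4x
# the spot density there); positive Moran's I reflects that binarised spots
# are contiguous patches, not scattered single vertices.
print("\nmean per interaction class (cell-type pair):")
print(table.groupby("interaction_class").pct_total_signal.mean().round(3))
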