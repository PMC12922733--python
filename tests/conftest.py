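"""Shared fixtures: small synthetic roots and simple label volumes.

The tiny root is deliberately coarse (0.3 μm voxels, ~0.5M voxels) so the
whole unit suite stays fast; resolution-sensitive accuracy checks live in
the acceptance tests, which use the generator's full default geometry.
"""

import numpy as np
import pytest

from pdmap import (
    LabelVolume,
    PitFieldParams,
    RootGeometryParams,
    build_ground_truth,
    generate_label_volume,
    render_wall_channel,
    simulate_root,
)

TINY_LAYERS = ("epidermis", "cortex", "core")


@pytest.fixture(scope="session")
def tiny_geometry():
    return RootGeometryParams(
        layer_radii=(9.0, 5.5, 2.5),
        cells_per_ring=(6, 6, 1),
        axial_cell_length=(10.0, 10.0, 10.0),
        stack_extent=(22.0, 22.0, 30.0),
        voxel_size=(0.3, 0.3, 0.3),
        layer_names=TINY_LAYERS,
    )


@pytest.fixture(scope="session")
def tiny_labels(tiny_geometry):
    return generate_label_volume(tiny_geometry)


@pytest.fixture(scope="session")
def tiny_truth(tiny_geometry):
    return build_ground_truth(tiny_geometry)


@pytest.fixture(scope="session")
def tiny_wall(tiny_labels):
    return render_wall_channel(tiny_labels, wall_thickness=1.0, blur_sigma=0.2,
                               noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def tiny_sample(tiny_geometry):
    return simulate_root(
        tiny_geometry,
        PitFieldParams(
            rate_per_area={"apical_basal": 0.1, "radial": 0.05, "circumferential": 0.05},
            seed=42,
        ),
    )


@pytest.fixture(scope="session")
def cube_labels():
    """A single 10x10x10 μm cubic cell at 0.5 μm voxels, padded."""
    n, pad = 20, 4
    arr = np.zeros((n + 2 * pad,) * 3, dtype=np.int32)
    arr[pad:pad + n, pad:pad + n, pad:pad + n] = 1
    return LabelVolume(arr, (0.5, 0.5, 0.5))


@pytest.fixture(scope="session")
def two_cube_labels():
    """Two 10 μm cubes sharing a full 10x10 μm face (labels 1, 2)."""
    n, pad = 20, 4
    arr = np.zeros((n + 2 * pad, 2 * n + 2 * pad, n + 2 * pad), dtype=np.int32)
    arr[pad:pad + n, pad:pad + n, pad:pad + n] = 1
    arr[pad:pad + n, pad + n:pad + 2 * n, pad:pad + n] = 2
    return LabelVolume(arr, (0.5, 0.5, 0.5))
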