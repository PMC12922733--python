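"""Root-axis estimation, layer assignment and interface classification."""

import numpy as np
import pytest

from pdmap import (
    CellRecord,
    Interface,
    LabelVolume,
    MeshParams,
    annotate_interfaces,
    assign_cell_layers,
    build_meshes,
    classify_interface_orientation,
    compute_cell_records,
    estimate_root_axis,
    extract_interfaces,
    filter_interfaces,
    name_interaction_class,
)
from pdmap.annotation import CLASS_SEPARATOR, INNER_CORE, RootAxis


class TestRootAxis:
    def test_straight_root_axis_along_z(self, tiny_labels):
        axis = estimate_root_axis(tiny_labels)
        assert axis.axis_direction @ np.array([0, 0, 1.0]) > 0.999

    def test_translation_leaves_direction_unchanged(self, tiny_labels):
        a = estimate_root_axis(tiny_labels)
        moved = LabelVolume(
            tiny_labels.labels, tiny_labels.voxel_size, origin=(5.0, -3.0, 11.0)
        )
        b = estimate_root_axis(moved)
        assert np.allclose(a.axis_direction, b.axis_direction, atol=1e-9)

    def test_rotated_stack_rotates_axis(self, tiny_labels):
        # 90° about x: z -> y in array terms (swap axes 0 and 1)
        rot = LabelVolume(
            np.swapaxes(tiny_labels.labels, 0, 1).copy(),
            tiny_labels.voxel_size,
        )
        axis = estimate_root_axis(rot)
        # axis should now lie along y (array axis 1 -> physical y)
        assert abs(axis.axis_direction[1]) > np.cos(np.deg2rad(1.0))

    def test_sphere_has_no_axis(self):
        n = 40
        zz, yy, xx = np.indices((n, n, n))
        r = np.sqrt((zz - n / 2) ** 2 + (yy - n / 2) ** 2 + (xx - n / 2) ** 2)
        lab = (r < 15).astype(np.int32)
        with pytest.raises(ValueError, match="no dominant axis"):
            estimate_root_axis(LabelVolume(lab, (0.5, 0.5, 0.5)))


class TestAssignLayers:
    def test_tiny_root_layers_fully_recovered(self, tiny_labels, tiny_truth,
                                              tiny_geometry):
        axis = estimate_root_axis(tiny_labels)
        cells = assign_cell_layers(
            compute_cell_records(tiny_labels), axis, tiny_geometry.layer_names
        )
        truth_layer = dict(zip(tiny_truth.cells.label, tiny_truth.cells.layer))
        assert all(c.layer_name == truth_layer[c.label] for c in cells)

    def test_single_layer_requested(self, tiny_labels):
        axis = estimate_root_axis(tiny_labels)
        cells = assign_cell_layers(
            compute_cell_records(tiny_labels), axis, ("everything",)
        )
        assert {c.layer_name for c in cells} == {"everything"}

    def test_scaling_invariance(self, tiny_labels, tiny_geometry):
        axis = estimate_root_axis(tiny_labels)
        cells = compute_cell_records(tiny_labels)
        a = assign_cell_layers(cells, axis, tiny_geometry.layer_names)
        doubled = [
            CellRecord(label=c.label, centroid=2 * c.centroid, volume=c.volume)
            for c in cells
        ]
        axis2 = RootAxis(2 * axis.axis_point, axis.axis_direction, axis.anisotropy)
        b = assign_cell_layers(doubled, axis2, tiny_geometry.layer_names)
        assert [c.layer_name for c in a] == [c.layer_name for c in b]

    def test_inner_core_band(self, tiny_labels, tiny_truth):
        axis = estimate_root_axis(tiny_labels)
        cells = assign_cell_layers(
            compute_cell_records(tiny_labels), axis,
            ("epidermis", "cortex"), n_bands=3,
        )
        truth_layer = dict(zip(tiny_truth.cells.label, tiny_truth.cells.layer))
        for c in cells:
            expected = truth_layer[c.label]
            assert c.layer_name == (INNER_CORE if expected == "core" else expected)

    def test_fewer_cells_than_layers_errors(self, tiny_labels):
        axis = estimate_root_axis(tiny_labels)
        cells = compute_cell_records(tiny_labels)[:2]
        with pytest.raises(ValueError, match="fewer cells"):
            assign_cell_layers(cells, axis, ("a", "b", "c"))


def _flat_patch_mesh(normal):
    """A two-triangle unit square patch with the requested normal."""
    from pdmap.meshing import SurfaceMesh

    n = np.asarray(normal, dtype=float)
    n /= np.linalg.norm(n)
    helper = np.array([1.0, 0, 0]) if abs(n[0]) < 0.9 else np.array([0, 1.0, 0])
    u = np.cross(helper, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    base = np.array([10.0, 0.0, 5.0])
    verts = np.stack([base, base + u, base + u + v, base + v])
    tris = np.array([[0, 1, 2], [0, 2, 3]])
    cross = np.cross(verts[tris[:, 1]] - verts[tris[:, 0]],
                     verts[tris[:, 2]] - verts[tris[:, 0]])
    if (cross[0] @ n) < 0:
        tris = tris[:, [0, 2, 1]]
    return SurfaceMesh(
        vertices=verts, triangles=tris,
        tri_pair=np.array([[1, 2], [1, 2]]),
        vertex_order=np.full(4, 2), edges=np.empty((0, 2), dtype=int),
        cube_size=0.5,
    )


class TestOrientation:
    AXIS = RootAxis(np.zeros(3), np.array([0, 0, 1.0]), 3.0)

    def _ifc(self):
        return Interface(cell_a=1, cell_b=2, area=1.0,
                         tri_idx=np.array([0, 1]), vertex_idx=np.arange(4))

    def test_axial_normal_is_apical_basal(self):
        mesh = _flat_patch_mesh((0, 0, 1))
        assert classify_interface_orientation(self._ifc(), mesh, self.AXIS) == "apical_basal"

    def test_radial_normal_between_rings(self):
        # patch at (10, 0, 5): radial direction is +x
        mesh = _flat_patch_mesh((1, 0, 0))
        assert classify_interface_orientation(self._ifc(), mesh, self.AXIS) == "radial"

    def test_circumferential_normal(self):
        mesh = _flat_patch_mesh((0, 1, 0))
        assert classify_interface_orientation(self._ifc(), mesh, self.AXIS) == "circumferential"

    def test_diagonal_normal_unclassified(self):
        mesh = _flat_patch_mesh((1, 1, 0))
        assert classify_interface_orientation(self._ifc(), mesh, self.AXIS) == "unclassified"

    def test_synthetic_root_classes_recovered(self, tiny_labels, tiny_truth,
                                              tiny_geometry):
        axis = estimate_root_axis(tiny_labels)
        cells = assign_cell_layers(
            compute_cell_records(tiny_labels), axis, tiny_geometry.layer_names
        )
        mesh = build_meshes(tiny_labels, MeshParams())
        ifcs = filter_interfaces(extract_interfaces(mesh), 3.0)
        annotate_interfaces(ifcs, mesh, axis, cells)
        cc = tiny_truth.cell_interfaces().set_index(["cell_a", "cell_b"])
        total = match = 0
        for i in ifcs:
            if i.is_exterior or i.pair not in cc.index:
                continue
            total += 1
            match += i.orientation_class == cc.loc[i.pair, "class"]
        assert total > 20
        assert match / total >= 0.95


class TestInteractionClass:
    CELLS = {
        1: CellRecord(1, np.zeros(3), 1.0, layer_name="epidermis", layer_index=0),
        2: CellRecord(2, np.zeros(3), 1.0, layer_name="epidermis", layer_index=0),
        3: CellRecord(3, np.zeros(3), 1.0, layer_name="cortex", layer_index=1),
        4: CellRecord(4, np.zeros(3), 1.0, layer_name="endodermis", layer_index=2),
    }

    @staticmethod
    def _ifc(a, b):
        return Interface(cell_a=a, cell_b=b, area=1.0,
                         tri_idx=np.arange(1), vertex_idx=np.arange(3))

    def test_same_layer_collapses(self):
        assert name_interaction_class(self._ifc(1, 2), self.CELLS) == "epidermis"

    def test_cortex_endodermis(self):
        expected = f"cortex{CLASS_SEPARATOR}endodermis"
        assert name_interaction_class(self._ifc(3, 4), self.CELLS) == expected

    def test_order_invariance(self):
        assert name_interaction_class(self._ifc(1, 3), self.CELLS) == \
            name_interaction_class(self._ifc(3, 1), self.CELLS)

    def test_unannotated_cell_errors(self):
        cells = dict(self.CELLS)
        cells[9] = CellRecord(9, np.zeros(3), 1.0)
        with pytest.raises(ValueError, match="no layer annotation"):
            name_interaction_class(self._ifc(1, 9), cells)

    def test_exterior_named_exterior(self):
        assert name_interaction_class(self._ifc(0, 1), self.CELLS) == "exterior"
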