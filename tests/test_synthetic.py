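"""The generator's geometry, truth tables and point processes."""

import numpy as np
import pytest

from pdmap import (
    PitFieldParams,
    RootGeometryParams,
    build_ground_truth,
    generate_label_volume,
    place_pit_fields,
    render_wall_channel,
)


class TestLabelVolume:
    def test_one_layer_one_sector_two_axial_segments(self):
        g = RootGeometryParams(
            layer_radii=(10.0,), cells_per_ring=(1,), axial_cell_length=(12.0,),
            stack_extent=(25.0, 25.0, 25.0), voxel_size=(0.5, 0.5, 0.5),
        )
        assert generate_label_volume(g).n_cells == 2

    def test_three_layer_root_has_96_cells(self):
        g = RootGeometryParams(
            layer_radii=(22.0, 15.0, 8.0), cells_per_ring=(8, 8, 8),
            axial_cell_length=(12.5,) * 3, stack_extent=(50.0, 50.0, 50.0),
            voxel_size=(0.5, 0.5, 0.5),
        )
        labels = generate_label_volume(g)
        assert g.n_cells() == 96
        assert labels.n_cells == 96

    def test_voxel_counts_match_analytic_volumes(self):
        g = RootGeometryParams(voxel_size=(0.25, 0.25, 0.25))
        labels = generate_label_volume(g)
        truth = build_ground_truth(g)
        counts = np.bincount(labels.labels.ravel())
        vox_vol = np.prod(labels.voxel_size)
        rel = counts[truth.cells.label.values] * vox_vol / truth.cells.volume_um3.values
        assert np.abs(rel - 1).max() < 0.10

    def test_each_label_single_connected_component(self, tiny_labels):
        from scipy import ndimage

        struct = np.ones((3, 3, 3), dtype=bool)
        for lid in sorted(tiny_labels.label_ids):
            _, n = ndimage.label(tiny_labels.labels == lid, structure=struct)
            assert n == 1

    def test_unresolvable_geometry_rejected(self):
        with pytest.raises(ValueError, match="unresolvable"):
            RootGeometryParams(
                layer_radii=(10.0, 9.5), cells_per_ring=(8, 8),
                axial_cell_length=(10.0, 10.0), stack_extent=(25.0, 25.0, 30.0),
                voxel_size=(1.0, 1.0, 1.0),
            )

    def test_radii_must_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            RootGeometryParams(layer_radii=(10.0, 12.0), cells_per_ring=(4, 4),
                               axial_cell_length=(10.0, 10.0))


class TestWallChannel:
    def test_sharp_render_is_binary_boundary_mask(self, tiny_labels):
        wall = render_wall_channel(tiny_labels, wall_thickness=0.1, blur_sigma=0.0,
                                   noise_sd=0.0)
        vals = np.unique(wall.values)
        assert set(vals) <= {0.0, 1.0}
        lab = tiny_labels.labels
        w = wall.values.astype(bool)
        assert w.any()
        # never bright outside the tissue, and exactly on label changes inside
        assert not w[lab == 0].any()
        bound = np.zeros(lab.shape, dtype=bool)
        for ax in range(3):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[ax] = slice(0, -1)
            sl_b[ax] = slice(1, None)
            d = lab[tuple(sl_a)] != lab[tuple(sl_b)]
            bound[tuple(sl_a)] |= d
            bound[tuple(sl_b)] |= d
            for edge in (0, -1):
                sl_e = [slice(None)] * 3
                sl_e[ax] = edge
                bound[tuple(sl_e)] = True
        bound &= lab > 0
        assert np.array_equal(w, bound)

    def test_same_seed_bit_identical(self, tiny_labels):
        a = render_wall_channel(tiny_labels, 1.0, 0.3, 0.05, seed=7)
        b = render_wall_channel(tiny_labels, 1.0, 0.3, 0.05, seed=7)
        assert np.array_equal(a.values, b.values)
        c = render_wall_channel(tiny_labels, 1.0, 0.3, 0.05, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_boundary_brighter_than_interior(self, tiny_labels):
        wall = render_wall_channel(tiny_labels, 1.0, 0.3, 0.05, seed=3)
        lab = tiny_labels.labels
        bound = np.zeros(lab.shape, dtype=bool)
        for ax in range(3):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[ax] = slice(0, -1)
            sl_b[ax] = slice(1, None)
            d = lab[tuple(sl_a)] != lab[tuple(sl_b)]
            bound[tuple(sl_a)] |= d
            bound[tuple(sl_b)] |= d
        bound &= lab > 0
        interior = (lab > 0) & ~bound
        assert wall.values[bound].mean() > wall.values[interior].mean()


class TestPitFields:
    def test_zero_rates_give_pure_noise(self, tiny_labels, tiny_truth):
        params = PitFieldParams(
            rate_per_area={"apical_basal": 0, "radial": 0, "circumferential": 0},
            noise_sd=0.05, seed=1,
        )
        pd_ch, truth = place_pit_fields(tiny_labels, tiny_truth, params)
        assert truth.cell_interfaces().true_count.sum() == 0
        assert len(truth.spots) == 0
        assert abs(pd_ch.values.std() - 0.05) < 0.01

    def test_spot_count_conservation(self, tiny_sample):
        truth = tiny_sample.truth
        assert len(truth.spots) == truth.cell_interfaces().true_count.sum()
        # every spot belongs to a known interface
        assert set(truth.spots.interface_id) <= set(truth.interfaces.interface_id)

    def test_missing_class_in_rate_map_errors(self, tiny_labels, tiny_truth):
        with pytest.raises(ValueError, match="missing interface classes"):
            place_pit_fields(
                tiny_labels, tiny_truth,
                PitFieldParams(rate_per_area={"apical_basal": 0.1}),
            )

    def test_poisson_mean_count_recovery(self):
        # one big apical-basal wall of ~100 μm²; Monte-Carlo over seeds
        g = RootGeometryParams(
            layer_radii=(5.65,), cells_per_ring=(1,), axial_cell_length=(15.0,),
            stack_extent=(12.0, 12.0, 30.0), voxel_size=(0.3, 0.3, 0.3),
            layer_names=("core",),
        )
        labels = generate_label_volume(g)
        truth = build_ground_truth(g)
        cc = truth.cell_interfaces()
        assert len(cc) == 1 and cc.iloc[0]["class"] == "apical_basal"
        area = cc.iloc[0].area_um2
        assert area == pytest.approx(np.pi * 5.65**2, rel=1e-6)
        rate = 0.5
        params = {"apical_basal": rate, "radial": rate, "circumferential": rate}
        counts = []
        for seed in range(200):
            _, t = place_pit_fields(
                labels, truth,
                PitFieldParams(rate_per_area=params, seed=seed, spot_amplitude=0.0),
            )
            counts.append(t.cell_interfaces().true_count.iloc[0])
        mean = np.mean(counts)
        expected = rate * area
        se = np.sqrt(expected / len(counts))
        assert abs(mean - expected) < 3 * se

    def test_spot_positions_lie_on_their_interfaces(self, tiny_sample):
        truth = tiny_sample.truth
        ifc = truth.interfaces.set_index("interface_id")
        ox = tiny_sample.labels.extent[0] / 2
        oy = tiny_sample.labels.extent[1] / 2
        for _, sp in truth.spots.sample(min(50, len(truth.spots)),
                                        random_state=0).iterrows():
            row = ifc.loc[sp.interface_id]
            x, y, z = sp.x - ox, sp.y - oy, sp.z
            r = np.hypot(x, y)
            if row["class"] == "apical_basal":
                assert z == pytest.approx(row.z_wall, abs=1e-9)
                assert row.r_in - 1e-9 <= r <= row.r_out + 1e-9
            elif row["class"] == "radial":
                assert r == pytest.approx(row.r_wall, abs=1e-9)
                assert row.z0 - 1e-9 <= z <= row.z1 + 1e-9
            else:
                theta = np.arctan2(y, x)
                dt = np.mod(theta - row.theta_wall + np.pi, 2 * np.pi) - np.pi
                assert abs(dt) < 1e-6


def test_simulate_root_deterministic(tiny_geometry):
    from pdmap import simulate_root

    a = simulate_root(tiny_geometry, seed=9)
    b = simulate_root(tiny_geometry, seed=9)
    assert np.array_equal(a.pd_channel.values, b.pd_channel.values)
    assert np.array_equal(a.wall.values, b.wall.values)
    assert a.truth.interfaces.equals(b.truth.interfaces)
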