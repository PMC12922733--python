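"""Total Signal, Signal Density, sample normalisation and Moran's I."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from pdmap import (
    MeshParams,
    MoransInputs,
    PipelineParams,
    ProjectionParams,
    VertexSignal,
    build_meshes,
    extract_interfaces,
    grid_weights,
    morans_I,
    normalize_sample,
    patch_morans_inputs,
    run_pipeline,
    signal_density,
    total_signal,
)


def brute_force_morans(x: np.ndarray, w: np.ndarray) -> float:
    """Independent O(N²) double-loop evaluation of Moran's I."""
    n = len(x)
    z = x - x.mean()
    num = 0.0
    wsum = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * z[i] * z[j]
            wsum += w[i, j]
    return n / wsum * num / (z @ z)


def random_graph_inputs(rng, n):
    a = (rng.random((n, n)) < min(0.5, 8.0 / n)).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    if a.sum() == 0:
        a[0, 1] = a[1, 0] = 1.0
    x = rng.integers(0, 2, n).astype(float)
    if x.min() == x.max():
        x[0] = 1 - x[0]
    return x, a


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        yy, xx = np.indices((8, 8))
        x = ((yy + xx) % 2).astype(float).ravel()
        assert morans_I(MoransInputs(x, grid_weights((8, 8)))) == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("n", [8, 16, 32, 64])
    def test_two_block_matches_closed_form(self, n):
        v = np.zeros((n, n))
        v[:, n // 2:] = 1.0
        I = morans_I(MoransInputs(v.ravel(), grid_weights((n, n))))
        # closed form: (E_within - E_between) / E for rook edges
        assert I == pytest.approx(1 - 1 / (n - 1), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        x, a = random_graph_inputs(rng, n)
        fast = morans_I(MoransInputs(x, sparse.csr_matrix(a)))
        slow = brute_force_morans(x, a)
        assert fast == pytest.approx(slow, abs=1e-12)

    def test_six_vertex_example(self):
        rng = np.random.default_rng(123)
        _, a = random_graph_inputs(rng, 6)
        x = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        assert morans_I(MoransInputs(x, sparse.csr_matrix(a))) == pytest.approx(
            brute_force_morans(x, a), abs=1e-12
        )

    def test_permutation_mean_near_randomization_expectation(self):
        rng = np.random.default_rng(7)
        n = 100
        x, a = random_graph_inputs(rng, n)
        w = sparse.csr_matrix(a)
        vals = []
        for _ in range(2000):
            vals.append(morans_I(MoransInputs(rng.permutation(x), w)))
        expected = -1.0 / (n - 1)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se

    def test_constant_values_undefined(self):
        w = grid_weights((3, 3))
        assert np.isnan(morans_I(MoransInputs(np.ones(9), w)))

    def test_invalid_weights_rejected(self):
        x = np.array([0.0, 1.0])
        with pytest.raises(ValueError, match="zero diagonal"):
            MoransInputs(x, sparse.csr_matrix(np.array([[1.0, 1], [1, 0]])))
        with pytest.raises(ValueError, match="symmetric"):
            MoransInputs(x, sparse.csr_matrix(np.array([[0.0, 1], [0, 0]])))
        with pytest.raises(ValueError, match="two vertices"):
            MoransInputs(np.array([1.0]), sparse.csr_matrix((1, 1)))


@pytest.fixture(scope="module")
def wall(two_cube_labels):
    mesh = build_meshes(two_cube_labels, MeshParams(cube_size=0.5))
    ifc = [i for i in extract_interfaces(mesh) if not i.is_exterior][0]
    return mesh, ifc


class TestTotalSignal:

    def test_no_positive_vertices_zero(self, wall):
        mesh, ifc = wall
        sig = VertexSignal(raw=np.zeros(mesh.n_vertices),
                           binary=np.zeros(mesh.n_vertices))
        assert total_signal(mesh, ifc, sig) == 0.0

    def test_full_coverage_equals_area(self, wall):
        mesh, ifc = wall
        sig = VertexSignal(raw=np.ones(mesh.n_vertices),
                           binary=np.ones(mesh.n_vertices))
        assert total_signal(mesh, ifc, sig) == pytest.approx(ifc.area, rel=1e-9)

    def test_half_coverage_half_area(self, wall):
        mesh, ifc = wall
        binary = np.zeros(mesh.n_vertices)
        # positive on the half of the wall with z below the wall centroid
        zc = mesh.patch_centroid(ifc.tri_idx)[2]
        binary[ifc.vertex_idx[mesh.vertices[ifc.vertex_idx, 2] < zc]] = 1.0
        sig = VertexSignal(raw=binary, binary=binary)
        s = total_signal(mesh, ifc, sig)
        assert s == pytest.approx(ifc.area / 2, rel=0.1)

    def test_morans_on_patch_matches_oracle(self, wall):
        mesh, ifc = wall
        rng = np.random.default_rng(0)
        values = rng.integers(0, 2, mesh.n_vertices).astype(float)
        inputs = patch_morans_inputs(mesh, ifc, values)
        dense = inputs.weights.toarray()
        assert morans_I(inputs) == pytest.approx(
            brute_force_morans(inputs.x, dense), abs=1e-12
        )


class TestNormalize:
    @staticmethod
    def _frame(s):
        return pd.DataFrame(
            dict(total_signal=s, area_um2=np.ones(len(s)),
                 signal_density=np.asarray(s, dtype=float))
        )

    def test_simple_proportions(self):
        out = normalize_sample(self._frame([1.0, 1.0, 2.0]))
        assert np.allclose(out.pct_total_signal, [25, 25, 50])

    def test_single_interface_is_100(self):
        out = normalize_sample(self._frame([3.7]))
        assert out.pct_total_signal.iloc[0] == pytest.approx(100.0)

    def test_zero_sum_errors(self):
        with pytest.raises(ValueError, match="no signal"):
            normalize_sample(self._frame([0.0, 0.0]))

    def test_signal_density_arithmetic(self):
        assert signal_density(0.0, 10.0) == 0.0
        assert signal_density(10.0, 10.0) == 1.0
        assert signal_density(25.0, 100.0) == 0.25
        with pytest.raises(ValueError):
            signal_density(1.0, 0.0)


class TestPipeline:
    def test_percentages_sum_to_100(self, tiny_sample):
        params = PipelineParams(
            projection=ProjectionParams(base_trim=0.2, layer_decay=1.0),
            layer_names=("epidermis", "cortex", "core"),
        )
        res = run_pipeline(tiny_sample.pd_channel, labels=tiny_sample.labels,
                           params=params)
        assert res.table.pct_total_signal.sum() == pytest.approx(100.0, rel=1e-9)
        assert res.table.pct_signal_density.sum() == pytest.approx(100.0, rel=1e-9)
        assert res.table.morans_I.notna().any()

    def test_zero_marker_channel_errors(self, tiny_sample):
        zero = tiny_sample.pd_channel.with_values(
            np.zeros_like(tiny_sample.pd_channel.values)
        )
        params = PipelineParams(
            projection=ProjectionParams(base_trim=0.2, layer_decay=1.0),
            layer_names=("epidermis", "cortex", "core"),
            compute_morans=False,
        )
        with pytest.raises(ValueError, match="no signal"):
            run_pipeline(zero, labels=tiny_sample.labels, params=params)
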