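"""Volume-to-surface sampling, manifold smoothing, patching, selection."""

import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path

import cortdecode as cd
from cortdecode.surface import (
    FeatureMatrix,
    PatchPartition,
    SurfaceTimeSeries,
    anova_f_scores,
    smoothing_operator,
)
from cortdecode.volume import VolumeTimeSeries


def _grid_volume(data):
    """Volume with identity voxel->world mapping (1 mm voxels at origin)."""
    return VolumeTimeSeries(data=data, affine=np.eye(4), tr_s=1.5)


class TestSampling:
    def test_vertex_at_voxel_center_reads_that_voxel(self):
        data = np.zeros((4, 4, 4, 2))
        data[1, 2, 3, 0] = 7.0
        data[1, 2, 3, 1] = -2.0
        mesh = cd.CorticalMesh(
            vertices=np.array([[1.0, 2.0, 3.0]]), faces=np.empty((0, 3), dtype=int)
        )
        sts = cd.sample_volume_to_surface(_grid_volume(data), mesh)
        assert np.allclose(sts.data[:, 0], [7.0, -2.0])

    def test_midpoint_of_two_voxel_centers_is_their_mean(self):
        data = np.zeros((4, 4, 4, 1))
        data[1, 1, 1, 0] = 10.0
        data[2, 1, 1, 0] = 20.0
        mesh = cd.CorticalMesh(
            vertices=np.array([[1.5, 1.0, 1.0]]), faces=np.empty((0, 3), dtype=int)
        )
        sts = cd.sample_volume_to_surface(_grid_volume(data), mesh)
        assert np.isclose(sts.data[0, 0], 15.0)

    def test_constant_volume_gives_constant_surface(self, icosphere2):
        vol_data = np.full((16, 16, 16, 3), 42.0)
        affine = np.eye(4) * 2.0
        affine[3, 3] = 1.0
        affine[:3, 3] = -15.0  # centre the 16^3 grid of 2 mm voxels on origin
        vol = VolumeTimeSeries(data=vol_data, affine=affine, tr_s=1.5)
        sts = cd.sample_volume_to_surface(vol, icosphere2)
        assert np.allclose(sts.data, 42.0)

    def test_vertex_outside_bounds_lists_offenders(self):
        data = np.zeros((4, 4, 4, 1))
        mesh = cd.CorticalMesh(
            vertices=np.array([[1.0, 1.0, 1.0], [10.0, 0.0, 0.0]]),
            faces=np.empty((0, 3), dtype=int),
        )
        with pytest.raises(ValueError, match=r"outside volume bounds: 1"):
            cd.sample_volume_to_surface(_grid_volume(data), mesh)


class TestSmoothing:
    def test_constant_field_is_preserved(self, icosphere2):
        sts = SurfaceTimeSeries(
            data=np.full((3, icosphere2.n_vertices), 5.0), tr_s=1.5
        )
        out = cd.surface_smooth(sts, icosphere2, fwhm_mm=8.0)
        assert np.allclose(out.data, 5.0)

    def test_zero_fwhm_is_identity(self, icosphere2):
        rng = np.random.default_rng(0)
        sts = SurfaceTimeSeries(
            data=rng.standard_normal((2, icosphere2.n_vertices)), tr_s=1.5
        )
        out = cd.surface_smooth(sts, icosphere2, fwhm_mm=0.0)
        assert np.array_equal(out.data, sts.data)

    def test_matches_dense_matrix_power_oracle(self, icosphere2):
        """Iterated sparse smoothing equals the dense operator power."""
        s, n_iter = smoothing_operator(icosphere2, fwhm_mm=6.0)
        assert n_iter >= 1
        impulse = np.zeros((1, icosphere2.n_vertices))
        impulse[0, 17] = 1.0
        sts = SurfaceTimeSeries(data=impulse, tr_s=1.5)
        out = cd.surface_smooth(sts, icosphere2, fwhm_mm=6.0)
        dense = np.linalg.matrix_power(s.toarray(), n_iter)
        assert np.max(np.abs(out.data[0] - dense[:, 17])) <= 1e-10

    def test_maximum_principle_and_variance_reduction(self, icosphere2):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, icosphere2.n_vertices))
        out = cd.surface_smooth(
            SurfaceTimeSeries(data=x, tr_s=1.5), icosphere2, fwhm_mm=5.0
        )
        for f in range(4):
            assert x[f].min() - 1e-12 <= out.data[f].min()
            assert out.data[f].max() <= x[f].max() + 1e-12
            assert out.data[f].var() <= x[f].var()


class TestPatchPartition:
    def test_every_vertex_its_own_patch_when_k_equals_v(self, icosahedron):
        part = cd.build_patch_partition(icosahedron, icosahedron.n_vertices)
        assert part.n_patches == 12
        # patch ids are a relabelling of vertices; each patch is a singleton
        assert len(np.unique(part.assignment)) == 12

    def test_single_patch(self, icosahedron):
        part = cd.build_patch_partition(icosahedron, 1)
        assert part.n_patches == 1
        assert np.all(part.assignment == 0)

    def test_partition_invariants(self, icosphere2):
        part = cd.build_patch_partition(icosphere2, 40)
        assert part.n_patches == 40
        counts = np.bincount(part.assignment, minlength=40)
        assert counts.sum() == icosphere2.n_vertices
        assert np.all(counts > 0)

    def test_k_capped_at_vertex_count(self, icosahedron):
        part = cd.build_patch_partition(icosahedron, 1000)
        assert part.n_patches == 12

    def test_matches_exhaustive_farthest_point_oracle(self, icosahedron):
        """Greedy centers equal a brute-force max-min search on the
        all-pairs geodesic distance matrix."""
        adj = cd.vertex_adjacency(icosahedron)
        dmat = shortest_path(adj, directed=False)
        k = 4
        centers = [0]
        for _ in range(1, k):
            mind = dmat[centers].min(axis=0)
            centers.append(int(np.argmax(mind)))  # first max = lowest id
        part = cd.build_patch_partition(icosahedron, k, start_vertex=0)
        assert part.centers.tolist() == centers
        # second center is at maximal graph distance from vertex 0
        assert dmat[0, part.centers[1]] == dmat[0].max()
        # assignment: nearest center, ties to the lower patch id
        expect = np.empty(12, dtype=int)
        for v in range(12):
            d = dmat[centers, v]
            expect[v] = int(np.argmin(d))
        assert np.array_equal(part.assignment, expect)


class TestPatchFeatures:
    def test_identity_partition_returns_vertex_values(self):
        part = PatchPartition(centers=np.arange(3), assignment=np.arange(3))
        sts = SurfaceTimeSeries(data=np.array([[1.0, 2.0, 3.0]]), tr_s=1.5)
        fm = cd.patch_features(sts, part)
        assert np.allclose(fm.data, [[1.0, 2.0, 3.0]])

    def test_single_patch_is_global_mean(self):
        part = PatchPartition(centers=np.array([0]), assignment=np.zeros(3, dtype=int))
        sts = SurfaceTimeSeries(data=np.array([[1.0, 2.0, 6.0], [3.0, 3.0, 3.0]]), tr_s=1.5)
        fm = cd.patch_features(sts, part)
        assert np.allclose(fm.data, [[3.0], [3.0]])

    def test_two_patch_toy(self):
        """Vertices {a:1, b:3} and {c:5} -> features [2, 5]."""
        part = PatchPartition(centers=np.array([0, 2]), assignment=np.array([0, 0, 1]))
        sts = SurfaceTimeSeries(data=np.array([[1.0, 3.0, 5.0]]), tr_s=1.5)
        fm = cd.patch_features(sts, part)
        assert np.allclose(fm.data, [[2.0, 5.0]])


class TestSelectFeatures:
    def _fm(self, cols, labels):
        data = np.column_stack(cols)
        return FeatureMatrix(
            data=data, feature_ids=np.arange(data.shape[1]), labels=np.asarray(labels)
        )

    def test_two_group_toy_f_statistic(self):
        """Groups A=(1,2), B=(5,6): between/within sums of squares give 32."""
        fm = self._fm([np.array([1.0, 2.0, 5.0, 6.0])], [1, 1, 2, 2])
        f = anova_f_scores(fm)
        # independent oracle: direct sums of squares
        a, b = np.array([1.0, 2.0]), np.array([5.0, 6.0])
        grand = 3.5
        ssb = 2 * (a.mean() - grand) ** 2 + 2 * (b.mean() - grand) ** 2
        ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        expect = (ssb / 1) / (ssw / 2)
        assert expect == 32.0
        assert np.isclose(f[0], 32.0)

    def test_constant_feature_ranks_last_label_copy_first(self):
        labels = [1, 1, 2, 2, 3, 3]
        fm = self._fm(
            [
                np.full(6, 4.0),                      # constant -> F = 0
                np.array([0.3, -0.1, 0.2, 0.0, -0.2, 0.1]),  # noise
                np.array(labels, dtype=float),        # exact copy -> F = inf
            ],
            labels,
        )
        order = cd.select_features(fm, 3)
        assert order[0] == 2
        assert order[-1] == 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((12, 5))
        labels = np.repeat([1, 2, 3], 4)
        fm = FeatureMatrix(data=data, feature_ids=np.arange(5), labels=labels)
        scaled = FeatureMatrix(
            data=data * np.array([1e3, 2.0, 0.5, 10.0, 7.0]) + 3.0,
            feature_ids=np.arange(5),
            labels=labels,
        )
        assert np.array_equal(cd.select_features(fm, 5), cd.select_features(scaled, 5))

    def test_tie_break_prefers_lower_feature_id(self):
        col = np.array([1.0, 2.0, 5.0, 6.0])
        fm = self._fm([col, col.copy()], [1, 1, 2, 2])
        assert cd.select_features(fm, 2).tolist() == [0, 1]

    def test_class_with_single_sample_raises(self):
        fm = self._fm([np.array([1.0, 2.0, 3.0])], [1, 1, 2])
        with pytest.raises(ValueError, match="< 2 training samples"):
            cd.select_features(fm, 1)


def test_end_to_end_extraction_is_deterministic(small_subject):
    mesh, sim = small_subject
    kwargs = dict(fwhm_mm=6.0, k_base=100, block_size=5)
    a = cd.extract_block_samples(sim.runs, mesh, sim.schedule, **kwargs)
    b = cd.extract_block_samples(sim.runs, mesh, sim.schedule, **kwargs)
    assert np.array_equal(a.data, b.data)
    assert np.array_equal(a.labels, b.labels)
    assert np.array_equal(a.groups, b.groups)
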