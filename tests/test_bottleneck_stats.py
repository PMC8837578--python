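"""Classification, prevalence statistics and bottleneck clustering."""

import numpy as np
import pytest

from wmbottleneck.bottleneck_stats import (
    classify,
    find_bottleneck_regions,
    prevalence_tables,
    single_fixel_voxel_histogram,
    zero_and_single_bundle_maps,
)
from wmbottleneck.fixel_extract import ConsistencyError, FixelGrid

Z = [0.0, 0.0, 1.0]
X = [1.0, 0.0, 0.0]
Y = [0.0, 1.0, 0.0]


def make_grid(shape, fixel_dirs_per_voxel):
    counts = np.zeros(shape, dtype=np.int64)
    offsets = np.zeros(shape, dtype=np.int64)
    dirs = []
    off = 0
    for ijk in np.ndindex(*shape):
        ds = fixel_dirs_per_voxel.get(ijk, [])
        counts[ijk] = len(ds)
        offsets[ijk] = off
        dirs.extend(ds)
        off += len(ds)
    n = len(dirs)
    return FixelGrid(
        shape=shape,
        affine=np.eye(4),
        counts=counts,
        offsets=offsets,
        directions=np.asarray(dirs, float).reshape(n, 3),
        peak_amplitudes=np.full(n, 0.5),
        lobe_integrals=np.full(n, 0.2),
    )


def _classify(grid, counts_fixel, counts_voxel=None, mask=None):
    counts_fixel = np.asarray(counts_fixel)
    if counts_voxel is None:
        # derive the voxel counts as the per-voxel max (valid when bundle
        # sets are nested; explicit counts used where the union is larger)
        counts_voxel = np.zeros(grid.shape, dtype=int)
        for ijk in np.ndindex(*grid.shape):
            idx = grid.fixels_of_voxel(*ijk)
            counts_voxel[ijk] = counts_fixel[idx].max() if len(idx) else 0
    if mask is None:
        mask = np.ones(grid.shape, bool)
    return classify(grid, counts_fixel, np.asarray(counts_voxel), mask)


class TestClassify:
    def test_bottleneck_case_single_fixel_multi_bundle(self):
        # one fixel traversed by two bundles: the bottleneck configuration
        grid = make_grid((1, 1, 1), {(0, 0, 0): [Y]})
        c = _classify(grid, [2])
        assert c.voxel_class(0, 0, 0) == "single-fixel/multi-bundle"
        assert c.fixel_class(0) == "multi-bundle"

    def test_fanning_case_multi_fixel_single_bundle(self):
        # two fixels, both traversed by the same single bundle
        grid = make_grid((1, 1, 1), {(0, 0, 0): [Z, X]})
        c = _classify(grid, [1, 1])
        assert c.voxel_class(0, 0, 0) == "multi-fixel/single-bundle"
        assert c.fixel_class(0) == c.fixel_class(1) == "single-bundle"

    def test_crossing_case_mixed_fixel_classes(self):
        # two fixels, bundle sets of size 1 and 2 -> multi-bundle voxel
        grid = make_grid((1, 1, 1), {(0, 0, 0): [Z, X]})
        c = _classify(grid, [1, 2])
        assert c.voxel_class(0, 0, 0) == "multi-fixel/multi-bundle"
        assert c.fixel_class(0) == "single-bundle"
        assert c.fixel_class(1) == "multi-bundle"

    def test_zero_bundle_fixel_flagged(self):
        grid = make_grid((1, 1, 1), {(0, 0, 0): [Z]})
        c = _classify(grid, [0])
        assert c.fixel_class(0) == "zero-bundle"
        assert c.voxel_class(0, 0, 0) == "single-fixel/zero-bundle"

    def test_inconsistent_counts_raise(self):
        grid = make_grid((1, 1, 1), {(0, 0, 0): [Z]})
        with pytest.raises(ConsistencyError):
            # multi-bundle fixel inside a single-bundle voxel is impossible
            classify(grid, np.array([2]), np.ones((1, 1, 1), int), np.ones((1, 1, 1), bool))

    def test_mask_shape_mismatch_raises(self):
        grid = make_grid((2, 1, 1), {(0, 0, 0): [Z]})
        with pytest.raises(ValueError):
            classify(grid, np.array([1]), np.ones((2, 1, 1), int), np.ones((3, 1, 1), bool))


class TestPrevalenceTables:
    def test_multi_bundle_fraction_arithmetic(self):
        dirs = {(i, 0, 0): [Z] for i in range(100)}
        grid = make_grid((100, 1, 1), dirs)
        counts = np.array([1] * 50 + [2] * 30 + [3] * 20)
        tables = prevalence_tables(_classify(grid, counts))
        assert tables["multi_bundle_fixel_fraction"] == pytest.approx(0.5)
        fr = tables["bundles_per_fixel"]["fractions"]
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_all_single_bundle_gives_zero_fraction(self):
        grid = make_grid((4, 1, 1), {(i, 0, 0): [Z] for i in range(4)})
        tables = prevalence_tables(_classify(grid, [1, 1, 1, 1]))
        assert tables["multi_bundle_fixel_fraction"] == 0.0

    def test_zero_bundle_elements_change_no_fraction(self):
        grid_a = make_grid((3, 1, 1), {(i, 0, 0): [Z] for i in range(3)})
        t_a = prevalence_tables(_classify(grid_a, [1, 2, 2]))
        # same data plus two zero-bundle fixels in extra voxels
        grid_b = make_grid((5, 1, 1), {(i, 0, 0): [Z] for i in range(5)})
        t_b = prevalence_tables(_classify(grid_b, [1, 2, 2, 0, 0]))
        assert t_a["bundles_per_fixel"]["fractions"] == t_b["bundles_per_fixel"]["fractions"]
        assert (
            t_a["multi_bundle_fixel_fraction"] == t_b["multi_bundle_fixel_fraction"]
        )

    def test_histogram_caps_at_seven_plus(self):
        grid = make_grid((2, 1, 1), {(i, 0, 0): [Z] for i in range(2)})
        tables = prevalence_tables(_classify(grid, [9, 3]))
        assert tables["bundles_per_fixel"]["counts"]["7+"] == 1

    def test_empty_denominator_marker_not_nan(self):
        grid = make_grid((2, 1, 1), {})
        tables = prevalence_tables(_classify(grid, []))
        assert tables["bundles_per_fixel"]["empty"] is True
        assert tables["bundles_per_fixel"]["fractions"] is None


class TestSingleFixelVoxelHistogram:
    def test_no_single_fixel_voxels_gives_empty_marker(self):
        grid = make_grid((1, 1, 1), {(0, 0, 0): [Z, X]})
        table = single_fixel_voxel_histogram(_classify(grid, [1, 1]))
        assert table["empty"] is True

    def test_bottleneck_voxels_counted_multi(self):
        grid = make_grid((2, 1, 1), {(0, 0, 0): [Z], (1, 0, 0): [Z]})
        table = single_fixel_voxel_histogram(_classify(grid, [2, 1]))
        assert table["fraction_multi"] == pytest.approx(0.5)


class TestZeroAndSingleBundleMaps:
    def test_masks_partition_with_multi(self):
        grid = make_grid((3, 1, 1), {(i, 0, 0): [Z] for i in range(3)})
        c = _classify(grid, [0, 1, 2])
        zero, single = zero_and_single_bundle_maps(c)
        assert zero.tolist() == [True, False, False]
        assert single.tolist() == [False, True, False]
        multi = c.fixel_bundle_count >= 2
        assert np.all(zero ^ single ^ multi)  # exhaustive, disjoint


class TestFindBottleneckRegions:
    def _line_grid(self, n=8, direction=Y):
        dirs = {(i, 0, 0): [direction] for i in range(n)}
        return make_grid((n, 1, 1), dirs)

    def test_threshold_above_max_gives_empty_list(self):
        grid = self._line_grid()
        counts = np.full(grid.n_fixels, 3)
        assert find_bottleneck_regions(counts, grid, min_bundles=7) == []

    def test_min_bundles_below_two_rejected(self):
        grid = self._line_grid()
        with pytest.raises(ValueError):
            find_bottleneck_regions(np.full(grid.n_fixels, 3), grid, min_bundles=1)

    def test_coherent_line_forms_one_cluster(self):
        grid = self._line_grid()
        counts = np.full(grid.n_fixels, 7)
        found = find_bottleneck_regions(counts, grid, min_bundles=7, min_size=5)
        assert len(found) == 1
        assert found[0].size_voxels == 8
        assert found[0].min_bundle_count == 7

    def test_two_disjoint_corridors_give_two_clusters(self):
        dirs = {(i, 0, 0): [Y] for i in range(16)}
        grid = make_grid((16, 1, 1), dirs)
        counts = np.zeros(grid.n_fixels, dtype=int)
        counts[:6] = 7
        counts[10:] = 7  # gap of 4 empty voxels between corridors
        found = find_bottleneck_regions(counts, grid, min_bundles=7, min_size=3)
        assert len(found) == 2

    def test_incoherent_directions_fragment(self):
        # alternating orthogonal orientations: zero tolerance -> no edges
        dirs = {(i, 0, 0): [Y if i % 2 == 0 else X] for i in range(8)}
        grid = make_grid((8, 1, 1), dirs)
        counts = np.full(grid.n_fixels, 7)
        tight = find_bottleneck_regions(counts, grid, min_bundles=7, angle_tol_deg=1.0, min_size=2)
        assert tight == []  # all components are singletons
        loose = find_bottleneck_regions(counts, grid, min_bundles=7, angle_tol_deg=95.0, min_size=2)
        assert len(loose) == 1

    def test_members_meet_threshold(self):
        grid = self._line_grid()
        counts = np.array([7, 7, 7, 2, 7, 7, 7, 7])
        found = find_bottleneck_regions(counts, grid, min_bundles=7, min_size=2)
        for cluster in found:
            assert np.all(counts[cluster.fixel_indices] >= 7)

    def test_overlap3_phantom_yields_one_corridor_cluster(self, phantom_run):
        res = phantom_run("overlap3")["result"]
        found = find_bottleneck_regions(
            res.counts_fixel, res.fixels, min_bundles=3, min_size=3
        )
        assert len(found) == 1
        # corridor runs along y
        assert abs(found[0].direction[1]) > np.cos(np.deg2rad(10))
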