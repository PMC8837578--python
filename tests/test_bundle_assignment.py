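"""Bundle-to-fixel assignment: density maps, profiles, bundle counting."""

import numpy as np
import pytest

from wmbottleneck.bundle_assignment import (
    BundleProfile,
    FixelDensityMap,
    bundles_per_fixel,
    bundles_per_voxel,
    fixel_density,
    threshold_profile,
)
from wmbottleneck.fixel_extract import FixelGrid
from wmbottleneck.tract_io import Bundle, map_streamline_to_voxels


def make_grid(shape, fixel_dirs_per_voxel):
    """FixelGrid with explicit per-voxel fixel directions (C voxel order)."""
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


Z = [0.0, 0.0, 1.0]
X = [1.0, 0.0, 0.0]


class TestFixelDensity:
    def test_aligned_streamlines_count_on_matching_fixel(self):
        grid = make_grid((1, 1, 1), {(0, 0, 0): [Z, X]})
        streamlines = [
            np.array([[0.5, 0.5, 0.1], [0.5, 0.5, 0.9]]) for _ in range(10)
        ]
        density = fixel_density(Bundle("b", streamlines), grid)
        assert density.counts.tolist() == [10, 0]

    def test_exact_tie_goes_to_lower_flat_index(self):
        grid = make_grid((1, 1, 1), {(0, 0, 0): [Z, X]})
        # 45 degrees between the x and z fixels: |dot| identical
        diag = np.array([[0.1, 0.5, 0.1], [0.9, 0.5, 0.9]])
        density = fixel_density(Bundle("b", [diag]), grid)
        assert density.counts.tolist() == [1, 0]

    def test_empty_bundle_gives_zero_map(self):
        grid = make_grid((1, 1, 1), {(0, 0, 0): [Z]})
        density = fixel_density(Bundle("b", []), grid)
        assert np.all(density.counts == 0)

    def test_zero_fixel_voxels_contribute_nothing(self):
        grid = make_grid((2, 1, 1), {(0, 0, 0): [X]})  # voxel 1 has no fixel
        line = np.array([[0.1, 0.5, 0.5], [1.9, 0.5, 0.5]])
        density = fixel_density(Bundle("b", [line]), grid)
        assert density.counts.tolist() == [1]


class TestThresholdProfile:
    def test_five_percent_of_max_rule(self):
        grid = make_grid((4, 1, 1), {(i, 0, 0): [Z] for i in range(4)})
        density = FixelDensityMap("b", np.array([100, 20, 4, 0]))
        profile = threshold_profile(density, grid, frac=0.05)
        assert profile.fixel_mask.tolist() == [True, True, False, False]

    def test_all_equal_positive_counts_all_kept(self):
        grid = make_grid((3, 1, 1), {(i, 0, 0): [Z] for i in range(3)})
        profile = threshold_profile(FixelDensityMap("b", np.array([7, 7, 7])), grid)
        assert profile.fixel_mask.all()

    def test_inclusive_boundary(self):
        grid = make_grid((2, 1, 1), {(i, 0, 0): [Z] for i in range(2)})
        profile = threshold_profile(FixelDensityMap("b", np.array([19, 1])), grid, frac=0.05)
        assert profile.fixel_mask.tolist() == [True, True]  # 1 >= 0.95

    def test_all_zero_density_yields_empty_profile(self, caplog):
        grid = make_grid((2, 1, 1), {(i, 0, 0): [Z] for i in range(2)})
        with caplog.at_level("WARNING"):
            profile = threshold_profile(FixelDensityMap("b", np.zeros(2, int)), grid)
        assert not profile.fixel_mask.any()
        assert not profile.voxel_mask.any()

    def test_invalid_fraction_rejected(self):
        grid = make_grid((1, 1, 1), {(0, 0, 0): [Z]})
        with pytest.raises(ValueError):
            threshold_profile(FixelDensityMap("b", np.array([1])), grid, frac=0.0)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        grid = make_grid((8, 1, 1), {(i, 0, 0): [Z] for i in range(8)})
        for _ in range(20):
            density = FixelDensityMap("b", rng.integers(0, 100, size=8))
            lo = threshold_profile(density, grid, frac=0.05).fixel_mask
            hi = threshold_profile(density, grid, frac=0.10).fixel_mask
            assert not np.any(hi & ~lo)  # raising frac never adds fixels

    def test_voxel_mask_is_projection_of_fixel_mask(self):
        grid = make_grid((2, 1, 1), {(0, 0, 0): [Z, X], (1, 0, 0): [Z]})
        profile = threshold_profile(FixelDensityMap("b", np.array([50, 3, 0])), grid)
        assert profile.fixel_mask.tolist() == [True, True, False]
        assert profile.voxel_mask[0, 0, 0] and not profile.voxel_mask[1, 0, 0]


class TestBundleCounting:
    def test_count_once_union_rule(self):
        # one voxel, fixel1 in {A,B}, fixel2 in {B,C} -> 3 distinct bundles
        grid = make_grid((1, 1, 1), {(0, 0, 0): [Z, X]})
        profiles = [
            BundleProfile("A", np.array([True, False]), np.ones((1, 1, 1), bool), 0.05),
            BundleProfile("B", np.array([True, True]), np.ones((1, 1, 1), bool), 0.05),
            BundleProfile("C", np.array([False, True]), np.ones((1, 1, 1), bool), 0.05),
        ]
        per_fixel = bundles_per_fixel(profiles)
        per_voxel = bundles_per_voxel(profiles)
        assert per_fixel.tolist() == [2, 2]
        assert per_voxel[0, 0, 0] == 3

    def test_single_bundle_voxel(self):
        grid = make_grid((1, 1, 1), {(0, 0, 0): [Z]})
        profiles = [BundleProfile("A", np.array([True]), np.ones((1, 1, 1), bool), 0.05)]
        assert bundles_per_voxel(profiles)[0, 0, 0] == 1

    def test_no_profiles_all_zero(self):
        assert bundles_per_fixel([], n_fixels=4).tolist() == [0, 0, 0, 0]
        assert np.all(bundles_per_voxel([], shape=(2, 2, 2)) == 0)

    def test_voxel_count_bounded_by_fixel_counts_and_profiles(self, phantom_run):
        res = phantom_run("overlap3")["result"]
        grid = res.fixels
        per_fixel, per_voxel = res.counts_fixel, res.counts_voxel
        n_profiles = len(res.profiles)
        for ijk in np.argwhere(grid.counts > 0):
            idx = grid.fixels_of_voxel(*ijk)
            v = per_voxel[tuple(ijk)]
            assert v >= per_fixel[idx].max()
            assert v <= per_fixel[idx].sum() or v <= n_profiles
            assert v <= n_profiles


class TestExhaustiveRecountOracle:
    def test_toy_grid_matches_brute_force(self):
        """bundles_per_fixel / bundles_per_voxel vs an independent
        per-streamline recount on a 5x5x5 grid with 3 hand-placed bundles."""
        fixel_dirs = {}
        for ijk in np.ndindex(5, 5, 5):
            fixel_dirs[ijk] = [Z, X] if (ijk[0] + ijk[1]) % 2 == 0 else [Z]
        grid = make_grid((5, 5, 5), fixel_dirs)
        rng = np.random.default_rng(21)
        bundles = []
        for b in range(3):
            streamlines = []
            for _ in range(rng.integers(5, 21)):
                # axis-aligned-ish lines with jitter, along varying axes
                axis = b % 2
                start = rng.uniform(0.5, 4.5, size=3)
                end = start.copy()
                start[axis], end[axis] = 0.3, 4.7
                mid = (start + end) / 2 + rng.normal(scale=0.1, size=3)
                streamlines.append(np.vstack([start, mid, end]))
            bundles.append(Bundle(f"B{b}", streamlines))

        densities = [fixel_density(b, grid) for b in bundles]
        profiles = [threshold_profile(d, grid, frac=0.05) for d in densities]
        got_fixel = bundles_per_fixel(profiles)
        got_voxel = bundles_per_voxel(profiles)

        # --- independent recount: dict-based, straight from visits ---
        streams_per_fixel = {}
        for bundle in bundles:
            for streamline in bundle.streamlines:
                hit = set()
                for visit in map_streamline_to_voxels(streamline, np.eye(4)):
                    i, j, k = visit.voxel
                    if not (0 <= i < 5 and 0 <= j < 5 and 0 <= k < 5):
                        continue
                    o, c = int(grid.offsets[i, j, k]), int(grid.counts[i, j, k])
                    best, best_dot = None, -1.0
                    for f in range(o, o + c):
                        d = abs(float(grid.directions[f] @ visit.direction))
                        if d > best_dot + 1e-12:
                            best, best_dot = f, d
                    if best is not None:
                        hit.add(best)
                for f in hit:
                    streams_per_fixel.setdefault(bundle.name, {}).setdefault(f, 0)
                    streams_per_fixel[bundle.name][f] += 1
        exp_fixel = np.zeros(grid.n_fixels, dtype=int)
        exp_voxel = np.zeros((5, 5, 5), dtype=int)
        for name, counts in streams_per_fixel.items():
            peak = max(counts.values())
            kept = {f for f, c in counts.items() if c >= 0.05 * peak and c > 0}
            voxels = set()
            for f in kept:
                exp_fixel[f] += 1
                voxels.add(tuple(grid.voxel_index[f]))
            for v in voxels:
                exp_voxel[v] += 1
        np.testing.assert_array_equal(got_fixel, exp_fixel)
        np.testing.assert_array_equal(got_voxel, exp_voxel)
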