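import numpy as np
import pytest

from livervoi import (
    DegenerateImageError,
    NoValidCandidateError,
    SphereVOI,
    find_min_cvv,
    local_stats,
    place_reference_voi,
    sphere_mask,
)
from livervoi.phantom import LABEL_LIVER
from livervoi.volume_io import VoxelGrid

from conftest import brute_force_local_stats, make_grid


class TestLocalStats:
    def test_constant_grid_gives_zero_sd_and_cvv_exactly(self):
        grid = make_grid(np.full((10, 10, 10), 2.5), spacing=(4.1, 4.1, 2.0))
        stats = local_stats(grid, 12.0)
        assert stats.valid_map.all()
        assert np.array_equal(stats.mean_map, np.full(grid.shape, 2.5))
        assert np.array_equal(stats.sd_map, np.zeros(grid.shape))
        assert np.array_equal(stats.cvv_map, np.zeros(grid.shape))

    def test_neighborhood_of_one_two_three(self):
        # 3 voxels in a 1-mm line; a 2-mm sphere at the middle voxel covers
        # exactly {1, 2, 3}: mean 2, sample SD 1, CVv 0.5
        grid = make_grid(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1))
        stats = local_stats(grid, 2.0)
        assert stats.mean_map[1, 0, 0] == pytest.approx(2.0, abs=1e-12)
        assert stats.sd_map[1, 0, 0] == pytest.approx(1.0, abs=1e-12)
        assert stats.cvv_map[1, 0, 0] == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spacing = tuple(rng.uniform(0.8, 4.5, size=3))
        shape = tuple(rng.integers(6, 13, size=3))
        grid = VoxelGrid(values=rng.normal(2.0, 0.5, size=shape), spacing=spacing)
        diameter = rng.uniform(3.0, 4.0) * min(spacing)
        stats = local_stats(grid, diameter)
        mean, sd, cvv, valid = brute_force_local_stats(grid, diameter)
        assert np.array_equal(stats.valid_map, valid)
        assert np.allclose(stats.mean_map, mean, atol=1e-9, rtol=0)
        assert np.allclose(stats.sd_map, sd, atol=1e-9, rtol=0)
        assert np.allclose(stats.cvv_map[valid], cvv[valid], atol=1e-9, rtol=0)

    def test_nonpositive_mean_is_invalid(self):
        values = np.zeros((6, 6, 6))
        values[5, 5, 5] = 1.0
        grid = make_grid(values)
        stats = local_stats(grid, 2.0)
        assert not stats.valid_map[0, 0, 0]
        assert np.isinf(stats.cvv_map[0, 0, 0])
        assert stats.valid_map[5, 5, 5]

    def test_restrict_to_marks_others_invalid(self, rng):
        grid = make_grid(rng.uniform(1, 3, size=(8, 8, 8)))
        keep = np.zeros(grid.shape, dtype=bool)
        keep[2:4, 2:4, 2:4] = True
        stats = local_stats(grid, 4.0, restrict_to=keep)
        assert stats.valid_map[keep].all()
        assert not stats.valid_map[~keep].any()
        assert np.isinf(stats.cvv_map[~keep]).all()

    def test_nonpositive_diameter_rejected(self):
        grid = make_grid(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            local_stats(grid, 0.0)


class TestFindMinCvv:
    def test_constant_grid_tie_breaks_to_lexicographic_smallest(self):
        grid = make_grid(np.full((12, 12, 12), 3.0), spacing=(2.0, 2.0, 2.0))
        voi_large = SphereVOI((11.0, 11.0, 11.0), 16.0)
        idx = find_min_cvv(grid, voi_large, d_medium_mm=8.0, d_voi_mm=6.0)
        # expected: first candidate in C order, computed independently
        from livervoi.cvv_search import _voi_fits_mask

        candidates = sphere_mask(grid, voi_large) & _voi_fits_mask(grid, 3.0, grid)
        expected = tuple(int(v) for v in np.argwhere(candidates)[0])
        assert idx == expected
        assert idx == find_min_cvv(grid, voi_large, d_medium_mm=8.0, d_voi_mm=6.0)

    def test_scale_invariance_of_selection(self, rng):
        base = rng.uniform(1.0, 3.0, size=(14, 14, 14))
        voi_large = SphereVOI((13.0, 13.0, 13.0), 20.0)
        picks = []
        for c in (0.5, 1.0, 7.0):
            grid = make_grid(c * base, spacing=(2.0, 2.0, 2.0))
            picks.append(find_min_cvv(grid, voi_large, d_medium_mm=8.0, d_voi_mm=6.0))
        assert picks[0] == picks[1] == picks[2]

    def test_empty_candidate_set_raises(self):
        grid = make_grid(np.ones((4, 4, 4)))
        # reference sphere larger than the grid: cannot fit anywhere
        with pytest.raises(NoValidCandidateError):
            find_min_cvv(grid, SphereVOI((2.0, 2.0, 2.0), 20.0), 2.0, 10.0)
        # search sphere outside the grid
        with pytest.raises(NoValidCandidateError):
            find_min_cvv(grid, SphereVOI((100.0, 0.0, 0.0), 4.0), 2.0, 2.0)

    def test_all_zero_image_is_degenerate(self):
        grid = make_grid(np.zeros((10, 10, 10)))
        with pytest.raises(DegenerateImageError):
            find_min_cvv(grid, SphereVOI((5.0, 5.0, 5.0), 8.0), 4.0, 2.0)

    def test_translation_covariance(self, rng):
        from scipy.ndimage import gaussian_filter

        content = gaussian_filter(rng.uniform(1, 3, size=(20, 20, 20)), 1.5)
        grid1 = make_grid(content, spacing=(2.0, 2.0, 2.0))
        grid2 = make_grid(np.roll(content, 1, axis=0), spacing=(2.0, 2.0, 2.0))
        c1 = (19.0, 19.0, 19.0)
        c2 = (21.0, 19.0, 19.0)  # shifted by one voxel along x
        i1 = find_min_cvv(grid1, SphereVOI(c1, 14.0), 8.0, 6.0)
        i2 = find_min_cvv(grid2, SphereVOI(c2, 14.0), 8.0, 6.0)
        assert i2 == (i1[0] + 1, i1[1], i1[2])


class TestPlaceReferenceVoi:
    def test_constant_grid_report(self):
        grid = make_grid(np.full((16, 16, 16), 1.7), spacing=(4.0, 4.0, 4.0))
        rep = place_reference_voi(
            grid, (30.0, 30.0, 30.0), d_large_mm=40.0, d_medium_mm=16.0, d_voi_mm=12.0
        )
        assert rep.voi30_mean == pytest.approx(1.7)
        assert rep.voi30_sd == 0.0
        assert rep.threshold == pytest.approx(1.7)
        assert rep.min_cvv == 0.0

    def test_phantom_center_lands_inside_liver(self, phantom7):
        grid, labels, _ = phantom7
        rep = place_reference_voi(grid, (260.0, 280.0, 108.0))
        assert labels.values[rep.center_index] == LABEL_LIVER
        mask30 = sphere_mask(grid, SphereVOI(rep.center_mm, 30.0))
        assert np.all(labels.values[mask30] == LABEL_LIVER)

    def test_voi30_mean_matches_liver_interior_ground_truth(self, phantom7):
        grid, labels, truth = phantom7
        rep = place_reference_voi(grid, (260.0, 280.0, 108.0))
        # interior = liver voxels whose 30-mm sphere is pure liver: the
        # region the reference VOI can sample without partial-volume bias
        from scipy.ndimage import binary_erosion

        from livervoi.cvv_search import spherical_kernel

        liver = labels.values == LABEL_LIVER
        interior = binary_erosion(liver, spherical_kernel(grid.spacing, 30.0))
        interior_mean = grid.values[interior].mean()
        assert rep.voi30_mean == pytest.approx(interior_mean, abs=0.05)
        assert rep.threshold == pytest.approx(
            rep.voi30_mean + 3 * rep.voi30_sd, abs=1e-12
        )

    @pytest.mark.parametrize("d_medium", [40.0, 60.0, 80.0, 100.0, 120.0])
    def test_all_studied_neighborhood_sizes_accepted(self, phantom7, d_medium):
        grid, _, _ = phantom7
        rep = place_reference_voi(grid, (260.0, 280.0, 108.0), d_medium_mm=d_medium)
        assert rep.params["d_medium_mm"] == d_medium
        assert rep.voi30_voxel_count > 0

    def test_invalid_config_rejected(self, phantom7):
        grid, _, _ = phantom7
        with pytest.raises(ValueError):
            place_reference_voi(grid, (260, 280, 108), d_voi_mm=200.0, d_large_mm=150.0)
        with pytest.raises(ValueError):
            place_reference_voi(grid, (260, 280, 108), k=-1.0)

    def test_report_serializes(self, phantom7):
        import json

        grid, _, _ = phantom7
        rep = place_reference_voi(grid, (260.0, 280.0, 108.0))
        payload = json.loads(json.dumps(rep.to_dict()))
        assert payload["threshold"] == rep.threshold
        assert payload["params"]["tie_break"] == "lexicographic-smallest-index"
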