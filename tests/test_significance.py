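import warnings

import numpy as np
import pytest
from scipy import stats

from conftest import make_object
from objcoloc.colocalisation import OverlapCriterion
from objcoloc.roi import RoiMask
from objcoloc.significance import (
    PlacementError,
    SignificanceConfig,
    check_spatial_ratio,
    monte_carlo_significance,
    randomize_objects,
)


def suppress_ratio_warning():
    return warnings.catch_warnings()


class TestRandomizeObjects:
    def test_single_pixel_uniform_over_roi(self, square_roi_mask, rng):
        """A 1-px object lands on each of the 100 ROI positions uniformly."""
        obj = make_object({(3, 3)})
        counts = np.zeros((12, 12))
        n = 10000
        for _ in range(n):
            grid = randomize_objects([obj], square_roi_mask, rng)
            counts += grid
        inside = counts[1:11, 1:11].ravel() / n
        assert np.all(np.abs(inside - 0.01) <= 0.005)
        assert counts[square_roi_mask.labels == 0].sum() == 0
        # chi-square goodness of fit against the uniform law
        chi2 = ((counts[1:11, 1:11].ravel() - n / 100) ** 2 / (n / 100)).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=99)

    def test_object_filling_roi_is_forced(self, rng):
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[2:4, 2:4] = 1
        mask = RoiMask(labels=labels)
        obj = make_object({(2, 2), (2, 3), (3, 2), (3, 3)})
        for _ in range(20):
            grid = randomize_objects([obj], mask, rng)
            assert np.array_equal(grid, labels > 0)

    def test_pixel_conservation_under_merging(self, square_roi_mask, rng):
        objs = [make_object({(2, 2), (2, 3), (3, 2)}, object_id=i) for i in range(6)]
        total = sum(o.area_px for o in objs)
        for _ in range(30):
            grid = randomize_objects(objs, square_roi_mask, rng)
            assert grid.sum() <= total

    def test_shape_preserved_translation_only(self, square_roi_mask, rng):
        """Placed pixels are a pure translation of the original shape."""
        shape = {(0, 0), (0, 1), (1, 1), (2, 1), (2, 2)}
        obj = make_object({(r + 3, c + 3) for r, c in shape})
        for _ in range(50):
            grid = randomize_objects([obj], square_roi_mask, rng)
            coords = np.argwhere(grid)
            assert len(coords) == len(shape)
            normalized = {tuple(p) for p in coords - coords.min(axis=0)}
            assert normalized == shape

    def test_unplaceable_object_raises(self, rng):
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[2, 2] = 1  # 1-px ROI
        mask = RoiMask(labels=labels)
        obj = make_object({(0, 0), (0, 1), (0, 2)})
        with pytest.raises(PlacementError, match="ROI 1"):
            randomize_objects([obj], mask, rng, max_attempts=10)

    def test_objects_stay_in_their_own_roi(self, rng):
        labels = np.zeros((14, 26), dtype=np.int32)
        labels[2:12, 2:12] = 1
        labels[2:12, 14:24] = 2
        mask = RoiMask(labels=labels)
        obj1 = make_object({(3, 3), (3, 4)}, roi_id=1)
        obj2 = make_object({(3, 15), (4, 15)}, roi_id=2)
        for _ in range(50):
            grid = randomize_objects([obj1, obj2], mask, rng)
            assert grid[labels == 1].sum() == 2
            assert grid[labels == 2].sum() == 2
            assert grid[labels == 0].sum() == 0


class TestMonteCarloSignificance:
    def test_same_seed_bit_identical(self, square_roi_mask):
        red = [make_object({(2, 2), (2, 3), (3, 3)}, 1, "red")]
        green = [make_object({(7, 7), (7, 8), (8, 8)}, 2, "green")]
        cfg = SignificanceConfig(n_iterations=50, seed=123)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = monte_carlo_significance(red, green, square_roi_mask,
                                         OverlapCriterion(min_pixels=1), cfg)
            b = monte_carlo_significance(red, green, square_roi_mask,
                                         OverlapCriterion(min_pixels=1), cfg)
        assert np.array_equal(a.random_counts, b.random_counts)
        assert a.p_value == b.p_value and a.t_statistic == b.t_statistic

    def test_degenerate_all_zero_gives_p_one(self):
        """Huge ROI, tiny far-apart objects, strict criterion: every random
        draw gives 0 colocalisations, observed is 0, so p = 1."""
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[1:39, 1:39] = 1
        mask = RoiMask(labels=labels)
        red = [make_object({(3, 3)}, 1, "red")]
        green = [make_object({(30, 30)}, 2, "green")]
        with pytest.warns(UserWarning, match="zero variance"):
            res = monte_carlo_significance(
                red, green, mask, OverlapCriterion(min_pixels=3),
                SignificanceConfig(n_iterations=20, seed=1),
            )
        assert res.observed_count == 0
        assert np.all(res.random_counts == 0)
        assert res.p_value == 1.0

    def test_planted_overlaps_highly_significant(self):
        """50 exact overlaps in small ROIs sit far above the null support."""
        from objcoloc.detection import SegmentedObject

        h = w = 20
        n_rois = 50
        cols = 10
        labels = np.zeros((5 * h, cols * w), dtype=np.int32)
        reds, greens = [], []
        for k in range(n_rois):
            r0, c0 = (k // cols) * h, (k % cols) * w
            labels[r0 + 1 : r0 + h - 1, c0 + 1 : c0 + w - 1] = k + 1
            blob = {(r0 + 5 + dr, c0 + 5 + dc) for dr in range(3) for dc in range(4)}
            reds.append(make_object(blob, k + 1, "red", roi_id=k + 1))
            greens.append(make_object(blob, 100 + k, "green", roi_id=k + 1))
        mask = RoiMask(labels=labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = monte_carlo_significance(
                reds, greens, mask, OverlapCriterion(min_pixels=3),
                SignificanceConfig(n_iterations=100, seed=5),
            )
        assert res.observed_count == 50
        assert res.mean_random < 50
        assert res.p_value < 0.01

    def test_collision_probability_closed_form(self, square_roi_mask):
        """1 red + 1 green single-pixel object in a 100-px ROI collide with
        probability 1/100 under uniform independent placement."""
        red = [make_object({(2, 2)}, 1, "red")]
        green = [make_object({(5, 5)}, 2, "green")]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = monte_carlo_significance(
                red, green, square_roi_mask, OverlapCriterion(min_pixels=1),
                SignificanceConfig(n_iterations=10000, seed=11),
            )
        assert 0.005 <= res.mean_random <= 0.015

    def test_t_statistic_matches_direct_formula(self, square_roi_mask):
        red = [make_object({(2, 2), (2, 3)}, 1, "red")]
        green = [make_object({(5, 5), (5, 6)}, 2, "green")]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = monte_carlo_significance(
                red, green, square_roi_mask, OverlapCriterion(min_pixels=1),
                SignificanceConfig(n_iterations=200, seed=3), observed_count=2,
            )
        counts = res.random_counts
        if counts.std(ddof=1) > 0:
            t = (counts.mean() - 2) / (counts.std(ddof=1) / np.sqrt(len(counts)))
            assert res.t_statistic == pytest.approx(t)
            p = 2 * stats.t.sf(abs(t), df=len(counts) - 1)
            assert res.p_value == pytest.approx(p)

    def test_null_calibration(self):
        """When the observed scene is itself a draw from the null, the
        two-sided p-value rejects at 5% rarely: over 200 replicate scenes
        the rejection fraction stays in [0.01, 0.12]."""
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[1:11, 1:11] = 1
        mask = RoiMask(labels=labels)
        template_red = [make_object({(2, 2)}, 1, "red")]
        template_green = [make_object({(6, 6)}, 2, "green")]
        crit = OverlapCriterion(min_pixels=1)
        rejections = 0
        n_scenes = 200
        master = np.random.SeedSequence(777)
        scene_seeds = master.spawn(n_scenes)
        from objcoloc.colocalisation import count_colocalisations
        from objcoloc.detection import segment_objects

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, ss in enumerate(scene_seeds):
                rng = np.random.default_rng(ss)
                red_grid = randomize_objects(template_red, mask, rng)
                green_grid = randomize_objects(template_green, mask, rng)
                raw = np.zeros((12, 12), dtype=np.uint16)
                reds = segment_objects(red_grid, mask, raw, channel_name="red")
                greens = segment_objects(green_grid, mask, raw, channel_name="green")
                observed = count_colocalisations(reds, greens, crit).n_coloc
                res = monte_carlo_significance(
                    reds, greens, mask, crit,
                    SignificanceConfig(n_iterations=100, seed=10_000 + i),
                    observed_count=observed,
                )
                if res.p_value < 0.05:
                    rejections += 1
        assert 0.01 <= rejections / n_scenes <= 0.12

    def test_spatial_ratio_guard_warns(self, square_roi_mask):
        big = make_object({(r, c) for r in range(2, 5) for c in range(2, 5)})
        with pytest.warns(UserWarning, match="600"):
            ok = check_spatial_ratio([big], square_roi_mask)
        assert not ok

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SignificanceConfig(n_iterations=1)
        with pytest.raises(ValueError):
            SignificanceConfig(sidedness="sideways")
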