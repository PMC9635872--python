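import numpy as np
import pytest

from atlasmaker.consensus import (
    average_masks,
    build_label_model,
    imprint_overlap_curve,
    intersect_models,
    threshold_consensus,
)
from atlasmaker.core import BinaryMask, dice
from atlasmaker.errors import ConfigError, DiagnosticError, GeometryError
from atlasmaker.phantom import (
    PhantomParams,
    make_neural_tube_phantom,
    simulate_user_segmentations,
)

from .conftest import UNIT, random_mask


@pytest.fixture(scope="module")
def tube_truth():
    _, truth = make_neural_tube_phantom(
        shape=(48, 48, 48), seed=0, params=PhantomParams(noise_sd=0.0)
    )
    return truth.total_domain


class TestAverageMasks:
    def test_identical_masks_give_extreme_counts(self, tube_truth):
        cmap = average_masks([tube_truth] * 4)
        assert set(np.unique(cmap.counts)) <= {0, 4}

    def test_disjoint_masks_max_count_one(self):
        a = BinaryMask(np.zeros((6, 6, 6), bool), UNIT)
        b = BinaryMask(np.zeros((6, 6, 6), bool), UNIT)
        a.values[:3], b.values[3:] = True, True
        assert average_masks([a, b]).counts.max() == 1

    def test_matches_per_voxel_sum(self):
        rng = np.random.default_rng(0)
        masks = [random_mask((16, 16, 16), rng) for _ in range(5)]
        cmap = average_masks(masks)
        expected = sum(m.values.astype(int) for m in masks)
        assert np.array_equal(cmap.counts, expected)

    def test_geometry_mismatch(self):
        a = BinaryMask(np.zeros((4, 4, 4), bool), UNIT)
        b = BinaryMask(np.zeros((4, 4, 5), bool), UNIT)
        with pytest.raises(GeometryError):
            average_masks([a, b])


class TestThresholdConsensus:
    def test_extremes_are_union_and_intersection(self):
        rng = np.random.default_rng(1)
        masks = [random_mask((12, 12, 12), rng) for _ in range(4)]
        cmap = average_masks(masks)
        union = np.logical_or.reduce([m.values for m in masks])
        inter = np.logical_and.reduce([m.values for m in masks])
        assert np.array_equal(threshold_consensus(cmap, 1).values, union)
        assert np.array_equal(threshold_consensus(cmap, 4).values, inter)

    def test_at_least_three_selects_high_counts(self):
        rng = np.random.default_rng(2)
        masks = [random_mask((10, 10, 10), rng) for _ in range(5)]
        cmap = average_masks(masks)
        mask3 = threshold_consensus(cmap, 3)
        assert np.array_equal(mask3.values, cmap.counts >= 3)
        assert set(np.unique(cmap.counts[mask3.values])) <= {3, 4, 5}

    def test_nesting_for_increasing_k(self):
        rng = np.random.default_rng(3)
        masks = [random_mask((10, 10, 10), rng) for _ in range(6)]
        cmap = average_masks(masks)
        for k in range(1, 6):
            outer = threshold_consensus(cmap, k).values
            inner = threshold_consensus(cmap, k + 1).values
            assert not np.any(inner & ~outer)

    def test_out_of_range_k(self):
        cmap = average_masks([random_mask((4, 4, 4), np.random.default_rng(0))] * 2)
        for k in (0, 3):
            with pytest.raises(ConfigError):
                threshold_consensus(cmap, k)


class TestBuildLabelModel:
    def test_identical_inputs_pass_through(self, tube_truth):
        groups = [[tube_truth] * 3 for _ in range(4)]
        model = build_label_model(groups, user_rule="all", embryo_k=3)
        assert np.array_equal(model.mask.values, tube_truth.values)

    def test_model_beats_mean_individual_dice(self, tube_truth):
        """Consensus over simulated embryos outscores the average single embryo."""
        for seed in range(5):
            groups = []
            singles = []
            for e in range(5):
                users = simulate_user_segmentations(
                    tube_truth, 3, 0.25, seed=1000 * seed + e
                )
                groups.append(users)
                singles.append(
                    np.mean([dice(u, tube_truth) for u in users])
                )
            model = build_label_model(groups, user_rule=2, embryo_k=3)
            assert dice(model.mask, tube_truth) >= np.mean(singles)

    def test_stricter_embryo_threshold_nests(self, tube_truth):
        groups = [
            simulate_user_segmentations(tube_truth, 2, 0.2, seed=e) for e in range(5)
        ]
        strict = build_label_model(groups, user_rule=1, embryo_k=5).mask
        loose = build_label_model(groups, user_rule=1, embryo_k=3).mask
        assert not np.any(strict.values & ~loose.values)

    def test_permutation_invariance(self, tube_truth):
        groups = [
            simulate_user_segmentations(tube_truth, 3, 0.2, seed=e) for e in range(4)
        ]
        a = build_label_model(groups, user_rule="all", embryo_k=3).mask
        shuffled = [list(reversed(g)) for g in reversed(groups)]
        b = build_label_model(shuffled, user_rule="all", embryo_k=3).mask
        assert np.array_equal(a.values, b.values)

    def test_too_few_embryos(self, tube_truth):
        with pytest.raises(ConfigError):
            build_label_model([[tube_truth] * 2] * 2)


class TestImprintCurve:
    def test_union_imprint_gives_zero_overlap(self, tube_truth):
        """With the imprint taken against the k=1 support, overlap vanishes."""
        users = simulate_user_segmentations(tube_truth, 4, 0.1, seed=0)
        clipped = [u & tube_truth for u in users]
        curve = imprint_overlap_curve(average_masks(clipped), tube_truth, imprint_k=1)
        assert (curve.overlap_fraction == 0).all()

    def test_shell_overlap_decreases_with_k(self):
        # core agreed by all raters, a surrounding shell only by one
        counts = np.zeros((12, 12, 12), np.int32)
        counts[4:8, 4:8, 4:8] = 3
        counts[2:10, 2:10, 2:10][counts[2:10, 2:10, 2:10] == 0] = 1
        reference = BinaryMask(np.ones((12, 12, 12), bool), UNIT)
        from atlasmaker.consensus import ConsensusMap

        cmap = ConsensusMap(counts, 3, UNIT)
        curve = imprint_overlap_curve(cmap, reference)
        # the k=1 signal spills into the strict-consensus hole; k=3 does not
        assert curve.overlap_fraction.iloc[0] > 0
        assert curve.overlap_fraction.iloc[0] > curve.overlap_fraction.iloc[1]
        assert curve.overlap_fraction.iloc[2] == 0.0

    def test_empty_signal_flagged_zero(self):
        from atlasmaker.consensus import ConsensusMap

        counts = np.zeros((8, 8, 8), np.int32)
        counts[2:4, 2:4, 2:4] = 1
        cmap = ConsensusMap(counts, 3, UNIT)
        curve = imprint_overlap_curve(cmap, BinaryMask(np.ones((8, 8, 8), bool), UNIT))
        assert curve.overlap_fraction.iloc[2] == 0.0
        assert bool(curve.empty_signal.iloc[2])

    def test_empty_reference_rejected(self):
        from atlasmaker.consensus import ConsensusMap

        cmap = ConsensusMap(np.ones((4, 4, 4), np.int32), 2, UNIT)
        with pytest.raises(DiagnosticError):
            imprint_overlap_curve(cmap, BinaryMask(np.zeros((4, 4, 4), bool), UNIT))


class TestIntersectModels:
    def test_self_intersection_dice_one(self, tube_truth):
        table, combined = intersect_models([tube_truth, tube_truth])
        assert table.dice.iloc[0] == pytest.approx(1.0)
        assert table.intersection_um3.iloc[0] == pytest.approx(tube_truth.volume_um3)

    def test_disjoint_models(self):
        a = BinaryMask(np.zeros((6, 6, 6), bool), UNIT)
        b = BinaryMask(np.zeros((6, 6, 6), bool), UNIT)
        a.values[:2], b.values[4:] = True, True
        table, _ = intersect_models([a, b])
        assert table.intersection_um3.iloc[0] == 0.0

    def test_matches_voxel_loop_and_bitmask(self):
        rng = np.random.default_rng(5)
        masks = [random_mask((8, 8, 8), rng) for _ in range(3)]
        table, combined = intersect_models(masks)
        for _, row in table.iterrows():
            a, b = masks[int(row.model_a)], masks[int(row.model_b)]
            assert row.intersection_um3 == np.sum(a.values & b.values)
        for i, m in enumerate(masks):
            assert np.array_equal((combined >> i) & 1 == 1, m.values)


class TestMajorityFusionProperty:
    def test_majority_dice_increases_with_rater_count(self, tube_truth):
        """Mean majority-vote Dice strictly increases over n = 3, 5, 7 raters."""
        means = []
        for n in (3, 5, 7):
            scores = []
            for seed in range(50):
                users = simulate_user_segmentations(
                    tube_truth, n, 0.2, seed=10_000 + seed
                )
                majority = threshold_consensus(average_masks(users), n // 2 + 1)
                scores.append(dice(majority, tube_truth))
            means.append(np.mean(scores))
        assert means[0] < means[1] < means[2]
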