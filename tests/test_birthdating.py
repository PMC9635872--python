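import numpy as np
import pytest

from atlasmaker.birthdating import (
    build_birthdate_map,
    interval_growth_table,
    population_birthdates,
)
from atlasmaker.core import BinaryMask, euler_rigid
from atlasmaker.errors import ConfigError
from atlasmaker.phantom import make_neural_tube_phantom
from atlasmaker.registration import apply_transform

from .conftest import UNIT


def _cube(n, lo, hi):
    m = np.zeros((n, n, n), bool)
    m[lo:hi, lo:hi, lo:hi] = True
    return BinaryMask(m, UNIT)


@pytest.fixture
def nested_cubes():
    """Cubes 8^3 in 12^3 in 16^3 inside a 20^3 total domain (24^3 grid)."""
    total = _cube(24, 2, 22)
    m1 = _cube(24, 8, 16)
    m2 = _cube(24, 6, 18)
    m3 = _cube(24, 4, 20)
    return [m1, m2, m3], total


class TestBuildBirthdateMap:
    def test_nested_cube_interval_counts(self, nested_cubes):
        masks, total = nested_cubes
        bmap = build_birthdate_map(masks, total, [24, 36, 48], 72)
        counts = [int((bmap.labels == i).sum()) for i in range(1, 5)]
        assert counts == [512, 1216, 2368, 3904]
        assert bmap.repaired_voxels == 0

    def test_partition_is_exact(self, nested_cubes):
        masks, total = nested_cubes
        bmap = build_birthdate_map(masks, total, [24, 36, 48], 72)
        assert int((bmap.labels > 0).sum()) == total.voxel_count
        assert np.array_equal(bmap.labels > 0, total.values)

    def test_single_mask_equal_to_total(self):
        total = _cube(16, 2, 14)
        bmap = build_birthdate_map([total], total, [48], 72)
        assert int((bmap.labels == 1).sum()) == total.voxel_count
        assert int((bmap.labels == 2).sum()) == 0

    def test_nesting_repair_counts_lobe(self):
        """A lobe of the early mask outside the late mask is union-repaired."""
        total = _cube(24, 2, 22)
        early = _cube(24, 8, 16)
        early.values[2:6, 8:16, 8:16] = True  # 4*8*8 = 256-voxel lobe, clear of the late cube
        late = _cube(24, 6, 18)
        bmap = build_birthdate_map([early, late], total, [24, 48], 72)
        assert bmap.repaired_voxels == 256
        # repaired cumulative mask keeps the lobe out of interval 2
        assert int((bmap.labels == 1).sum()) == early.voxel_count
        union = early | late
        assert int((bmap.labels == 2).sum()) == union.voxel_count - early.voxel_count

    def test_monotone_nesting_after_enforcement(self, nested_cubes):
        masks, total = nested_cubes
        shuffled = [masks[1], masks[0], masks[2]]  # violates nesting on purpose
        bmap = build_birthdate_map(shuffled, total, [24, 36, 48], 72)
        cumulative = np.zeros(total.shape, bool)
        for i in range(1, bmap.n_intervals):
            cumulative |= bmap.labels == i
            assert not np.any(cumulative & ~total.values)

    def test_unsorted_times_rejected(self, nested_cubes):
        masks, total = nested_cubes
        with pytest.raises(ConfigError):
            build_birthdate_map(masks, total, [36, 24, 48], 72)

    def test_acquisition_before_last_conversion_rejected(self, nested_cubes):
        masks, total = nested_cubes
        with pytest.raises(ConfigError):
            build_birthdate_map(masks, total, [24, 36, 48], 48)


class TestPopulationBirthdates:
    def test_population_inside_first_interval(self, nested_cubes):
        masks, total = nested_cubes
        bmap = build_birthdate_map(masks, total, [24, 36, 48], 72)
        pop = _cube(24, 9, 15)
        frac = population_birthdates(pop, bmap)
        assert frac.fractions.tolist() == pytest.approx([1.0, 0, 0, 0])

    def test_whole_domain_population_matches_interval_volumes(self, nested_cubes):
        masks, total = nested_cubes
        bmap = build_birthdate_map(masks, total, [24, 36, 48], 72)
        frac = population_birthdates(total, bmap)
        expected = np.array([512, 1216, 2368, 3904]) / 8000
        assert frac.fractions == pytest.approx(expected)

    def test_fractions_sum_to_one(self, nested_cubes):
        masks, total = nested_cubes
        bmap = build_birthdate_map(masks, total, [24, 36, 48], 72)
        rng = np.random.default_rng(0)
        pop = BinaryMask(total.values & (rng.random(total.shape) < 0.3), UNIT)
        frac = population_birthdates(pop, bmap)
        assert frac.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_shell_population_recovers_constructed_mix(self):
        """A population built to span shells 20/60/20 is recovered exactly."""
        _, truth = make_neural_tube_phantom(shape=(48, 48, 48), seed=0)
        s1, s2, s3 = truth.shells
        bmap = build_birthdate_map([s1, s2], s3, [24, 48], 72)
        rng = np.random.default_rng(1)
        pop = np.zeros(s3.shape, bool)
        targets = {1: 0.2, 2: 0.6, 3: 0.2}
        counts = {}
        for label, f in targets.items():
            voxels = np.argwhere(bmap.labels == label)
            take = int(round(f * 5000))
            pick = voxels[rng.choice(len(voxels), take, replace=False)]
            pop[tuple(pick.T)] = True
            counts[label] = take
        frac = population_birthdates(BinaryMask(pop, s3.spacing), bmap)
        total = sum(counts.values())
        expected = [counts[1] / total, counts[2] / total, counts[3] / total]
        assert frac.fractions == pytest.approx(expected, abs=0.01)

    def test_population_outside_domain_flagged(self, nested_cubes):
        masks, total = nested_cubes
        bmap = build_birthdate_map(masks, total, [24, 36, 48], 72)
        outside = BinaryMask(np.zeros(total.shape, bool), UNIT)
        outside.values[0, 0, 0] = True
        frac = population_birthdates(outside, bmap)
        assert frac.empty
        assert frac.outside_domain_um3 > 0

    def test_fractions_invariant_under_joint_rigid_motion(self, nested_cubes):
        masks, total = nested_cubes
        bmap = build_birthdate_map(masks, total, [24, 36, 48], 72)
        pop = _cube(24, 5, 17)
        before = population_birthdates(pop, bmap).fractions
        t = euler_rigid((0, 0, 10), (1.3, -0.7, 0.4))
        moved_masks = [apply_transform(m, t, interpolation="nearest") for m in masks]
        moved_total = apply_transform(total, t, interpolation="nearest")
        moved_pop = apply_transform(pop, t, interpolation="nearest")
        bmap2 = build_birthdate_map(moved_masks, moved_total, [24, 36, 48], 72)
        after = population_birthdates(moved_pop, bmap2).fractions
        assert after == pytest.approx(before, abs=0.02)


class TestIntervalGrowthTable:
    def test_nested_cube_cumulative_ratios(self, nested_cubes):
        masks, total = nested_cubes
        bmap = build_birthdate_map(masks, total, [24, 36, 48], 72)
        table = interval_growth_table(bmap)
        assert table.cumulative_ratio.tolist() == pytest.approx(
            [512 / 8000, 1728 / 8000, 4096 / 8000, 1.0]
        )

    def test_single_interval_ratio_one(self):
        total = _cube(16, 2, 14)
        bmap = build_birthdate_map([total], total, [48], 72)
        table = interval_growth_table(bmap)
        assert table.cumulative_ratio.iloc[-1] == pytest.approx(1.0)

    def test_ratios_non_decreasing_end_at_one(self):
        _, truth = make_neural_tube_phantom(shape=(48, 48, 48), seed=2)
        s1, s2, s3 = truth.shells
        bmap = build_birthdate_map([s1, s2], s3, [24, 48], 72)
        ratios = interval_growth_table(bmap).cumulative_ratio.to_numpy()
        assert np.all(np.diff(ratios) >= 0)
        assert ratios[-1] == pytest.approx(1.0)
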