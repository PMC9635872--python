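import numpy as np
import pandas as pd
import pytest

from atlasmaker.core import BinaryMask, VolumeStack, dice
from atlasmaker.errors import ConfigError, TrainingError
from atlasmaker.phantom import (
    PhantomParams,
    make_neural_tube_phantom,
    sample_annotations,
)
from atlasmaker.segmentation import (
    Annotation,
    PixelClassifier,
    UserVolumeTable,
    compute_features,
    flag_outlier_users,
    segment_volume,
    train_classifier,
)

from .conftest import UNIT


class TestComputeFeatures:
    def test_constant_volume(self):
        vol = VolumeStack(np.full((8, 8, 8), 7.0), UNIT)
        fs = compute_features(vol, (1, 2))
        for m, v in zip(fs.means, fs.variances):
            assert np.allclose(m, 7.0)
            assert np.allclose(v, 0.0)

    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(0)
        vol = VolumeStack(rng.random((6, 6, 6)), UNIT)
        fs = compute_features(vol, (0,))
        assert np.array_equal(fs.means[0], vol.values)
        assert np.allclose(fs.variances[0], 0.0)

    def test_matches_sliding_window_loop(self):
        """Mean/variance layers agree with a brute-force reflected window."""
        rng = np.random.default_rng(7)
        vals = rng.random((8, 8, 8))
        fs = compute_features(VolumeStack(vals, UNIT), (1,))
        padded = np.pad(vals, 1, mode="symmetric")  # edge value repeated, as in the filter
        for idx in np.ndindex(8, 8, 8):
            z, y, x = idx
            win = padded[z : z + 3, y : y + 3, x : x + 3]
            assert fs.means[0][idx] == pytest.approx(win.mean(), abs=1e-10)
            assert fs.variances[0][idx] == pytest.approx(win.var(), abs=1e-10)

    def test_oversized_scale_rejected(self):
        vol = VolumeStack(np.zeros((8, 8, 8)), UNIT)
        with pytest.raises(ConfigError):
            compute_features(vol, (1, 5))


def _two_level_phantom(fg=200.0, bg=20.0, noise_sd=0.0, seed=0):
    (ch1, _), truth = make_neural_tube_phantom(
        shape=(48, 48, 48),
        seed=seed,
        params=PhantomParams(foreground=fg, background=bg, noise_sd=noise_sd),
    )
    return ch1, truth


class TestTrainAndSegment:
    def test_separable_phantom_reaches_full_training_accuracy(self):
        vol, truth = _two_level_phantom()
        fs = compute_features(vol, (1, 2))
        ann = sample_annotations(truth.total_domain, 50, seed=1)
        clf = train_classifier(fs, ann, seed=0)
        pred = clf.model.predict(fs.at(ann.indices))
        assert np.mean(pred == ann.labels) == 1.0

    def test_fixed_seed_serializes_identically(self):
        vol, truth = _two_level_phantom()
        fs = compute_features(vol, (1, 2))
        ann = sample_annotations(truth.total_domain, 50, seed=1)
        a = train_classifier(fs, ann, seed=0).to_bytes()
        b = train_classifier(fs, ann, seed=0).to_bytes()
        assert a == b

    def test_reloaded_classifier_predicts_identically(self, tmp_path):
        vol, truth = _two_level_phantom(noise_sd=36.0)
        fs = compute_features(vol, (1, 2))
        ann = sample_annotations(truth.total_domain, 50, seed=1)
        clf = train_classifier(fs, ann, seed=0)
        clf.save(tmp_path / "clf.pkl")
        reloaded = PixelClassifier.load(tmp_path / "clf.pkl")
        m1 = segment_volume(vol, clf)
        m2 = segment_volume(vol, reloaded)
        assert np.array_equal(m1.values, m2.values)

    def test_noisy_phantom_dice(self):
        """Dice >= 0.90 against truth at noise sd = 20% of contrast."""
        vol, truth = _two_level_phantom(noise_sd=36.0, seed=2)
        fs = compute_features(vol, (1, 2, 4))
        ann = sample_annotations(truth.total_domain, 100, seed=3)
        clf = train_classifier(fs, ann, seed=0)
        mask = segment_volume(vol, clf)
        assert dice(mask, truth.total_domain) >= 0.90

    def test_all_background_volume_segments_empty(self):
        vol, truth = _two_level_phantom(noise_sd=10.0)
        fs = compute_features(vol, (1, 2))
        ann = sample_annotations(truth.total_domain, 50, seed=1)
        clf = train_classifier(fs, ann, seed=0)
        flat = VolumeStack(np.full((48, 48, 48), 20.0), UNIT)
        assert segment_volume(flat, clf).voxel_count == 0

    def test_threshold_monotonicity(self):
        vol, truth = _two_level_phantom(noise_sd=36.0)
        fs = compute_features(vol, (1, 2))
        ann = sample_annotations(truth.total_domain, 50, seed=1)
        clf = train_classifier(fs, ann, seed=0)
        strict = segment_volume(vol, PixelClassifier(clf.model, clf.scales, 0, 1.0))
        loose = segment_volume(vol, PixelClassifier(clf.model, clf.scales, 0, 0.5))
        assert not np.any(strict.values & ~loose.values)

    def test_single_class_annotation_rejected(self):
        vol, _ = _two_level_phantom()
        fs = compute_features(vol, (1,))
        ann = Annotation(np.array([[1, 1, 1], [2, 2, 2]]), np.array([1, 1]))
        with pytest.raises(TrainingError):
            train_classifier(fs, ann)

    def test_dice_degrades_with_annotation_label_noise(self):
        """Average Dice is non-increasing as annotation labels are corrupted."""
        vol, truth = _two_level_phantom(noise_sd=36.0, seed=5)
        fs = compute_features(vol, (1, 2))
        mean_dice = []
        for noise in (0.0, 0.1, 0.3):
            scores = []
            for seed in range(5):
                ann = sample_annotations(truth.total_domain, 80, seed=seed)
                labels = ann.labels.copy()
                rng = np.random.default_rng(100 + seed)
                flip = rng.random(labels.size) < noise
                labels[flip] = 1 - labels[flip]
                noisy = Annotation(ann.indices, labels, ann.strokes)
                clf = train_classifier(fs, noisy, seed=0)
                scores.append(dice(segment_volume(vol, clf), truth.total_domain))
            mean_dice.append(np.mean(scores))
        assert mean_dice[0] >= mean_dice[1] >= mean_dice[2]


class TestOutlierUsers:
    def test_identical_users_f_zero_none_flagged(self):
        table = UserVolumeTable.from_array(np.tile([100.0, 110, 120, 105], (4, 1)))
        flagged, summary = flag_outlier_users(table)
        assert flagged == set()
        assert summary.F.iloc[0] == 0.0

    def test_inflated_user_flagged(self):
        """A user +30% above the others across 12 specimens is the only outlier."""
        rng = np.random.default_rng(0)
        base = 1000 + 50 * rng.random(12)
        vols = np.stack([base * (1 + rng.uniform(-0.02, 0.02, 12)) for _ in range(5)])
        vols[3] = base * 1.30
        flagged, summary = flag_outlier_users(UserVolumeTable.from_array(vols))
        assert flagged == {"u4"}

    def test_tight_users_not_flagged(self):
        rng = np.random.default_rng(1)
        base = 500 + 20 * rng.random(12)
        vols = np.stack([base * (1 + rng.uniform(-0.02, 0.02, 12)) for _ in range(4)])
        flagged, _ = flag_outlier_users(UserVolumeTable.from_array(vols))
        assert flagged == set()

    def test_low_cv_never_flagged(self):
        """No flagging when between-user coefficient of variation < 1%."""
        rng = np.random.default_rng(2)
        for seed in range(5):
            r = np.random.default_rng(seed)
            base = 800 + 100 * r.random(10)
            vols = np.stack(
                [base * (1 + r.uniform(-0.005, 0.005, 10)) for _ in range(5)]
            )
            means = vols.mean(axis=1)
            assert means.std() / means.mean() < 0.01
            flagged, _ = flag_outlier_users(UserVolumeTable.from_array(vols))
            assert flagged == set()

    def test_too_few_users_rejected(self):
        with pytest.raises(ConfigError):
            flag_outlier_users(UserVolumeTable.from_array(np.ones((1, 5))))

    def test_anova_matches_scipy(self):
        """The internal sum-of-squares ANOVA agrees with scipy's F test."""
        from scipy import stats

        from atlasmaker.segmentation import _one_way_anova

        rng = np.random.default_rng(3)
        table = rng.normal(100, 10, size=(4, 8))
        F, p = _one_way_anova(table)
        F_ref, p_ref = stats.f_oneway(*table)
        assert F == pytest.approx(F_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)
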