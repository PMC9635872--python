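"""Trainable voxel classification from sparse brush annotations.

Each user draws foreground strokes on areas with signal and background
strokes on areas considered noise; a per-user classifier is trained on
local mean and local variance features (deliberately minimal, so the
pipeline stays cheap enough to run on consumer hardware) and then applied
to whole volumes to produce binary masks — one mask per user classifier
per embryo.  Classifiers whose segmented volumes deviate too much from the
other users' (ANOVA across a panel of specimens plus a relative-deviation
threshold, default 10%) are flagged as outliers and excluded.

The classifier family is a random decision-forest on the mean/variance
features; training is fully deterministic for a fixed seed and serialized
classifiers reload with bit-identical predictions, so a classifier can be
reused to segment every dataset of a study.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.ensemble import RandomForestClassifier

from .core import BinaryMask, VolumeStack
from .errors import ConfigError, TrainingError

FOREGROUND = 1
BACKGROUND = 0

DEFAULT_SCALES = (1, 2, 4)


@dataclass
class Annotation:
    """Sparse voxel labels: (n, 3) grid indices and {0, 1} class labels.

    ``strokes`` optionally groups voxels into the brush strokes they came
    from (same length as ``labels``); it is carried for provenance only.
    """

    indices: np.ndarray
    labels: np.ndarray
    strokes: np.ndarray | None = None

    def __post_init__(self):
        self.indices = np.atleast_2d(np.asarray(self.indices, int))
        self.labels = np.asarray(self.labels, int).ravel()
        if self.indices.shape != (self.labels.size, 3):
            raise ConfigError("annotation indices must be (n, 3) with n labels")

    def validate_for(self, shape) -> None:
        if not ({FOREGROUND, BACKGROUND} <= set(np.unique(self.labels))):
            raise TrainingError(
                "annotation must contain both foreground and background strokes"
            )
        if np.any(self.indices < 0) or np.any(self.indices >= np.asarray(shape)):
            raise ConfigError("annotation indices fall outside the grid")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Annotation":
        """Build from a table with columns x, y, z, label (grid axis order z,y,x)."""
        idx = df[["z", "y", "x"]].to_numpy(int)
        strokes = df["stroke"].to_numpy() if "stroke" in df else None
        return cls(idx, df["label"].to_numpy(int), strokes)


@dataclass
class FeatureStack:
    """Per-scale local-mean and local-variance volumes.

    One mean and one variance layer per scale; scale radii are in voxels
    (cubic windows, anisotropy ignored at feature level).
    """

    scales: tuple[int, ...]
    means: list[np.ndarray]
    variances: list[np.ndarray]

    def __post_init__(self):
        if len(self.scales) == 0:
            raise ConfigError("scale list must be non-empty")
        if not (len(self.means) == len(self.variances) == len(self.scales)):
            raise ConfigError("one mean and one variance layer required per scale")

    @property
    def shape(self):
        return self.means[0].shape

    def as_matrix(self) -> np.ndarray:
        """(n_voxels, 2 * n_scales) design matrix, mean layers first per scale."""
        layers = []
        for m, v in zip(self.means, self.variances):
            layers.append(m.ravel())
            layers.append(v.ravel())
        return np.stack(layers, axis=1)

    def at(self, indices: np.ndarray) -> np.ndarray:
        flat = np.ravel_multi_index(tuple(np.asarray(indices, int).T), self.shape)
        return self.as_matrix()[flat]


def compute_features(vol: VolumeStack, scales=DEFAULT_SCALES) -> FeatureStack:
    """Local mean and variance in cubic windows of each radius.

    A window of radius ``r`` spans ``(2r + 1)^3`` voxels; edges are handled
    by reflection.  Radius 0 degenerates to the input itself with zero
    variance.  Variance is computed as ``E[x^2] - E[x]^2``, clipped at 0
    against floating-point cancellation.
    """
    scales = tuple(int(s) for s in scales)
    if any(s < 0 for s in scales):
        raise ConfigError("scale radii must be non-negative")
    if max(scales) > min(vol.shape) // 2:
        raise ConfigError(
            f"scale {max(scales)} exceeds half the smallest grid dimension "
            f"of shape {vol.shape}"
        )
    x = vol.values.astype(np.float64)
    means, variances = [], []
    for r in scales:
        if r == 0:
            means.append(x.copy())
            variances.append(np.zeros_like(x))
            continue
        size = 2 * r + 1
        m = ndimage.uniform_filter(x, size=size, mode="reflect")
        m2 = ndimage.uniform_filter(x * x, size=size, mode="reflect")
        means.append(m)
        variances.append(np.clip(m2 - m * m, 0.0, None))
    return FeatureStack(scales, means, variances)


@dataclass
class PixelClassifier:
    """A trained per-user voxel classifier.

    Wraps the decision-forest state together with the feature scale list,
    the training seed and the foreground probability threshold, so that the
    exact same segmentation can be reproduced on any dataset.
    """

    model: RandomForestClassifier
    scales: tuple[int, ...]
    seed: int
    threshold: float = 0.5

    def to_bytes(self) -> bytes:
        return pickle.dumps(self, protocol=5)

    @classmethod
    def from_bytes(cls, blob: bytes) -> "PixelClassifier":
        obj = pickle.loads(blob)
        if not isinstance(obj, cls):
            raise ConfigError("serialized object is not a PixelClassifier")
        return obj

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.to_bytes())

    @classmethod
    def load(cls, path) -> "PixelClassifier":
        with open(path, "rb") as fh:
            return cls.from_bytes(fh.read())


def train_classifier(
    features: FeatureStack,
    annotation: Annotation,
    seed: int = 0,
    n_estimators: int = 100,
    threshold: float = 0.5,
) -> PixelClassifier:
    """Train a decision-forest voxel classifier on annotated voxels.

    Requires both classes in the annotation.  A fixed seed yields an
    identical model (training is single-threaded).
    """
    annotation.validate_for(features.shape)
    X = features.at(annotation.indices)
    y = annotation.labels
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    model.fit(X, y)
    return PixelClassifier(model, features.scales, seed, threshold)


def segment_volume(vol: VolumeStack, clf: PixelClassifier) -> BinaryMask:
    """Apply a trained classifier to a whole volume.

    A voxel is foreground when its predicted foreground probability is at
    least the classifier's threshold.
    """
    features = compute_features(vol, clf.scales)
    X = features.as_matrix()
    fg_col = list(clf.model.classes_).index(FOREGROUND) if FOREGROUND in clf.model.classes_ else None
    if fg_col is None:
        prob = np.zeros(X.shape[0])
    else:
        prob = clf.model.predict_proba(X)[:, fg_col]
    mask = (prob >= clf.threshold).reshape(vol.shape)
    return BinaryMask(mask, vol.spacing, vol.axis_labels)


@dataclass
class UserVolumeTable:
    """Segmented volumes (um^3): rows = users, columns = specimens."""

    table: pd.DataFrame

    @classmethod
    def from_array(cls, volumes: np.ndarray, user_ids=None, specimen_ids=None):
        volumes = np.atleast_2d(np.asarray(volumes, float))
        users = user_ids or [f"u{i + 1}" for i in range(volumes.shape[0])]
        specimens = specimen_ids or [f"e{i + 1}" for i in range(volumes.shape[1])]
        return cls(pd.DataFrame(volumes, index=users, columns=specimens))

    def validate(self) -> None:
        if self.table.shape[0] < 2:
            raise ConfigError("outlier testing needs at least 2 users")
        if self.table.shape[1] < 3:
            raise ConfigError("outlier testing needs at least 3 specimens")


def _one_way_anova(values: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA across rows (users as factor, specimens as replicates).

    Sum-of-squares formulas computed directly; returns (F, p).  A table
    with zero within- and between-group variation yields F = 0, p = 1.
    """
    k, n = values.shape
    grand = values.mean()
    group_means = values.mean(axis=1)
    ss_between = n * np.sum((group_means - grand) ** 2)
    ss_within = np.sum((values - group_means[:, None]) ** 2)
    df_between = k - 1
    df_within = k * (n - 1)
    ms_between = ss_between / df_between
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        return np.inf, 0.0
    ms_within = ss_within / df_within
    F = ms_between / ms_within
    p = float(stats.f.sf(F, df_between, df_within))
    return float(F), p


def flag_outlier_users(
    table: UserVolumeTable | pd.DataFrame,
    rel_tol: float = 0.10,
    alpha: float = 0.05,
) -> tuple[set, pd.DataFrame]:
    """Flag users whose segmented volumes deviate from the consensus.

    A user is an outlier when the user factor is significant in a one-way
    ANOVA at ``alpha`` AND that user's mean volume deviates by more than
    ``rel_tol`` (default 10%) from the mean of the remaining users.  After
    each removal the test is rerun on the survivors until nothing more is
    flagged.  Returns the flagged user ids and a per-iteration ANOVA
    summary table (F, p, the flagged user and its relative deviation).
    """
    if isinstance(table, pd.DataFrame):
        table = UserVolumeTable(table)
    table.validate()
    df = table.table.copy()
    flagged: set = set()
    rows = []
    while df.shape[0] >= 2:
        F, p = _one_way_anova(df.to_numpy(float))
        user_means = df.mean(axis=1)
        deviations = {}
        for user in df.index:
            others = user_means.drop(user).mean()
            deviations[user] = abs(user_means[user] - others) / others if others else np.inf
        worst = max(deviations, key=deviations.get)
        is_outlier = p < alpha and deviations[worst] > rel_tol
        rows.append(
            {
                "F": F,
                "p": p,
                "worst_user": worst,
                "worst_rel_deviation": deviations[worst],
                "flagged": is_outlier,
            }
        )
        if not is_outlier:
            break
        flagged.add(worst)
        df = df.drop(index=worst)
    return flagged, pd.DataFrame(rows)
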