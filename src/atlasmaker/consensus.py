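"""Consensus fusion of segmentations into label 3D-models.

Per-user binary masks of a single embryo are averaged into an agreement
count per voxel; thresholding that count gives the embryo's consensus
mask.  Per-embryo masks are then averaged and thresholded again (signal
agreed by at least ``k`` embryos, default 3) to give the label 3D-model
that enters the atlas.  Fusion is pure vote counting — agreement is kept
as integer counts so thresholds stay exact even when embryos have
different numbers of retained users.

Threshold selection across embryos is supported by the imprint diagnostic:
the thresholded signal is compared against the signal's negative imprint
onto a reference domain (the voxels of the reference never touched by any
rater), and a good threshold leaves only marginal overlap between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import BinaryMask, VoxelSpacing, dice
from .errors import ConfigError, DiagnosticError, GeometryError


@dataclass
class ConsensusMap:
    """Voxelwise agreement counts across raters (users or embryos)."""

    counts: np.ndarray
    n_raters: int
    spacing: VoxelSpacing

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.n_raters:
            raise GeometryError("agreement counts must lie in [0, n_raters]")


@dataclass
class Label3DModel:
    """A thresholded cross-embryo consensus mask with its provenance."""

    mask: BinaryMask
    embryo_ids: list
    user_threshold: object  # int or "all"
    embryo_threshold: int


def average_masks(masks: list[BinaryMask]) -> ConsensusMap:
    """Sum masks voxelwise into an agreement-count grid."""
    if len(masks) < 2:
        raise ConfigError("averaging needs at least 2 masks")
    first = masks[0]
    counts = np.zeros(first.shape, dtype=np.int32)
    for m in masks:
        first.require_same_geometry(m, "masks to average")
        counts += m.values.astype(np.int32)
    return ConsensusMap(counts, len(masks), first.spacing)


def threshold_consensus(cmap: ConsensusMap, k: int) -> BinaryMask:
    """Voxels where at least ``k`` raters agree.

    ``k = 1`` is the union of the inputs, ``k = n_raters`` their
    intersection; masks are nested for increasing ``k``.
    """
    if not 1 <= k <= cmap.n_raters:
        raise ConfigError(f"threshold k={k} outside [1, {cmap.n_raters}]")
    return BinaryMask(cmap.counts >= k, cmap.spacing)


def _user_k(user_rule, n_users: int) -> int:
    if user_rule in (None, "all"):
        return n_users
    k = int(user_rule)
    if not 1 <= k <= n_users:
        raise ConfigError(f"user threshold {k} outside [1, {n_users}]")
    return k


def build_label_model(
    per_embryo_user_masks: list[list[BinaryMask]],
    user_rule="all",
    embryo_k: int = 3,
    embryo_ids=None,
) -> Label3DModel:
    """Fuse per-user masks of several embryos into a label 3D-model.

    Per embryo, user masks are averaged and thresholded by ``user_rule``
    (default ``"all"``: consensus among all of that embryo's users; an
    integer selects at-least-k agreement).  The per-embryo consensus masks
    are then averaged across embryos and thresholded at ``embryo_k``
    (default: signal present in at least 3 embryos).
    """
    n_embryos = len(per_embryo_user_masks)
    if n_embryos < 3:
        raise ConfigError("label model needs at least 3 embryos")
    if embryo_k > n_embryos:
        raise ConfigError(f"embryo_k={embryo_k} exceeds the {n_embryos} embryos given")
    embryo_masks = []
    for user_masks in per_embryo_user_masks:
        if len(user_masks) < 2:
            raise ConfigError("each embryo needs at least 2 retained users")
        cmap = average_masks(user_masks)
        embryo_masks.append(threshold_consensus(cmap, _user_k(user_rule, len(user_masks))))
    model_mask = threshold_consensus(average_masks(embryo_masks), embryo_k)
    ids = list(embryo_ids) if embryo_ids is not None else list(range(n_embryos))
    return Label3DModel(model_mask, ids, user_rule, embryo_k)


def imprint_overlap_curve(
    signal_map: ConsensusMap, reference: BinaryMask, imprint_k: int | None = None
) -> pd.DataFrame:
    """Overlap of thresholded signal with its negative imprint, per threshold.

    The negative imprint is the hole the signal carves into the reference
    domain: reference minus the signal thresholded at ``imprint_k`` raters
    (default: all raters, the strictest consensus).  For each threshold
    ``k`` the returned table reports
    ``overlap(k) = |signal_k ∩ imprint| / |signal_k|`` (0, flagged, when
    ``signal_k`` is empty): how much of the loosely-thresholded signal
    spills into territory the strict consensus calls signal-free.  The
    overlap decreases with ``k``; the curve is a diagnostic for choosing
    the embryo consensus threshold — pick the smallest ``k`` where the
    overlap becomes marginal.  The choice itself is left to the operator.
    """
    if reference.voxel_count == 0:
        raise DiagnosticError("reference domain is empty")
    if signal_map.counts.shape != reference.shape:
        raise GeometryError("signal map and reference geometry differ")
    if imprint_k is None:
        imprint_k = signal_map.n_raters
    imprint = reference - threshold_consensus(signal_map, imprint_k)
    rows = []
    for k in range(1, signal_map.n_raters + 1):
        signal_k = threshold_consensus(signal_map, k)
        n_sig = signal_k.voxel_count
        inter = (signal_k & imprint).voxel_count
        rows.append(
            {
                "k": k,
                "signal_voxels": n_sig,
                "imprint_overlap_voxels": inter,
                "overlap_fraction": inter / n_sig if n_sig else 0.0,
                "empty_signal": n_sig == 0,
            }
        )
    return pd.DataFrame(rows)


def intersect_models(
    models: list[Label3DModel | BinaryMask], model_ids=None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pairwise overlap of label 3D-models plus a membership bitmask grid.

    Returns a table of pairwise intersection volumes (um^3) and Dice
    scores, and an integer grid whose bit ``i`` is set where model ``i``
    is present — useful to study overlap or segregation of neuronal
    populations in the atlas.
    """
    masks = [m.mask if isinstance(m, Label3DModel) else m for m in models]
    if not masks:
        raise ConfigError("no models given")
    first = masks[0]
    for m in masks[1:]:
        first.require_same_geometry(m, "models to intersect")
    ids = list(model_ids) if model_ids is not None else list(range(len(masks)))
    combined = np.zeros(first.shape, dtype=np.uint32)
    for i, m in enumerate(masks):
        combined |= m.values.astype(np.uint32) << i
    rows = []
    for i, j in combinations(range(len(masks)), 2):
        inter = (masks[i] & masks[j]).voxel_count
        rows.append(
            {
                "model_a": ids[i],
                "model_b": ids[j],
                "intersection_um3": inter * first.spacing.voxel_volume,
                "dice": dice(masks[i], masks[j]),
            }
        )
    return pd.DataFrame(rows), combined
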