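"""Synthetic embryo phantoms with known ground truth.

Every pipeline stage is testable without real data through a neural-tube
phantom: channel 1 is a bright tube-shaped "differentiation domain" (an
elliptical cylinder bent along the AP axis with a dorsal notch, coarsely
echoing hindbrain geometry — the bend and notch give registration enough
structure to lock rotation) over a dark background with additive Gaussian
noise; channel 2 carries striped, rhombomere-like sub-domains.  The truth
record holds the exact generated masks: the total domain, the stripes,
nested inner-to-outer birthdate shells hitting requested volume fractions,
and population subsets.

Multi-user segmentation noise is simulated by flipping voxels in a band
around the truth surface (human disagreement concentrates at boundaries,
which is exactly what consensus fusion must tolerate), and multi-embryo
variability by regenerating the phantom under mild shape jitter and a
random small rigid transform whose ground truth is returned for
registration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import BinaryMask, RigidTransform, VolumeStack, VoxelSpacing, euler_rigid
from .errors import ConfigError
from .registration import apply_transform
from .segmentation import Annotation

#: default voxel spacing of generated phantoms (um), matching a typical
#: confocal acquisition with coarser z-steps
DEFAULT_SPACING = VoxelSpacing(0.57, 0.57, 1.19)


@dataclass
class PhantomParams:
    """Geometry and signal parameters of the neural-tube phantom."""

    foreground: float = 200.0
    background: float = 20.0
    #: additive Gaussian noise, in intensity units (default 20% of contrast)
    noise_sd: float = 36.0
    #: tube radii as fractions of the DV / ML grid size
    radius_frac_dv: float = 0.30
    radius_frac_ml: float = 0.34
    #: ML bow of the centerline as a fraction of the ML grid size
    bend_frac: float = 0.10
    n_stripes: int = 5
    shell_fractions: tuple = (0.3, 0.3, 0.4)
    #: overall scale factor of the tube radii (shape jitter hook)
    radius_scale: float = 1.0

    def __post_init__(self):
        f = np.asarray(self.shell_fractions, float)
        if np.any(f <= 0) or not np.isclose(f.sum(), 1.0):
            raise ConfigError("shell fractions must be positive and sum to 1")


@dataclass
class PhantomTruth:
    """Exact ground-truth masks of one generated phantom."""

    spacing: VoxelSpacing
    total_domain: BinaryMask
    stripes: BinaryMask
    #: cumulative nested shells, innermost first; the last equals total_domain
    shells: list[BinaryMask] = field(default_factory=list)
    populations: dict = field(default_factory=dict)
    params: PhantomParams = field(default_factory=PhantomParams)
    seed: int = 0


def make_neural_tube_phantom(
    shape=(64, 64, 64),
    spacing: VoxelSpacing = DEFAULT_SPACING,
    seed: int = 0,
    params: PhantomParams | None = None,
) -> tuple[tuple[VolumeStack, VolumeStack], PhantomTruth]:
    """Generate a two-channel phantom stack plus its ground truth.

    Returns ``((channel1, channel2), truth)``.  Channel 1 is the
    differentiation-domain signal, channel 2 the stripe signal.  A fixed
    seed gives bit-identical output.  Shell masks are cut at quantiles of
    the normalized tube radius, so requested volume fractions are met to
    within quantization error.
    """
    params = params or PhantomParams()
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 32:
        raise ConfigError(f"phantom shape must be 3D with every axis >= 32, got {shape}")
    nz, ny, nx = shape
    z, y, x = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    # centerline bowed in ML along AP
    yc = ny / 2.0 + params.bend_frac * ny * np.sin(np.pi * x / (nx - 1))
    zc = nz / 2.0
    rz = params.radius_frac_dv * nz * params.radius_scale
    ry = params.radius_frac_ml * ny * params.radius_scale
    rho = np.sqrt(((z - zc) / rz) ** 2 + ((y - yc) / ry) ** 2)
    tube = rho <= 1.0
    # dorsal notch: a roof opening along the midline (dorsal = low axis-0 index)
    notch = ((zc - z) > 0.55 * rz) & (np.abs(y - yc) < 0.25 * ry)
    margin = (x >= 2) & (x <= nx - 3)
    domain = tube & ~notch & margin
    if not domain.any():
        raise ConfigError("phantom parameters produce an empty domain")

    stripe_width = (nx - 4) / (2 * params.n_stripes - 1)
    stripe_idx = np.floor((x - 2) / stripe_width).astype(int)
    stripes = domain & (stripe_idx % 2 == 0)

    fractions = np.cumsum(params.shell_fractions)[:-1]
    qs = np.quantile(rho[domain], fractions)
    shells = [BinaryMask(domain & (rho <= q), spacing) for q in qs]
    shells.append(BinaryMask(domain.copy(), spacing))

    ventral = domain & (z > zc)
    populations = {
        "stripes": BinaryMask(stripes.copy(), spacing),
        "ventral": BinaryMask(ventral, spacing),
    }

    rng = np.random.default_rng(seed)
    contrast = params.foreground - params.background
    ch1 = params.background + contrast * domain.astype(float)
    ch2 = params.background + contrast * stripes.astype(float)
    if params.noise_sd > 0:
        ch1 = ch1 + rng.normal(0.0, params.noise_sd, shape)
        ch2 = ch2 + rng.normal(0.0, params.noise_sd, shape)
    ch1 = np.clip(ch1, 0, None)
    ch2 = np.clip(ch2, 0, None)

    truth = PhantomTruth(
        spacing=spacing,
        total_domain=BinaryMask(domain, spacing),
        stripes=BinaryMask(stripes, spacing),
        shells=shells,
        populations=populations,
        params=params,
        seed=seed,
    )
    return (VolumeStack(ch1, spacing), VolumeStack(ch2, spacing)), truth


def boundary_band(mask: BinaryMask, width: int = 2) -> BinaryMask:
    """Voxels within ``width`` voxels of the mask surface (both sides)."""
    dil = ndimage.binary_dilation(mask.values, iterations=width)
    ero = ndimage.binary_erosion(mask.values, iterations=width)
    return BinaryMask(dil & ~ero, mask.spacing)


def simulate_user_segmentations(
    truth: BinaryMask,
    n_users: int,
    boundary_flip_rate: float,
    seed: int = 0,
    band_width: int = 2,
) -> list[BinaryMask]:
    """Simulate per-user masks by flipping voxels near the truth boundary.

    Each user's mask equals the truth except in a band of ``band_width``
    voxels around the surface, where voxels flip independently with the
    given rate; far interior and exterior voxels are never touched.
    """
    if not 0.0 <= boundary_flip_rate <= 0.5:
        raise ConfigError("boundary flip rate must lie in [0, 0.5]")
    band = boundary_band(truth, band_width).values
    rng = np.random.default_rng(seed)
    masks = []
    for _ in range(n_users):
        flips = band & (rng.random(truth.shape) < boundary_flip_rate)
        masks.append(BinaryMask(truth.values ^ flips, truth.spacing))
    return masks


@dataclass
class TransformJitter:
    """Bounds of the per-embryo random rigid perturbation."""

    max_voxels: float = 10.0
    max_deg: float = 10.0


@dataclass
class EmbryoReplicate:
    """One simulated embryo: stacks, its own truth, and the applied transform.

    ``applied`` is the pull-back transform used to resample the phantom
    into the replicate; registering the replicate (moving) back onto the
    reference phantom (fixed) recovers the *inverse* of ``applied``.
    """

    channels: tuple[VolumeStack, VolumeStack]
    truth: PhantomTruth
    applied: RigidTransform


def simulate_embryo_replicates(
    shape=(64, 64, 64),
    spacing: VoxelSpacing = DEFAULT_SPACING,
    n_embryos: int = 5,
    transform_jitter: TransformJitter | None = None,
    shape_jitter: float = 0.02,
    seed: int = 0,
    params: PhantomParams | None = None,
) -> list[EmbryoReplicate]:
    """Simulate embryo-to-embryo variability around the phantom.

    Each replicate regenerates the phantom with its tube radii scaled by a
    factor drawn from N(1, ``shape_jitter``) (mild shape variability) and
    resamples it under a random small rigid transform drawn within the
    jitter bounds.  Truth masks are resampled nearest-neighbour under the
    same transform.  Zero jitter reproduces the phantom bit-identically.
    """
    if n_embryos < 1:
        raise ConfigError("need at least one embryo")
    jitter = transform_jitter or TransformJitter()
    if jitter.max_voxels > min(shape) / 3:
        raise ConfigError("translation jitter too large: stacks would not overlap")
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    base_geometry = VolumeStack(np.zeros(shape, np.uint8), spacing)
    replicates = []
    for _ in range(n_embryos):
        scale = 1.0 + (rng.normal(0.0, shape_jitter) if shape_jitter > 0 else 0.0)
        angles = rng.uniform(-jitter.max_deg, jitter.max_deg, 3) if jitter.max_deg else np.zeros(3)
        shifts_vox = (
            rng.uniform(-jitter.max_voxels, jitter.max_voxels, 3)
            if jitter.max_voxels
            else np.zeros(3)
        )
        shifts_um = shifts_vox * np.asarray(spacing.xyz)
        center = base_geometry.physical_center()
        rot = euler_rigid(tuple(angles), (0, 0, 0)).rotation
        transform = RigidTransform(rot, center - rot @ center + shifts_um)
        if jitter.max_deg == 0 and jitter.max_voxels == 0:
            transform = RigidTransform.identity()
        jittered = replace(params, radius_scale=params.radius_scale * scale)
        channels, truth = make_neural_tube_phantom(shape, spacing, seed, jittered)
        if (
            transform.rotation_angle_deg() == 0.0
            and not np.any(transform.translation)
        ):
            replicates.append(EmbryoReplicate(channels, truth, transform))
            continue
        moved = tuple(
            apply_transform(ch, transform, base_geometry, "linear") for ch in channels
        )
        moved_truth = PhantomTruth(
            spacing=spacing,
            total_domain=apply_transform(truth.total_domain, transform, base_geometry, "nearest"),
            stripes=apply_transform(truth.stripes, transform, base_geometry, "nearest"),
            shells=[
                apply_transform(s, transform, base_geometry, "nearest")
                for s in truth.shells
            ],
            populations={
                k: apply_transform(v, transform, base_geometry, "nearest")
                for k, v in truth.populations.items()
            },
            params=jittered,
            seed=seed,
        )
        replicates.append(EmbryoReplicate(moved, moved_truth, transform))
    return replicates


def sample_annotations(
    truth: BinaryMask,
    n_per_class: int = 50,
    seed: int = 0,
    margin: int = 1,
    stroke_size: int = 10,
) -> Annotation:
    """Draw balanced brush-stroke annotations from a truth mask.

    Foreground voxels are sampled from the eroded interior and background
    voxels from outside the dilated mask (users annotate unambiguous
    regions, not the fuzzy boundary); voxels are grouped into pseudo-strokes
    of ``stroke_size``.
    """
    rng = np.random.default_rng(seed)
    interior = ndimage.binary_erosion(truth.values, iterations=margin) if margin else truth.values
    exterior = ~(
        ndimage.binary_dilation(truth.values, iterations=margin) if margin else truth.values
    )
    idx_parts, labels = [], []
    for region, label in ((interior, 1), (exterior, 0)):
        coords = np.argwhere(region)
        if len(coords) == 0:
            raise ConfigError("truth mask leaves no unambiguous voxels to annotate")
        pick = rng.choice(len(coords), size=min(n_per_class, len(coords)), replace=False)
        idx_parts.append(coords[pick])
        labels.append(np.full(len(pick), label))
    indices = np.vstack(idx_parts)
    labels = np.concatenate(labels)
    strokes = np.arange(len(labels)) // stroke_size
    return Annotation(indices, labels, strokes)
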