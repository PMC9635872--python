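"""Multi-step intensity-based rigid registration.

A moving embryo's reference channel (e.g. the pan-neuronal HuC signal) is
aligned to a fixed reference stack by a short schedule of rigid steps:
coarse steps on a subsampled pyramid recover integer-voxel translation by
phase correlation and the rotation by a per-axis angle scan; subpixel steps
refine all six rigid parameters by continuous local optimization at full
resolution.  The default schedule is 2 coarse + 2 subpixel steps.  The
similarity metric is normalized cross-correlation, appropriate for
same-modality alignment.  The recovered transform is then reused on the
second channel (the signal of interest), which is the point of registering
on a common reference channel.

Transforms follow the pull-back convention: the returned
:class:`~atlasmaker.core.RigidTransform` maps fixed-space physical points
(um) into moving-space physical points, which is exactly what resampling
needs.  Registration is deterministic: there is no randomized
initialization, and the step schedule never accepts a transform with a
worse similarity than the current best.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .core import BinaryMask, RigidTransform, VolumeStack
from .errors import ConfigError, RegistrationError


@dataclass
class RegistrationConfig:
    """Parameters of the rigid step schedule."""

    n_coarse_steps: int = 2
    n_subpixel_steps: int = 2
    pyramid_subsampling: bool = True
    similarity: str = "ncc"
    #: Powell iteration cap per subpixel step
    max_iterations: int = 5
    #: half-width of the coarse per-axis rotation scan, degrees
    angle_range_deg: float = 12.0
    #: scan step of the first coarse rotation pass, degrees
    angle_step_deg: float = 3.0

    def __post_init__(self):
        if self.n_coarse_steps + self.n_subpixel_steps < 1:
            raise ConfigError("schedule must contain at least one step")
        if self.similarity != "ncc":
            raise ConfigError(f"unknown similarity metric {self.similarity!r}")


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return -np.inf
    return float(a @ b / (na * nb))


def _resample_values(
    values: np.ndarray,
    spacing_moving,
    spacing_fixed,
    transform: RigidTransform,
    output_shape,
    order: int,
    fast: bool = False,
) -> np.ndarray:
    """Resample ``values`` (moving grid) onto the fixed grid under ``transform``.

    ``transform`` maps fixed physical (x, y, z) points to moving physical
    points; voxel centers sit at ``(index + 0.5) * spacing``.  ``fast``
    drops to float32 arithmetic — used only inside the registration cost
    loop, never for user-facing resampling.
    """
    J = np.array([[0, 0, 1.0], [0, 1.0, 0], [1.0, 0, 0]])  # zyx <-> xyz
    Sf = np.diag(spacing_fixed.xyz)
    Sm_inv = np.diag(1.0 / np.asarray(spacing_moving.xyz))
    R, t = transform.rotation, transform.translation
    half = np.full(3, 0.5)
    A = J @ Sm_inv @ R @ Sf @ J
    b = J @ (Sm_inv @ (R @ (Sf @ half) + t) - half)
    values = np.asarray(values)
    if order > 0:
        target = np.float32 if fast else np.float64
        if values.dtype != target:
            values = values.astype(target)
    return ndimage.affine_transform(
        values,
        A,
        offset=b,
        output_shape=tuple(output_shape),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=order > 1,
    )


def apply_transform(
    vol: VolumeStack | BinaryMask,
    transform: RigidTransform,
    target_geometry: VolumeStack | None = None,
    interpolation: str = "linear",
):
    """Resample a stack or mask onto a target geometry under a rigid transform.

    ``target_geometry`` supplies the output grid shape and spacing and
    defaults to the input's own geometry.  Intensities are interpolated
    linearly; masks are interpolated linearly on their {0, 1} indicator and
    re-thresholded at 0.5, or resampled nearest-neighbour when
    ``interpolation="nearest"``.  Voxels mapping outside the moving field of
    view are 0.
    """
    if target_geometry is None:
        target_geometry = vol
    if target_geometry is None:
        raise ConfigError("target geometry is required")
    if interpolation not in ("linear", "nearest"):
        raise ConfigError(f"unknown interpolation {interpolation!r}")
    order = 0 if interpolation == "nearest" else 1
    is_mask = isinstance(vol, BinaryMask)
    values = vol.values.astype(float) if is_mask else vol.values
    out = _resample_values(
        values, vol.spacing, target_geometry.spacing, transform,
        target_geometry.shape, order,
    )
    if is_mask:
        return BinaryMask(out >= 0.5, target_geometry.spacing, vol.axis_labels)
    if order == 0:
        out = out.astype(vol.values.dtype, copy=False)
    return VolumeStack(out, target_geometry.spacing, vol.axis_labels)


def _params_to_transform(params: np.ndarray, center: np.ndarray) -> RigidTransform:
    """Six parameters (angles deg about x/y/z, translation um) -> transform.

    Rotation is taken about ``center`` (the fixed stack's physical center)
    so that angle and translation parameters are decoupled.
    """
    from .core import euler_rigid

    ax, ay, az, tx, ty, tz = params
    rot = euler_rigid((ax, ay, az), (0, 0, 0)).rotation
    translation = center - rot @ center + np.array([tx, ty, tz])
    return RigidTransform(rot, translation)


def _downsample(stack: VolumeStack, max_dim: int = 64) -> VolumeStack:
    """Halve (with anti-alias smoothing) until the largest dimension <= max_dim."""
    values = stack.values.astype(float)
    sp = np.asarray(stack.spacing.zyx, float)
    while max(values.shape) > max_dim:
        values = ndimage.gaussian_filter(values, sigma=1.0)
        values = values[::2, ::2, ::2]
        sp = sp * 2
    from .core import VoxelSpacing

    return VolumeStack(values, VoxelSpacing(sp[2], sp[1], sp[0]))


def register_rigid(
    moving_ref: VolumeStack,
    fixed_ref: VolumeStack,
    config: RegistrationConfig | None = None,
) -> tuple[RigidTransform, list[float]]:
    """Rigidly align ``moving_ref`` to ``fixed_ref``.

    Returns the transform (fixed physical -> moving physical, for
    resampling) maximizing normalized cross-correlation over the step
    schedule, plus the per-step trace of the best similarity, which is
    non-decreasing across completed steps.

    Raises :class:`RegistrationError` for constant-intensity inputs, or —
    with the best transform found attached — when the coarse search leaves
    no overlap between the stacks.
    """
    config = config or RegistrationConfig()
    for name, stack in (("fixed", fixed_ref), ("moving", moving_ref)):
        if np.ptp(stack.values) == 0:
            raise RegistrationError(f"{name} stack has constant intensity")

    center = fixed_ref.physical_center()
    # the coarse search runs one pyramid level below the subsampling cap:
    # the scan only needs to land inside the capture range of the
    # continuous refinement, and a 32-level keeps it cheap
    fixed_c = _downsample(fixed_ref, max_dim=32) if config.pyramid_subsampling else fixed_ref
    moving_c = _downsample(moving_ref, max_dim=32) if config.pyramid_subsampling else moving_ref

    def cost_on(fixed, moving):
        # NCC restricted to the voxels the moving stack actually covers;
        # zero-filled out-of-field regions would otherwise bias the optimum
        # whenever the perturbation pushes structure outside the FOV
        fvals = fixed.values.astype(np.float32)
        ones = np.ones(moving.shape, dtype=np.uint8)
        min_overlap = 0.25 * fvals.size

        def cost(params):
            transform = _params_to_transform(params, center)
            res = _resample_values(
                moving.values, moving.spacing, fixed.spacing,
                transform, fixed.shape, order=1, fast=True,
            )
            valid = _resample_values(
                ones, moving.spacing, fixed.spacing,
                transform, fixed.shape, order=0,
            ).astype(bool)
            if valid.sum() < min_overlap:
                return np.inf
            return -_ncc(fvals[valid], res[valid])

        return cost

    full_cost = cost_on(fixed_ref, moving_ref)
    coarse_cost = cost_on(fixed_c, moving_c)
    params = np.zeros(6)
    best_full = -full_cost(params)
    trace: list[float] = []

    def accept(candidate: np.ndarray) -> None:
        """Keep the candidate only if it improves the full-resolution similarity."""
        nonlocal params, best_full
        score = -full_cost(candidate)
        if score > best_full:
            params, best_full = np.asarray(candidate, float), score

    # --- coarse steps: integer-voxel translation by phase correlation,
    # rotation by per-axis scan on the pyramid level; the scan tightens
    # each step; candidates are vetted at the coarse level and only
    # accepted when the full-resolution similarity improves ---
    step_deg = config.angle_step_deg
    for _ in range(config.n_coarse_steps):
        # residual translation given the current estimate
        current = _params_to_transform(params, center)
        res = _resample_values(
            moving_c.values, moving_c.spacing, fixed_c.spacing, current,
            fixed_c.shape, order=1,
        )
        shift, _, _ = phase_cross_correlation(
            fixed_c.values.astype(float), res, normalization=None
        )
        shift_um = shift[::-1] * np.asarray(fixed_c.spacing.xyz)
        cand = params.copy()
        cand[3:] = params[3:] - current.rotation @ shift_um
        accept(cand)
        # per-axis rotation scan around the current estimate
        for axis in range(3):
            scan_best, scan_score = None, -np.inf
            for ang in params[axis] + np.arange(
                -config.angle_range_deg, config.angle_range_deg + 1e-9, step_deg
            ):
                cand = params.copy()
                cand[axis] = ang
                score = -coarse_cost(cand)
                if score > scan_score:
                    scan_best, scan_score = cand, score
            if scan_best is not None:
                accept(scan_best)
        step_deg = max(step_deg / 3.0, 0.5)
        trace.append(best_full)

    if config.n_coarse_steps:
        check = _resample_values(
            moving_c.values, moving_c.spacing, fixed_c.spacing,
            _params_to_transform(params, center), fixed_c.shape, order=0,
        )
        if not np.any(check):
            raise RegistrationError(
                "no overlap between stacks after coarse search",
                best_transform=_params_to_transform(params, center),
            )

    # --- subpixel steps: continuous 6-parameter refinement; earlier steps
    # run on a half-resolution level, the final step at full resolution ---
    half_cost = coarse_cost
    for step in range(config.n_subpixel_steps):
        last = step == config.n_subpixel_steps - 1
        result = optimize.minimize(
            full_cost if last else half_cost,
            params,
            method="Powell",
            options={
                "maxiter": config.max_iterations if not last else max(2, config.max_iterations // 2),
                "xtol": 1e-3,
                "ftol": 1e-8,
            },
        )
        accept(result.x)
        trace.append(best_full)

    return _params_to_transform(params, center), trace
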