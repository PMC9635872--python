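"""Stack, mask and transform I/O.

Supported volume formats are multi-page TIFF (uint8/uint16, optionally
carrying ImageJ-style spacing metadata) and NRRD (spacing from the header's
space directions).  Proprietary microscope formats are out of scope; convert
to TIFF/NRRD first.  Masks are serialized as 8-bit volumes with values
{0, 255} and read back with a ``> 0`` threshold, matching the most common
mask dialects.  Rigid transforms are plain text: four lines of four floats,
a row-major homogeneous matrix with um translations, written at full
precision so round-trips are lossless.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

from .core import BinaryMask, RigidTransform, VolumeStack, VoxelSpacing
from .errors import AtlasError, DimensionalityError, ValidationError

log = logging.getLogger(__name__)

#: spacing assumed when a file carries no calibration (um)
DEFAULT_SPACING = VoxelSpacing(1.0, 1.0, 1.0)


def _format_of(path, format_hint=None) -> str:
    if format_hint:
        return format_hint.lower()
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == ".nrrd":
        return "nrrd"
    raise AtlasError(f"cannot infer volume format from {path!r}; pass format_hint")


def _read_tiff(path, default_spacing):
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        spacing = None
        try:
            page = tif.pages[0]
            res = page.resolution  # pixels per unit along x, y
            ij = tif.imagej_metadata or {}
            dz = ij.get("spacing")
            if res and res[0] and res[1] and dz:
                spacing = VoxelSpacing(1.0 / res[0], 1.0 / res[1], float(dz))
        except Exception:  # metadata is best-effort; fall through to default
            spacing = None
    if spacing is None:
        log.warning(
            "TIFF %s carries no voxel spacing; falling back to default %s",
            path,
            default_spacing,
        )
        spacing = default_spacing
    return values, spacing


def _read_nrrd(path, default_spacing):
    img = sitk.ReadImage(os.fspath(path))
    values = sitk.GetArrayFromImage(img)  # (z, y, x)
    sp = img.GetSpacing()  # (x, y, z)
    if len(sp) == 3:
        spacing = VoxelSpacing(*sp)
    else:
        log.warning("NRRD %s has no 3D spacing; using default %s", path, default_spacing)
        spacing = default_spacing
    return values, spacing


def read_stack(path, format_hint=None, default_spacing=DEFAULT_SPACING) -> VolumeStack:
    """Read a 3D volume from TIFF or NRRD.

    Spacing is taken from the file metadata when present; otherwise
    ``default_spacing`` is used and a warning is logged.  A 2D-only file
    raises :class:`DimensionalityError`.
    """
    if not Path(path).exists():
        raise AtlasError(f"no such file: {path}")
    fmt = _format_of(path, format_hint)
    try:
        if fmt == "tiff":
            values, spacing = _read_tiff(path, default_spacing)
        elif fmt == "nrrd":
            values, spacing = _read_nrrd(path, default_spacing)
        else:
            raise AtlasError(f"unsupported format {fmt!r}")
    except AtlasError:
        raise
    except Exception as exc:
        raise AtlasError(f"unreadable volume file {path}: {exc}") from exc
    values = np.asarray(values)
    if values.ndim == 2:
        raise DimensionalityError(f"{path} holds a 2D image, expected a z-stack")
    return VolumeStack(values, spacing)


def write_stack(stack: VolumeStack, path, format_hint=None) -> None:
    """Write a volume to TIFF (with ImageJ spacing metadata) or NRRD."""
    fmt = _format_of(path, format_hint)
    sp = stack.spacing
    values = np.asarray(stack.values)
    if values.dtype == bool:
        values = values.astype(np.uint8) * 255
    elif values.dtype == np.float64:
        values = values.astype(np.float32)  # ImageJ TIFF has no float64
    if fmt == "tiff":
        tifffile.imwrite(
            os.fspath(path),
            values,
            imagej=True,
            resolution=(1.0 / sp.dx, 1.0 / sp.dy),
            metadata={"spacing": sp.dz, "unit": "um", "axes": "ZYX"},
        )
    elif fmt == "nrrd":
        img = sitk.GetImageFromArray(values)
        img.SetSpacing(sp.xyz)
        sitk.WriteImage(img, os.fspath(path))
    else:
        raise AtlasError(f"unsupported format {fmt!r}")


def read_mask(path, format_hint=None, default_spacing=DEFAULT_SPACING) -> BinaryMask:
    """Read a binary mask; any strictly positive voxel is foreground."""
    stack = read_stack(path, format_hint, default_spacing)
    return BinaryMask(stack.values > 0, stack.spacing, stack.axis_labels)


def write_mask(mask: BinaryMask, path, format_hint=None) -> None:
    """Write a mask as an 8-bit volume with foreground = 255."""
    out = VolumeStack(
        np.where(mask.values, 255, 0).astype(np.uint8), mask.spacing, mask.axis_labels
    )
    write_stack(out, path, format_hint)


def write_transform(transform: RigidTransform, path) -> None:
    """Write a rigid transform as 4 text lines x 4 floats (row-major)."""
    m = transform.as_matrix()
    with open(path, "w") as fh:
        for row in m:
            fh.write(" ".join(format(v, ".17g") for v in row) + "\n")


def read_transform(path) -> RigidTransform:
    """Read a rigid transform written by :func:`write_transform`.

    Raises :class:`ValidationError` if the rotation block is not orthonormal
    or encodes a reflection.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rows.append([float(v) for v in line.split()])
    m = np.array(rows, float)
    if m.shape != (4, 4):
        raise ValidationError(f"transform file {path} is not a 4x4 matrix")
    return RigidTransform.from_matrix(m)
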