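"""Domain types and voxel-grid geometry.

All image grids in this package are 3D numpy arrays indexed ``(z, y, x)``
with semantic axis labels ``(DV, ML, AP)``: embryos are imaged mounted
dorsally with the anterior to the left, so grid axis 0 runs dorsoventral,
axis 1 mediolateral and axis 2 anteroposterior.  Voxel spacing is
anisotropic (confocal z-steps are coarser than the in-plane pixel size,
e.g. 0.57 x 0.57 x 1.19 um) and is attached to every grid; physical
positions use the center-of-voxel convention

    position(i, j, k) = ((k + 0.5) dx, (j + 0.5) dy, (i + 0.5) dz)   [um]

in (x, y, z) order.  Rigid transforms act in this physical um space, never
in voxel index space, so anisotropy is handled exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, GeometryError, ValidationError

DEFAULT_AXIS_LABELS = ("DV", "ML", "AP")

#: grid axis index for each semantic axis label
AXIS_INDEX = {"DV": 0, "ML": 1, "AP": 2}

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical edge lengths of one voxel, in micrometres.

    ``dx``/``dy``/``dz`` follow image convention: ``dx`` and ``dy`` are the
    in-plane pixel size (grid axes 2 and 1), ``dz`` the z-step (grid axis 0).
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self):
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ConfigError(f"voxel spacing must be strictly positive, got {self}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        return self.dx * self.dy * self.dz

    @property
    def zyx(self) -> tuple[float, float, float]:
        """Spacing ordered by grid axes (axis 0, axis 1, axis 2)."""
        return (self.dz, self.dy, self.dx)

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)

    def isclose(self, other: "VoxelSpacing", rtol: float = 1e-6) -> bool:
        return np.allclose(self.xyz, other.xyz, rtol=rtol, atol=0.0)


def _check_3d(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 3:
        from .errors import DimensionalityError

        raise DimensionalityError(f"expected a 3D grid, got ndim={values.ndim}")
    if min(values.shape) < 1:
        raise GeometryError(f"grid dimensions must be >= 1, got shape {values.shape}")
    return values


@dataclass
class VolumeStack:
    """A 3D intensity grid with physical spacing.

    The unit of all image I/O.  ``values`` is indexed ``(z, y, x)`` =
    ``(DV, ML, AP)``; intensities are non-negative.
    """

    values: np.ndarray
    spacing: VoxelSpacing
    axis_labels: tuple[str, str, str] = DEFAULT_AXIS_LABELS

    def __post_init__(self):
        self.values = _check_3d(self.values)
        self.axis_labels = tuple(self.axis_labels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_index(self, label: str) -> int:
        """Grid axis index of a semantic axis label (``AP``/``ML``/``DV``)."""
        try:
            return self.axis_labels.index(label)
        except ValueError:
            raise ConfigError(
                f"unknown axis label {label!r}; expected one of {self.axis_labels}"
            ) from None

    def same_geometry(self, other) -> bool:
        return self.shape == other.shape and self.spacing.isclose(other.spacing)

    def require_same_geometry(self, other, what: str = "operands") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"{what} must share shape and spacing: "
                f"{self.shape}/{self.spacing} vs {other.shape}/{other.spacing}"
            )

    def physical_center(self) -> np.ndarray:
        """Center of the grid in physical (x, y, z) um coordinates."""
        nz, ny, nx = self.shape
        return np.array(
            [nx * self.spacing.dx, ny * self.spacing.dy, nz * self.spacing.dz]
        ) / 2.0

    def copy(self) -> "VolumeStack":
        return replace(self, values=self.values.copy())


@dataclass
class BinaryMask(VolumeStack):
    """A boolean 3D grid sharing the :class:`VolumeStack` geometry contract.

    The unit of segmentation output and of all set algebra.
    """

    def __post_init__(self):
        super().__post_init__()
        self.values = self.values.astype(bool, copy=False)

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def volume_um3(self) -> float:
        return self.voxel_count * self.spacing.voxel_volume

    def __and__(self, other):
        return mask_algebra(self, other, "intersection")

    def __or__(self, other):
        return mask_algebra(self, other, "union")

    def __sub__(self, other):
        return mask_algebra(self, other, "difference")


_MASK_OPS = {
    "union": np.logical_or,
    "intersection": np.logical_and,
    "difference": lambda a, b: np.logical_and(a, np.logical_not(b)),
}


def mask_algebra(a: BinaryMask, b: BinaryMask, op: str) -> BinaryMask:
    """Voxelwise boolean combination of two masks on the same grid.

    ``op`` is one of ``union``, ``intersection``, ``difference``
    (difference is ``a \\ b``).  Spacing and axis labels of ``a`` are
    preserved.
    """
    if op not in _MASK_OPS:
        raise ConfigError(f"unknown mask operation {op!r}")
    a.require_same_geometry(b, "mask operands")
    return BinaryMask(_MASK_OPS[op](a.values, b.values), a.spacing, a.axis_labels)


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    av = a.values if isinstance(a, VolumeStack) else np.asarray(a, bool)
    bv = b.values if isinstance(b, VolumeStack) else np.asarray(b, bool)
    denom = av.sum() + bv.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(av, bv).sum() / denom


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion of physical (x, y, z) um space.

    ``rotation`` is a 3x3 orthonormal matrix with det +1, ``translation`` a
    3-vector in um.  Maps a point ``p`` to ``rotation @ p + translation``.
    In registration the returned transform maps fixed-space physical points
    into moving-space physical points (the resampling, pull-back convention).
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValidationError(f"rotation must be 3x3, got {R.shape}")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9 * 10):
            raise ValidationError("rotation block is not orthonormal (R^T R != I)")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation block has det -1 (reflection rejected)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array of physical (x, y, z) points."""
        points = np.asarray(points, float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (row-major, um translation)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, float)
        if m.shape != (4, 4):
            raise ValidationError(f"expected a 4x4 matrix, got {m.shape}")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-9):
            raise ValidationError("last row of homogeneous matrix must be 0 0 0 1")
        return cls(m[:3, :3], m[:3, 3])

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def euler_rigid(
    angles_deg: tuple[float, float, float],
    translation: tuple[float, float, float],
) -> RigidTransform:
    """Build a rigid transform from Euler angles (deg) about x, y, z axes.

    Rotations are applied in x-then-y-then-z order about the physical axes;
    translation is in um.  Convenience constructor used by registration and
    the phantom simulator.
    """
    ax, ay, az = np.radians(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return RigidTransform(Rz @ Ry @ Rx, np.asarray(translation, float))
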