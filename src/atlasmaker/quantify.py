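"""Volume quantification, virtual-reslice axis profiles and smoothing.

Tissue volumes are foreground voxel counts times the voxel volume.  Axis
profiles virtually reslice a signal and a reference domain along a body
axis (AP, ML or DV) one voxel plane at a time and report the per-slice
signal/reference volume ratio; ratio curves are smoothed with a local
linear kernel estimator using the Epanechnikov kernel, with the bandwidth
selected by leave-one-out cross-validation unless fixed.  Interindividual
variability is summarized as percent deviation of individual volumes from
the consensus model volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AXIS_INDEX, BinaryMask
from .errors import ConfigError, GeometryError


def mask_volume(mask: BinaryMask) -> float:
    """Foreground volume in um^3 (voxel count x voxel volume)."""
    return mask.volume_um3


@dataclass
class AxisProfile:
    """Per-slice signal and reference volumes along one body axis.

    ``ratio`` is per-slice signal/reference; slices with an empty reference
    are kept in the table but flagged invalid and excluded from smoothing.
    """

    axis: str
    bin_centers_um: np.ndarray
    signal_um3: np.ndarray
    reference_um3: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray
    smoothed_ratio: np.ndarray | None = None
    bandwidth_um: float | None = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "axis_position_um": self.bin_centers_um,
                "signal_um3": self.signal_um3,
                "reference_um3": self.reference_um3,
                "ratio": self.ratio,
                "valid": self.valid,
            }
        )
        if self.smoothed_ratio is not None:
            df["smoothed_ratio"] = self.smoothed_ratio
        return df


def axis_profile(
    signal: BinaryMask,
    reference: BinaryMask,
    axis: str = "AP",
    bin_width_um: float | None = None,
    normalize: str = "per_slice",
) -> AxisProfile:
    """Quantify the signal ratio along a body axis by virtual reslicing.

    Default bins are single voxel planes along the named axis; an optional
    ``bin_width_um`` aggregates consecutive planes.  ``normalize``
    selects the ratio definition: ``"per_slice"`` (signal/reference within
    each slice, the default) or ``"global"`` (per-slice signal over the
    whole-domain reference volume).
    """
    signal.require_same_geometry(reference, "signal and reference")
    if reference.voxel_count == 0:
        raise GeometryError("reference domain is empty")
    if normalize not in ("per_slice", "global"):
        raise ConfigError(f"unknown normalization {normalize!r}")
    ax = signal.axis_index(axis)
    step = signal.spacing.zyx[ax]
    other = tuple(i for i in range(3) if i != ax)
    vv = signal.spacing.voxel_volume
    sig = signal.values.sum(axis=other) * vv
    ref = reference.values.sum(axis=other) * vv
    centers = (np.arange(signal.shape[ax]) + 0.5) * step
    if bin_width_um is not None:
        if bin_width_um <= 0:
            raise ConfigError("bin width must be positive")
        per_bin = max(1, int(round(bin_width_um / step)))
        n_bins = int(np.ceil(sig.size / per_bin))
        pad = n_bins * per_bin - sig.size
        sig = np.pad(sig, (0, pad)).reshape(n_bins, per_bin).sum(axis=1)
        ref = np.pad(ref, (0, pad)).reshape(n_bins, per_bin).sum(axis=1)
        centers = np.pad(centers, (0, pad), constant_values=np.nan).reshape(
            n_bins, per_bin
        )
        centers = np.nanmean(centers, axis=1)
    valid = ref > 0
    ratio = np.zeros_like(sig)
    denom = ref if normalize == "per_slice" else reference.volume_um3
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(valid, sig / np.where(valid, denom, 1.0), 0.0)
    return AxisProfile(axis, centers, sig, ref, ratio, valid)


# ---------------------------------------------------------------------------
# local linear kernel regression


def epanechnikov(u: np.ndarray) -> np.ndarray:
    """Epanechnikov kernel K(u) = 0.75 (1 - u^2) on |u| <= 1, else 0."""
    u = np.asarray(u, float)
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u * u), 0.0)


@dataclass
class RegressionConfig:
    """Local-linear smoother settings.

    ``bandwidth`` is in the units of ``x`` (um for axis profiles), or the
    string ``"cv"`` for leave-one-out cross-validation over a log-spaced
    grid of ``cv_grid_size`` bandwidths spanning
    [2 x median x-spacing, range(x) / 2].
    """

    kernel: str = "epanechnikov"
    bandwidth: float | str = "cv"
    cv_grid_size: int = 20

    def __post_init__(self):
        if self.kernel != "epanechnikov":
            raise ConfigError(f"unsupported kernel {self.kernel!r}")
        if not isinstance(self.bandwidth, str) and self.bandwidth <= 0:
            raise ConfigError("fixed bandwidth must be positive")


@dataclass
class SmoothResult:
    x: np.ndarray
    fitted: np.ndarray
    bandwidth_um: float
    #: query points where the window had to be widened to find 2 points
    widened: np.ndarray


def _local_linear_weights(x: np.ndarray, x0: float, h: float):
    """Smoother weights l_i(x0) of the local linear fit; None if degenerate."""
    u = (x - x0) / h
    w = epanechnikov(u)
    active = w > 0
    if active.sum() < 2 or np.ptp(x[active]) == 0:
        return None
    d = x - x0
    s0 = np.sum(w)
    s1 = np.sum(w * d)
    s2 = np.sum(w * d * d)
    det = s0 * s2 - s1 * s1
    if det <= 0:
        return None
    return w * (s2 - s1 * d) / det


def _fit_at(x, y, x0, h):
    """Fitted value at x0, widening the window locally when too sparse."""
    widened = False
    h_loc = h
    for _ in range(200):
        weights = _local_linear_weights(x, x0, h_loc)
        if weights is not None:
            return float(weights @ y), widened
        h_loc *= 1.5
        widened = True
    # pathological (all x identical): fall back to the plain mean
    return float(np.mean(y)), True


def _loo_score(x, y, h):
    """Leave-one-out squared prediction error of the smoother at bandwidth h."""
    err = 0.0
    n = x.size
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        pred, _ = _fit_at(x[mask], y[mask], x[i], h)
        err += (y[i] - pred) ** 2
    return err / n


def _cv_bandwidth(x, y, grid_size):
    spac = np.diff(np.sort(x))
    spac = spac[spac > 0]
    lo = 2.0 * np.median(spac) if spac.size else 1.0
    hi = max(np.ptp(x) / 2.0, lo * 1.001)
    grid = np.geomspace(lo, hi, grid_size)
    scores = [_loo_score(x, y, h) for h in grid]
    return float(grid[int(np.argmin(scores))])


def local_linear_smooth(
    x: np.ndarray,
    y: np.ndarray,
    config: RegressionConfig | None = None,
    x_query: np.ndarray | None = None,
) -> SmoothResult:
    """Local linear kernel regression with the Epanechnikov kernel.

    At each query point ``x0`` a weighted least-squares line is fitted with
    weights ``K((x_i - x0) / h)``; the fitted intercept is the smoothed
    value.  Local linear fits reproduce straight lines exactly for any
    bandwidth.  Where fewer than two data points fall in the window, the
    window is widened locally and the point flagged.
    """
    config = config or RegressionConfig()
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise ConfigError("x and y must have equal length")
    if x.size < 5:
        raise ConfigError("smoothing needs at least 5 points")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if x_query is None:
        x_query = x.copy()
    x_query = np.asarray(x_query, float).ravel()
    if config.bandwidth == "cv":
        h = _cv_bandwidth(x, y, config.cv_grid_size)
    else:
        h = float(config.bandwidth)
    fitted = np.empty(x_query.size)
    widened = np.zeros(x_query.size, bool)
    for i, x0 in enumerate(x_query):
        fitted[i], widened[i] = _fit_at(x, y, x0, h)
    return SmoothResult(x_query, fitted, h, widened)


def smooth_profile(profile: AxisProfile, config: RegressionConfig | None = None) -> AxisProfile:
    """Attach a smoothed ratio curve to an axis profile (valid bins only)."""
    x = profile.bin_centers_um[profile.valid]
    y = profile.ratio[profile.valid]
    result = local_linear_smooth(x, y, config, x_query=profile.bin_centers_um)
    profile.smoothed_ratio = result.fitted
    profile.bandwidth_um = result.bandwidth_um
    return profile


def variability_to_model(
    individual_volumes, model_volume: float
) -> tuple[pd.DataFrame, float]:
    """Percent deviation of individual volumes from the model volume.

    ``deviation_i = 100 |V_i - V_model| / V_model``; returns the
    per-individual table and the mean deviation — the study-level summary
    of interindividual variability relative to the consensus model.
    """
    if model_volume <= 0:
        raise ZeroDivisionError("model volume must be positive")
    vols = np.asarray(list(individual_volumes), float)
    dev = 100.0 * np.abs(vols - model_volume) / model_volume
    df = pd.DataFrame({"volume_um3": vols, "deviation_pct": dev})
    return df, float(dev.mean())
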