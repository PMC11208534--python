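"""Tuning maps: spatial and toroidal rate maps, 1-D autocorrelograms,
angular tuning and toroidal peak phases.

Toroidal rate maps handle the hexagonal 60-degree axis relation by shearing
the first angle before binning (u = theta1 - theta2/2), tiling 3x3 copies
for periodic smoothing, and un-shearing the smoothed middle tile, so fields
remain convex on a hexagonal torus.  Peak phases are circular mass centers
of the binned activity distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, shift as nd_shift

from .coordinatize import ToroidalCoordinates
from .downsample import PointCloud, radial_downsample

__all__ = [
    "RateMap2D",
    "Autocorr1D",
    "ToroidalPhase",
    "spatial_ratemap",
    "autocorr_1d",
    "toroidal_ratemap",
    "toroidal_peak",
    "angular_tuning",
    "toroidal3d_tuning",
]


@dataclass
class RateMap2D:
    """Binned mean activity with occupancy counts and smoothing width."""

    values: np.ndarray  # (bins, bins)
    occupancy: np.ndarray  # (bins, bins) sample counts
    sigma_bins: float
    kind: str = "spatial"  # or "toroidal"


@dataclass
class Autocorr1D:
    values: np.ndarray  # per shift 0..max_shift
    bin_cm: float

    def __post_init__(self):
        if self.values.size and np.argmax(self.values) != 0:
            raise ValueError("autocorrelogram must peak at zero shift")


@dataclass
class ToroidalPhase:
    """Peak (mass-center) phase of a unit on the torus, [0, 2pi)^2."""

    theta: Tuple[float, float]
    degenerate: bool = False


def _binned_mean(activity, xi, yi, bins):
    H = np.zeros((bins, bins))
    C = np.zeros((bins, bins))
    np.add.at(H, (yi, xi), activity)
    np.add.at(C, (yi, xi), 1)
    return H, C


def spatial_ratemap(
    activity: np.ndarray,
    positions: np.ndarray,
    arena: float,
    bins: int = 30,
    sigma_bins: float = 2.0,
) -> RateMap2D:
    """Mean activity on a square spatial grid, Gaussian smoothed.

    Non-visited bins are assigned the mean of visited bins before smoothing.
    ``positions`` is (T, 2) in cm within [0, arena].
    """
    activity = np.asarray(activity, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] != activity.shape[0]:
        raise ValueError("activity and positions must be aligned")
    xi = np.clip((positions[:, 0] / arena * bins).astype(int), 0, bins - 1)
    yi = np.clip((positions[:, 1] / arena * bins).astype(int), 0, bins - 1)
    H, C = _binned_mean(activity, xi, yi, bins)
    visited = C > 0
    if not visited.any():
        raise ValueError("no visited bins")
    M = np.where(visited, H / np.maximum(C, 1), 0.0)
    M[~visited] = M[visited].mean()
    return RateMap2D(gaussian_filter(M, sigma_bins), C, sigma_bins, kind="spatial")


def autocorr_1d(
    activity: np.ndarray,
    linear_pos: np.ndarray,
    bin_cm: float,
    max_shift: int = 300,
) -> Autocorr1D:
    """Spatial autocorrelogram of 1-D tuning.

    Mean activity per spatial bin is dotted with a zero-padded copy of
    itself shifted by 0..max_shift bins.
    """
    activity = np.asarray(activity, dtype=float)
    linear_pos = np.asarray(linear_pos, dtype=float)
    if bin_cm <= 0:
        raise ValueError("bin_cm must be positive")
    if linear_pos.size == 0:
        raise ValueError("empty track")
    span = linear_pos.max() - linear_pos.min()
    nb = int(np.floor(span / bin_cm)) + 1
    idx = np.clip(((linear_pos - linear_pos.min()) / bin_cm).astype(int), 0, nb - 1)
    H = np.bincount(idx, weights=activity, minlength=nb)
    C = np.bincount(idx, minlength=nb)
    a = np.where(C > 0, H / np.maximum(C, 1), 0.0)
    out = np.zeros(max_shift + 1)
    for s in range(min(max_shift + 1, nb)):
        out[s] = a[: nb - s] @ a[s:]
    return Autocorr1D(values=out, bin_cm=bin_cm)


def toroidal_ratemap(
    activity: np.ndarray,
    coords: ToroidalCoordinates,
    bin_deg: float = 12.0,
    sigma_bins: float = 2.0,
    hexagonal: bool = True,
    dims: Tuple[int, int] = (0, 1),
) -> RateMap2D:
    """Mean activity binned over two decoded torus angles.

    With ``hexagonal`` the first angle is sheared (u = theta1 - theta2/2 mod
    2pi) before binning so the 60-degree axis geometry is respected; the
    binned map is tiled 3x3, smoothed, the middle tile extracted and
    un-sheared back row by row.
    """
    activity = np.asarray(activity, dtype=float)
    th = coords.angles[coords.valid][:, list(dims)]
    act = activity[coords.valid]
    if th.size == 0:
        raise ValueError("no valid coordinate samples")
    if act.shape[0] != th.shape[0]:
        raise ValueError("activity and coordinates must be aligned")
    bins = int(round(360.0 / bin_deg))
    t1, t2 = th[:, 0], th[:, 1]
    if hexagonal:
        t1 = (t1 - t2 / 2.0) % (2 * np.pi)
    xi = np.clip((t1 / (2 * np.pi) * bins).astype(int), 0, bins - 1)
    yi = np.clip((t2 / (2 * np.pi) * bins).astype(int), 0, bins - 1)
    H, C = _binned_mean(act, xi, yi, bins)
    visited = C > 0
    if not visited.any():
        raise ValueError("empty toroidal occupancy")
    M = np.where(visited, H / np.maximum(C, 1), 0.0)
    M[~visited] = M[visited].mean()
    if sigma_bins > 0:
        tiled = np.tile(M, (3, 3))
        M = gaussian_filter(tiled, sigma_bins)[bins : 2 * bins, bins : 2 * bins]
    if hexagonal:
        # un-shear: roll each row r back by r/2 bins (linear interpolation)
        out = np.empty_like(M)
        for r in range(bins):
            out[r] = _frac_roll(M[r], r / 2.0)
        M = out
    return RateMap2D(M, C, sigma_bins, kind="toroidal")


def _frac_roll(row: np.ndarray, k: float) -> np.ndarray:
    """Circular shift of a 1-D array by a possibly fractional k bins."""
    base = int(np.floor(k))
    frac = k - base
    r0 = np.roll(row, base)
    if frac == 0:
        return r0
    return (1 - frac) * r0 + frac * np.roll(row, base + 1)


def toroidal_peak(map16: np.ndarray, tol: float = 1e-10) -> ToroidalPhase:
    """Circular mass center of an activity distribution on the torus.

    ``map16`` is a (b, b) nonnegative binned activity map (rows = theta2,
    columns = theta1, bin centers at (i + 0.5) * 2pi / b).  Antipodally
    balanced activity (vanishing resultant) is flagged degenerate.
    """
    m = np.asarray(map16, dtype=float)
    if m.min() < 0 or not m.any():
        raise ValueError("activity must be nonnegative and not all zero")
    b1 = m.shape[1]
    b0 = m.shape[0]
    c1 = (np.arange(b1) + 0.5) / b1 * 2 * np.pi
    c0 = (np.arange(b0) + 0.5) / b0 * 2 * np.pi
    z1 = (m.sum(axis=0) @ np.exp(1j * c1)) / m.sum()
    z2 = (m.sum(axis=1) @ np.exp(1j * c0)) / m.sum()
    degenerate = bool(min(abs(z1), abs(z2)) < tol)
    return ToroidalPhase(
        theta=(float(np.angle(z1) % (2 * np.pi)), float(np.angle(z2) % (2 * np.pi))),
        degenerate=degenerate,
    )


def angular_tuning(activity: np.ndarray, hd: np.ndarray, bins: int = 60) -> np.ndarray:
    """Max-normalized mean activity per head-direction bin."""
    activity = np.asarray(activity, dtype=float)
    hd = np.asarray(hd, dtype=float) % (2 * np.pi)
    if activity.size == 0:
        raise ValueError("empty input")
    idx = np.clip((hd / (2 * np.pi) * bins).astype(int), 0, bins - 1)
    H = np.bincount(idx, weights=activity, minlength=bins)
    C = np.bincount(idx, minlength=bins)
    curve = np.where(C > 0, H / np.maximum(C, 1), 0.0)
    peak = curve.max()
    return curve / peak if peak > 0 else curve


def toroidal3d_tuning(
    activity: np.ndarray, coords3: np.ndarray, eps: float = 0.5
) -> Tuple[np.ndarray, np.ndarray]:
    """Sparse 3-torus tuning: radial downsampling of the 3-angle coordinates
    gives spherical bin centers; each center is colored by the mean activity
    of the samples nearest to it (wrapped toroidal metric).

    Returns (centers (m, 3), mean activity per center (m,)).
    """
    activity = np.asarray(activity, dtype=float)
    coords3 = np.asarray(coords3, dtype=float)
    if coords3.size == 0:
        raise ValueError("empty coordinates")
    if coords3.ndim != 2 or coords3.shape[1] != 3:
        raise ValueError("coords3 must be (T, 3)")
    # embed on the torus so Euclidean distance respects wrap-around
    emb = np.concatenate([np.cos(coords3), np.sin(coords3)], axis=1)
    cloud = radial_downsample(PointCloud(emb), eps)
    centers_idx = cloud.indices
    d = _wrapped_dist(coords3, coords3[centers_idx])
    nearest = np.argmin(d, axis=1)
    vals = np.array(
        [
            activity[nearest == k].mean() if np.any(nearest == k) else 0.0
            for k in range(len(centers_idx))
        ]
    )
    return coords3[centers_idx], vals


def _wrapped_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(len(a), len(b)) toroidal Euclidean distances between angle tuples."""
    diff = a[:, None, :] - b[None, :, :]
    diff = (diff + np.pi) % (2 * np.pi) - np.pi
    return np.sqrt((diff**2).sum(axis=2))
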