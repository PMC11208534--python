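"""Circle-valued coordinates from persistent 1-cocycles.

A significant 1-dimensional bar's representative cocycle (integer lift of
the Z_p coefficients) is harmonically smoothed by least squares over the
1-skeleton of the Rips complex at a scale just below the bar's death,
yielding an angle per landmark that winds once around the corresponding
hole.  Several bars give toroidal coordinates.  Landmark angles are
extrapolated to arbitrary time points (or other sessions sharing the neuron
set) through per-neuron circular activity distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import lsqr

from .downsample import PointCloud
from .topology import Barcode

__all__ = [
    "CircularCoordinate",
    "ToroidalCoordinates",
    "circular_coords",
    "extrapolate_coords",
    "align_to_reference_angle",
    "circular_correlation",
]


@dataclass
class CircularCoordinate:
    """Angle per landmark in [0, 2pi) for one 1-D bar."""

    angles: np.ndarray
    bar_id: int  # rank of the source bar among dim-1 bars (by lifetime)
    tau: float  # Rips scale at which the cocycle was smoothed


@dataclass
class ToroidalCoordinates:
    """Per-time-point angle tuples (theta_1..theta_n) in [0, 2pi).

    ``valid`` flags time points with defined angles (nonzero activity);
    ``neuron_distributions`` (n_dims, n_neurons, n_bins) are the circular
    activity distributions used for extrapolation.
    """

    angles: np.ndarray  # (T, n_dims)
    valid: np.ndarray = None
    times: Optional[np.ndarray] = None
    neuron_distributions: Optional[np.ndarray] = None

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2:
            raise ValueError("angles must be (T, n_dims)")
        if self.valid is None:
            self.valid = np.ones(self.angles.shape[0], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_dims(self) -> int:
        return self.angles.shape[1]


def circular_coords(
    barcode: Barcode,
    bar_ids: Sequence[int],
    X: PointCloud,
    scale_frac: float = 0.99,
) -> List[CircularCoordinate]:
    """Circle maps for chosen 1-D bars at tau = birth + scale_frac*(death-birth).

    The stored Z_p cocycle is lifted to integers in (-p/2, p/2), restricted
    to edges present at tau, and smoothed: solve min_f ||delta0 f - eta||_2
    on the 1-skeleton; the vertex angles are 2*pi*(f mod 1).
    """
    if barcode.distances is None:
        raise ValueError("barcode must carry its distance matrix")
    D = barcode.distances
    n = D.shape[0]
    if n != len(X):
        raise ValueError("point cloud does not match the barcode's landmarks")
    bars1 = barcode.in_dim(1)
    out = []
    for bid in bar_ids:
        bar = bars1[bid]
        if bar.cocycle is None:
            raise ValueError(f"bar {bid} has no stored cocycle")
        tau = bar.birth + scale_frac * (bar.death - bar.birth)
        if not np.isfinite(tau) or bar.death < tau:
            raise ValueError(f"invalid smoothing scale for bar {bid}")
        # edges of the Rips 1-skeleton at tau
        iu, ju = np.triu_indices(n, k=1)
        keep = D[iu, ju] <= tau
        iu, ju = iu[keep], ju[keep]
        ne = iu.size
        # integer cocycle values on those edges (orientation i < j)
        eta = np.zeros(ne)
        lookup = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(iu, ju))}
        dropped = 0
        agg = {}
        for a, b, c in bar.cocycle:
            key = (int(a), int(b))
            agg[key] = agg.get(key, 0.0) + c
        for (a, b), c in agg.items():
            k = lookup.get((a, b))
            if k is None:
                dropped += 1  # cocycle edge not present at tau
                continue
            eta[k] = c
        d0 = coo_matrix(
            (
                np.r_[-np.ones(ne), np.ones(ne)],
                (np.r_[np.arange(ne), np.arange(ne)], np.r_[iu, ju]),
            ),
            shape=(ne, n),
        ).tocsr()
        f = lsqr(d0, eta, atol=1e-10, btol=1e-10)[0]
        angles = (2 * np.pi * (f % 1.0)) % (2 * np.pi)
        out.append(CircularCoordinate(angles=angles, bar_id=bid, tau=tau))
    return out


def _circular_histogram(
    angles: np.ndarray, weights: np.ndarray, n_bins: int, smooth_bins: float
) -> np.ndarray:
    idx = np.floor(angles / (2 * np.pi) * n_bins).astype(int) % n_bins
    h = np.bincount(idx, weights=weights, minlength=n_bins).astype(float)
    if smooth_bins > 0:
        h = gaussian_filter1d(h, smooth_bins, mode="wrap")
    return h


def extrapolate_coords(
    coords: List[CircularCoordinate],
    landmark_rates: np.ndarray,
    target_rates: np.ndarray,
    n_bins: int = 16,
    smooth_bins: float = 1.0,
    times: Optional[np.ndarray] = None,
) -> ToroidalCoordinates:
    """Extend landmark angles to all time points of ``target_rates``.

    For each circular dimension, every neuron's activity across landmarks is
    binned over the landmark angles into a smoothed circular distribution
    (its tuning on that circle, normalized to unit mass).  At each target
    time the neuron distributions are summed weighted by instantaneous
    activity, and the angle is the circular mass center of the sum.  Time
    points with zero total weight are masked.

    ``landmark_rates`` and ``target_rates`` are (n_neurons, n_landmarks) and
    (n_neurons, T) and must share the neuron set.
    """
    landmark_rates = np.asarray(landmark_rates, dtype=float)
    target_rates = np.asarray(target_rates, dtype=float)
    if landmark_rates.shape[0] != target_rates.shape[0]:
        raise ValueError("landmark and target rates must share the neuron set")
    n_neurons = landmark_rates.shape[0]
    T = target_rates.shape[1]
    n_dims = len(coords)
    centers = (np.arange(n_bins) + 0.5) / n_bins * 2 * np.pi
    angles = np.zeros((T, n_dims))
    valid = np.ones(T, dtype=bool)
    dists = np.zeros((n_dims, n_neurons, n_bins))
    for d, cc in enumerate(coords):
        if cc.angles.shape[0] != landmark_rates.shape[1]:
            raise ValueError("coordinate length does not match landmark count")
        for i in range(n_neurons):
            h = _circular_histogram(cc.angles, landmark_rates[i], n_bins, smooth_bins)
            s = h.sum()
            dists[d, i] = h / s if s > 0 else 0.0
        # combined distribution per time: (T, n_bins)
        P = target_rates.T @ dists[d]
        z = P @ np.exp(1j * centers)
        angles[:, d] = np.angle(z) % (2 * np.pi)
        valid &= np.abs(z) > 0
    return ToroidalCoordinates(
        angles=angles, valid=valid, times=times, neuron_distributions=dists
    )


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher-Lee circular correlation coefficient between two angle series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    # O(n) expansion of sum_{ij} sin(a_i - a_j) sin(b_i - b_j)
    s, c = np.sin(a), np.cos(a)
    u, v = np.sin(b), np.cos(b)
    num = (s @ u) * (c @ v) - (s @ v) * (c @ u)
    da = (s @ s) * (c @ c) - (s @ c) ** 2
    db = (u @ u) * (v @ v) - (u @ v) ** 2
    den = np.sqrt(da * db)
    return float(num / den) if den > 0 else 0.0


def align_to_reference_angle(theta: np.ndarray, ref: np.ndarray):
    """Fix the orientation/offset gauge of a circular coordinate.

    Tests both orientations {theta, -theta}; for each, the offset is the
    circular mean of (ref - candidate); returns the aligned angles, the sign
    and the offset minimizing the mean circular distance
    (1 - cos(ref - aligned)).
    """
    theta = np.asarray(theta, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if theta.shape != ref.shape:
        raise ValueError("theta and ref must have equal length")
    best = None
    for sign in (1.0, -1.0):
        cand = sign * theta
        offset = np.angle(np.exp(1j * (ref - cand)).mean())
        err = float(np.mean(1 - np.cos(ref - cand - offset)))
        if best is None or err < best[0]:
            best = (err, sign, offset)
    err, sign, offset = best
    aligned = (sign * theta + offset) % (2 * np.pi)
    return aligned, sign, offset
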