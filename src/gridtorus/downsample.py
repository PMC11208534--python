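"""Two-step point-cloud reduction.

A radial (farthest-point / maximin) pass spreads landmarks at least ``eps``
apart, then a fuzzy-membership pass keeps the ``m`` points most central to
the cloud's dense regions, discarding outliers.  Memberships follow the
fuzzy-topological construction: per-point kernel widths are calibrated so
that each point's kappa-neighborhood carries log2(kappa) total membership,
and pairwise memberships are symmetrized with the probabilistic sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "PointCloud",
    "FuzzyMembership",
    "radial_downsample",
    "fit_memberships",
    "fuzzy_downsample",
]


@dataclass
class PointCloud:
    """m x d coordinates plus the original (time) indices of each point."""

    points: np.ndarray
    indices: np.ndarray = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("points must be 2-D (m x d)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")
        if self.indices is None:
            self.indices = np.arange(self.points.shape[0])
        self.indices = np.asarray(self.indices)
        if self.indices.shape[0] != self.points.shape[0]:
            raise ValueError("indices length must match the number of points")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("indices must be unique")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class FuzzyMembership:
    """Per-point kernel widths, kappa-neighborhoods and symmetrized mu."""

    sigma: np.ndarray  # (m,)
    neighbors: np.ndarray  # (m, kappa) indices of the kappa nearest points
    mu: np.ndarray  # (m, m) symmetric memberships in [0, 1]


def radial_downsample(X: PointCloud, eps: float) -> PointCloud:
    """Greedy maximin landmark selection with an ``eps`` exclusion radius.

    The first landmark is the point with maximum summed absolute coordinate
    value; every point within ``eps`` (Euclidean) of a landmark is discarded,
    and the next landmark is the survivor farthest from the landmark set
    (largest minimum distance).  Landmarks are returned in selection order;
    all pairwise landmark distances are >= eps.
    """
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    pts = X.points
    n = len(X)
    if n == 0:
        return PointCloud(np.empty((0, X.points.shape[1])), np.empty(0, dtype=int))
    first = int(np.argmax(np.abs(pts).sum(axis=1)))
    alive = np.ones(n, dtype=bool)
    mindist = np.full(n, np.inf)
    chosen = []
    cur = first
    while True:
        chosen.append(cur)
        d = np.linalg.norm(pts - pts[cur], axis=1)
        mindist = np.minimum(mindist, d)
        alive &= mindist >= eps
        if eps == 0:
            alive[cur] = False
        if not np.any(alive):
            break
        cand = np.where(alive)[0]
        cur = int(cand[np.argmax(mindist[cand])])
    return PointCloud(pts[chosen], X.indices[chosen])


def fit_memberships(X: PointCloud, kappa: int) -> FuzzyMembership:
    """Calibrate per-point kernel widths and symmetrized memberships.

    For each point x, sigma_x solves sum_{y in N_x} exp(-d(x, y)/sigma_x)
    = log2(kappa) over the kappa nearest neighbors (bisection to 1e-8
    relative tolerance).  Directed memberships are supported on the
    neighborhood graph (mu_x(y) = 0 for y outside N_x: a point can only
    belong to neighborhoods it is a member of, which is what lets the
    selection stage reject isolated outliers), then symmetrized by the
    probabilistic sum mu(x, y) = mu_x(y) + mu_y(x) - mu_x(y) mu_y(x).
    """
    n = len(X)
    if not 0 < kappa < n:
        raise ValueError(f"kappa must be in (0, {n})")
    D = cdist(X.points, X.points)
    order = np.argsort(D, axis=1, kind="stable")
    neighbors = order[:, 1 : kappa + 1]  # exclude the point itself
    nd = np.take_along_axis(D, neighbors, axis=1)
    target = np.log2(kappa)
    sigma = np.empty(n)
    for i in range(n):
        sigma[i] = _solve_sigma(nd[i], target)
    mu_dir = np.zeros((n, n))
    rows = np.repeat(np.arange(n), kappa)
    mu_dir[rows, neighbors.ravel()] = np.exp(-nd / sigma[:, None]).ravel()
    mu = mu_dir + mu_dir.T - mu_dir * mu_dir.T
    np.fill_diagonal(mu, 1.0)
    return FuzzyMembership(sigma=sigma, neighbors=neighbors, mu=mu)


def _solve_sigma(dists: np.ndarray, target: float, rtol: float = 1e-8) -> float:
    """Bisection for sum(exp(-d/sigma)) = target; monotone increasing in sigma."""
    nz = np.count_nonzero(dists == 0)
    if nz >= target:
        # duplicates already saturate the target; take the limit convention
        logger.info("duplicate points saturate the membership target; sigma -> 0")
        return np.finfo(float).tiny
    lo, hi = 1e-12, 1.0
    while np.exp(-dists / hi).sum() < target:
        hi *= 2
        if hi > 1e12:
            break
    while (hi - lo) > rtol * hi:
        mid = 0.5 * (lo + hi)
        if np.exp(-dists / mid).sum() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fuzzy_downsample(
    X: PointCloud, kappa: int, m: int, membership: Optional[FuzzyMembership] = None
) -> PointCloud:
    """Keep the ``m`` points most central under the fuzzy memberships.

    Greedy: the n-th point maximizes F_n(x) = sum of mu(x, y) over the points
    not yet selected; F is maintained incrementally by subtracting the
    selected point's membership column.  Points are returned in selection
    order.  Ties break toward the lower point index.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    n = len(X)
    if m > n:
        raise ValueError(f"m={m} exceeds the cloud size {n}")
    if membership is None:
        membership = fit_memberships(X, kappa)
    mu = membership.mu
    F = mu.sum(axis=1)
    selected = np.zeros(n, dtype=bool)
    chosen = []
    for _ in range(m):
        cand = np.where(~selected)[0]
        nxt = int(cand[np.argmax(F[cand])])
        chosen.append(nxt)
        selected[nxt] = True
        F -= mu[:, nxt]
    return PointCloud(X.points[chosen], X.indices[chosen])
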