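"""Barcodes of the reduced point cloud and shuffle-based significance.

Persistent cohomology of the Vietoris-Rips filtration is computed on the
cosine-distance matrix with Z_47 coefficients (47 is unlikely to divide any
torsion), keeping representative 1-cocycles for the coordinatization stage.
Significance thresholds come from a time-roll null: each neuron's rate
series is circularly rolled by an independent uniform offset, the whole
whiten-downsample-persistence pipeline is rerun, and the 99th percentile of
maximal lifetimes per dimension over shuffles is the threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._cohomology import rips_cohomology
from .downsample import PointCloud, fit_memberships, fuzzy_downsample, radial_downsample
from .preprocess import ParameterProfile, RateMatrix, pca_whiten

__all__ = [
    "PersistenceBar",
    "Barcode",
    "compute_persistence",
    "cloud_from_rates",
    "shuffle_null",
    "count_significant_bars",
]


@dataclass
class PersistenceBar:
    """A single persistence interval [birth, death) with optional cocycle."""

    dim: int
    birth: float
    death: float  # may be inf
    cocycle: Optional[np.ndarray] = None  # (n_edges, 3): i, j, integer coeff

    def __post_init__(self):
        if self.death < self.birth:
            raise ValueError("death must be >= birth")

    @property
    def lifetime(self) -> float:
        return self.death - self.birth


@dataclass
class Barcode:
    """Bars across dimensions plus the distance matrix they came from.

    ``thresholds`` maps dimension -> shuffle-null lifetime threshold (the
    99th percentile of maximal shuffled lifetimes).
    """

    bars: List[PersistenceBar]
    metric: str = "cosine"
    prime: int = 47
    thresholds: Dict[int, float] = field(default_factory=dict)
    distances: Optional[np.ndarray] = None

    def in_dim(self, dim: int) -> List[PersistenceBar]:
        return [b for b in self.bars if b.dim == dim]

    def to_json(self) -> str:
        recs = [
            {
                "dim": b.dim,
                "birth": b.birth,
                "death": None if np.isinf(b.death) else b.death,
                "lifetime": None if np.isinf(b.death) else b.lifetime,
                "significant": bool(
                    b.dim in self.thresholds
                    and np.isfinite(b.death)
                    and b.lifetime > self.thresholds[b.dim]
                ),
            }
            for b in self.bars
        ]
        return json.dumps(
            {
                "metric": self.metric,
                "prime": self.prime,
                "thresholds": {str(k): v for k, v in self.thresholds.items()},
                "bars": recs,
            },
            indent=1,
        )


def compute_persistence(
    X: PointCloud,
    maxdim: int = 2,
    metric: str = "cosine",
    prime: int = 47,
    thresh: Optional[float] = None,
    cocycles: bool = True,
) -> Barcode:
    """Vietoris-Rips barcode of a point cloud.

    The filtration runs to the enclosing radius by default (beyond it the
    complex is a cone, so no feature above dimension 0 survives anyway).
    Representative cocycles are kept for dimension-1 bars.
    """
    if maxdim < 0:
        raise ValueError("maxdim must be nonnegative")
    D = squareform(pdist(X.points, metric=metric))
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances (zero vectors under cosine?)")
    bars_raw, reps = rips_cohomology(D, maxdim=maxdim, thresh=thresh, p=prime, cocycles=cocycles)
    bars = []
    rank1 = 0
    for dim, b, d in bars_raw:
        coc = None
        if dim == 1:
            coc = reps.get((1, rank1))
            rank1 += 1
        bars.append(PersistenceBar(dim, b, d, cocycle=coc))
    return Barcode(bars=bars, metric=metric, prime=prime, distances=D)


def cloud_from_rates(rates: RateMatrix, profile: ParameterProfile) -> PointCloud:
    """Whiten + two-step downsampling: the pipeline's standard reduction.

    ``rates`` should already be square-rooted and speed-filtered; this
    applies z-scoring, PCA whitening to ``profile.d`` dimensions, radial
    downsampling at ``profile.eps`` and fuzzy downsampling to ``profile.m``
    points (kappa capped below the radial-stage output size).
    """
    white = pca_whiten(rates, profile.d)
    cloud = PointCloud(white.values.T, indices=np.arange(white.values.shape[1]))
    radial = radial_downsample(cloud, profile.eps)
    kappa = min(profile.kappa, len(radial) - 1)
    m = min(profile.m, len(radial))
    return fuzzy_downsample(radial, kappa, m)


def shuffle_null(
    rates: RateMatrix,
    profile: ParameterProfile,
    n_shuffles: int = 100,
    seed: int = 0,
    maxdim: int = 2,
    metric: str = "cosine",
    prime: int = 47,
    return_samples: bool = False,
):
    """Per-dimension lifetime thresholds from time-rolled surrogates.

    Each neuron's rate series is independently rolled by a uniform circular
    offset over the full recording, the whiten/downsample/persistence
    pipeline is rerun, and the maximal finite lifetime per dimension is
    recorded; thresholds are the 99th percentiles over shuffles.  The
    infinite dimension-0 bar is excluded.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    T = rates.n_time
    maxlife = np.zeros((n_shuffles, maxdim + 1))
    for s in range(n_shuffles):
        rolled = np.empty_like(rates.values)
        for i in range(rates.n_neurons):
            rolled[i] = np.roll(rates.values[i], rng.integers(0, T))
        surrogate = RateMatrix(rolled, dt=rates.dt, times=rates.times, transform=rates.transform)
        cloud = cloud_from_rates(surrogate, profile)
        bc = compute_persistence(cloud, maxdim=maxdim, metric=metric, prime=prime, cocycles=False)
        for d in range(maxdim + 1):
            lives = [b.lifetime for b in bc.in_dim(d) if np.isfinite(b.death)]
            maxlife[s, d] = max(lives, default=0.0)
    thresholds = {d: float(np.percentile(maxlife[:, d], 99)) for d in range(maxdim + 1)}
    if return_samples:
        return thresholds, maxlife
    return thresholds


def plot_barcode(barcode: Barcode, ax=None, max_bars: int = 30):
    """Lifetime diagram: bars per dimension with the shuffle thresholds
    shaded.  Returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    y = 0
    colors = {0: "C0", 1: "C1", 2: "C2"}
    dims = sorted({b.dim for b in barcode.bars})
    for d in dims:
        bars = sorted(
            barcode.in_dim(d), key=lambda b: -(b.lifetime if np.isfinite(b.death) else 1e9)
        )[:max_bars]
        for b in bars:
            death = b.death if np.isfinite(b.death) else max(
                x.death for x in barcode.bars if np.isfinite(x.death)
            ) * 1.1
            ax.hlines(y, b.birth, death, color=colors.get(d, "k"), lw=2)
            y += 1
        if d in barcode.thresholds:
            ax.axvspan(0, barcode.thresholds[d], color=colors.get(d, "k"), alpha=0.08)
        y += 2
    ax.set_xlabel("filtration scale")
    ax.set_yticks([])
    ax.set_title("persistence barcode (H0/H1/H2)")
    return ax


def count_significant_bars(barcode: Barcode, dim: int) -> int:
    """Number of finite bars in ``dim`` whose lifetime exceeds the
    shuffle-null threshold."""
    if dim not in barcode.thresholds:
        raise ValueError(f"no shuffle threshold stored for dimension {dim}")
    thr = barcode.thresholds[dim]
    return sum(
        1 for b in barcode.in_dim(dim) if np.isfinite(b.death) and b.lifetime > thr
    )
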