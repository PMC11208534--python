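"""Covariate-free ensemble (module) detection.

Neurons are grouped by the shape of their time-lagged cross-correlations:
c_ij(tau) = sum_t s_i(t) s_j(t+tau) over lags 0..tau_max, collapsed to the
inverse normalized cross-correlation C_ij = min(c_ij, c_ji) / max(c_ij, c_ji)
over the lag window.  Each neuron's feature vector is its row of C squared
elementwise; neurons are clustered by average-linkage agglomeration on the
pairwise correlation distance of these features, cut at a threshold rho, and
clusters below a minimum size are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from .preprocess import RateMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CrossCorrSet",
    "EnsemblePartition",
    "crosscorr",
    "inverse_norm_crosscorr",
    "cluster_ensembles",
]


@dataclass
class CrossCorrSet:
    """c[i, j, k]: cross-correlation of neurons i, j at lag k * lag_step."""

    c: np.ndarray  # (n, n, n_lags), lags 0..tau_max
    lag_step: float  # seconds


@dataclass
class EnsemblePartition:
    """Cluster labels (-1 = discarded) plus the distance matrix behind them."""

    labels: np.ndarray  # (n,) ints, -1 for neurons in dropped clusters
    distance: np.ndarray  # (n, n) correlation distance between features
    rho: float
    min_size: int

    @property
    def ensembles(self) -> List[np.ndarray]:
        """Retained ensembles as index arrays, largest first."""
        out = [
            np.where(self.labels == k)[0]
            for k in np.unique(self.labels)
            if k >= 0
        ]
        return sorted(out, key=len, reverse=True)


def crosscorr(r: RateMatrix, tau_max: float) -> CrossCorrSet:
    """Time-lagged cross-correlations over lags 0..tau_max.

    ``r`` should be the clustering-path rate matrix (wide kernel, coarse
    sampling).  The lag step is the rate sample step.
    """
    if tau_max < r.dt:
        raise ValueError(f"tau_max={tau_max} is below the lag step {r.dt}")
    s = r.values
    n, T = s.shape
    n_lags = int(np.floor(tau_max / r.dt)) + 1
    c = np.empty((n, n, n_lags))
    for k in range(n_lags):
        c[:, :, k] = s[:, : T - k] @ s[:, k:].T
    return CrossCorrSet(c=c, lag_step=r.dt)


def inverse_norm_crosscorr(cc: CrossCorrSet) -> np.ndarray:
    """C_ij = min over the lag window of {c_ij, c_ji} / the matching max.

    The min and max are taken jointly over both orderings (equivalently over
    positive and negative lags).  Values lie in [0, 1]; 1 means a flat
    correlogram (no evidence of coupling).  All-zero pairs are defined as 1
    and logged.
    """
    c = cc.c
    both = np.concatenate([c, np.transpose(c, (1, 0, 2))], axis=2)
    lo = both.min(axis=2)
    hi = both.max(axis=2)
    out = np.ones_like(hi)
    nz = hi > 0
    out[nz] = lo[nz] / hi[nz]
    if not np.all(nz):
        logger.info("%d neuron pairs had all-zero correlograms", int((~nz).sum() // 2))
    return out


def cluster_ensembles(
    C: np.ndarray,
    rho: float,
    min_size: int = 19,
    extra_features: Optional[Sequence[np.ndarray]] = None,
) -> EnsemblePartition:
    """Average-linkage agglomerative clustering of neurons.

    Feature vector of neuron i is row i of C squared elementwise with the
    self-entry removed (the diagonal is degenerate); when several recordings
    of the same population are available (``extra_features``), features are
    averaged across them.  The pairwise distance is one minus the Pearson
    correlation of feature vectors; the dendrogram is cut at ``rho`` and
    clusters smaller than ``min_size`` are discarded (label -1).
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if C.ndim != 2 or C.shape[1] != n:
        raise ValueError("C must be square")
    if n < 2:
        raise ValueError("need at least 2 neurons to cluster")
    feats = [C**2]
    if extra_features is not None:
        feats += [np.asarray(F, dtype=float) ** 2 for F in extra_features]
    F = np.mean(feats, axis=0)

    D = np.zeros((n, n))
    mask_cols = ~np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            keep = mask_cols[i] & mask_cols[j]
            keep[i] = keep[j] = False
            a, b = F[i, keep], F[j, keep]
            sa, sb = a.std(), b.std()
            rij = 0.0 if sa == 0 or sb == 0 else np.corrcoef(a, b)[0, 1]
            D[i, j] = D[j, i] = 1.0 - rij

    if rho <= 0:
        labels = np.arange(n)
    else:
        agg = AgglomerativeClustering(
            n_clusters=None,
            metric="precomputed",
            linkage="average",
            distance_threshold=rho,
        )
        labels = agg.fit_predict(D)
    # drop small clusters, relabel retained ones by decreasing size
    out = np.full(n, -1)
    kept = [
        k for k in np.unique(labels) if np.count_nonzero(labels == k) >= min_size
    ]
    kept.sort(key=lambda k: -np.count_nonzero(labels == k))
    for newk, k in enumerate(kept):
        out[labels == k] = newk
    return EnsemblePartition(labels=out, distance=D, rho=rho, min_size=min_size)
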