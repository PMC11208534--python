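"""From event times to the whitened point cloud.

Spike (or calcium-event) times are turned into smooth firing rates by summing
unit-area Gaussian kernels, square-root transformed to stabilize variance,
restricted to moments of movement, z-scored, and PCA-whitened down to a few
components.  The resulting time-indexed point cloud is what the downsampling
and persistence stages consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "SpikeTrainSet",
    "RateMatrix",
    "ParameterProfile",
    "rates_from_spikes",
    "sqrt_transform",
    "speed_filter",
    "zscore_rates",
    "pca_whiten",
]


@dataclass
class SpikeTrainSet:
    """Per-neuron sorted event times (seconds) over a recording span."""

    spikes: list  # list of 1-D float arrays
    span: tuple  # (t_start, t_stop)
    neuron_ids: Optional[list] = None

    def __post_init__(self):
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        if self.neuron_ids is None:
            self.neuron_ids = list(range(len(self.spikes)))
        t0, t1 = self.span
        for i, s in enumerate(self.spikes):
            if np.any(np.diff(s) < 0):
                raise ValueError(f"spike times of neuron {i} are not sorted")
            if s.size and (s[0] < t0 - 1e-9 or s[-1] > t1 + 1e-9):
                raise ValueError(f"spike times of neuron {i} outside span")

    @property
    def n_neurons(self) -> int:
        return len(self.spikes)


@dataclass
class RateMatrix:
    """Neurons x time firing-rate array with its sample step and provenance.

    ``times`` holds the timestamp of every retained column, so that masking
    (speed filtering) keeps the mapping back to the recording.
    """

    values: np.ndarray  # (n_neurons, n_time)
    dt: float
    times: np.ndarray = None
    transform: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (neurons x time)")
        if self.times is None:
            self.times = np.arange(self.values.shape[1]) * self.dt
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape[0] != self.values.shape[1]:
            raise ValueError("times length must equal the number of columns")
        if self.transform in ("raw", "sqrt") and self.values.size and self.values.min() < 0:
            raise ValueError(f"{self.transform} rates must be nonnegative")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


@dataclass
class ParameterProfile:
    """Pipeline parameters (units: seconds, cm, counts).

    Defaults are the package's standard study conditions for simulated
    grid-module recordings; per-dataset overrides are expected for real data.
    """

    sigma_smooth: float = 0.06  # rate kernel width for the topology path (s)
    dt_topology: float = 0.01  # rate sample step for the topology path (s)
    dt_cluster: float = 0.03  # sample step for ensemble cross-correlations (s)
    sigma_cluster: float = 0.3  # rate kernel width for clustering (s)
    d: int = 6  # whitened PCA dimension
    eps: float = 0.5  # radial downsampling radius
    kappa: int = 600  # fuzzy-membership neighborhood size
    m: int = 400  # number of retained landmarks
    rho_cluster: float = 0.4  # agglomerative cut distance (correlation units)
    tau_max: float = 3.0  # cross-correlation lag window (s)
    speed_min: float = 5.0  # minimum running speed (cm/s)

    def __post_init__(self):
        for name in (
            "sigma_smooth",
            "dt_topology",
            "dt_cluster",
            "sigma_cluster",
            "eps",
            "tau_max",
        ):
            if getattr(self, name) < 0 or (
                name in ("sigma_smooth", "dt_topology", "dt_cluster") and getattr(self, name) == 0
            ):
                raise ValueError(f"{name} must be positive")
        if self.d < 1 or self.kappa < 1 or self.m < 1:
            raise ValueError("d, kappa and m must be positive counts")


def rates_from_spikes(
    spikes: SpikeTrainSet, sigma: float, dt: float, truncate: float = 5.0
) -> RateMatrix:
    """Continuous firing rates from event times.

    Every event contributes a unit-area Gaussian of width ``sigma`` (so rates
    are in events per second), and the summed function is sampled every
    ``dt`` seconds across the recording span.  Kernels are truncated at
    ``truncate`` standard deviations (< 1e-6 of the mass at the default).
    """
    if sigma <= 0 or dt <= 0:
        raise ValueError("sigma and dt must be positive")
    t0, t1 = spikes.span
    times = t0 + np.arange(int(np.floor((t1 - t0) / dt)) + 1) * dt
    norm = 1.0 / (sigma * np.sqrt(2 * np.pi))
    half = truncate * sigma
    values = np.zeros((spikes.n_neurons, times.size))
    for i, st in enumerate(spikes.spikes):
        if st.size == 0:
            continue
        lo = np.searchsorted(times, st - half, side="left")
        hi = np.searchsorted(times, st + half, side="right")
        row = values[i]
        for s, a, b in zip(st, lo, hi):
            row[a:b] += norm * np.exp(-0.5 * ((times[a:b] - s) / sigma) ** 2)
    return RateMatrix(values, dt=dt, times=times, transform="raw")


def sqrt_transform(r: RateMatrix) -> RateMatrix:
    """Elementwise square root of raw rates (variance stabilization)."""
    if r.values.min() < 0:
        raise ValueError("sqrt_transform requires nonnegative rates")
    return replace(r, values=np.sqrt(r.values), transform="sqrt")


def speed_filter(
    r: RateMatrix,
    speed: np.ndarray,
    v_min: float,
    drop_silent: bool = False,
) -> RateMatrix:
    """Keep only columns where running speed is at least ``v_min`` cm/s.

    ``speed`` must be sampled on the same time base as ``r``.  With
    ``drop_silent`` (intended for event data), population vectors with no
    activity at all are also excluded.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.shape[0] != r.n_time:
        raise ValueError(
            f"speed has {speed.shape[0]} samples but the rate matrix has {r.n_time} columns"
        )
    keep = speed >= v_min
    if drop_silent:
        keep &= r.values.sum(axis=0) > 0
    if not np.any(keep):
        raise ValueError("speed filter removed every sample")
    return replace(r, values=r.values[:, keep], times=r.times[keep])


def zscore_rates(r: RateMatrix) -> RateMatrix:
    """Z-score each neuron over the retained samples.

    Zero-variance neurons are dropped with a warning (they carry no
    information and would break the normalization).
    """
    mu = r.values.mean(axis=1, keepdims=True)
    sd = r.values.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    if not np.all(ok):
        warnings.warn(
            f"dropping {np.count_nonzero(~ok)} zero-variance neuron(s) before z-scoring"
        )
    vals = (r.values[ok] - mu[ok]) / sd[ok]
    return replace(r, values=vals, transform="zscored")


def pca_whiten(r: RateMatrix, d: int) -> RateMatrix:
    """Project z-scored population vectors onto the first ``d`` principal
    components and divide by the square roots of the eigenvalues.

    Returns a ``d`` x T matrix tagged ``whitened``; the empirical covariance
    of the retained components is the identity.
    """
    if r.transform != "zscored":
        r = zscore_rates(r)
    if d > r.n_neurons:
        raise ValueError(f"d={d} exceeds the number of neurons ({r.n_neurons})")
    pca = PCA(n_components=d, whiten=True, svd_solver="full")
    comp = pca.fit_transform(r.values.T)  # (T, d), uncorrelated columns
    comp /= comp.std(axis=0, ddof=0)  # unit empirical covariance
    return replace(r, values=comp.T, transform="whitened")
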