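"""Hexagonal vs square torus classification via heat-kernel models.

The heat kernel with a point source on a flat torus is a lattice sum of
Gaussians; on the hexagonal torus the quadratic form is
(2/sqrt(3)) (x^2 + x y + y^2), on the square torus x^2 + y^2.  Each unit's
observed toroidal rate map (10x10 bins of landmark coordinates) is
correlated with model maps centered at the unit's peak phase; an ensemble
is hexagonal when the median hex correlation exceeds 0.6 and the square
median.  The torus is parameterized on [0, 1)^2 internally (angles are
divided by 2pi at the module boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .coordinatize import ToroidalCoordinates
from .maps import RateMap2D, ToroidalPhase
from .preprocess import RateMatrix

__all__ = [
    "HeatKernelConfig",
    "TorusClassification",
    "heat_kernel",
    "model_ratemap",
    "observed_ratemap_10",
    "classify_torus",
    "heat_model_rates",
]


@dataclass
class HeatKernelConfig:
    """Diffusion time and truncation of the lattice sum."""

    t: float = 0.1
    k_range: Tuple[int, ...] = (-1, 0, 1)
    variant: str = "hex"  # or "sqr"

    def __post_init__(self):
        if self.t <= 0:
            raise ValueError("diffusion time t must be positive")
        if self.variant not in ("hex", "sqr"):
            raise ValueError("variant must be 'hex' or 'sqr'")


@dataclass
class TorusClassification:
    """Per-unit best-fit correlations and the ensemble-level label."""

    hex_corr: np.ndarray  # per unit, max over the two orientations
    sqr_corr: np.ndarray
    median_hex: float
    median_sqr: float
    label: str  # 'hexagonal', 'square' or 'unclassified'


def heat_kernel(x, y, cfg: HeatKernelConfig):
    """Temperature at normalized torus position(s) (x, y) in [0, 1)^2.

    Truncated lattice sum with a 1/t prefactor:
    H(x, y) = (1/t) sum_{k,l} exp(-pi/t * Q(k+x, l+y)) with Q the hexagonal
    or square quadratic form.  Coordinates are wrapped into [0, 1) so the
    kernel is periodic under the truncation convention.
    """
    x = np.asarray(x, dtype=float) % 1.0
    y = np.asarray(y, dtype=float) % 1.0
    out = np.zeros(np.broadcast(x, y).shape)
    for k in cfg.k_range:
        for l in cfg.k_range:
            a = k + x
            b = l + y
            if cfg.variant == "hex":
                q = (2.0 / np.sqrt(3.0)) * (a**2 + a * b + b**2)
            else:
                q = a**2 + b**2
            out = out + np.exp(-np.pi / cfg.t * q)
    return out / cfg.t


def model_ratemap(
    peak: ToroidalPhase,
    cfg: HeatKernelConfig,
    bins: int = 10,
    m: int = 400,
    reverse: bool = False,
    basis: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Idealized rate map: mean heat-kernel temperature in ``bins``^2 square
    bins of an evenly sampled torus with the origin shifted to the unit's
    peak.  ``reverse`` flips the second sampled coordinate (the two axis
    orientations of the hexagonal torus); ``basis`` applies a unimodular
    lattice change-of-basis to the relative coordinates before evaluating
    the kernel (the decoded axes may be any primitive pair of the lattice).
    """
    if peak.degenerate:
        raise ValueError("degenerate peak phase")
    # even grid of ~m samples whose side is a multiple of the bin count
    n = bins * max(1, int(round(np.sqrt(m) / bins)))
    u = (np.arange(n) + 0.5) / n
    U, V = np.meshgrid(u, u)
    px, py = peak.theta[0] / (2 * np.pi), peak.theta[1] / (2 * np.pi)
    RU, RV = U - px, V - py
    if reverse:
        RV = -RV
    if basis is not None:
        RU, RV = (
            basis[0, 0] * RU + basis[0, 1] * RV,
            basis[1, 0] * RU + basis[1, 1] * RV,
        )
    H = heat_kernel(RU, RV, cfg)
    # mean per bin
    return H.reshape(bins, n // bins, bins, n // bins).mean(axis=(1, 3))


def observed_ratemap_10(
    activity: np.ndarray, coords: ToroidalCoordinates, bins: int = 10
) -> np.ndarray:
    """Mean activity in ``bins``^2 bins of the landmark torus coordinates
    (unsmoothed, no shear: the heat-kernel models carry the geometry)."""
    th = coords.angles[coords.valid]
    act = np.asarray(activity, dtype=float)[coords.valid]
    xi = np.clip((th[:, 0] / (2 * np.pi) * bins).astype(int), 0, bins - 1)
    yi = np.clip((th[:, 1] / (2 * np.pi) * bins).astype(int), 0, bins - 1)
    H = np.zeros((bins, bins))
    C = np.zeros((bins, bins))
    np.add.at(H, (yi, xi), act)
    np.add.at(C, (yi, xi), 1)
    M = np.where(C > 0, H / np.maximum(C, 1), 0.0)
    if (C > 0).any():
        M[C == 0] = M[C > 0].mean()
    return M


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _gauge_matrices() -> List[np.ndarray]:
    """Gauge freedom of the decoded torus axes: the same unimodular
    short-vector changes-of-basis that toroidal alignment enumerates."""
    from .dynamics import hex_basis_changes

    return hex_basis_changes()


def classify_torus(
    unit_maps: Sequence[np.ndarray],
    peaks: Sequence[ToroidalPhase],
    t: float = 0.1,
    bins: int = 10,
    median_threshold: float = 0.6,
) -> TorusClassification:
    """Hexagonal-torus test for an ensemble.

    Per unit: Pearson correlation of the observed (bins^2) map with the
    hexagonal and square heat-kernel models, maximized over the decoded
    axes' gauge group (orientation reversals plus unimodular axis
    substitutions - the decoded circles may be any primitive axis pair of
    the lattice).  The ensemble is hexagonal iff the median hex correlation
    exceeds ``median_threshold`` AND the square median.
    """
    if len(unit_maps) < 2:
        raise ValueError("need at least 2 units to classify")
    if len(unit_maps) != len(peaks):
        raise ValueError("maps and peaks must be aligned")
    hex_cfg = HeatKernelConfig(t=t, variant="hex")
    sqr_cfg = HeatKernelConfig(t=t, variant="sqr")
    gauges = _gauge_matrices()
    hex_corr = np.zeros(len(unit_maps))
    sqr_corr = np.zeros(len(unit_maps))
    for i, (M, pk) in enumerate(zip(unit_maps, peaks)):
        if pk.degenerate:
            hex_corr[i] = sqr_corr[i] = np.nan
            continue
        hex_corr[i] = max(
            _corr(M, model_ratemap(pk, hex_cfg, bins=bins, basis=G)) for G in gauges
        )
        sqr_corr[i] = max(
            _corr(M, model_ratemap(pk, sqr_cfg, bins=bins, basis=G)) for G in gauges
        )
    median_hex = float(np.nanmedian(hex_corr))
    median_sqr = float(np.nanmedian(sqr_corr))
    if median_hex > median_threshold and median_hex > median_sqr:
        label = "hexagonal"
    elif median_sqr > median_threshold and median_sqr > median_hex:
        label = "square"
    else:
        label = "unclassified"
    return TorusClassification(hex_corr, sqr_corr, median_hex, median_sqr, label)


def heat_model_rates(
    coords: ToroidalCoordinates,
    peaks: Sequence[ToroidalPhase],
    cfg: Optional[HeatKernelConfig] = None,
) -> RateMatrix:
    """Idealized time-varying rates: each unit's rate is the hexagonal heat
    kernel evaluated at the decoded torus position relative to the unit's
    peak.  Masked time points propagate as zero rate columns."""
    if cfg is None:
        cfg = HeatKernelConfig(variant="hex")
    th = coords.angles / (2 * np.pi)
    T = th.shape[0]
    out = np.zeros((len(peaks), T))
    for i, pk in enumerate(peaks):
        px, py = pk.theta[0] / (2 * np.pi), pk.theta[1] / (2 * np.pi)
        vals = heat_kernel(th[:, 0] - px, th[:, 1] - py, cfg)
        out[i] = np.where(coords.valid, vals, 0.0)
    return RateMatrix(out, dt=1.0 if coords.times is None else float(np.median(np.diff(coords.times))), times=coords.times)
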