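"""Cross-session toroidal dynamics: alignment, phase conservation,
trajectory unwrapping and per-trial path length.

Decoded torus coordinates carry an arbitrary gauge: per-axis orientation
and offset, plus (on the hexagonal torus) the choice of two of three
lattice axes 60/120 degrees apart.  Alignment enumerates the unimodular
lattice changes-of-basis with entries in {-1, 0, 1} extended by the
(1, +-1) axis combinations, composed with flips and offsets, and keeps the
transform minimizing the mean circular difference after light temporal
smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import pearsonr

from .coordinatize import ToroidalCoordinates

__all__ = [
    "TorusTransform",
    "TrialPath",
    "hex_basis_changes",
    "align_tori",
    "phase_distance_test",
    "unwrap_torus",
    "trial_path_length",
    "toroidal_phase_distance",
]


@dataclass
class TorusTransform:
    """theta' = (M @ theta + offsets) mod 2pi with M unimodular."""

    matrix: np.ndarray  # (2, 2) integer, |det| = 1
    offsets: np.ndarray  # (2,)

    def apply(self, angles: np.ndarray) -> np.ndarray:
        return (angles @ self.matrix.T + self.offsets) % (2 * np.pi)

    def inverse(self) -> "TorusTransform":
        Minv = np.round(np.linalg.inv(self.matrix)).astype(int)
        return TorusTransform(Minv, (-Minv @ self.offsets) % (2 * np.pi))

    def compose(self, other: "TorusTransform") -> "TorusTransform":
        """Transform equivalent to applying ``other`` first, then self."""
        return TorusTransform(
            self.matrix @ other.matrix,
            (self.matrix @ other.offsets + self.offsets) % (2 * np.pi),
        )


@dataclass
class TrialPath:
    trial_id: int
    path: np.ndarray  # unwrapped (n, 2) within the trial
    fit_r: Tuple[float, float]
    length: Optional[float]  # normalized; None when excluded by the r rule
    included: bool


def hex_basis_changes() -> List[np.ndarray]:
    """Unimodular 2x2 integer matrices with rows drawn from the hexagonal
    axis set {+-(1,0), +-(0,1), +-(1,1), +-(1,-1)} and |det| = 1: the
    orientation flips and 60/120-degree axis substitutions of the torus."""
    rows = [
        (1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1), (1, -1), (-1, 1),
    ]
    out = []
    seen = set()
    for r1 in rows:
        for r2 in rows:
            M = np.array([r1, r2])
            if abs(round(np.linalg.det(M))) == 1 and M.tobytes() not in seen:
                seen.add(M.tobytes())
                out.append(M)
    return out


def _circ_smooth(angles: np.ndarray, sigma_samples: float) -> np.ndarray:
    """Gaussian smoothing on the circle (via unit phasors)."""
    if sigma_samples <= 0:
        return angles
    z = np.exp(1j * angles)
    zs = gaussian_filter1d(z.real, sigma_samples, axis=0) + 1j * gaussian_filter1d(
        z.imag, sigma_samples, axis=0
    )
    return np.angle(zs) % (2 * np.pi)


def align_tori(
    coords_a: ToroidalCoordinates,
    coords_b: ToroidalCoordinates,
    smooth_s: float = 0.2,
    dt: Optional[float] = None,
) -> TorusTransform:
    """Best transform mapping ``coords_a`` onto ``coords_b``.

    Candidates are enumerated over the hexagonal-axis unimodular matrices;
    for each, both series are smoothed with a 200 ms circular Gaussian, the
    per-axis offset is the circular mean of the residual, and the mean
    circular difference (1 - cos) decides.  Only overlapping valid samples
    are compared.
    """
    keep = coords_a.valid & coords_b.valid
    if not np.any(keep):
        raise ValueError("no overlapping valid samples")
    if dt is None:
        if coords_a.times is not None and len(coords_a.times) > 1:
            dt = float(np.median(np.diff(coords_a.times)))
        else:
            dt = 1.0
    sig = smooth_s / dt
    A = _circ_smooth(coords_a.angles, sig)[keep]
    B = _circ_smooth(coords_b.angles, sig)[keep]
    best = None
    for M in hex_basis_changes():
        cand = (A @ M.T) % (2 * np.pi)
        offs = np.angle(np.exp(1j * (B - cand)).mean(axis=0))
        err = float(np.mean(1 - np.cos(B - cand - offs)))
        if best is None or err < best[0]:
            best = (err, M, offs % (2 * np.pi))
    _, M, offs = best
    return TorusTransform(matrix=M, offsets=offs)


def toroidal_phase_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Flat-metric distances between phase tuples with per-axis wrap."""
    d = (np.asarray(a) - np.asarray(b) + np.pi) % (2 * np.pi) - np.pi
    return np.sqrt((d**2).sum(axis=-1))


def phase_distance_test(
    phases_a: np.ndarray,
    phases_b: np.ndarray,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Conservation of per-neuron toroidal phases across sessions.

    Returns the mean toroidal phase distance between matched neurons and a
    one-sided permutation P-value: the null permutes neuron identities in
    session b; P = (1 + #{null <= observed}) / (n_shuffles + 1).
    """
    phases_a = np.asarray(phases_a, dtype=float)
    phases_b = np.asarray(phases_b, dtype=float)
    if phases_a.shape != phases_b.shape or phases_a.ndim != 2:
        raise ValueError("phase lists must be matched (n, 2) arrays")
    n = phases_a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 neurons")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    obs = float(toroidal_phase_distance(phases_a, phases_b).mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(n)
        null = float(toroidal_phase_distance(phases_a, phases_b[perm]).mean())
        if null <= obs:
            count += 1
    return obs, (1 + count) / (n_shuffles + 1)


def unwrap_torus(
    coords: ToroidalCoordinates,
    smooth_s: float = 0.2,
    dt: Optional[float] = None,
) -> List[np.ndarray]:
    """Unwrap toroidal coordinates onto the flat plane.

    After 200 ms circular smoothing, each step tests the four combinations
    of 0/1 crossings of the two circular origins and keeps the continuation
    closest (Euclidean) to the previous point — equivalently the minimal
    wrapped representative per axis.  Masked samples split the path into
    separately unwrapped segments.
    """
    if dt is None:
        if coords.times is not None and len(coords.times) > 1:
            dt = float(np.median(np.diff(coords.times)))
        else:
            dt = 1.0
    ang = _circ_smooth(coords.angles, smooth_s / dt if smooth_s else 0)
    segments = []
    T = ang.shape[0]
    i = 0
    while i < T:
        if not coords.valid[i]:
            i += 1
            continue
        j = i
        while j < T and coords.valid[j]:
            j += 1
        seg = ang[i:j].copy()
        d = np.diff(seg, axis=0)
        d = (d + np.pi) % (2 * np.pi) - np.pi  # closest continuation
        segments.append(np.vstack([seg[0], seg[0] + np.cumsum(d, axis=0)]))
        i = j
    return segments


def trial_path_length(
    path: np.ndarray,
    trial_id: int = 0,
    baseline_mean: float = 1.0,
    r_threshold: float = 0.5,
) -> TrialPath:
    """Length of one trial's toroidal trajectory.

    Each axis is regressed linearly against time; the trial is included
    only when |r| exceeds ``r_threshold`` on both axes, and its length is
    the Euclidean distance between the fitted endpoints divided by
    ``baseline_mean``.
    """
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[1] != 2:
        raise ValueError("path must be (n, 2)")
    n = path.shape[0]
    if n < 3:
        return TrialPath(trial_id, path, (0.0, 0.0), None, False)
    t = np.arange(n, dtype=float)
    rs = []
    ends = []
    for a in range(2):
        y = path[:, a]
        if y.std() == 0:
            rs.append(0.0)
            ends.append((y[0], y[-1]))
            continue
        slope, intercept = np.polyfit(t, y, 1)
        rs.append(float(pearsonr(t, y)[0]))
        ends.append((intercept, intercept + slope * (n - 1)))
    included = all(abs(r) > r_threshold for r in rs)
    length = None
    if included:
        d0 = ends[0][1] - ends[0][0]
        d1 = ends[1][1] - ends[1][0]
        length = float(np.hypot(d0, d1) / baseline_mean)
    return TrialPath(trial_id, path, (rs[0], rs[1]), length, included)
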