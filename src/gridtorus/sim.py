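"""Continuous-attractor-network simulators and trajectory generators.

Three noiseless grid-cell CAN models provide synthetic modules with known
toroidal structure for every downstream stage:

* an inhibitory-sheet network (purely inhibitory ring-of-discs connectivity
  with shifted outputs per preferred direction, rectified-linear relaxation
  dynamics) producing hexagonal firing patterns;
* a twisted-torus network (Gaussian excitation minus a constant tail on the
  twisted torus, divisive normalization) whose bump lives on a hexagonal
  torus;
* an untwisted (square-torus) variant of the same dynamics producing square
  lattice patterns.

Connectivity in all models depends only on the difference of sheet
coordinates, so the recurrent input is evaluated as an FFT circular
correlation over the sheet; a dense-weight code path is kept for
cross-checking and for non-integer direction offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.interpolate import interp1d

from .preprocess import RateMatrix

__all__ = [
    "TrajectorySample",
    "CANConfig",
    "SimOutput",
    "random_walk_trajectory",
    "constant_speed_trajectory",
    "simulate_inhibitory_sheet",
    "simulate_twisted_torus",
    "simulate_square_torus",
    "bump_phase",
]

SQRT3_2 = np.sqrt(3.0) / 2.0


@dataclass
class TrajectorySample:
    """A sampled 2-D path: time (s), position (cm), speed (cm/s), heading (rad).

    Speed and heading are derived from position differences, so they are
    consistent with the path by construction.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    speed: np.ndarray
    heading: np.ndarray

    def __post_init__(self):
        for name in ("t", "x", "y", "speed", "heading"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time must be strictly increasing")
        n = self.t.size
        if any(getattr(self, f).size != n for f in ("x", "y", "speed", "heading")):
            raise ValueError("all fields must have equal length")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    @classmethod
    def from_positions(cls, t, x, y) -> "TrajectorySample":
        """Fill speed and heading from position differences (forward)."""
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        dx, dy, dtv = np.diff(x), np.diff(y), np.diff(t)
        sp = np.hypot(dx, dy) / dtv
        hd = np.arctan2(dy, dx)
        speed = np.append(sp, sp[-1] if sp.size else 0.0)
        heading = np.append(hd, hd[-1] if hd.size else 0.0)
        # hold heading through standstills (arctan2(0,0) is meaningless)
        still = np.append(sp == 0, False) if sp.size else np.zeros(t.size, bool)
        for i in np.where(still)[0]:
            if i > 0:
                heading[i] = heading[i - 1]
        return cls(t, x, y, speed, heading)

    def resample(self, dt: float) -> "TrajectorySample":
        """Linear interpolation of the path on a uniform grid of step dt."""
        tt = self.t[0] + np.arange(int(np.floor((self.t[-1] - self.t[0]) / dt)) + 1) * dt
        fx = interp1d(self.t, self.x)
        fy = interp1d(self.t, self.y)
        return TrajectorySample.from_positions(tt, fx(tt), fy(tt))


def random_walk_trajectory(
    duration: float,
    arena: float = 150.0,
    dt: float = 0.01,
    speed_mean: float = 15.0,
    speed_sd: float = 5.0,
    turn_sd: float = 0.6,
    seed: int = 0,
) -> TrajectorySample:
    """Smooth random foraging walk in a square box with reflecting walls.

    Heading diffuses (standard deviation ``turn_sd * sqrt(dt)`` rad per
    step); speed follows a clipped AR(1) around ``speed_mean`` cm/s.  Wall
    hits reflect the heading so the speed distribution is unaffected.
    """
    if duration <= 0 or arena <= 0:
        raise ValueError("duration and arena must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    x[0] = y[0] = arena / 2.0
    phi = rng.uniform(0, 2 * np.pi)
    sp = speed_mean
    for i in range(1, n):
        phi += turn_sd * np.sqrt(dt) * rng.standard_normal()
        sp += 0.5 * (speed_mean - sp) * dt + speed_sd * np.sqrt(dt) * rng.standard_normal()
        sp = max(sp, 0.0) if speed_mean > 0 else 0.0
        nx = x[i - 1] + sp * dt * np.cos(phi)
        ny = y[i - 1] + sp * dt * np.sin(phi)
        if nx < 0 or nx > arena:
            phi = np.pi - phi
            nx = np.clip(nx, 0, arena)
        if ny < 0 or ny > arena:
            phi = -phi
            ny = np.clip(ny, 0, arena)
        x[i], y[i] = nx, ny
    return TrajectorySample.from_positions(t, x, y)


def constant_speed_trajectory(
    duration: float, speed: float, heading: float = 0.0, dt: float = 0.01
) -> TrajectorySample:
    """Straight unbounded run; useful for wheel-like 1-D drive and for
    path-integration checks."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    x = speed * t * np.cos(heading)
    y = speed * t * np.sin(heading)
    return TrajectorySample.from_positions(t, x, y)


@dataclass
class CANConfig:
    """Parameters of the attractor models.

    ``model`` selects the dynamics; the inhibitory sheet uses (J, gamma, l,
    R, W0, rho_relax), the torus models use (intensity, tail, sigma_w,
    tau_norm, grid_gain).  ``dt`` is the integration step; output rates are
    resampled at ``resample_dt``.  Constants of the torus models are not
    uniquely fixed by the source model description; the published defaults
    of that model family are used and all are exposed here.
    """

    model: str = "twisted_torus"
    shape: Tuple[int, int] = None  # (rows, cols) of the sheet
    J: float = 1.0  # excitatory drive (inhibitory sheet)
    gamma: float = 0.15  # velocity gain (inhibitory sheet, per m/s)
    speed_scale: float = 0.01  # converts trajectory speed (cm/s) to m/s
    l: float = 2.0  # preferred-direction output offset (sheet units)
    R: float = 20.0  # connectivity radius (sheet units)
    W0: float = -0.01  # inhibitory weight
    rho_relax: float = 10.0  # relaxation constant
    grid_gain: float = 0.06  # velocity gain (torus models, per cm)
    intensity: float = 0.3  # Gaussian weight amplitude (torus models)
    tail: float = 0.05  # constant inhibitory tail (torus models)
    sigma_w: float = 0.24  # Gaussian weight width (torus models)
    tau_norm: float = 1.0  # divisive-normalization mixing (torus models)
    sharpen: float = 2.0  # transfer exponent before normalization (torus models)
    dt: float = 0.002  # integration step (s)
    resample_dt: float = 0.01  # output sample step (s)
    stabilization_steps: int = 2000
    rate_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("inhibitory_sheet", "twisted_torus", "square_torus"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.shape is None:
            self.shape = {
                "inhibitory_sheet": (44, 56),
                "twisted_torus": (20, 20),
                "square_torus": (10, 10),
            }[self.model]
        if self.rho_relax <= 0:
            raise ValueError("rho_relax must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.rate_floor < 0:
            raise ValueError("rate_floor must be nonnegative")


@dataclass
class SimOutput:
    """Simulated module: rates, nominal unit phases on the sheet, the
    driving trajectory and the tracked bump phase (ground truth)."""

    rates: RateMatrix
    unit_phases: np.ndarray  # (N, 2) in [0, 1)^2
    trajectory: TrajectorySample
    bump_phases: np.ndarray = None  # (T, 2) in [0, 2pi)


def _check_rates(f: np.ndarray):
    if not np.all(np.isfinite(f)):
        raise ArithmeticError(
            "non-finite rates during CAN integration: unstable parameters "
            "(reduce gamma/grid_gain or increase rho_relax/tau_norm)"
        )


# ------------------------------------------------------------ inhibitory sheet


def sheet_weight_matrix(cfg: CANConfig) -> np.ndarray:
    """Dense W for the inhibitory sheet: W[i, j] = W0 when unit j lies in the
    R-disc centered at unit i's location shifted by l along i's own
    preferred direction (each cell inhibits a disc offset along its
    preferred direction; this presynaptic offset is what makes the pattern
    translate coherently with velocity).  Kept as the reference
    implementation and for non-integer l."""
    rows, cols = cfg.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pos = np.c_[cc.ravel(), rr.ravel()].astype(float)  # (N, 2) as (x, y)
    dirs = _preferred_directions(rows, cols)
    shifted = pos + cfg.l * np.c_[np.cos(dirs), np.sin(dirs)]  # x_i + l e_i
    dx = np.abs(shifted[:, None, 0] - pos[None, :, 0])
    dy = np.abs(shifted[:, None, 1] - pos[None, :, 1])
    dx = np.minimum(dx, cols - dx)
    dy = np.minimum(dy, rows - dy)
    return np.where(np.hypot(dx, dy) <= cfg.R, cfg.W0, 0.0)


def _preferred_directions(rows: int, cols: int) -> np.ndarray:
    """Preferred directions tiled in 2x2 blocks (E, N / W, S), radians."""
    ang = np.empty((rows, cols))
    ang[0::2, 0::2] = 0.0  # E
    ang[0::2, 1::2] = np.pi / 2  # N
    ang[1::2, 0::2] = np.pi  # W
    ang[1::2, 1::2] = -np.pi / 2  # S
    return ang.ravel()


def _disc_kernel(rows: int, cols: int, R: float) -> np.ndarray:
    dr = np.minimum(np.arange(rows), rows - np.arange(rows))
    dc = np.minimum(np.arange(cols), cols - np.arange(cols))
    return (np.hypot(dr[:, None], dc[None, :]) <= R).astype(float)


def simulate_inhibitory_sheet(cfg: CANConfig, traj: TrajectorySample) -> SimOutput:
    """Rectified-linear relaxation dynamics on the inhibitory sheet.

    f <- f + (1/rho) (-f + [J + f.W + gamma * s * cos(phi - phi_pref)]_+),
    integrated at cfg.dt after interpolating the trajectory, initialized at
    random and stabilized with `stabilization_steps` zero-movement updates;
    rates below `rate_floor` are zeroed; output is resampled at
    `resample_dt`.
    """
    if cfg.model != "inhibitory_sheet":
        raise ValueError("config.model must be 'inhibitory_sheet'")
    rows, cols = cfg.shape
    N = rows * cols
    tr = traj.resample(cfg.dt)
    dirs = _preferred_directions(rows, cols)
    rng = np.random.default_rng(cfg.seed)
    f = rng.uniform(0, 1, N)

    use_fft = float(cfg.l).is_integer()
    if use_fft:
        kern = np.fft.rfft2(_disc_kernel(rows, cols, cfg.R))
        li = int(cfg.l)
        shifts = {0.0: (0, li), np.pi / 2: (li, 0), np.pi: (0, -li), -np.pi / 2: (-li, 0)}
        groups = [((dirs == a).reshape(rows, cols), shifts[a]) for a in shifts]

        def recurrent(fv):
            # sum over presynaptic direction groups of (group rates * disc)
            # recentered at x_i + l e_i
            fgrid = fv.reshape(rows, cols)
            out = np.zeros((rows, cols))
            for mask, (sr, sc) in groups:
                g = np.fft.irfft2(np.fft.rfft2(np.where(mask, fgrid, 0.0)) * kern, s=(rows, cols))
                out += np.roll(g, (sr, sc), axis=(0, 1))
            return cfg.W0 * out.ravel()
    else:  # dense fallback
        W = sheet_weight_matrix(cfg)

        def recurrent(fv):
            return fv @ W

    inv_rho = 1.0 / cfg.rho_relax

    def step(fv, drive):
        upd = np.maximum(cfg.J + recurrent(fv) + drive, 0.0)
        fv = fv + inv_rho * (-fv + upd)
        fv[fv < cfg.rate_floor] = 0.0
        return fv

    for _ in range(cfg.stabilization_steps):
        f = step(f, 0.0)
    _check_rates(f)

    keep = max(int(round(cfg.resample_dt / cfg.dt)), 1)
    out = np.empty((N, len(tr.t[::keep])))
    k = 0
    for i in range(tr.t.size):
        drive = cfg.gamma * cfg.speed_scale * tr.speed[i] * np.cos(tr.heading[i] - dirs)
        f = step(f, drive)
        if i % keep == 0:
            out[:, k] = f
            k += 1
    _check_rates(out)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    phases = np.c_[cc.ravel() / cols, rr.ravel() / rows]
    rates = RateMatrix(out[:, :k], dt=cfg.dt * keep, times=tr.t[::keep][:k])
    return SimOutput(rates=rates, unit_phases=phases, trajectory=tr)


# ------------------------------------------------------------- torus models


def _torus_basis(cfg: CANConfig) -> np.ndarray:
    """Columns are the lattice generators: the sheet is R^2 / (Z a1 + Z a2).

    The twisted torus identifies the top edge with a half-period horizontal
    shift (a2 = (1/2, sqrt(3)/2)); the square variant uses the unit square
    lattice.  Units live on a regular grid in the lattice-basis (q)
    coordinates, so connectivity is stationary on the rectangular q-torus
    and the recurrent input is an FFT circular correlation.
    """
    a1 = np.array([1.0, 0.0])
    a2 = np.array([0.5, SQRT3_2]) if cfg.model == "twisted_torus" else np.array([0.0, 1.0])
    return np.c_[a1, a2]


def torus_weight_kernel(cfg: CANConfig, v: np.ndarray) -> np.ndarray:
    """Connectivity kernel on the (rows, cols) q-difference grid for a
    physical velocity shift ``v`` (already scaled by grid_gain): Gaussian of
    the minimal flat-torus distance minus the constant inhibitory tail."""
    rows, cols = cfg.shape
    B = _torus_basis(cfg)
    dqv = np.linalg.solve(B, np.asarray(v, dtype=float))
    dq1 = np.arange(cols) / cols - dqv[0]
    dq2 = np.arange(rows) / rows - dqv[1]
    U1 = dq1[None, :]
    U2 = dq2[:, None]
    d2 = np.full((rows, cols), np.inf)
    for a in (-2, -1, 0, 1, 2):
        for b in (-2, -1, 0, 1, 2):
            px = (U1 + a) * B[0, 0] + (U2 + b) * B[0, 1]
            py = (U1 + a) * B[1, 0] + (U2 + b) * B[1, 1]
            d2 = np.minimum(d2, px**2 + py**2)
    return cfg.intensity * np.exp(-d2 / cfg.sigma_w**2) - cfg.tail


def unit_phase_grid(cfg: CANConfig) -> np.ndarray:
    """Per-unit torus phases in [0, 1)^2: the lattice-basis (q) coordinates
    of each unit, genuine circle coordinates of the sheet for both the
    twisted and the square torus."""
    rows, cols = cfg.shape
    q1 = (np.arange(cols) + 0.5) / cols
    q2 = (np.arange(rows) + 0.5) / rows
    Q1, Q2 = np.meshgrid(q1, q2)
    return np.c_[Q1.ravel(), Q2.ravel()]


def _simulate_torus(cfg: CANConfig, traj: TrajectorySample) -> SimOutput:
    rows, cols = cfg.shape
    N = rows * cols
    B = _torus_basis(cfg)
    rng = np.random.default_rng(cfg.seed)

    # seed a single bump at a random center (the deterministic dynamics
    # conserve bump number, and a symmetric multi-bump state would never
    # resolve without noise)
    qc = rng.uniform(0, 1, 2)
    A = np.maximum(torus_weight_kernel(cfg, B @ qc), 0)
    A = A / max(A.mean(), 1e-12)

    dx = np.append(np.diff(traj.x), 0.0) * cfg.grid_gain
    dy = np.append(np.diff(traj.y), 0.0) * cfg.grid_gain
    q = cfg.sharpen
    tau = cfg.tau_norm

    def step(A, v):
        K = torus_weight_kernel(cfg, v)
        # B[c_j] = sum_i A[c_i] K[c_i - c_j]: circular cross-correlation
        B = np.fft.irfft2(np.fft.rfft2(A) * np.conj(np.fft.rfft2(K)), s=(rows, cols))
        B = np.maximum(B, 0.0)
        Bq = B**q
        mean = Bq.mean()
        if not np.isfinite(mean) or mean <= 0:
            raise ArithmeticError("population activity collapsed or diverged")
        return (1 - tau) * B + tau * (Bq / mean)

    zero = np.zeros(2)
    for _ in range(cfg.stabilization_steps):
        A = step(A, zero)
    _check_rates(A)

    phases_grid = unit_phase_grid(cfg)
    T = traj.t.size
    out = np.empty((N, T))
    phases = np.empty((T, 2))
    for i in range(T):
        A = step(A, np.array([dx[i], dy[i]]))
        out[:, i] = A.ravel()
        phases[i] = bump_phase(out[:, i], phases_grid)
    _check_rates(out)
    rates = RateMatrix(out, dt=traj.dt, times=traj.t)
    return SimOutput(
        rates=rates,
        unit_phases=phases_grid,
        trajectory=traj,
        bump_phases=phases,
    )


def bump_phase(activity: np.ndarray, unit_phases: np.ndarray) -> np.ndarray:
    """Population-vector phase of the activity bump, per torus axis, in
    [0, 2pi)."""
    out = np.empty(2)
    for a in range(2):
        ang = 2 * np.pi * unit_phases[:, a]
        out[a] = np.arctan2(
            (activity * np.sin(ang)).sum(), (activity * np.cos(ang)).sum()
        ) % (2 * np.pi)
    return out


def simulate_twisted_torus(cfg: CANConfig, traj: TrajectorySample) -> SimOutput:
    """Divisive-normalization attractor on the twisted torus (hexagonal
    grid patterns)."""
    if cfg.model != "twisted_torus":
        raise ValueError("config.model must be 'twisted_torus'")
    return _simulate_torus(cfg, traj)


def simulate_square_torus(cfg: CANConfig, traj: TrajectorySample) -> SimOutput:
    """Untwisted variant of the torus attractor (square grid patterns)."""
    if cfg.model != "square_torus":
        raise ValueError("config.model must be 'square_torus'")
    return _simulate_torus(cfg, traj)
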