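"""Trajectory generators and the three attractor models."""

import dataclasses

import numpy as np
import pytest

import gridtorus as gt
from gridtorus.sim import (
    CANConfig,
    TrajectorySample,
    _disc_kernel,
    _preferred_directions,
    sheet_weight_matrix,
)

SQRT3 = np.sqrt(3.0)


# ----------------------------------------------------------- trajectories


def test_walk_sample_count_and_determinism():
    t1 = gt.random_walk_trajectory(100.0, dt=0.02, seed=5)
    assert t1.t.size == 5000
    t2 = gt.random_walk_trajectory(100.0, dt=0.02, seed=5)
    assert np.array_equal(t1.x, t2.x) and np.array_equal(t1.y, t2.y)
    t3 = gt.random_walk_trajectory(100.0, dt=0.02, seed=6)
    assert not np.array_equal(t1.x, t3.x)


def test_zero_speed_walk_is_static():
    t = gt.random_walk_trajectory(10.0, speed_mean=0.0, speed_sd=0.0, seed=0)
    assert np.all(t.x == t.x[0]) and np.all(t.y == t.y[0])
    assert np.all(t.speed == 0)


def test_walk_stays_in_arena_and_kinematics_consistent():
    t = gt.random_walk_trajectory(60.0, arena=50.0, speed_mean=40.0, seed=1)
    assert t.x.min() >= 0 and t.x.max() <= 50 and t.y.min() >= 0 and t.y.max() <= 50
    # speed equals displacement over dt; heading matches the displacement
    d = np.hypot(np.diff(t.x), np.diff(t.y)) / np.diff(t.t)
    assert np.allclose(t.speed[:-1], d, atol=1e-9)
    hd = np.arctan2(np.diff(t.y), np.diff(t.x))
    moving = d > 0
    assert np.allclose(
        np.angle(np.exp(1j * (t.heading[:-1][moving] - hd[moving]))), 0, atol=1e-9
    )


def test_walk_rejects_bad_args():
    with pytest.raises(ValueError):
        gt.random_walk_trajectory(0.0)
    with pytest.raises(ValueError):
        gt.random_walk_trajectory(10.0, arena=-1.0)


# ----------------------------------------------------------- torus models


@pytest.mark.parametrize("model,shape", [("twisted_torus", (20, 20)), ("square_torus", (10, 10))])
def test_torus_models_path_integrate(model, shape):
    """Integrated bump displacement is proportional to integrated
    trajectory displacement (r > 0.95 on a noiseless straight run)."""
    cfg = CANConfig(model=model, shape=shape, seed=3, stabilization_steps=400)
    sim = {"twisted_torus": gt.simulate_twisted_torus, "square_torus": gt.simulate_square_torus}[model]
    traj = gt.constant_speed_trajectory(3.0, speed=15.0, heading=0.3, dt=0.01)
    out = sim(cfg, traj)
    ph = np.unwrap(out.bump_phases, axis=0)
    disp = np.hypot(traj.x - traj.x[0], traj.y - traj.y[0])
    for a in range(2):
        r = np.corrcoef(ph[:, a] - ph[0, a], disp)[0, 1]
        assert abs(r) > 0.95
    # and the integration gain matches grid_gain through the lattice basis
    B = np.c_[[1.0, 0.0], [0.5, SQRT3 / 2]] if model == "twisted_torus" else np.eye(2)
    expect = -2 * np.pi * cfg.grid_gain * np.linalg.solve(
        B, [traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0]]
    )
    got = ph[-1] - ph[0]
    assert np.allclose(got, expect, rtol=0.03, atol=0.15)


def test_torus_model_deterministic_and_unit_phases_even():
    cfg = CANConfig(model="twisted_torus", seed=7, stabilization_steps=100)
    traj = gt.constant_speed_trajectory(0.5, speed=10.0, dt=0.01)
    o1 = gt.simulate_twisted_torus(cfg, traj)
    o2 = gt.simulate_twisted_torus(cfg, traj)
    assert np.array_equal(o1.rates.values, o2.rates.values)
    # unit phases form an even lattice covering [0,1)^2
    ph = o1.unit_phases
    assert ph.shape == (400, 2)
    for a in range(2):
        assert np.allclose(np.sort(np.unique(ph[:, a])), (np.arange(20) + 0.5) / 20)


def test_torus_model_rates_nonnegative_and_finite(twisted_module):
    v = twisted_module.rates.values
    assert np.all(v >= 0) and np.all(np.isfinite(v))


def test_torus_model_rejects_wrong_model_tag():
    with pytest.raises(ValueError):
        gt.simulate_twisted_torus(
            CANConfig(model="square_torus"), gt.constant_speed_trajectory(0.1, 1.0)
        )


# ------------------------------------------------------- inhibitory sheet


def _static_traj(duration=1.0, dt=0.002):
    n = int(duration / dt)
    return TrajectorySample.from_positions(
        np.arange(n) * dt, np.full(n, 10.0), np.full(n, 10.0)
    )


def test_sheet_zero_speed_fixed_point():
    """After stabilization the zero-velocity state is a fixed point: the
    per-step change is below 1e-6."""
    cfg = CANConfig(model="inhibitory_sheet", seed=1, stabilization_steps=12000)
    out = gt.simulate_inhibitory_sheet(cfg, _static_traj())
    v = out.rates.values
    steps_per_sample = round(0.01 / cfg.dt)
    per_step = np.abs(np.diff(v[:, -20:], axis=1)).max() / steps_per_sample
    assert per_step < 1e-6
    assert np.all(v >= 0)


def test_sheet_gamma_zero_equals_zero_speed_drift():
    """With gamma = 0 a moving trajectory produces the same activity as a
    static one (velocity input disabled)."""
    cfg = dataclasses.replace(
        CANConfig(model="inhibitory_sheet", seed=2), gamma=0.0, stabilization_steps=500
    )
    moving = gt.constant_speed_trajectory(0.5, speed=30.0, dt=0.002)
    static = _static_traj(0.5)
    o1 = gt.simulate_inhibitory_sheet(cfg, moving)
    o2 = gt.simulate_inhibitory_sheet(cfg, static)
    assert np.allclose(o1.rates.values, o2.rates.values)


def test_sheet_fft_recurrent_equals_dense_weight_matrix():
    """One application of the FFT recurrent path equals f.W with the dense
    matrix (the FFT path is an exact evaluation, not an approximation)."""
    cfg = CANConfig(model="inhibitory_sheet", shape=(12, 16), R=4.0, l=2.0)
    rows, cols = cfg.shape
    rng = np.random.default_rng(0)
    f = rng.random(rows * cols)
    W = sheet_weight_matrix(cfg)
    dense = f @ W
    kern = np.fft.rfft2(_disc_kernel(rows, cols, cfg.R))
    dirs = _preferred_directions(rows, cols)
    li = int(cfg.l)
    shifts = {0.0: (0, li), np.pi / 2: (li, 0), np.pi: (0, -li), -np.pi / 2: (-li, 0)}
    out = np.zeros((rows, cols))
    for a, (sr, sc) in shifts.items():
        fd = np.where((dirs == a).reshape(rows, cols), f.reshape(rows, cols), 0.0)
        g = np.fft.irfft2(np.fft.rfft2(fd) * kern, s=(rows, cols))
        out += np.roll(g, (sr, sc), axis=(0, 1))
    assert np.allclose(cfg.W0 * out.ravel(), dense, atol=1e-10)


def test_sheet_pattern_translates_proportionally_to_speed():
    """On straight runs the pattern's Fourier phase advances linearly with
    running speed."""
    cfg = CANConfig(model="inhibitory_sheet", seed=1)
    vels = []
    for sp in (10.0, 20.0):
        traj = gt.constant_speed_trajectory(1.5, speed=sp, heading=0.0, dt=0.002)
        out = gt.simulate_inhibitory_sheet(cfg, traj)
        A = out.rates.values
        rows, cols = cfg.shape
        F0 = A[:, 0].reshape(rows, cols)
        S = np.abs(np.fft.fft2(F0))
        S[0, 0] = 0
        k = np.unravel_index(np.argmax(S), S.shape)
        ph = np.unwrap(
            [np.angle(np.fft.fft2(A[:, i].reshape(rows, cols))[k]) for i in range(A.shape[1])]
        )
        vels.append((ph[-1] - ph[0]) / ((A.shape[1] - 1) * 0.01))
    assert vels[1] / vels[0] == pytest.approx(2.0, rel=0.15)


def test_sheet_rejects_wrong_model_and_detects_nan():
    with pytest.raises(ValueError):
        gt.simulate_inhibitory_sheet(
            CANConfig(model="twisted_torus"), _static_traj(0.1)
        )
    bad = dataclasses.replace(
        CANConfig(model="inhibitory_sheet", shape=(12, 16), R=4.0, seed=0),
        W0=1.0,  # runaway positive feedback
        stabilization_steps=800,
    )
    with pytest.raises(ArithmeticError):
        gt.simulate_inhibitory_sheet(bad, _static_traj(0.1))


def test_config_validation():
    with pytest.raises(ValueError):
        CANConfig(model="nope")
    with pytest.raises(ValueError):
        CANConfig(rho_relax=0.0)
    with pytest.raises(ValueError):
        CANConfig(dt=-1.0)
    with pytest.raises(ValueError):
        CANConfig(rate_floor=-1.0)
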