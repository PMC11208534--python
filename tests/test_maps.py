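"""Spatial/toroidal rate maps, autocorrelograms, peaks and tuning curves."""

import numpy as np
import pytest

import gridtorus as gt
from gridtorus.coordinatize import ToroidalCoordinates
from gridtorus.maps import _frac_roll, _wrapped_dist


def test_spatial_ratemap_uniform_activity_is_flat():
    rng = np.random.default_rng(0)
    pos = rng.uniform(0, 100, (5000, 2))
    m = gt.spatial_ratemap(np.ones(5000), pos, arena=100.0)
    assert np.allclose(m.values, 1.0, atol=1e-9)


def test_spatial_ratemap_single_hot_bin_smoothed_peak():
    pos = np.tile([[55.0, 25.0]], (50, 1))
    filler = np.c_[np.linspace(0, 99, 200), np.linspace(0, 99, 200)]
    act = np.r_[np.ones(50), np.zeros(200)]
    m = gt.spatial_ratemap(act, np.vstack([pos, filler]), arena=100.0)
    iy, ix = np.unravel_index(np.argmax(m.values), m.values.shape)
    assert (ix, iy) == (16, 7)  # bin of (55, 25) at 30 bins
    assert m.values.max() < 1.0  # smoothing spread the peak


def test_spatial_ratemap_unvisited_bins_get_visited_mean():
    # occupy only the left half with activity 2; unvisited right half must
    # be filled with the visited mean before smoothing
    rng = np.random.default_rng(1)
    pos = np.c_[rng.uniform(0, 49, 4000), rng.uniform(0, 99, 4000)]
    m = gt.spatial_ratemap(2 * np.ones(4000), pos, arena=100.0, sigma_bins=0.0)
    assert np.allclose(m.values, 2.0)


def test_spatial_ratemap_rejects_empty():
    with pytest.raises(ValueError):
        gt.spatial_ratemap(np.array([]), np.empty((0, 2)), arena=100.0)


def test_autocorr_periodic_tuning_peaks_at_period():
    """Tuning with a 20-bin period gives local maxima at shifts 0, 20, 40."""
    pos = np.tile(np.arange(0.5, 100.5, 1.0), 30)  # 1 cm bins, uniform
    act = 1 + np.cos(2 * np.pi * pos / 20.0)
    ac = gt.autocorr_1d(act, pos, bin_cm=1.0, max_shift=60)
    v = ac.values
    for s in (20, 40):
        assert v[s] > v[s - 5] and v[s] > v[s + 5]
    assert np.argmax(v) == 0


def test_autocorr_constant_tuning_declines_linearly():
    pos = np.arange(0.5, 50.5, 1.0)
    ac = gt.autocorr_1d(np.ones_like(pos), pos, bin_cm=1.0, max_shift=49)
    nb = 50
    expect = np.array([nb - s for s in range(50)], dtype=float)
    assert np.allclose(ac.values, expect)


def test_autocorr_single_bin_only_zero_shift():
    pos = np.full(10, 3.2)
    ac = gt.autocorr_1d(np.ones(10), pos, bin_cm=1.0, max_shift=5)
    assert ac.values[0] > 0 and np.all(ac.values[1:] == 0)


def test_autocorr_rejects_bad_inputs():
    with pytest.raises(ValueError):
        gt.autocorr_1d(np.ones(5), np.full(5, 1.0), bin_cm=0.0)
    with pytest.raises(ValueError):
        gt.autocorr_1d(np.array([]), np.array([]), bin_cm=1.0)


def _impulse_coords(theta, n=4000, seed=0):
    rng = np.random.default_rng(seed)
    ang = rng.uniform(0, 2 * np.pi, (n, 2))
    act = np.zeros(n)
    d = _wrapped_dist(ang, np.array([theta]))[:, 0]
    act[d < 0.3] = 1.0
    return act, ToroidalCoordinates(angles=ang)


def test_toroidal_ratemap_impulse_at_origin():
    act, co = _impulse_coords((0.1, 0.1))
    m = gt.toroidal_ratemap(act, co)
    iy, ix = np.unravel_index(np.argmax(m.values), m.values.shape)
    assert iy == 0  # theta2 ~ 0.1 rad -> first row
    assert ix in (0, 29)


def test_toroidal_ratemap_periodic_equivariance():
    """Shifting all angles by whole bins translates the map."""
    act, co = _impulse_coords((1.0, 2.0), seed=1)
    m0 = gt.toroidal_ratemap(act, co, hexagonal=False)
    delta = 2 * np.pi / 30 * 6  # six bins
    co2 = ToroidalCoordinates(angles=(co.angles + delta) % (2 * np.pi))
    m1 = gt.toroidal_ratemap(act, co2, hexagonal=False)
    assert np.allclose(np.roll(np.roll(m0.values, 6, 0), 6, 1), m1.values, atol=0.05)


def test_toroidal_ratemap_single_convex_field_on_sim(twisted_decoded):
    """A simulated twisted-torus unit has one convex toroidal field: the
    smoothed map has a single connected super-threshold region."""
    from scipy.ndimage import label

    rates = twisted_decoded["rates"]
    co = twisted_decoded["coords_all"]
    m = gt.toroidal_ratemap(rates.values[37] ** 2, co)
    v = m.values
    lab, n = label((v > 0.5 * v.max()).astype(int))
    # merge wrap-around components
    from scipy.ndimage import label as _label

    big = np.tile(v > 0.5 * v.max(), (2, 2))
    lab2, n2 = _label(big)
    sizes = np.bincount(lab2.ravel())[1:]
    assert (sizes >= sizes.max() * 0.99).sum() <= 4  # one field and its wraps


def test_toroidal_peak_examples():
    m = np.zeros((16, 16))
    m[0, 4] = 1.0  # theta1 bin 4 of 16 -> (4.5/16)*360 = 101.25 deg
    pk = gt.toroidal_peak(m)
    assert np.degrees(pk.theta[0]) == pytest.approx(101.25)
    # equal mass at 0 and 90 degrees -> 45
    m = np.zeros((360, 360))
    m[0, 0] = 1.0
    m[0, 90] = 1.0
    pk = gt.toroidal_peak(m)
    expect = np.degrees(np.angle(np.exp(1j * np.deg2rad(0.5)) + np.exp(1j * np.deg2rad(90.5))))
    assert np.degrees(pk.theta[0]) == pytest.approx(expect, abs=1e-6)
    # antipodal cancellation is degenerate
    m = np.zeros((16, 16))
    m[0, 0] = m[0, 8] = 1.0
    assert gt.toroidal_peak(m).degenerate
    with pytest.raises(ValueError):
        gt.toroidal_peak(np.zeros((4, 4)))


def test_toroidal_peak_reduces_to_circular_mean():
    """With one sample per bin the mass center is the ordinary circular
    mean of the samples."""
    rng = np.random.default_rng(2)
    b = 360
    w = rng.random(b)
    m = np.tile(w, (1, 1))  # 1 x 360: theta1 resolved, theta2 single bin
    pk = gt.toroidal_peak(m)
    centers = (np.arange(b) + 0.5) / b * 2 * np.pi
    expect = np.angle(w @ np.exp(1j * centers)) % (2 * np.pi)
    assert pk.theta[0] == pytest.approx(expect, abs=1e-9)


def test_angular_tuning_examples():
    rng = np.random.default_rng(3)
    hd = rng.uniform(0, 2 * np.pi, 5000)
    act = np.exp(2 * np.cos(hd - 1.5))  # von Mises tuned at 1.5 rad
    curve = gt.angular_tuning(act, hd)
    assert curve.max() == 1.0
    assert np.argmax(curve) == int(1.5 / (2 * np.pi) * 60)
    dense_hd = np.linspace(0, 2 * np.pi, 600, endpoint=False)
    assert np.allclose(gt.angular_tuning(np.ones(600), dense_hd), 1.0)
    single = gt.angular_tuning(np.array([2.0]), np.array([0.5]))
    assert (single > 0).sum() == 1
    with pytest.raises(ValueError):
        gt.angular_tuning(np.array([]), np.array([]))


def test_frac_roll_interpolates():
    row = np.array([1.0, 0.0, 0.0, 0.0])
    assert np.allclose(_frac_roll(row, 1.0), [0, 1, 0, 0])
    assert np.allclose(_frac_roll(row, 0.5), [0.5, 0.5, 0, 0])


def test_toroidal3d_matches_nearest_center_assignment():
    rng = np.random.default_rng(4)
    coords = rng.uniform(0, 2 * np.pi, (500, 3))
    act = rng.random(500)
    centers, vals = gt.toroidal3d_tuning(act, coords, eps=1.5)
    d = _wrapped_dist(coords, centers)
    nearest = np.argmin(d, axis=1)
    expect = np.array([act[nearest == k].mean() if np.any(nearest == k) else 0.0
                       for k in range(len(centers))])
    assert np.allclose(vals, expect)
    # uniform activity -> uniform values
    _, v2 = gt.toroidal3d_tuning(np.ones(500), coords, eps=1.5)
    assert np.allclose(v2[v2 > 0], 1.0)
    with pytest.raises(ValueError):
        gt.toroidal3d_tuning(np.array([]), np.empty((0, 3)))
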