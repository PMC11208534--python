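"""Radial (maximin) and fuzzy-membership downsampling against brute-force
re-implementations of their defining rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist, pdist, squareform

import gridtorus as gt
from gridtorus.downsample import PointCloud, fit_memberships


# ------------------------------------------------------------- brute force


def brute_radial(points, eps):
    """Literal greedy maximin with an eps exclusion radius."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    chosen = [int(np.argmax(np.abs(pts).sum(axis=1)))]
    while True:
        d = cdist(pts, pts[chosen]).min(axis=1)
        if eps == 0:
            alive = [i for i in range(n) if i not in chosen]
        else:
            alive = [i for i in range(n) if i not in chosen and d[i] >= eps]
        if not alive:
            break
        chosen.append(max(alive, key=lambda i: d[i]))
    return chosen


def brute_memberships(points, kappa):
    pts = np.asarray(points, dtype=float)
    D = squareform(pdist(pts))
    n = len(pts)
    mu_dir = np.zeros((n, n))
    target = np.log2(kappa)
    for i in range(n):
        nb = np.argsort(D[i], kind="stable")[1 : kappa + 1]
        nd = D[i, nb]

        def f(sig):
            return np.exp(-nd / sig).sum() - target

        lo, hi = 1e-12, 1.0
        while f(hi) < 0:
            hi *= 2
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        mu_dir[i, nb] = np.exp(-nd / ((lo + hi) / 2))
    return mu_dir + mu_dir.T - mu_dir * mu_dir.T


def brute_fuzzy(points, kappa, m):
    """Literal greedy: at each step pick argmax of the summed membership to
    the residual cloud."""
    mu = brute_memberships(points, kappa)
    np.fill_diagonal(mu, 1.0)
    n = len(points)
    chosen = []
    for _ in range(m):
        best, best_val = None, -np.inf
        for x in range(n):
            if x in chosen:
                continue
            val = sum(mu[x, y] for y in range(n) if y not in chosen)
            if val > best_val + 1e-12:
                best, best_val = x, val
        chosen.append(best)
    return chosen


# ------------------------------------------------------------------- tests


def test_radial_line_example():
    """{0, 0.1, 1, 2} with eps = 0.5 selects 2, 0, 1 in that order."""
    X = PointCloud(np.array([[0.0], [0.1], [1.0], [2.0]]))
    out = gt.radial_downsample(X, 0.5)
    assert out.points.ravel().tolist() == [2.0, 0.0, 1.0]
    assert out.indices.tolist() == [3, 0, 2]


def test_radial_eps_zero_keeps_all_and_large_eps_keeps_one():
    rng = np.random.default_rng(0)
    X = PointCloud(rng.normal(size=(30, 3)))
    assert len(gt.radial_downsample(X, 0.0)) == 30
    diam = pdist(X.points).max()
    assert len(gt.radial_downsample(X, diam + 1)) == 1


@settings(deadline=None, derandomize=True, max_examples=15)
@given(st.integers(0, 10_000))
def test_radial_landmarks_pairwise_separated(seed):
    rng = np.random.default_rng(seed)
    X = PointCloud(rng.uniform(size=(40, 2)))
    eps = 0.2
    out = gt.radial_downsample(X, eps)
    if len(out) > 1:
        assert pdist(out.points).min() >= eps - 1e-12


def test_radial_matches_brute_force():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(60, 3))
    got = gt.radial_downsample(PointCloud(pts), 1.0).indices.tolist()
    assert got == brute_radial(pts, 1.0)


def test_sigma_closed_form_four_equidistant_neighbors():
    """kappa = 4 neighbors all at distance 1: sigma = 1/ln 2."""
    # 4 points at distance 1 from the origin in 4-D, mutually farther apart
    pts = np.vstack([np.zeros(4), np.eye(4)])
    fm = fit_memberships(PointCloud(pts), kappa=4)
    assert fm.sigma[0] == pytest.approx(1.0 / np.log(2), rel=1e-6)


def test_membership_symmetry_and_self_membership():
    rng = np.random.default_rng(1)
    fm = fit_memberships(PointCloud(rng.normal(size=(20, 3))), kappa=5)
    assert np.allclose(fm.mu, fm.mu.T)
    assert np.allclose(np.diag(fm.mu), 1.0)
    assert fm.mu.min() >= 0 and fm.mu.max() <= 1 + 1e-12


def test_probabilistic_sum_formula():
    """mu_x(y) = mu_y(x) = 0.5 combines to 0.75."""
    a = b = 0.5
    assert a + b - a * b == pytest.approx(0.75)
    # and the matrix path implements exactly that formula on the kNN support
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(10, 2))
    fm = fit_memberships(PointCloud(pts), kappa=3)
    D = squareform(pdist(pts))
    mu_dir = np.zeros((10, 10))
    for i in range(10):
        mu_dir[i, fm.neighbors[i]] = np.exp(-D[i, fm.neighbors[i]] / fm.sigma[i])
    expect = mu_dir + mu_dir.T - mu_dir * mu_dir.T
    np.fill_diagonal(expect, 1.0)
    assert np.allclose(fm.mu, expect)


def test_fuzzy_selects_all_when_m_equals_cloud_size():
    rng = np.random.default_rng(3)
    X = PointCloud(rng.normal(size=(15, 2)))
    out = gt.fuzzy_downsample(X, kappa=4, m=15)
    assert sorted(out.indices.tolist()) == list(range(15))


def test_fuzzy_first_point_is_argmax_total_membership():
    rng = np.random.default_rng(5)
    X = PointCloud(rng.normal(size=(25, 2)))
    fm = fit_memberships(X, kappa=6)
    out = gt.fuzzy_downsample(X, kappa=6, m=1, membership=fm)
    assert out.indices[0] == int(np.argmax(fm.mu.sum(axis=1)))


def test_fuzzy_excludes_far_outlier():
    rng = np.random.default_rng(6)
    cluster = rng.normal(0, 0.2, size=(30, 2))
    outlier = np.array([[50.0, 50.0]])
    X = PointCloud(np.vstack([cluster, outlier]))
    out = gt.fuzzy_downsample(X, kappa=5, m=10)
    assert 30 not in out.indices


def test_fuzzy_matches_brute_force_greedy():
    """Exact agreement with a literal implementation of the selection rule
    on clouds up to 200 points."""
    for seed, n, kappa, m in [(0, 60, 8, 20), (1, 200, 15, 40)]:
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        got = gt.fuzzy_downsample(PointCloud(pts), kappa, m).indices.tolist()
        assert got == brute_fuzzy(pts, kappa, m)


def test_fuzzy_rejects_bad_m():
    X = PointCloud(np.random.default_rng(0).normal(size=(10, 2)))
    with pytest.raises(ValueError):
        gt.fuzzy_downsample(X, kappa=3, m=0)
    with pytest.raises(ValueError):
        gt.fuzzy_downsample(X, kappa=3, m=11)


def test_downsampled_circle_preserves_h1_bar():
    """The dominant H1 bar of a dense noisy circle survives fuzzy
    downsampling with birth/death within 10%."""
    rng = np.random.default_rng(7)
    th = rng.uniform(0, 2 * np.pi, 400)
    pts = np.c_[np.cos(th), np.sin(th)] + rng.normal(0, 0.05, (400, 2))
    full = gt.compute_persistence(PointCloud(pts), maxdim=1, metric="euclidean", cocycles=False)
    bar_full = full.in_dim(1)[0]
    small = gt.fuzzy_downsample(PointCloud(pts), kappa=50, m=120)
    red = gt.compute_persistence(small, maxdim=1, metric="euclidean", cocycles=False)
    bar_red = red.in_dim(1)[0]
    assert bar_red.death == pytest.approx(bar_full.death, rel=0.10)
    assert abs(bar_red.birth - bar_full.birth) <= 0.1 * bar_full.death
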