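"""Heat kernels on the hexagonal/square torus and torus classification."""

import numpy as np
import pytest

import gridtorus as gt
from gridtorus.hexatorus import HeatKernelConfig, heat_kernel, model_ratemap
from gridtorus.maps import ToroidalPhase


def brute_heat(x, y, t, variant):
    """Direct 9-term lattice summation."""
    total = 0.0
    for k in (-1, 0, 1):
        for l in (-1, 0, 1):
            a, b = k + x, l + y
            q = (2 / np.sqrt(3)) * (a * a + a * b + b * b) if variant == "hex" else a * a + b * b
            total += np.exp(-np.pi / t * q)
    return total / t


def test_square_kernel_value_at_origin():
    """H_sqr(0, 0; 0.1) = 10 (1 + 4 e^{-10 pi} + 4 e^{-20 pi})."""
    cfg = HeatKernelConfig(t=0.1, variant="sqr")
    got = heat_kernel(0.0, 0.0, cfg)
    expect = 10.0 * (1 + 4 * np.exp(-10 * np.pi) + 4 * np.exp(-20 * np.pi))
    assert got == pytest.approx(expect, rel=1e-12)


@pytest.mark.parametrize("variant", ["hex", "sqr"])
def test_kernel_matches_direct_summation(variant):
    cfg = HeatKernelConfig(t=0.1, variant=variant)
    rng = np.random.default_rng(0)
    for _ in range(50):
        x, y = rng.uniform(0, 1, 2)
        assert heat_kernel(x, y, cfg) == pytest.approx(
            brute_heat(x, y, 0.1, variant), rel=1e-12
        )


def test_kernel_periodicity_under_wrapping():
    cfg = HeatKernelConfig(variant="hex")
    assert heat_kernel(0.3, 0.7, cfg) == pytest.approx(heat_kernel(1.3, 0.7, cfg))
    assert heat_kernel(0.3, 0.7, cfg) == pytest.approx(heat_kernel(0.3, -0.3, cfg))


def test_hex_kernel_symmetry():
    cfg = HeatKernelConfig(variant="hex")
    rng = np.random.default_rng(1)
    for _ in range(20):
        x, y = rng.uniform(0, 1, 2)
        assert heat_kernel(x, y, cfg) == pytest.approx(heat_kernel(y, x, cfg))


def test_kernel_positive_peaked_and_mass_decreasing_in_t():
    u = (np.arange(50) + 0.5) / 50
    U, V = np.meshgrid(u, u)
    for variant in ("hex", "sqr"):
        prev_mass = None
        for t in (0.05, 0.1, 0.2, 0.4):
            H = heat_kernel(U, V, HeatKernelConfig(t=t, variant=variant))
            assert np.all(H > 0)
            iy, ix = np.unravel_index(np.argmax(H), H.shape)
            assert ix in (0, 49) and iy in (0, 49)  # maximum at the origin
            mass = H.mean()
            if prev_mass is not None:
                assert mass < prev_mass
            prev_mass = mass


def test_kernel_rejects_bad_t():
    with pytest.raises(ValueError):
        HeatKernelConfig(t=0.0)


def test_model_ratemap_peak_location_and_equivariance():
    cfg = HeatKernelConfig(variant="hex")
    m0 = model_ratemap(ToroidalPhase(theta=(0.0, 0.0)), cfg)
    iy, ix = np.unravel_index(np.argmax(m0), m0.shape)
    # the origin sits on the corner shared by the wrap-adjacent bins
    assert iy in (0, 9) and ix in (0, 9)
    # shifting the peak by 3 of 10 bins translates the model map
    shift = 3 * 2 * np.pi / 10
    m1 = model_ratemap(ToroidalPhase(theta=(shift, shift)), cfg)
    assert np.allclose(np.roll(np.roll(m0, 3, 0), 3, 1), m1, atol=1e-9)


def test_model_ratemap_matches_dense_evaluation():
    cfg = HeatKernelConfig(variant="sqr")
    pk = ToroidalPhase(theta=(1.0, 2.0))
    m = model_ratemap(pk, cfg, bins=10, m=400)
    n = 20
    u = (np.arange(n) + 0.5) / n
    U, V = np.meshgrid(u, u)
    H = heat_kernel(U - pk.theta[0] / (2 * np.pi), V - pk.theta[1] / (2 * np.pi), cfg)
    dense = H.reshape(10, 2, 10, 2).mean(axis=(1, 3))
    assert np.allclose(m, dense)
    with pytest.raises(ValueError):
        model_ratemap(ToroidalPhase(theta=(0, 0), degenerate=True), cfg)


def _maps_from_kernel(variant, basis=None, n_units=8, seed=0):
    rng = np.random.default_rng(seed)
    cfg = HeatKernelConfig(variant=variant)
    maps, peaks = [], []
    n = 40
    u = (np.arange(n) + 0.5) / n
    U, V = np.meshgrid(u, u)
    for _ in range(n_units):
        px, py = rng.uniform(0, 1, 2)
        RU, RV = U - px, V - py
        if basis is not None:
            RU, RV = basis[0, 0] * RU + basis[0, 1] * RV, basis[1, 0] * RU + basis[1, 1] * RV
        H = heat_kernel(RU, RV, cfg)
        maps.append(H.reshape(10, 4, 10, 4).mean(axis=(1, 3)))
        peaks.append(ToroidalPhase(theta=(2 * np.pi * px, 2 * np.pi * py)))
    return maps, peaks


def test_classify_self_fits():
    maps, peaks = _maps_from_kernel("hex")
    cls = gt.classify_torus(maps, peaks)
    assert cls.label == "hexagonal" and cls.median_hex > 0.99
    maps, peaks = _maps_from_kernel("sqr")
    cls = gt.classify_torus(maps, peaks)
    assert cls.label == "square" and cls.median_sqr > cls.median_hex


def test_classify_invariant_to_lattice_basis_change():
    basis = np.array([[1, 0], [1, 1]])
    maps, peaks = _maps_from_kernel("hex", basis=basis)
    cls = gt.classify_torus(maps, peaks)
    assert cls.label == "hexagonal"


def test_classify_rejects_tiny_ensemble():
    maps, peaks = _maps_from_kernel("hex", n_units=1)
    with pytest.raises(ValueError):
        gt.classify_torus(maps, peaks)


def test_heat_model_rates_constant_at_peak_is_maximal():
    from gridtorus.coordinatize import ToroidalCoordinates

    pk = ToroidalPhase(theta=(1.0, 2.0))
    co = ToroidalCoordinates(angles=np.tile([1.0, 2.0], (5, 1)))
    r = gt.heat_model_rates(co, [pk])
    cfg = HeatKernelConfig(variant="hex")
    assert np.allclose(r.values, heat_kernel(0.0, 0.0, cfg))
    # away from the peak the modeled rate is lower
    co2 = ToroidalCoordinates(angles=np.tile([1.0 + np.pi, 2.0], (5, 1)))
    r2 = gt.heat_model_rates(co2, [pk])
    assert np.all(r2.values < r.values)
    # empty coordinates give an empty matrix
    co0 = ToroidalCoordinates(angles=np.empty((0, 2)))
    assert gt.heat_model_rates(co0, [pk]).values.shape == (1, 0)


def test_heat_model_autocorr_matches_observed_periodicity(twisted_decoded):
    """Idealized heat-model rates reproduce the 1-D periodicity of the
    observed rates on a linearized coordinate."""
    rates = twisted_decoded["rates"]
    co = twisted_decoded["coords_all"]
    maps, peaks = [], []
    lin = np.cumsum(np.full(rates.n_time, 0.5))  # fake 1-D track position
    from conftest import observed_unit_maps

    maps, peaks = observed_unit_maps(twisted_decoded)
    unit = 3
    model = gt.heat_model_rates(co, [peaks[unit]])
    ac_obs = gt.autocorr_1d(rates.values[unit] ** 2, lin, bin_cm=4.0, max_shift=100)
    ac_mod = gt.autocorr_1d(model.values[0], lin, bin_cm=4.0, max_shift=100)

    def peak_lags(v):
        v = v / v[0]
        return {s for s in range(3, 100) if v[s] >= v[s - 2] and v[s] >= v[s + 2] and v[s] > 0.1}

    # the modeled and observed autocorrelograms share at least one
    # non-trivial periodicity peak
    assert peak_lags(ac_obs.values[:101]) & peak_lags(ac_mod.values[:101])
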