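"""Shared fixtures: simulated grid modules and their decoded tori.

The heavy artifacts (attractor simulations, persistence, decoding) are
session-scoped so the whole suite pays for them once.
"""

import numpy as np
import pytest

import gridtorus as gt
from gridtorus.pipeline import RunConfig, decode_torus


@pytest.fixture(scope="session")
def twisted_module():
    """A 20x20 twisted-torus module driven by a 5000-frame random walk."""
    traj = gt.random_walk_trajectory(50.0, arena=150.0, dt=0.01, speed_mean=15.0, seed=3)
    out = gt.simulate_twisted_torus(gt.CANConfig(model="twisted_torus", seed=4), traj)
    return out


@pytest.fixture(scope="session")
def square_module():
    """A 10x10 square-torus module on the same kind of walk."""
    traj = gt.random_walk_trajectory(50.0, arena=150.0, dt=0.01, speed_mean=15.0, seed=3)
    out = gt.simulate_square_torus(gt.CANConfig(model="square_torus", seed=4), traj)
    return out


def _prep(out):
    rates = gt.sqrt_transform(out.rates)
    speed = np.interp(rates.times, out.trajectory.t, out.trajectory.speed)
    keep = speed >= 5.0
    return gt.speed_filter(rates, speed, 5.0), out.bump_phases[keep]


@pytest.fixture(scope="session")
def twisted_prepped(twisted_module):
    """(sqrt+speed-filtered rates, matching true bump phases)."""
    return _prep(twisted_module)


@pytest.fixture(scope="session")
def square_prepped(square_module):
    return _prep(square_module)


@pytest.fixture(scope="session")
def twisted_decoded(twisted_prepped):
    """Full decode of the twisted module with its shuffle-null thresholds."""
    rates, true_phases = twisted_prepped
    cfg = RunConfig(
        profile=gt.ParameterProfile(d=6, eps=0.5, kappa=600, m=180),
        n_shuffles=5,
        seed=9,
    )
    barcode, cloud, coords_lm, coords_all = decode_torus(rates, cfg)
    return {
        "rates": rates,
        "true_phases": true_phases,
        "barcode": barcode,
        "cloud": cloud,
        "coords_lm": coords_lm,
        "coords_all": coords_all,
    }


@pytest.fixture(scope="session")
def square_decoded(square_prepped):
    """Decode of the square module (no shuffle null; two longest H1 bars)."""
    rates, true_phases = square_prepped
    cfg = RunConfig(
        profile=gt.ParameterProfile(d=6, eps=0.5, kappa=600, m=180),
        do_shuffle=False,
        seed=9,
    )
    barcode, cloud, coords_lm, coords_all = decode_torus(rates, cfg)
    return {
        "rates": rates,
        "true_phases": true_phases,
        "barcode": barcode,
        "cloud": cloud,
        "coords_lm": coords_lm,
        "coords_all": coords_all,
    }


def landmark_coords(decoded):
    """Landmark-level ToroidalCoordinates from the per-bar circle maps."""
    return gt.ToroidalCoordinates(
        angles=np.stack([c.angles for c in decoded["coords_lm"]], axis=1)
    )


def observed_unit_maps(decoded):
    """(maps, peaks) of every unit on the landmark torus (10^2 bins)."""
    rates = decoded["rates"]
    cloud = decoded["cloud"]
    lm_raw = rates.values[:, cloud.indices] ** 2  # undo sqrt: raw rates
    lmc = landmark_coords(decoded)
    maps = [gt.observed_ratemap_10(lm_raw[i], lmc) for i in range(lm_raw.shape[0])]
    peaks = [gt.toroidal_peak(m - m.min() + 1e-12) for m in maps]
    return maps, peaks
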