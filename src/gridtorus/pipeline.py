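"""End-to-end pipeline: rates -> ensembles -> barcode -> torus coordinates
-> maps -> classification, with artifacts written per stage."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as gio
from .coordinatize import circular_coords, extrapolate_coords
from .downsample import PointCloud
from .ensembles import cluster_ensembles, crosscorr, inverse_norm_crosscorr
from .hexatorus import classify_torus, observed_ratemap_10
from .maps import toroidal_peak
from .preprocess import (
    ParameterProfile,
    RateMatrix,
    rates_from_spikes,
    speed_filter,
    sqrt_transform,
)
from .topology import (
    Barcode,
    cloud_from_rates,
    compute_persistence,
    count_significant_bars,
    shuffle_null,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "decode_torus"]


@dataclass
class RunConfig:
    """Paths, parameters and stage toggles for one pipeline run."""

    spikes: Optional[str] = None  # spike file; rates HDF5 also accepted
    tracking: Optional[str] = None
    out_dir: str = "gridtorus_out"
    profile: ParameterProfile = field(default_factory=ParameterProfile)
    seed: int = 0
    maxdim: int = 2
    n_shuffles: int = 20
    n_h1_bars: int = 2  # circular features to coordinatize
    do_cluster: bool = True
    do_shuffle: bool = True
    do_classify: bool = True

    def digest(self) -> str:
        blob = json.dumps(
            {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
             for k, v in vars(self).items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def decode_torus(rates: RateMatrix, cfg: RunConfig):
    """Barcode + 2-D torus coordinates for one ensemble's rate matrix.

    Returns (barcode, landmark cloud, landmark coords, extrapolated coords).
    """
    profile = cfg.profile
    cloud = cloud_from_rates(rates, profile)
    barcode = compute_persistence(cloud, maxdim=cfg.maxdim)
    if cfg.do_shuffle:
        barcode.thresholds = shuffle_null(
            rates, profile, n_shuffles=cfg.n_shuffles, seed=cfg.seed, maxdim=cfg.maxdim
        )
        n_sig = count_significant_bars(barcode, 1)
    else:
        n_sig = cfg.n_h1_bars
    n_use = min(max(n_sig, 1), cfg.n_h1_bars)
    coords_lm = circular_coords(barcode, list(range(n_use)), cloud)
    # decode weights are raw rates (undo the sqrt of the metric path)
    weights = rates.values**2 if rates.transform == "sqrt" else rates.values
    coords_all = extrapolate_coords(
        coords_lm, weights[:, cloud.indices], weights, times=rates.times
    )
    return barcode, cloud, coords_lm, coords_all


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all requested stages, writing artifacts under cfg.out_dir.

    Every artifact embeds the config hash and seed; any stage failure
    aborts with the stage name while earlier artifacts remain on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"config_hash": cfg.digest(), "seed": cfg.seed, "stages": []}
    stage = "load"
    try:
        spath = Path(cfg.spikes)
        if spath.suffix in (".h5", ".hdf5"):
            import h5py

            with h5py.File(spath, "r") as f:
                if "rates" in f:
                    rates = RateMatrix(
                        f["rates"][...], dt=float(f.attrs["dt"]), times=f["times"][...]
                    )
                else:
                    raise KeyError("rates")
        else:
            spikes = gio.read_spikes(spath)
            rates = rates_from_spikes(
                spikes, cfg.profile.sigma_smooth, cfg.profile.dt_topology
            )
        rates = sqrt_transform(rates)
        if cfg.tracking:
            traj = gio.read_tracking(cfg.tracking)
            speed = np.interp(rates.times, traj.t, traj.speed)
            rates = speed_filter(rates, speed, cfg.profile.speed_min)
        report["stages"].append(stage)

        ensembles = [np.arange(rates.n_neurons)]
        if cfg.do_cluster:
            stage = "cluster"
            cc = crosscorr(rates, cfg.profile.tau_max)
            C = inverse_norm_crosscorr(cc)
            part = cluster_ensembles(C, cfg.profile.rho_cluster)
            if part.ensembles:
                ensembles = part.ensembles
            np.savetxt(out / "ensemble_labels.txt", part.labels, fmt="%d",
                       header=f"config {cfg.digest()} seed {cfg.seed}")
            report["stages"].append(stage)
        report["n_ensembles"] = len(ensembles)

        report["ensembles"] = []
        for k, idx in enumerate(ensembles):
            stage = f"barcode[{k}]"
            sub = RateMatrix(rates.values[idx], dt=rates.dt, times=rates.times,
                             transform=rates.transform)
            barcode, cloud, coords_lm, coords_all = decode_torus(sub, cfg)
            gio.write_barcode(barcode, out / f"barcode_{k}.json")
            gio.write_coords(coords_all, out / f"coords_{k}.csv")
            ens = {
                "n_neurons": int(len(idx)),
                "n_landmarks": int(len(cloud)),
            }
            if barcode.thresholds:
                ens["significant_bars"] = {
                    str(d): count_significant_bars(barcode, d) for d in (1, 2)
                }
            if cfg.do_classify and coords_all.n_dims >= 2:
                stage = f"classify[{k}]"
                lm_coords = type(coords_all)(
                    angles=np.stack([c.angles for c in coords_lm], axis=1)
                )
                maps = [
                    observed_ratemap_10(sub.values[i, cloud.indices], lm_coords)
                    for i in range(len(idx))
                ]
                peaks = [toroidal_peak(m - m.min() + 1e-12) for m in maps]
                cls = classify_torus(maps, peaks)
                ens["classification"] = {
                    "median_hex": cls.median_hex,
                    "median_sqr": cls.median_sqr,
                    "label": cls.label,
                }
            report["ensembles"].append(ens)
            report["stages"].append(stage)
    except Exception as e:  # noqa: BLE001 - stage name is the diagnostic
        report["failed_stage"] = stage
        report["error"] = str(e)
        (Path(cfg.out_dir) / "report.json").write_text(json.dumps(report, indent=1))
        raise RuntimeError(f"pipeline failed in stage {stage}: {e}") from e
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
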