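"""Experiment configuration, provenance and fixture generation.

A single hierarchical YAML config drives build -> simulate -> analyze.
Every run writes a manifest (config snapshot, package version, seeds,
timestamps, output inventory with checksums) so that reruns with the same
config and seeds are reproducible bit-for-bit where deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import ionic_models as im
from . import analysis as an
from . import fusion as fu
from . import simulator as sm
from .tissue import BoundaryProfile, build_elongated_tissue

log = logging.getLogger("cardiofuse")

_SCHEMA = {
    "tissue": {"nx", "ny", "nz", "block", "sigma", "mode", "seed"},
    "model": {"g_na", "gamma", "ts_prefactor", "g_gap_cm_cm", "g_gap_cm_cf",
              "g_gap_cf_cf"},
    "stimulus": {"amplitude_pa", "pulse_ms", "period_ms", "count",
                 "n_layers"},
    "simulation": {"dt_us", "duration_ms", "record_every_ms",
                   "stagnation_ms", "equilibrate_ms"},
    "sweep": {"g_na_values", "sigma_values", "seeds", "g_na_lo", "g_na_hi",
              "resolution"},
    "output": {"dir"},
}

DEFAULT_CONFIG = {
    "tissue": {"nx": 20, "ny": 20, "nz": 100, "block": None, "sigma": 3.0,
               "mode": "shoulder", "seed": 1},
    "model": {"g_na": 0.6, "gamma": 0.8, "ts_prefactor": 40.0},
    "stimulus": {"amplitude_pa": 4000.0, "pulse_ms": 2.0,
                 "period_ms": 1000.0, "count": 1, "n_layers": 2},
    "simulation": {"dt_us": 5.0, "duration_ms": 600.0,
                   "record_every_ms": 0.05, "stagnation_ms": 100.0,
                   "equilibrate_ms": 120.0},
    "output": {"dir": "cardiofuse_out"},
}


def validate_config(cfg: dict) -> dict:
    """Merge with defaults; raise listing unknown sections/keys."""
    bad = []
    for section, keys in cfg.items():
        if section not in _SCHEMA:
            bad.append(section)
            continue
        for k in keys or {}:
            if k not in _SCHEMA[section]:
                bad.append(f"{section}.{k}")
    if bad:
        raise ValueError(f"unknown config keys: {', '.join(sorted(bad))}")
    merged = {s: dict(v) for s, v in DEFAULT_CONFIG.items()}
    for section, keys in cfg.items():
        merged.setdefault(section, {}).update(keys or {})
    return merged


def load_config(path) -> dict:
    with open(path) as f:
        return validate_config(yaml.safe_load(f) or {})


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict
    started: str
    finished: str
    outputs: dict  # path -> sha256

    def write(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build(cfg):
    t = cfg["tissue"]
    block = t["block"]
    if block is None:
        b = t["nz"] // 5
        block = (2 * b, 3 * b - 1)
    profile = BoundaryProfile(sigma=float(t["sigma"]), mode=t["mode"],
                              seed=int(t["seed"]))
    return build_elongated_tissue(t["nx"], t["ny"], t["nz"],
                                  tuple(block), profile)


def _params(cfg):
    m = cfg["model"]
    return im.CMParams(), im.CFParams(g_Na=float(m["g_na"]),
                                      gamma=float(m["gamma"]),
                                      ts_prefactor=float(m.get(
                                          "ts_prefactor", 40.0)))


def run_experiment(config_path, out_dir=None) -> RunManifest:
    """Execute build -> simulate -> analyze for one config file."""
    cfg = load_config(config_path)
    out = Path(out_dir or cfg["output"]["dir"])
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")

    geo = _build(cfg)
    cm_p, cf_p = _params(cfg)
    s = cfg["stimulus"]
    stim = sm.StimulusProtocol(amplitude_pA=float(s["amplitude_pa"]),
                               pulse_ms=float(s["pulse_ms"]),
                               period_ms=float(s["period_ms"]),
                               count=int(s["count"]),
                               n_layers=int(s["n_layers"]))
    c = cfg["simulation"]
    simcfg = sm.SimulationConfig(dt_us=float(c["dt_us"]),
                                 duration_ms=float(c["duration_ms"]),
                                 record_every_ms=float(c["record_every_ms"]),
                                 stagnation_ms=c.get("stagnation_ms"),
                                 equilibrate_ms=float(c["equilibrate_ms"]))
    log.info("simulating %dx%dx%d lattice, g_Na=%.3g nS",
             geo.nx, geo.ny, geo.nz, cf_p.g_Na)
    res = sm.run(geo, stim, simcfg, cm_params=cm_p, cf_params=cf_p)

    amap = an.activation_map(res)
    success = an.classify_conduction(amap, geo)
    delay = an.center_block_delay(amap, geo) if success else None
    log.info("conduction %s%s", "success" if success else "failure",
             f", delay {delay:.1f} ms" if delay is not None else "")

    geo.to_hdf5(out / "geometry.h5")
    res.to_hdf5(out / "result.h5")
    np.savetxt(out / "layer_summary.csv",
               np.column_stack([np.arange(geo.nz), geo.layer_cf_counts()]),
               fmt="%d", delimiter=",", header="z,n_CF", comments="")
    with open(out / "analysis.json", "w") as f:
        json.dump({"success": bool(success), "delay_ms": delay,
                   "status": res.status, "t_end_ms": res.t_end}, f, indent=2)
    with open(out / "config_echo.yaml", "w") as f:
        yaml.safe_dump(cfg, f)

    outputs = {str(p.relative_to(out)): _sha256(p)
               for p in sorted(out.iterdir()) if p.is_file()
               and p.name != "manifest.json"}
    manifest = RunManifest(cfg, __version__,
                           {"tissue": cfg["tissue"]["seed"]},
                           started, time.strftime("%Y-%m-%dT%H:%M:%S"),
                           outputs)
    manifest.write(out / "manifest.json")
    return manifest


def make_fixtures(out_dir, seed: int = 0) -> list:
    """Write the small synthetic fixtures used by tests and examples.

    A tiny lattice geometry, a synthetic fusion spreadsheet in the
    supplementary-workbook layout (group slopes equal to the generator
    defaults), and a synthetic two-sigmoid trace table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    geo = build_elongated_tissue(4, 4, 20, (8, 11),
                                 BoundaryProfile(sigma=2.0, seed=seed))
    geo.to_hdf5(out / "tiny_geometry.h5")
    files.append(out / "tiny_geometry.h5")

    angle = fu.synth_pair_timeseries(fu.DEFAULT_ANGLE_SPECS, "angle_deg",
                                     seed=seed)
    length = fu.synth_pair_timeseries(fu.DEFAULT_LENGTH_SPECS, "length_um",
                                      seed=seed + 1)
    norm = [fu.normalize_length(s) for s in length]
    fu.write_pair_table(angle + length + norm,
                        out / "synthetic_fusion_pairs.xlsx")
    files.append(out / "synthetic_fusion_pairs.xlsx")

    t = np.arange(0.0, 120.0, 0.1)
    v = (-80.0 + 30.0 / (1.0 + np.exp(-(t - 40.0)))
         + 25.0 / (1.0 + np.exp(-(t - 80.0))))
    np.savetxt(out / "synthetic_double_depol_trace.csv",
               np.column_stack([t, v]), delimiter=",",
               header="time_ms,v_mv", comments="")
    files.append(out / "synthetic_double_depol_trace.csv")
    return files
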