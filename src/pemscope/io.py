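"""HDF5 scan containers and flat-file exports (TIFF, CSV, JSON sidecar).

Layout of a scan file::

    /raw/traces     [x, y, t]   float32 reflectivity
    /raw/timebase   [t]         seconds
    /raw/config                 JSON-encoded simulation/acquisition config
    /analysis/delta_f  [x, y, z]
    /analysis/f_B      [x, y, z]
    /analysis/amplitude[x, y, z]
    /analysis/surface  [x, y]
    /analysis/z        [z]
    /truth/surface     [x, y]   (synthetic scans only)

Axes and units are stored as attributes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import AcousticMedium, OpticalConfig
from .imaging import LayerFit, ScanVolume
from .phantom import ScanSimulation, SimulationConfig, ToFTrace
from .tfa import DepthProfile

__all__ = ["save_scan", "load_traces", "load_volume", "save_volume",
           "export_map_tiff", "export_map_csv", "export_profile_csv",
           "export_layerfits_csv", "write_sidecar"]


def _config_to_json(cfg: SimulationConfig | None) -> str:
    if cfg is None:
        return "{}"
    d = dataclasses.asdict(cfg)
    return json.dumps(d)


def _config_from_json(s: str) -> SimulationConfig | None:
    d = json.loads(s)
    if not d:
        return None
    optics = OpticalConfig(**d.pop("optics"))
    return SimulationConfig(optics=optics, **d)


def save_scan(path, sim: ScanSimulation,
              volume: ScanVolume | None = None) -> None:
    """Write a simulated scan (and optionally its analysis) to HDF5."""
    t = sim.trace_at(0, 0).time
    raw = np.stack([[sim.trace_at(ix, iy).amplitude
                     for iy in range(sim.ny)] for ix in range(sim.nx)])
    with h5py.File(path, "w") as f:
        g = f.create_group("raw")
        d = g.create_dataset("traces", data=raw.astype(np.float64))
        d.attrs["axes"] = "x,y,t"
        tb = g.create_dataset("timebase", data=t)
        tb.attrs["units"] = "s"
        g.attrs["config"] = _config_to_json(sim.config)
        g.attrs["pitch_m"] = sim.phantom.pitch
        g.attrs["control"] = json.dumps(dataclasses.asdict(sim.phantom.control))
        tr = f.create_group("truth")
        s = tr.create_dataset("surface", data=sim.surface_truth())
        s.attrs["units"] = "m (stand-off)"
        if volume is not None:
            _write_volume(f, volume)


def _write_volume(f: h5py.File, volume: ScanVolume) -> None:
    g = f.require_group("analysis")
    for name in ("delta_f", "amplitude"):
        if name in g:
            del g[name]
        d = g.create_dataset(name, data=getattr(volume, name))
        d.attrs["axes"] = "x,y,z"
    for name, data, units in (("surface", volume.surface, "m"),
                              ("z", volume.z, "m"),
                              ("x", volume.x, "m"), ("y", volume.y, "m")):
        if name in g:
            del g[name]
        d = g.create_dataset(name, data=data)
        d.attrs["units"] = units
    g.attrs["provenance"] = json.dumps(volume.provenance, default=str)


def save_volume(path, volume: ScanVolume) -> None:
    with h5py.File(path, "a") as f:
        _write_volume(f, volume)


def load_traces(path) -> tuple[list[list[ToFTrace]], dict]:
    """Read raw traces back as ToFTrace objects plus scan metadata."""
    with h5py.File(path, "r") as f:
        raw = f["raw/traces"][...]
        t = f["raw/timebase"][...]
        cfg = _config_from_json(f["raw"].attrs.get("config", "{}"))
        meta = {
            "pitch": float(f["raw"].attrs.get("pitch_m", 1.0)),
            "control": json.loads(f["raw"].attrs.get("control", "null")),
        }
        if "truth/surface" in f:
            meta["surface_truth"] = f["truth/surface"][...]
    traces = [[ToFTrace(time=t, amplitude=raw[ix, iy].astype(float),
                        config=cfg, position=(ix, iy))
               for iy in range(raw.shape[1])] for ix in range(raw.shape[0])]
    return traces, meta


def load_volume(path) -> ScanVolume:
    with h5py.File(path, "r") as f:
        g = f["analysis"]
        return ScanVolume(
            x=g["x"][...], y=g["y"][...], z=g["z"][...],
            delta_f=g["delta_f"][...], amplitude=g["amplitude"][...],
            surface=g["surface"][...],
            provenance=json.loads(g.attrs.get("provenance", "{}")),
        )


def export_map_tiff(path, map2d: np.ndarray) -> None:
    """Write a 2D map as 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(map2d, dtype=np.float32))


def export_map_csv(path, map2d: np.ndarray) -> None:
    pd.DataFrame(np.asarray(map2d)).to_csv(path, index=False, header=False)


def export_profile_csv(path, profile: DepthProfile) -> None:
    pd.DataFrame({
        "z_m": profile.z,
        "f_B_Hz": profile.f_B,
        "f_B_ref_Hz": profile.f_B_ref,
        "delta_f_Hz": profile.delta_f,
        "amplitude": profile.amplitude,
    }).to_csv(path, index=False)


def export_layerfits_csv(path, fits: list[LayerFit]) -> None:
    pd.DataFrame([{
        "centre_m": f.centre, "fwhm_m": f.fwhm, "amplitude_Hz": f.amplitude,
        "residual_Hz": f.residual, "converged": f.converged,
    } for f in fits]).to_csv(path, index=False)


def write_sidecar(path, provenance: dict) -> None:
    """JSON provenance sidecar next to an exported artefact."""
    Path(path).write_text(json.dumps(provenance, indent=2, default=str))
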