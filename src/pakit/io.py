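"""Readers and writers for the toolkit's on-disk formats.

Absorption maps and images travel as TIFF (one page per depth plane for
3-D) with a JSON sidecar carrying the physical spacing and origin; PNG is
accepted for 2-D input with spacing supplied by the caller.  Signal sets
and scan volumes use an HDF5 container; tables go to CSV; configuration is
YAML (JSON accepted).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .grids import AbsorptionMap
from .forward import SignalSet
from .orpam import ScanConfig, ScanVolume

__all__ = [
    "save_map", "load_map", "save_signals", "load_signals",
    "save_volume", "load_volume", "save_table", "load_config", "save_config",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_map(path, amap: AbsorptionMap) -> None:
    """Write a map as (multi-page) TIFF plus a JSON spacing/origin sidecar."""
    path = Path(path)
    values = amap.values
    if amap.ndim == 3:
        pages = np.moveaxis(values, -1, 0)  # one page per depth plane
    else:
        pages = values
    tifffile.imwrite(path, pages.astype(np.float32))
    meta = {"spacing": list(amap.spacing), "origin": list(amap.origin),
            "ndim": amap.ndim}
    _sidecar(path).write_text(json.dumps(meta))


def load_map(path, spacing=None) -> AbsorptionMap:
    """Read a TIFF/PNG map; spacing comes from the sidecar or the argument."""
    path = Path(path)
    if path.suffix.lower() in (".png",):
        import imageio.v3 as iio

        values = np.asarray(iio.imread(path), dtype=float)
        if values.ndim == 3:  # collapse RGB
            values = values.mean(axis=-1)
        if spacing is None:
            raise ValueError("PNG input needs an explicit spacing (μm)")
        return AbsorptionMap(values=values, spacing=spacing)
    pages = np.asarray(tifffile.imread(path), dtype=float)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    ndim = meta.get("ndim", pages.ndim)
    if ndim == 3 and pages.ndim == 3:
        values = np.moveaxis(pages, 0, -1)
    else:
        values = pages
    spacing = spacing or meta.get("spacing", (1.0,) * values.ndim)
    origin = tuple(meta.get("origin", (0.0,) * values.ndim))
    return AbsorptionMap(values=values, spacing=tuple(spacing), origin=origin)


def save_signals(path, signals: SignalSet) -> None:
    """HDF5 layout: /samples, /dt, /t0, /positions, /speed_of_sound."""
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=signals.samples)
        f.create_dataset("dt", data=signals.dt)
        f.create_dataset("t0", data=signals.t0)
        f.create_dataset("speed_of_sound", data=signals.speed_of_sound)
        if signals.element_positions is not None:
            f.create_dataset("positions", data=signals.element_positions)


def load_signals(path) -> SignalSet:
    with h5py.File(path, "r") as f:
        return SignalSet(
            samples=f["samples"][:],
            dt=float(f["dt"][()]),
            t0=float(f["t0"][()]),
            speed_of_sound=float(f["speed_of_sound"][()]),
            element_positions=f["positions"][:] if "positions" in f else None)


def export_signals_csv(path, signals: SignalSet) -> None:
    """Long-form CSV: element, time (s), value (Pa)."""
    times = signals.times
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["element", "time_s", "value"])
        for e in range(signals.element_count):
            for k in range(signals.n_t):
                writer.writerow([e, f"{times[k]:.9e}", f"{signals.samples[e, k]:.9e}"])


def save_volume(path, volume: ScanVolume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("a_lines", data=volume.a_lines)
        f.create_dataset("x_coords", data=volume.x_coords)
        f.create_dataset("y_coords", data=volume.y_coords)
        f.create_dataset("depth_coords", data=volume.depth_coords)
        f.attrs["config"] = json.dumps(_config_dict(volume.config))


def load_volume(path) -> ScanVolume:
    with h5py.File(path, "r") as f:
        cfg = json.loads(f.attrs["config"])
        jitter = cfg.pop("jitter", None)
        from .orpam import JitterModel

        config = ScanConfig(**{**cfg, "pixels": tuple(cfg["pixels"]),
                               "jitter": JitterModel(**jitter) if jitter else None})
        return ScanVolume(a_lines=f["a_lines"][:], x_coords=f["x_coords"][:],
                          y_coords=f["y_coords"][:],
                          depth_coords=f["depth_coords"][:], config=config)


def _config_dict(config: ScanConfig) -> dict:
    d = {"spot_fwhm": config.spot_fwhm, "step": config.step,
         "trajectory": config.trajectory, "pixels": list(config.pixels),
         "scan_diameter": config.scan_diameter,
         "axial_kernel_fwhm": config.axial_kernel_fwhm}
    if config.jitter is not None:
        d["jitter"] = {"drift_per_line": config.jitter.drift_per_line,
                       "seed": config.jitter.seed}
    return d


def save_image(path, image: np.ndarray, pixel_size_um: float) -> None:
    """16-bit TIFF image with a μm-per-pixel JSON sidecar."""
    path = Path(path)
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    tifffile.imwrite(path, (scaled * 65535).astype(np.uint16))
    _sidecar(path).write_text(json.dumps(
        {"um_per_pixel": pixel_size_um, "value_min": float(lo), "value_max": float(hi)}))


def save_table(path, rows: list[dict]) -> None:
    """CSV from a list of homogeneous dicts."""
    if not rows:
        raise ValueError("no rows to write")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))
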