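"""Optical-resolution photoacoustic microscopy (OR-PAM) scan simulator.

OR-PAM raster- or rotary-scans a focused laser spot across the tissue
surface and records one depth-resolved A-line per position.  Lateral
resolution is set by the optical spot (a Gaussian of given FWHM), axial
resolution by the detector bandwidth (modelled as a Gaussian depth blur):
the imaging chain is a linear PSF applied to the absorption map, scaled by
the medium's Gruneisen coefficient.  The acoustic propagation path is
exercised by the tomography modules; here the optics dominate.

Rendered products are B-scans (lateral × depth slices), maximum-amplitude
projections (MAPs) along depth, and depth sections — the standard views
for layered capillary networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator

from .grids import AbsorptionMap
from .media import MediumProperties, gruneisen
from .forward import SensitivityModel

__all__ = ["ScanConfig", "JitterModel", "ScanVolume", "scan", "bscan",
           "max_projection", "max_projection_profile", "depth_section",
           "detector_uniformity_curve"]

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM / sigma


@dataclass(frozen=True)
class JitterModel:
    """Accumulated lateral drift of successive A-line positions (tissue
    motion during a slow scan): per-line displacement ~ N(0, drift²) μm,
    integrated along the scan order."""

    drift_per_line: float = 2.0
    seed: int = 0


@dataclass(frozen=True)
class ScanConfig:
    """OR-PAM acquisition geometry.

    spot_fwhm: lateral optical spot size (μm); step: scan step (μm);
    trajectory: "raster" (pixels = (nx, ny)) or "rotary" (diameters across a
    disc of scan_diameter μm); axial_kernel_fwhm: detector-bandwidth depth
    blur (μm); jitter: optional lateral drift model.
    """

    spot_fwhm: float = 9.9
    step: float = 10.0
    trajectory: str = "raster"
    pixels: tuple[int, int] = (300, 300)
    scan_diameter: float = 5000.0
    axial_kernel_fwhm: float = 30.0
    jitter: Optional[JitterModel] = None

    def __post_init__(self) -> None:
        if self.spot_fwhm <= 0 or self.step <= 0:
            raise ValueError("spot_fwhm and step must be positive")
        if self.trajectory not in ("raster", "rotary"):
            raise ValueError(f"unknown trajectory {self.trajectory!r}")
        if self.trajectory == "raster" and min(self.pixels) < 2:
            raise ValueError("raster scan needs pixels >= (2, 2)")


@dataclass
class ScanVolume:
    """A-lines on a lateral scan grid: a_lines[ix, iy, iz], coords in μm.

    Depth sampling equals the source map's depth pitch (the c·dt/2
    equivalent of the acquisition) and is recorded in ``depth_coords``.
    """

    a_lines: np.ndarray
    x_coords: np.ndarray
    y_coords: np.ndarray
    depth_coords: np.ndarray
    config: ScanConfig

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.a_lines)):
            raise ValueError("A-lines must be finite")

    @property
    def depth_spacing(self) -> float:
        return float(self.depth_coords[1] - self.depth_coords[0]) \
            if len(self.depth_coords) > 1 else 0.0


def _blur_map(map3d: AbsorptionMap, config: ScanConfig) -> np.ndarray:
    sigmas = [config.spot_fwhm / _FWHM / map3d.spacing[0],
              config.spot_fwhm / _FWHM / map3d.spacing[1],
              config.axial_kernel_fwhm / _FWHM / map3d.spacing[2]]
    return ndimage.gaussian_filter(map3d.values, sigma=sigmas, mode="constant")


def _sample_a_lines(blurred: np.ndarray, map3d: AbsorptionMap,
                    xy_um: np.ndarray) -> np.ndarray:
    """Linearly interpolate full-depth A-lines at lateral positions (n, 2) μm."""
    ix = (xy_um[:, 0] - map3d.origin[0]) / map3d.spacing[0]
    iy = (xy_um[:, 1] - map3d.origin[1]) / map3d.spacing[1]
    nz = blurred.shape[2]
    out = np.empty((xy_um.shape[0], nz))
    coords = np.empty((2, xy_um.shape[0]))
    coords[0] = ix
    coords[1] = iy
    for iz in range(nz):
        out[:, iz] = ndimage.map_coordinates(blurred[:, :, iz], coords,
                                             order=1, mode="constant")
    return out


def _apply_jitter(xy: np.ndarray, jitter: Optional[JitterModel]) -> np.ndarray:
    if jitter is None:
        return xy
    rng = np.random.default_rng(jitter.seed)
    drift = np.cumsum(rng.normal(0.0, jitter.drift_per_line, (xy.shape[0], 2)), axis=0)
    return xy + drift


def scan(map3d: AbsorptionMap, config: ScanConfig,
         medium: MediumProperties) -> ScanVolume:
    """Simulate an OR-PAM scan of a 3-D absorption map.

    Each A-line is the map blurred laterally by the optical spot and
    axially by the detector kernel, sampled at the scan position and scaled
    by the Gruneisen coefficient.  Rotary trajectories sample evenly
    rotated diameters across the disc and regrid to Cartesian by linear
    interpolation.  The scan extent must fit inside the map.
    """
    if map3d.ndim != 3:
        raise ValueError("OR-PAM scanning needs a 3-D absorption map")
    tau = gruneisen(medium)
    blurred = tau * _blur_map(map3d, config)
    ext = map3d.extent()

    if config.trajectory == "raster":
        nx, ny = config.pixels
        span_x = (nx - 1) * config.step
        span_y = (ny - 1) * config.step
        for span, axis in ((span_x, 0), (span_y, 1)):
            if span > ext[axis]:
                raise ValueError(
                    f"scan extent {span:.0f} μm exceeds map extent "
                    f"{ext[axis]:.0f} μm on axis {axis}")
        x0 = map3d.origin[0] + 0.5 * (ext[0] - span_x)
        y0 = map3d.origin[1] + 0.5 * (ext[1] - span_y)
        xs = x0 + config.step * np.arange(nx)
        ys = y0 + config.step * np.arange(ny)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        xy = np.stack([gx.ravel(), gy.ravel()], axis=-1)
        xy = _apply_jitter(xy, config.jitter)
        a = _sample_a_lines(blurred, map3d, xy)
        volume = a.reshape(nx, ny, -1)
        return ScanVolume(a_lines=volume, x_coords=xs, y_coords=ys,
                          depth_coords=map3d.coords(2), config=config)

    # rotary: diameters through the disc centre, arc step <= step at the rim
    radius = config.scan_diameter / 2.0
    if config.scan_diameter > min(ext[0], ext[1]):
        raise ValueError(
            f"rotary scan diameter {config.scan_diameter:.0f} μm exceeds map "
            f"lateral extent {min(ext[0], ext[1]):.0f} μm")
    cx = map3d.origin[0] + 0.5 * ext[0]
    cy = map3d.origin[1] + 0.5 * ext[1]
    n_angles = max(2, int(math.ceil(math.pi * radius / config.step)))
    radial = np.arange(-radius, radius + 0.5 * config.step, config.step)
    pts = []
    for k in range(n_angles):
        ang = math.pi * k / n_angles
        ux, uy = math.cos(ang), math.sin(ang)
        for r in radial:
            pts.append((cx + r * ux, cy + r * uy))
    xy = np.array(pts)
    xy = _apply_jitter(xy, config.jitter)
    a = _sample_a_lines(blurred, map3d, xy)

    n_out = len(radial)
    xs = cx + np.linspace(-radius, radius, n_out)
    ys = cy + np.linspace(-radius, radius, n_out)
    interp = LinearNDInterpolator(xy, a, fill_value=0.0)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    volume = interp(np.stack([gx.ravel(), gy.ravel()], axis=-1)).reshape(
        n_out, n_out, -1)
    return ScanVolume(a_lines=volume, x_coords=xs, y_coords=ys,
                      depth_coords=map3d.coords(2), config=config)


def bscan(volume: ScanVolume, line_index: int, axis: int = 0) -> np.ndarray:
    """One (lateral × depth) slice: scan line ``line_index`` along ``axis``."""
    n_lines = volume.a_lines.shape[1 - axis]
    if not (0 <= line_index < n_lines):
        raise IndexError(f"line index {line_index} out of range [0, {n_lines})")
    return volume.a_lines[:, line_index, :] if axis == 0 \
        else volume.a_lines[line_index, :, :]


def max_projection(volume: Union[ScanVolume, np.ndarray]) -> np.ndarray:
    """Maximum-amplitude projection (MAP) along depth."""
    a = volume.a_lines if isinstance(volume, ScanVolume) else np.asarray(volume)
    if a.size == 0:
        raise ValueError("empty volume")
    return a.max(axis=-1)


def max_projection_profile(bscan_image: np.ndarray) -> np.ndarray:
    """1-D lateral profile: maximum of a B-scan along its depth axis."""
    return np.asarray(bscan_image).max(axis=-1)


def depth_section(volume, depth: float, thickness: float) -> np.ndarray:
    """Maximum over the depth slab [depth − t/2, depth + t/2] (μm).

    Accepts a ScanVolume or a 3-D AbsorptionMap.
    """
    if isinstance(volume, ScanVolume):
        zc = np.asarray(volume.depth_coords)
        a = volume.a_lines
    else:
        zc = volume.coords(volume.ndim - 1)
        a = volume.values
    sel = (zc >= depth - thickness / 2.0) & (zc <= depth + thickness / 2.0)
    if not np.any(sel):
        raise ValueError(f"empty depth slab at {depth} ± {thickness / 2} μm "
                         f"(axis spans {zc[0]:.0f}–{zc[-1]:.0f} μm)")
    return a[..., sel].max(axis=-1)


def detector_uniformity_curve(sensitivity: SensitivityModel, positions,
                              focal_zone: Optional[float] = None
                              ) -> tuple[np.ndarray, float]:
    """Detector response along a scan diameter plus its uniformity ratio.

    A virtual element looks along +x from the origin at its focal distance;
    ``positions`` are lateral offsets (μm) across the scan diameter.
    Returns (curve, min/max ratio within the focal zone, default the
    model's focal half-width).  Line-focused detectors are flat inside the
    focal slab (ratio 1); flat-field directivity decays off-axis, so its
    ratio is strictly smaller.
    """
    positions = np.asarray(positions, dtype=float)
    element = np.array([0.0, 0.0])
    axis_dir = np.array([1.0, 0.0])
    pts = np.stack([np.full_like(positions, sensitivity.focal_distance),
                    positions], axis=-1)
    curve = sensitivity.weight(element, axis_dir, pts)
    if focal_zone is None:
        focal_zone = sensitivity.focal_half_width
    inside = np.abs(positions) <= focal_zone
    if not np.any(inside):
        raise ValueError("no sample positions inside the focal zone")
    zone = curve[inside]
    ratio = float(zone.min() / zone.max()) if zone.max() > 0 else 0.0
    return curve, ratio
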