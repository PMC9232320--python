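"""Synthetic absorption-map phantoms: resolution targets and vasculature.

Generators emulate the imaging targets used to characterise a
photoacoustic system: point absorbers and thin filaments (carbon fiber /
hair) for resolution metrology, agar blocks with absorbing inclusions, and
layered oral-mucosa capillary networks — superficial loop-like capillaries,
a deeper reticular mesh, and large trunk vessels — for the microscopy
image products.

All shapes are rasterized with partial-coverage (area-fraction)
anti-aliasing: a node whose cell straddles the shape boundary receives a
fractional amplitude, so sub-pixel structures such as an 8.2 μm filament
remain representable on practical grids.  Every generator is a pure
function of its arguments and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .grids import AbsorptionMap

__all__ = [
    "VesselLayerSpec",
    "make_point_targets",
    "make_fiber",
    "make_uniform_sphere",
    "make_vessel_network",
    "make_agar_phantom",
    "default_oral_layers",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VesselLayerSpec:
    """One depth layer of a vascular phantom.

    depth: layer centre depth (μm); vessel_kind: "loop" (U-shaped superficial
    capillaries), "reticular" (branching polyline mesh) or "trunk" (few thick
    smoothly curved tubes); diameter_range: (min, max) vessel diameter (μm);
    count_density: structures per mm²; seed: per-layer RNG stream offset.
    """

    depth: float
    vessel_kind: str
    diameter_range: tuple[float, float]
    count_density: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        lo, hi = self.diameter_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid diameter_range {self.diameter_range}")
        if self.count_density < 0:
            raise ValueError("count_density must be non-negative")
        if self.vessel_kind not in ("loop", "reticular", "trunk"):
            raise ValueError(f"unknown vessel_kind {self.vessel_kind!r}")


def _empty(shape, spacing) -> AbsorptionMap:
    return AbsorptionMap(values=np.zeros(shape, dtype=float), spacing=spacing)


def make_point_targets(positions: Sequence[Sequence[float]], amplitude: float,
                       shape: Sequence[int], spacing) -> AbsorptionMap:
    """Map that is zero except at the grid nodes nearest the given positions (μm)."""
    amap = _empty(shape, spacing)
    for pos in positions:
        amap.values[amap.index_of(pos)] = amplitude
    return amap


def _coverage(distance: np.ndarray, radius: float, pitch: float) -> np.ndarray:
    """Fractional cell coverage from centre distance: linear ramp of one pitch
    across the boundary (exact for a half-plane edge, first-order for curved)."""
    return np.clip(0.5 + (radius - distance) / pitch, 0.0, 1.0)


_SUBSAMPLES = 5  # per-axis subdivision for area-fraction anti-aliasing


def _subcell_offsets(spacing: float) -> np.ndarray:
    k = np.arange(_SUBSAMPLES)
    return ((k + 0.5) / _SUBSAMPLES - 0.5) * spacing


def make_fiber(diameter: float, orientation, amplitude: float,
               shape: Sequence[int], spacing,
               center: Optional[Sequence[float]] = None) -> AbsorptionMap:
    """Straight filament crossing the whole grid.

    3-D: a cylinder whose axis runs along ``orientation`` (axis index 0/1 or
    an angle in degrees within the lateral plane) at the depth given by
    ``center``; 2-D: a band of the same circular footprint in-plane.
    Sub-pixel diameters yield a single-node-wide line of fractional amplitude.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    amap = _empty(shape, spacing)
    ndim = amap.ndim
    if center is None:
        center = [0.5 * (n - 1) * s for n, s in zip(amap.shape, amap.spacing)]
    center = np.asarray(center, dtype=float)

    if isinstance(orientation, str):
        orientation = {"x": 0, "y": 1}[orientation.lower()]
    if isinstance(orientation, (int, np.integer)):
        angle = 0.0 if orientation == 0 else 90.0
    else:
        angle = float(orientation)
    theta = math.radians(angle)
    # unit axis direction in the lateral plane (axes 0 and 1)
    direction = np.zeros(ndim)
    direction[0] = math.cos(theta)
    direction[1] = math.sin(theta)

    grids = np.meshgrid(*[amap.coords(ax) for ax in range(ndim)], indexing="ij")
    rel = [g - c for g, c in zip(grids, center)]

    # area-fraction anti-aliasing: average the inside indicator over a
    # subgrid of each cell.  Offsets parallel to a grid-aligned fiber axis
    # do not change the distance, so that axis is not subdivided.
    radius = diameter / 2.0
    coverage = np.zeros(amap.shape)
    offset_grids = [_subcell_offsets(amap.spacing[ax]) for ax in range(ndim)]
    if abs(abs(direction[0]) - 1.0) < 1e-12:
        offset_grids[0] = np.zeros(1)
    elif abs(abs(direction[1]) - 1.0) < 1e-12:
        offset_grids[1] = np.zeros(1)
    combos = np.stack(np.meshgrid(*offset_grids, indexing="ij"),
                      axis=-1).reshape(-1, ndim)
    weight = 1.0 / len(combos)
    for off in combos:
        shifted = [r + o for r, o in zip(rel, off)]
        along = sum(s * d for s, d in zip(shifted, direction))
        dist_sq = sum(s * s for s in shifted) - along ** 2
        coverage += dist_sq <= radius * radius
    amap.values[:] = amplitude * weight * coverage
    return amap


def make_uniform_sphere(radius: float, center: Sequence[float], amplitude: float,
                        shape: Sequence[int], spacing) -> AbsorptionMap:
    """Uniform ball (3-D) or disc (2-D) with partial-coverage edge weighting."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    amap = _empty(shape, spacing)
    if radius == 0:
        return amap
    center = np.asarray(center, dtype=float)
    for ax in range(amap.ndim):
        lo, hi = amap.origin[ax], amap.origin[ax] + (amap.shape[ax] - 1) * amap.spacing[ax]
        if center[ax] - radius < lo - 0.5 * amap.spacing[ax] or \
           center[ax] + radius > hi + 0.5 * amap.spacing[ax]:
            raise ValueError(f"sphere extends outside grid extent on axis {ax}")
    grids = np.meshgrid(*[amap.coords(ax) for ax in range(amap.ndim)], indexing="ij")
    rel = [g - c for g, c in zip(grids, center)]
    coverage = np.zeros(amap.shape)
    offset_grids = [_subcell_offsets(amap.spacing[ax]) for ax in range(amap.ndim)]
    combos = np.stack(np.meshgrid(*offset_grids, indexing="ij"),
                      axis=-1).reshape(-1, amap.ndim)
    for off in combos:
        dist_sq = sum((r + o) ** 2 for r, o in zip(rel, off))
        coverage += dist_sq <= radius * radius
    amap.values[:] = amplitude * coverage / len(combos)
    return amap


def _add_capsule(values: np.ndarray, spacing, p0, p1, radius: float,
                 amplitude: float) -> None:
    """Max-compose a finite cylinder with hemispherical caps between two
    physical points (μm) into ``values``, cropped to its bounding box."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    pitch = float(spacing.min())
    pad = radius + pitch
    lo_idx, hi_idx = [], []
    for ax in range(values.ndim):
        lo = min(p0[ax], p1[ax]) - pad
        hi = max(p0[ax], p1[ax]) + pad
        lo_idx.append(max(0, int(math.floor(lo / spacing[ax]))))
        hi_idx.append(min(values.shape[ax], int(math.ceil(hi / spacing[ax])) + 1))
    if any(l >= h for l, h in zip(lo_idx, hi_idx)):
        return
    sl = tuple(slice(l, h) for l, h in zip(lo_idx, hi_idx))
    axes = [np.arange(l, h) * s for l, h, s in zip(lo_idx, hi_idx, spacing)]
    grids = np.meshgrid(*axes, indexing="ij")
    d = p1 - p0
    seg_len_sq = float(d @ d)
    rel = [g - c for g, c in zip(grids, p0)]
    if seg_len_sq == 0.0:
        dist = np.sqrt(sum(r * r for r in rel))
    else:
        t = sum(r * dd for r, dd in zip(rel, d)) / seg_len_sq
        np.clip(t, 0.0, 1.0, out=t)
        dist = np.sqrt(sum((r - t * dd) ** 2 for r, dd in zip(rel, d)))
    np.maximum(values[sl], amplitude * _coverage(dist, radius, pitch), out=values[sl])


def _rasterize_polyline(values, spacing, points, radius, amplitude) -> None:
    for a, b in zip(points[:-1], points[1:]):
        _add_capsule(values, spacing, a, b, radius, amplitude)


def _loop_polyline(center_xy, depth, diameter, angle, rng) -> np.ndarray:
    """U-shaped capillary loop: two near-parallel limbs joined by a
    semicircular apex.  Limb length 3–6 diameters, apex radius 1–2."""
    limb = rng.uniform(3.0, 6.0) * diameter
    apex_r = rng.uniform(1.0, 2.0) * diameter
    u = np.array([math.cos(angle), math.sin(angle)])   # limb direction
    v = np.array([-u[1], u[0]])                        # across the loop
    base = np.asarray(center_xy) - 0.5 * limb * u
    pts = []
    for side in (-1.0, 1.0):
        start = base + side * apex_r * v
        pts.append([start, start + limb * u])
    arc = [base + limb * u + apex_r * (math.sin(t) * u - math.cos(t) * v)
           for t in np.linspace(0.0, math.pi, 9)]
    path = pts[0] + arc + pts[1][::-1]
    return np.array([[p[0], p[1], depth] for p in path])


def make_vessel_network(layers: Sequence[VesselLayerSpec], shape: Sequence[int],
                        spacing, seed: int = 0,
                        amplitude: float = 100.0) -> AbsorptionMap:
    """3-D layered vascular phantom, bitwise reproducible under ``seed``.

    Each layer populates its depth plane with structures of its kind;
    overlaps compose by elementwise maximum.  Structure counts are Poisson
    in the lateral area at ``count_density`` per mm².
    """
    amap = _empty(shape, spacing)
    if not layers:
        logger.warning("make_vessel_network called with no layers; returning zeros")
        return amap
    ext = amap.extent()
    depth_ext = ext[-1]
    area_mm2 = (ext[0] / 1000.0) * (ext[1] / 1000.0)
    for layer in layers:
        if layer.depth > depth_ext:
            raise ValueError(f"layer depth {layer.depth} μm outside grid depth "
                             f"extent {depth_ext} μm")
        rng = np.random.default_rng([int(seed), int(layer.seed), 0xA17])
        count = int(rng.poisson(layer.count_density * area_mm2))
        # a specified layer is always populated: the Poisson draw sets the
        # density beyond the first structure
        if layer.count_density > 0:
            count = max(1, count)
        for _ in range(count):
            diam = rng.uniform(*layer.diameter_range)
            cx = rng.uniform(0, ext[0])
            cy = rng.uniform(0, ext[1])
            angle = rng.uniform(0, 2 * math.pi)
            if layer.vessel_kind == "loop":
                path = _loop_polyline((cx, cy), layer.depth, diam, angle, rng)
            elif layer.vessel_kind == "reticular":
                path = _meander((cx, cy), layer.depth, angle, rng,
                                n_seg=rng.integers(4, 8),
                                step=rng.uniform(6, 10) * diam)
            else:  # trunk
                path = _meander((cx, cy), layer.depth, angle, rng,
                                n_seg=rng.integers(6, 10),
                                step=rng.uniform(4, 7) * diam, wobble=0.25)
            _rasterize_polyline(amap.values, amap.spacing, path, diam / 2.0, amplitude)
            # reticular meshes branch: spawn a side polyline from a midpoint
            if layer.vessel_kind == "reticular" and rng.random() < 0.7:
                mid = path[len(path) // 2]
                branch = _meander(mid[:2], layer.depth, angle + rng.uniform(0.6, 1.2),
                                  rng, n_seg=3, step=rng.uniform(5, 8) * diam)
                _rasterize_polyline(amap.values, amap.spacing, branch,
                                    diam / 2.0, amplitude)
    return amap


def _meander(start_xy, depth, angle, rng, n_seg, step, wobble=0.6) -> np.ndarray:
    """Random polyline wandering in-plane; smaller wobble gives smoother tubes."""
    pts = [np.array([start_xy[0], start_xy[1], depth])]
    a = angle
    for _ in range(int(n_seg)):
        a += rng.uniform(-wobble, wobble)
        nxt = pts[-1] + np.array([step * math.cos(a), step * math.sin(a), 0.0])
        pts.append(nxt)
    return np.array(pts)


def default_oral_layers(seed: int = 0) -> list[VesselLayerSpec]:
    """Three-layer oral-mucosa phantom: superficial capillary loops at
    ~100 μm, a reticular mesh at ~500 μm, and thick trunks at ~1 mm, with
    vessel diameter increasing with depth."""
    return [
        VesselLayerSpec(depth=100.0, vessel_kind="loop",
                        diameter_range=(8.0, 15.0), count_density=30.0, seed=seed + 1),
        VesselLayerSpec(depth=500.0, vessel_kind="reticular",
                        diameter_range=(25.0, 45.0), count_density=6.0, seed=seed + 2),
        VesselLayerSpec(depth=1000.0, vessel_kind="trunk",
                        diameter_range=(80.0, 120.0), count_density=1.5, seed=seed + 3),
    ]


def make_agar_phantom(background_mu: float, inclusions: Sequence[dict],
                      shape: Sequence[int], spacing, seed: int = 0) -> AbsorptionMap:
    """Agar-block stand-in: low uniform background absorption plus embedded
    fiber/sphere inclusions, composed by elementwise maximum.

    Each inclusion is a dict with ``kind`` ("fiber" or "sphere") and the
    keyword arguments of the corresponding generator.
    """
    if background_mu < 0:
        raise ValueError("background_mu must be non-negative")
    amap = _empty(shape, spacing)
    amap.values[:] = background_mu
    for spec in inclusions:
        spec = dict(spec)
        kind = spec.pop("kind")
        if kind == "fiber":
            inc = make_fiber(shape=shape, spacing=spacing, **spec)
        elif kind == "sphere":
            inc = make_uniform_sphere(shape=shape, spacing=spacing, **spec)
        else:
            raise ValueError(f"unknown inclusion kind {kind!r}")
        np.maximum(amap.values, inc.values, out=amap.values)
    return amap
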