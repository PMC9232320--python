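"""Raster containers shared across the toolkit.

All imaging grids carry a physical pixel pitch in micrometres.  Node
``(i, j[, k])`` sits at physical coordinate ``origin + index * spacing``;
indices are 0-based and the last axis is depth, increasing away from the
scanned surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AbsorptionMap", "PressureField", "TemperatureField"]


@dataclass
class _RasterField:
    """A scalar field on a regular grid with physical spacing in micrometres."""

    values: np.ndarray
    spacing: tuple[float, ...]
    origin: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError(f"grid must be 2-D or 3-D, got ndim={self.values.ndim}")
        spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (self.values.ndim,)))
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive, got {spacing}")
        self.spacing = spacing
        if not self.origin:
            self.origin = (0.0,) * self.values.ndim
        else:
            self.origin = tuple(float(o) for o in self.origin)
        if len(self.origin) != self.values.ndim:
            raise ValueError("origin dimensionality does not match values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def extent(self) -> tuple[float, ...]:
        """Physical size of the grid per axis in micrometres (shape × spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def coords(self, axis: int) -> np.ndarray:
        """Physical node-centre coordinates along one axis (μm)."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def index_of(self, position) -> tuple[int, ...]:
        """Nearest grid index to a physical position (μm); errors if outside."""
        position = np.asarray(position, dtype=float)
        idx = []
        for ax, p in enumerate(position):
            i = int(round((p - self.origin[ax]) / self.spacing[ax]))
            if not (0 <= i < self.shape[ax]):
                raise ValueError(
                    f"position {tuple(position)} outside grid extent on axis {ax}"
                )
            idx.append(i)
        return tuple(idx)

    def like(self, values: np.ndarray):
        return type(self)(values=values, spacing=self.spacing, origin=self.origin)


@dataclass
class AbsorptionMap(_RasterField):
    """Light-absorption coefficient θ_c per node (1/m) on a 2-D/3-D grid.

    Multiplying by a time-integrated fluence (J/m²) yields the absorbed
    optical energy density X_p (J/m³) that drives the photoacoustic source.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < 0):
            raise ValueError("absorption coefficients must be non-negative")


@dataclass
class PressureField(_RasterField):
    """Initial acoustic pressure p0 per node (Pa), same grid as its source map."""


@dataclass
class TemperatureField(_RasterField):
    """Temperature rise per node (K), same grid as its source map."""
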