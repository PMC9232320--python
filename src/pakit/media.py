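"""Thermoacoustic medium properties and the optical-to-acoustic energy chain.

A short laser pulse absorbed in tissue deposits an energy density X_p
(J/m³).  Under thermal and stress confinement — pulse much shorter than both
the thermal relaxation time T_r = l² / D and the stress relaxation time
T_y = l / c of the heated feature of size l — conduction during deposition
is negligible and the absorbed energy converts to an initial pressure

    p0 = Γ · X_p,

where Γ is the dimensionless Gruneisen coefficient, Γ = μ c² / Q_p for a
medium with volumetric thermal-expansion coefficient μ, sound speed c and
isobaric specific heat Q_p.  Room-temperature values are about 0.11 for
water and 0.25 for soft tissue; the built-in presets pin exactly those.

All quantities here are SI; the imaging modules use micrometres for grid
geometry and convert internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .grids import PressureField, TemperatureField

__all__ = [
    "MediumProperties",
    "get_preset",
    "PRESETS",
    "relaxation_times",
    "confinement_satisfied",
    "relative_volume_change",
    "compressibility",
    "temperature_rise",
    "gruneisen",
    "initial_pressure",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MediumProperties:
    """Physical constants of a propagation/absorption medium (SI units).

    Parameters
    ----------
    density_rho : mass density ρ (kg/m³).
    heat_capacity_p : isobaric specific heat Q_p (J/(kg·K)).
    heat_capacity_v : isochoric specific heat Q_v (J/(kg·K)).
    thermal_expansion : volumetric thermal expansion coefficient μ (1/K).
    sound_speed : ultrasound propagation speed c (m/s).
    thermal_diffusivity : D (m²/s).
    compressibility_s : isothermal compressibility (1/Pa); computed from the
        other constants when left ``None``.
    char_length : characteristic length of the thermal inhomogeneity (m),
        optional default for the relaxation-time computation.
    gruneisen_override : dimensionless Γ pinned for this medium; when set it
        takes precedence over the μ c² / Q_p formula.
    """

    name: str
    density_rho: float
    heat_capacity_p: float
    heat_capacity_v: float
    thermal_expansion: float
    sound_speed: float
    thermal_diffusivity: float
    compressibility_s: Optional[float] = None
    char_length: Optional[float] = None
    gruneisen_override: Optional[float] = None

    def __post_init__(self) -> None:
        for attr in ("density_rho", "heat_capacity_p", "heat_capacity_v",
                     "sound_speed", "thermal_diffusivity"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive, got {getattr(self, attr)}")
        if self.gruneisen_override is not None and not (0 < self.gruneisen_override < 2):
            raise ValueError(
                f"gruneisen_override must lie in (0, 2), got {self.gruneisen_override}"
            )

    def to_dict(self) -> dict:
        out = {
            "name": self.name,
            "density_rho": self.density_rho,
            "heat_capacity_p": self.heat_capacity_p,
            "heat_capacity_v": self.heat_capacity_v,
            "thermal_expansion": self.thermal_expansion,
            "sound_speed": self.sound_speed,
            "thermal_diffusivity": self.thermal_diffusivity,
        }
        for key in ("compressibility_s", "char_length", "gruneisen_override"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "MediumProperties":
        return cls(**d)


# Room-temperature presets.  Gruneisen values are pinned (0.11 water,
# 0.25 soft tissue); soft tissue carries μ = 4e-4 1/K and c = 1500 m/s.
PRESETS: dict[str, MediumProperties] = {
    "water": MediumProperties(
        name="water",
        density_rho=1000.0,
        heat_capacity_p=4180.0,
        heat_capacity_v=4130.0,
        thermal_expansion=2.1e-4,
        sound_speed=1480.0,
        thermal_diffusivity=1.43e-7,
        gruneisen_override=0.11,
    ),
    "soft_tissue": MediumProperties(
        name="soft_tissue",
        density_rho=1050.0,
        heat_capacity_p=3600.0,
        heat_capacity_v=3560.0,
        thermal_expansion=4e-4,
        sound_speed=1500.0,
        thermal_diffusivity=1.4e-7,
        gruneisen_override=0.25,
    ),
}


def get_preset(name: str) -> MediumProperties:
    """Return a built-in medium preset ("water" or "soft_tissue")."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown medium preset {name!r}; have {sorted(PRESETS)}") from None


def relaxation_times(medium: MediumProperties,
                     char_length: Optional[float] = None) -> tuple[float, float]:
    """Thermal and stress relaxation times of a heated feature.

    T_r = l²/D is the time for heat to diffuse across the feature;
    T_y = l/c is the time for a stress wave to traverse it.

    Parameters
    ----------
    char_length : feature size l in metres; falls back to the medium's
        ``char_length`` when omitted.

    Returns
    -------
    (thermal_time, stress_time) in seconds.
    """
    if char_length is None:
        char_length = medium.char_length
    if char_length is None or char_length <= 0:
        raise ValueError(f"char_length must be positive, got {char_length}")
    thermal_time = char_length ** 2 / medium.thermal_diffusivity
    stress_time = char_length / medium.sound_speed
    return thermal_time, stress_time


def confinement_satisfied(pulse_width: float, thermal_time: float,
                          stress_time: float, ratio_threshold: float = 0.1) -> bool:
    """Whether a pulse is short enough for thermal and stress confinement.

    True iff pulse_width ≤ ratio_threshold × min(T_r, T_y); the default
    threshold of 0.1 encodes "much smaller than".
    """
    for name, val in (("pulse_width", pulse_width), ("thermal_time", thermal_time),
                      ("stress_time", stress_time), ("ratio_threshold", ratio_threshold)):
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    return pulse_width <= ratio_threshold * min(thermal_time, stress_time)


def relative_volume_change(medium: MediumProperties, pressure: float,
                           temperature: float) -> float:
    """Diagnostic fractional volume change dV/V = -s·p + μ·ΔT.

    Under confinement this is ≈ 0; exposed only as a check, the imaging
    chain assumes it vanishes.
    """
    s = compressibility(medium)
    return -s * pressure + medium.thermal_expansion * temperature


def compressibility(medium: MediumProperties) -> float:
    """Isothermal compressibility s = Q_p / (ρ c² Q_v) in 1/Pa.

    An explicitly stored ``compressibility_s`` on the medium wins over the
    computed value.
    """
    if medium.compressibility_s is not None:
        return medium.compressibility_s
    return medium.heat_capacity_p / (
        medium.density_rho * medium.sound_speed ** 2 * medium.heat_capacity_v
    )


def temperature_rise(absorbed_energy, medium: MediumProperties) -> TemperatureField:
    """Temperature rise ΔT = X_p / (ρ Q_v) for absorbed energy density X_p (J/m³).

    Assumes 100% photothermal conversion.  Accepts a raster field or a bare
    array (spacing defaults to 1 μm for bare arrays).
    """
    values, spacing, origin = _unpack_field(absorbed_energy)
    if np.any(values < 0):
        raise ValueError("absorbed energy density must be non-negative")
    w = values / (medium.density_rho * medium.heat_capacity_v)
    return TemperatureField(values=w, spacing=spacing, origin=origin)


def gruneisen(medium: MediumProperties) -> float:
    """Gruneisen coefficient Γ: efficiency of light-to-pressure conversion.

    Returns the medium's pinned override when present, otherwise
    Γ = μ c² / Q_p.  Values outside (0, 2) are physically implausible and
    logged as a warning, but still returned.
    """
    if medium.gruneisen_override is not None:
        return medium.gruneisen_override
    tau = medium.thermal_expansion * medium.sound_speed ** 2 / medium.heat_capacity_p
    if not (0 < tau < 2):
        logger.warning("computed Gruneisen coefficient %.3g outside (0, 2) for %s",
                       tau, medium.name)
    return tau


def initial_pressure(absorbed_energy, tau: float) -> PressureField:
    """Initial pressure p0 = Γ · X_p (Pa) from absorbed energy density (J/m³)."""
    if not (tau > 0) or not math.isfinite(tau):
        raise ValueError(f"tau must be positive and finite, got {tau}")
    values, spacing, origin = _unpack_field(absorbed_energy)
    return PressureField(values=tau * values, spacing=spacing, origin=origin)


def _unpack_field(field) -> tuple[np.ndarray, tuple, tuple]:
    if hasattr(field, "values") and hasattr(field, "spacing"):
        return np.asarray(field.values, dtype=float), field.spacing, field.origin
    values = np.asarray(field, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("field values must be finite")
    return values, (1.0,) * values.ndim, (0.0,) * values.ndim
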