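"""Time-domain photoacoustic forward model on a circular transducer array.

The free-space Green's-function solution of the photoacoustic wave equation
says that the pressure recorded at a detector is, up to constants, the time
derivative of the spherical-shell integral of the initial pressure p0
divided by distance:

    p(r, t) = 1/(4π c²) · ∂/∂t [ c ∮_{|r−r'| = c t} p0(r') / |r−r'| dA ].

Discretization follows the shell-binning scheme: each voxel contributes
p0 · V_voxel / r to the time bins whose distance interval its own radial
footprint overlaps, with fractional (partial-shell) weights.  The *delta*
pulse response is defined as exactly this non-negative geometry sum; a
finite *gaussian* pulse convolves it with the pulse derivative L'(t) and
the 1/(4π c²) factor, producing the physical bipolar waveform (the N-wave
for a uniform sphere).  Absolute pressure calibration is otherwise out of
scope — relative amplitudes are the contract.

Geometry is 3-D throughout; 2-D maps are treated as a one-voxel-thick slab
so the same kernel and the analytic sphere oracle apply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import sparse

from .media import MediumProperties

__all__ = [
    "TransducerArray",
    "SensitivityModel",
    "PulseShape",
    "IlluminationModel",
    "SignalSet",
    "NoiseModel",
    "simulate_signals",
    "analytic_sphere_signal",
    "add_noise",
    "default_ring_array",
    "default_dt",
]

_UM = 1e-6  # micrometres → metres


@dataclass(frozen=True)
class SensitivityModel:
    """Per-source-position detector weighting.

    kind "ideal": weight 1 everywhere.  "line_focused": weight 1 inside a
    slab of ``focal_half_width`` (μm) around the element's focal line, with
    a cosine roll-off over ``rolloff`` (μm) outside.  "flat_field": cosine
    directivity raised to ``directivity_power``, decaying with off-axis
    angle seen from the element at ``focal_distance`` (μm).
    """

    kind: str = "ideal"
    focal_half_width: float = 500.0
    rolloff: float = 800.0
    focal_distance: float = 5000.0
    directivity_power: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("ideal", "line_focused", "flat_field"):
            raise ValueError(f"unknown sensitivity kind {self.kind!r}")

    def weight(self, element_pos: np.ndarray, axis_dir: np.ndarray,
               source_pos: np.ndarray) -> np.ndarray:
        """Weight for source positions (..., ndim), all coordinates in μm."""
        if self.kind == "ideal":
            return np.ones(source_pos.shape[:-1])
        rel = source_pos - element_pos
        along = rel @ axis_dir
        perp = np.linalg.norm(rel - along[..., None] * axis_dir, axis=-1)
        if self.kind == "line_focused":
            over = np.maximum(perp - self.focal_half_width, 0.0) / self.rolloff
            return np.cos(np.minimum(over, 1.0) * (math.pi / 2)) ** 2
        # flat_field: directivity cosine of the off-axis angle
        dist = np.linalg.norm(rel, axis=-1)
        cos_theta = np.divide(along, dist, out=np.ones_like(dist), where=dist > 0)
        return np.clip(cos_theta, 0.0, 1.0) ** self.directivity_power


@dataclass(frozen=True)
class TransducerArray:
    """Detector element positions (μm) with a shared sensitivity model.

    ``axis_dirs`` are unit vectors along each element's look direction
    (towards the array centre for a ring).
    """

    element_positions: np.ndarray
    axis_dirs: np.ndarray
    sensitivity: SensitivityModel = field(default_factory=SensitivityModel)

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.element_positions, dtype=float))
        object.__setattr__(self, "element_positions", pos)
        dirs = np.atleast_2d(np.asarray(self.axis_dirs, dtype=float))
        norms = np.linalg.norm(dirs, axis=1, keepdims=True)
        object.__setattr__(self, "axis_dirs", dirs / np.where(norms > 0, norms, 1.0))
        if pos.shape[0] < 1:
            raise ValueError("need at least one element")
        if dirs.shape != pos.shape:
            raise ValueError("axis_dirs shape must match element_positions")

    @property
    def element_count(self) -> int:
        return self.element_positions.shape[0]


def default_ring_array(grid, n_elements: int = 64,
                       radius: Optional[float] = None,
                       sensitivity: Optional[SensitivityModel] = None) -> TransducerArray:
    """Annular array: elements equally spaced on a circle around the grid.

    The default radius is twice the grid half-extent, keeping every element
    outside the absorber support.  For 3-D grids the ring lies in the
    mid-depth plane.
    """
    ext = grid.extent()
    center = np.array([grid.origin[ax] + 0.5 * (grid.shape[ax] - 1) * grid.spacing[ax]
                       for ax in range(grid.ndim)])
    if radius is None:
        radius = float(max(ext[0], ext[1]))  # 2 × half-extent
    angles = 2 * math.pi * np.arange(n_elements) / n_elements
    pos = np.tile(center, (n_elements, 1))
    pos[:, 0] += radius * np.cos(angles)
    pos[:, 1] += radius * np.sin(angles)
    dirs = center - pos
    return TransducerArray(element_positions=pos, axis_dirs=dirs,
                           sensitivity=sensitivity or SensitivityModel())


@dataclass(frozen=True)
class PulseShape:
    """Laser pulse time profile L(t): "delta" or "gaussian" (FWHM ``width`` s).

    L integrates to 1; ``energy_scale`` multiplies the deposited energy.
    """

    kind: str = "delta"
    width: float = 10e-9
    energy_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("delta", "gaussian"):
            raise ValueError(f"unknown pulse kind {self.kind!r}")
        if self.kind == "gaussian" and self.width <= 0:
            raise ValueError("gaussian pulse needs positive width")


@dataclass(frozen=True)
class IlluminationModel:
    """Uniform-fluence illumination: X_p = θ_c × fluence (J/m²)."""

    fluence: float = 1.0
    pulse: PulseShape = field(default_factory=PulseShape)

    def __post_init__(self) -> None:
        if self.fluence < 0:
            raise ValueError("fluence must be non-negative")

    def absorbed_energy(self, absorption_map):
        """Absorbed energy density X_p (J/m³) from an AbsorptionMap (θ_c in 1/m)."""
        return absorption_map.like(absorption_map.values * self.fluence)


@dataclass
class SignalSet:
    """Stacked transducer time series: samples[element, time] in Pa.

    Flattening is element-major (``samples.ravel(order="C")``): the flat
    vector stacks element 0's full A-line, then element 1's, and so on.
    Its length H = element_count × n_t matches the system-matrix row count.
    """

    samples: np.ndarray
    dt: float
    t0: float = 0.0
    speed_of_sound: float = 1500.0
    element_positions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def element_count(self) -> int:
        return self.samples.shape[0]

    @property
    def n_t(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_t)

    def flatten(self) -> np.ndarray:
        return self.samples.ravel(order="C")


@dataclass(frozen=True)
class NoiseModel:
    """Additive zero-mean white gaussian noise at ``snr_db`` below peak signal.

    ``snr_db=None`` (or +inf) means no noise; ``sigma`` sets an absolute
    noise standard deviation instead of a peak-relative one.
    """

    kind: str = "gaussian_white"
    snr_db: Optional[float] = 40.0
    sigma: Optional[float] = None
    seed: int = 0


def default_dt(grid, medium: MediumProperties) -> float:
    """Sampling interval resolving the grid: dt = spacing / (2 c)."""
    return min(grid.spacing) * _UM / (2.0 * medium.sound_speed)


# ---------------------------------------------------------------------------
# shared assembly kernel (also the system-matrix backbone)

def _grid_coords_um(grid) -> np.ndarray:
    axes = [grid.coords(ax) for ax in range(grid.ndim)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel(order="C") for m in mesh], axis=-1)


def _voxel_volume_m3(grid) -> float:
    # 2-D maps are a slab one voxel thick
    vol = 1.0
    for s in grid.spacing:
        vol *= s * _UM
    if grid.ndim == 2:
        vol *= min(grid.spacing) * _UM
    return vol


def element_geometry_matrix(grid, element_pos: np.ndarray, axis_dir: np.ndarray,
                            sensitivity: SensitivityModel, dt: float, n_t: int,
                            t0: float, c: float) -> sparse.csr_matrix:
    """Sparse (n_t × X) delta-pulse weight block for one element.

    Entry (k, b) is voxel b's contribution to time bin k: V_vox/r times the
    fraction of the voxel's radial footprint [r − dr/2, r + dr/2] that falls
    in the bin's distance interval, times the sensitivity weight.  dr is the
    smallest voxel pitch, so each voxel spreads over the bins its own width
    crosses (partial-shell weighting).
    """
    coords = _grid_coords_um(grid)                      # (X, ndim) μm
    nvox = coords.shape[0]
    rel = (coords - element_pos) * _UM
    r = np.linalg.norm(rel, axis=1)                     # m
    pitch_m = min(grid.spacing) * _UM
    r = np.maximum(r, 0.5 * pitch_m)                    # guard: element on a node
    amp = (_voxel_volume_m3(grid) / r) * sensitivity.weight(
        element_pos, axis_dir, coords)

    # continuous bin coordinate of each voxel's radial interval
    b_center = (r / c - t0) / dt
    half = pitch_m / (2.0 * c * dt)
    lo = b_center - half
    hi = b_center + half
    k0 = np.floor(lo + 0.5).astype(np.int64)
    k1 = np.floor(hi + 0.5).astype(np.int64)
    max_span = int((k1 - k0).max()) + 1 if nvox else 1

    rows, cols, data = [], [], []
    vox_idx = np.arange(nvox)
    for j in range(max_span):
        k = k0 + j
        overlap = np.minimum(hi, k + 0.5) - np.maximum(lo, k - 0.5)
        sel = (k <= k1) & (overlap > 0) & (k >= 0) & (k < n_t)
        if not np.any(sel):
            continue
        rows.append(k[sel])
        cols.append(vox_idx[sel])
        data.append(amp[sel] * overlap[sel] / (2.0 * half))
    if rows:
        mat = sparse.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_t, nvox))
    else:
        mat = sparse.coo_matrix((n_t, nvox))
    out = mat.tocsr()
    out.sort_indices()
    return out


def pulse_convolution_matrix(pulse: PulseShape, dt: float, n_t: int,
                             c: float) -> Optional[sparse.csr_matrix]:
    """Banded (n_t × n_t) operator turning the delta geometry response into
    the physical waveform: convolution with L'(t)·dt times 1/(4π c² dt).

    Returns None for a delta pulse (the geometry sum is the contract there).
    """
    if pulse.kind == "delta":
        return None
    sigma = pulse.width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    m = max(1, int(math.ceil(4.0 * sigma / dt)))
    tk = np.arange(-m, m + 1) * dt
    # L(t) unit-area gaussian; L'(t) = -t/σ² L(t)
    l = np.exp(-0.5 * (tk / sigma) ** 2) / (sigma * math.sqrt(2.0 * math.pi))
    lprime = -tk / sigma ** 2 * l
    kernel = pulse.energy_scale * lprime / (4.0 * math.pi * c ** 2)
    # p_k = Σ_m kernel[m] · y_{k−m}  →  band at diagonal offset −m
    offsets = [-int(tau) for tau in np.arange(-m, m + 1)]
    mat = sparse.diags(kernel, offsets, shape=(n_t, n_t), format="csr")
    mat.sort_indices()
    return mat


def assemble_operator(grid, array: TransducerArray, pulse: PulseShape,
                      dt: float, n_t: int, medium: MediumProperties,
                      t0: float = 0.0):
    """Build (G_delta, conv) for the full array: G_delta is the stacked
    (H × X) delta geometry matrix, conv the block-diagonal (H × H) pulse
    operator (None for delta pulses).  The forward simulation and the
    explicit system matrix both run through these exact objects.
    """
    c = medium.sound_speed
    blocks = [element_geometry_matrix(grid, array.element_positions[e],
                                      array.axis_dirs[e], array.sensitivity,
                                      dt, n_t, t0, c)
              for e in range(array.element_count)]
    g_delta = sparse.vstack(blocks, format="csr")
    g_delta.sort_indices()
    conv1 = pulse_convolution_matrix(pulse, dt, n_t, c)
    if conv1 is None:
        conv = None
    else:
        conv = sparse.block_diag([conv1] * array.element_count, format="csr")
        conv.sort_indices()
    return g_delta, conv


def required_time_samples(grid, array: TransducerArray, dt: float,
                          medium: MediumProperties, t0: float = 0.0) -> int:
    """Smallest n_t whose window covers the farthest voxel–element distance."""
    coords = _grid_coords_um(grid)
    corners = np.array([[c.min() for c in coords.T], [c.max() for c in coords.T]])
    dmax = 0.0
    for e in array.element_positions:
        for corner in _corner_points(corners):
            dmax = max(dmax, float(np.linalg.norm(corner - e)))
    t_max = dmax * _UM / medium.sound_speed
    return int(math.ceil((t_max - t0) / dt)) + 2


def _corner_points(bounds: np.ndarray) -> np.ndarray:
    ndim = bounds.shape[1]
    idx = np.indices((2,) * ndim).reshape(ndim, -1).T
    return bounds[idx, np.arange(ndim)]


def simulate_signals(pressure, array: TransducerArray, pulse: PulseShape,
                     dt: float, n_t: int, medium: MediumProperties,
                     t0: float = 0.0) -> SignalSet:
    """Simulate the recorded time series for every array element.

    Delta pulse: the raw spherical-shell geometry sum (non-negative for a
    non-negative p0).  Gaussian pulse: that response convolved with the
    pulse derivative, scaled to physical pressure (Pa).
    """
    need = required_time_samples(pressure, array, dt, medium, t0)
    if n_t < need:
        raise ValueError(
            f"time window too short: n_t={n_t} but the farthest voxel needs "
            f"n_t >= {need} at dt={dt:g} s")
    g_delta, conv = assemble_operator(pressure, array, pulse, dt, n_t, medium, t0)
    z = np.asarray(pressure.values, dtype=float).ravel(order="C")
    flat = g_delta.dot(z)
    if conv is not None:
        flat = conv.dot(flat)
    elif pulse.energy_scale != 1.0:
        flat = pulse.energy_scale * flat
    samples = flat.reshape(array.element_count, n_t)
    return SignalSet(samples=samples, dt=dt, t0=t0,
                     speed_of_sound=medium.sound_speed,
                     element_positions=array.element_positions)


def analytic_sphere_signal(radius: float, p0: float, distance: float,
                           c: float, times) -> np.ndarray:
    """Closed-form N-wave from a uniformly pressurised sphere.

    p(t) = p0 (r − c t) / (2 r) inside the window |r − c t| ≤ R, else 0:
    a bipolar ramp crossing zero at t = r/c with endpoints ± p0 R / (2 r).
    All lengths in metres, times in seconds.
    """
    if distance <= radius:
        raise ValueError("observation distance must exceed the sphere radius")
    t = np.asarray(times, dtype=float)
    arg = distance - c * t
    wave = p0 * arg / (2.0 * distance)
    wave[np.abs(arg) > radius] = 0.0
    return wave


def add_noise(signals: SignalSet, noise: NoiseModel) -> SignalSet:
    """Add seeded white gaussian noise at the requested SNR below peak signal."""
    if noise.kind != "gaussian_white":
        raise ValueError(f"unknown noise kind {noise.kind!r}")
    if noise.sigma is not None:
        sigma = noise.sigma
    else:
        if noise.snr_db is None or math.isinf(noise.snr_db):
            return replace_samples(signals, signals.samples.copy())
        peak = float(np.abs(signals.samples).max())
        if peak == 0:
            raise ValueError("all-zero signals: peak-relative SNR undefined; "
                             "set NoiseModel.sigma for an absolute noise level")
        sigma = peak / 10.0 ** (noise.snr_db / 20.0)
    rng = np.random.default_rng(noise.seed)
    noisy = signals.samples + rng.normal(0.0, sigma, signals.samples.shape)
    return replace_samples(signals, noisy)


def replace_samples(signals: SignalSet, samples: np.ndarray) -> SignalSet:
    return SignalSet(samples=samples, dt=signals.dt, t0=signals.t0,
                     speed_of_sound=signals.speed_of_sound,
                     element_positions=signals.element_positions)
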