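"""Explicit system matrix G for the linear imaging model H = G·Z + error.

Row a of G holds the weight of every image pixel z_b in recorded sample
n_a, so G·Z reproduces the forward simulation.  The matrix is assembled
through the *same* sparse kernel as :func:`pakit.forward.simulate_signals`
(matched discretization), which makes the equivalence bit-for-bit, not
merely close: column b equals the flattened signal simulated from the
indicator image of pixel b.

Two modes are provided: explicit (stored sparse factors) and matrix-free
(factors rebuilt per application), selected automatically by a memory cap.
Both satisfy the same apply/adjoint contracts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse

from . import forward as _fwd
from .forward import PulseShape, TransducerArray
from .media import MediumProperties

__all__ = ["SystemMatrix", "build_matrix", "apply", "adjoint", "save_matrix",
           "load_matrix"]


def provenance_hash(grid, array: TransducerArray, pulse: PulseShape,
                    dt: float, n_t: int, medium: MediumProperties,
                    t0: float = 0.0) -> str:
    """Stable hash of the (grid, array, pulse, medium, dt) tuple."""
    h = hashlib.sha256()
    h.update(np.asarray(grid.shape, dtype=np.int64).tobytes())
    h.update(np.asarray(grid.spacing, dtype=np.float64).tobytes())
    h.update(np.asarray(grid.origin, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(array.element_positions).tobytes())
    h.update(np.ascontiguousarray(array.axis_dirs).tobytes())
    s = array.sensitivity
    h.update(repr((s.kind, s.focal_half_width, s.rolloff, s.focal_distance,
                   s.directivity_power)).encode())
    h.update(repr((pulse.kind, pulse.width, pulse.energy_scale)).encode())
    h.update(repr((float(dt), int(n_t), float(t0), float(medium.sound_speed))).encode())
    return h.hexdigest()


@dataclass
class SystemMatrix:
    """Sparse H×X weight matrix, stored as (geometry, pulse-convolution)
    factors so that apply() runs the identical code path as the simulator."""

    g_delta: Optional[sparse.csr_matrix]
    conv: Optional[sparse.csr_matrix]
    image_shape: tuple[int, ...]
    element_count: int
    n_t: int
    provenance: str
    # matrix-free mode keeps the assembly arguments instead of the factors
    _assembly_args: Optional[tuple] = None

    @property
    def shape(self) -> tuple[int, int]:
        return (self.element_count * self.n_t, int(np.prod(self.image_shape)))

    @property
    def matrix_free(self) -> bool:
        return self.g_delta is None

    def _factors(self):
        if self.g_delta is not None:
            return self.g_delta, self.conv
        return _fwd.assemble_operator(*self._assembly_args)

    def materialize(self) -> sparse.csr_matrix:
        """The explicit H×X weight matrix (conv ∘ geometry)."""
        g_delta, conv = self._factors()
        return g_delta if conv is None else (conv @ g_delta).tocsr()

    def apply(self, image: np.ndarray) -> np.ndarray:
        """G·Z for a flat or grid-shaped image."""
        z = np.asarray(image, dtype=float).ravel(order="C")
        if z.size != self.shape[1]:
            raise ValueError(f"image size {z.size} != pixel count {self.shape[1]}")
        g_delta, conv = self._factors()
        out = g_delta.dot(z)
        return out if conv is None else conv.dot(out)

    def adjoint(self, data: np.ndarray) -> np.ndarray:
        """Gᵀ·N for a flat data vector; returns a flat image vector."""
        n = np.asarray(data, dtype=float).ravel(order="C")
        if n.size != self.shape[0]:
            raise ValueError(f"data size {n.size} != sample count {self.shape[0]}")
        g_delta, conv = self._factors()
        if conv is not None:
            n = conv.T.dot(n)
        return g_delta.T.dot(n)

    def row_norms_sq(self) -> np.ndarray:
        """Squared L2 norm of every row of the materialized matrix."""
        g = self.materialize()
        return np.asarray(g.multiply(g).sum(axis=1)).ravel()

    def rows(self) -> sparse.csr_matrix:
        return self.materialize()


def build_matrix(grid, array: TransducerArray, pulse: PulseShape, dt: float,
                 n_t: int, medium: MediumProperties, t0: float = 0.0,
                 memory_cap_bytes: float = 2e9,
                 matrix_free: Optional[bool] = None) -> SystemMatrix:
    """Assemble the system matrix for the same parameter tuple accepted by
    :func:`pakit.forward.simulate_signals`.

    A rough nnz estimate guards the explicit mode; above ``memory_cap_bytes``
    an error advises matrix-free mode (or pass ``matrix_free=True``).
    """
    nvox = int(np.prod(grid.shape))
    prov = provenance_hash(grid, array, pulse, dt, n_t, medium, t0)
    args = (grid, array, pulse, dt, n_t, medium, t0)
    if matrix_free:
        return SystemMatrix(g_delta=None, conv=None, image_shape=tuple(grid.shape),
                            element_count=array.element_count, n_t=n_t,
                            provenance=prov, _assembly_args=args)
    # each voxel touches a handful of time bins per element: ~16 B/entry
    pitch_m = min(grid.spacing) * 1e-6
    span = max(1.0, pitch_m / (medium.sound_speed * dt)) + 1.0
    est = nvox * array.element_count * span * 16.0
    if est > memory_cap_bytes:
        if matrix_free is None:
            raise MemoryError(
                f"explicit system matrix estimated at {est / 1e9:.1f} GB exceeds "
                f"the {memory_cap_bytes / 1e9:.1f} GB cap; pass matrix_free=True")
    g_delta, conv = _fwd.assemble_operator(grid, array, pulse, dt, n_t, medium, t0)
    return SystemMatrix(g_delta=g_delta, conv=conv, image_shape=tuple(grid.shape),
                        element_count=array.element_count, n_t=n_t, provenance=prov)


def apply(matrix: SystemMatrix, image: np.ndarray) -> np.ndarray:
    """Functional alias for ``matrix.apply``."""
    return matrix.apply(image)


def adjoint(matrix: SystemMatrix, data: np.ndarray) -> np.ndarray:
    """Functional alias for ``matrix.adjoint``."""
    return matrix.adjoint(data)


def save_matrix(path, matrix: SystemMatrix) -> None:
    """Persist the explicit matrix factors and provenance hash (HDF5)."""
    import h5py

    g = matrix.materialize().tocsr()
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=g.data)
        f.create_dataset("indices", data=g.indices)
        f.create_dataset("indptr", data=g.indptr)
        f.attrs["shape"] = g.shape
        f.attrs["image_shape"] = matrix.image_shape
        f.attrs["element_count"] = matrix.element_count
        f.attrs["n_t"] = matrix.n_t
        f.attrs["provenance"] = matrix.provenance


def load_matrix(path) -> SystemMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        g = sparse.csr_matrix(
            (f["data"][:], f["indices"][:], f["indptr"][:]),
            shape=tuple(f.attrs["shape"]))
        mat = SystemMatrix(
            g_delta=g, conv=None, image_shape=tuple(int(x) for x in f.attrs["image_shape"]),
            element_count=int(f.attrs["element_count"]), n_t=int(f.attrs["n_t"]),
            provenance=str(f.attrs["provenance"]))
    return mat
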