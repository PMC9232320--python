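"""Tomographic reconstruction: system matrix, Kaczmarz/Landweber, sparse view.

Simulates ring-array signals from a two-disc phantom, builds the explicit
weight matrix G (H = G·Z + error), reconstructs with row-action Kaczmarz
and with the filtered delay-and-sum baseline, and shows how both degrade
when only 8 of 64 elements are kept — the undersampling-artifact regime
where the iterative solver's nonnegativity prior pays off.
"""

import numpy as np

import pakit
from pakit import forward as fwd
from pakit.recon import compare_sparse_view, kaczmarz_reconstruct, landweber_reconstruct
from pakit.sysmatrix import build_matrix

tissue = pakit.get_preset("soft_tissue")
truth = pakit.make_agar_phantom(
    0.0,
    [{"kind": "sphere", "radius": 300.0, "center": [1100.0, 1400.0],
      "amplitude": 100.0},
     {"kind": "sphere", "radius": 200.0, "center": [2100.0, 1800.0],
      "amplitude": 80.0}],
    (32, 32), (100.0, 100.0))

array = fwd.default_ring_array(truth, n_elements=64)
pulse = pakit.PulseShape(kind="delta")
dt = fwd.default_dt(truth, tissue)
n_t = fwd.required_time_samples(truth, array, dt, tissue)
signals = fwd.simulate_signals(truth, array, pulse, dt, n_t, tissue)
matrix = build_matrix(truth, array, pulse, dt, n_t, tissue)
print(f"system matrix G: {matrix.shape[0]} samples × {matrix.shape[1]} pixels")

kz = kaczmarz_reconstruct(matrix, signals.flatten(), sweeps=60, nonneg=True)
print(f"Kaczmarz: {kz.iterations_run} sweeps, relative error "
      f"{pakit.relative_rmse(kz.image, truth.values):.2e}")

lw = landweber_reconstruct(matrix, signals.flatten(), iterations=30)
print(f"Landweber residuals monotone: "
      f"{bool(np.all(np.diff(lw.residual_history) <= 0))}")

print("\nsparse-view study (scale-fitted relative L2 error):")
for row in compare_sparse_view(truth, [8, 64], tissue, sweeps=60):
    print(f"  {row['element_count']:>2} elements  {row['solver']:<16} "
          f"{row['relative_error']:.3f}")
print("with 8 elements the iterative solver suppresses the streak "
      "artifacts that dominate backprojection")
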