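import numpy as np
import pytest

import pakit
from pakit import forward as fwd
from pakit.sysmatrix import build_matrix


@pytest.fixture(scope="session")
def tissue():
    return pakit.get_preset("soft_tissue")


@pytest.fixture(scope="session")
def water():
    return pakit.get_preset("water")


@pytest.fixture(scope="session")
def grid32(tissue):
    """Empty 32×32 tomography grid at 100 μm pitch."""
    return pakit.AbsorptionMap(values=np.zeros((32, 32)), spacing=(100.0, 100.0))


@pytest.fixture(scope="session")
def system32(grid32, tissue):
    """(array, pulse, dt, n_t, matrix) for the 32×32 grid, 16 elements."""
    array = fwd.default_ring_array(grid32, n_elements=16)
    pulse = pakit.PulseShape(kind="delta")
    dt = fwd.default_dt(grid32, tissue)
    n_t = fwd.required_time_samples(grid32, array, dt, tissue)
    matrix = build_matrix(grid32, array, pulse, dt, n_t, tissue)
    return array, pulse, dt, n_t, matrix


@pytest.fixture(scope="session")
def system16(tissue):
    """Full-view 64-element system on a 16×16 grid (solver recovery tests)."""
    grid = pakit.AbsorptionMap(values=np.zeros((16, 16)), spacing=(100.0, 100.0))
    array = fwd.default_ring_array(grid, n_elements=64)
    pulse = pakit.PulseShape(kind="delta")
    dt = fwd.default_dt(grid, tissue)
    n_t = fwd.required_time_samples(grid, array, dt, tissue)
    matrix = build_matrix(grid, array, pulse, dt, n_t, tissue)
    return grid, array, pulse, dt, n_t, matrix


@pytest.fixture(scope="session")
def two_disc_truth():
    """Two absorbing discs in a clear background (sparse-view studies)."""
    return pakit.make_agar_phantom(
        0.0,
        [{"kind": "sphere", "radius": 300.0, "center": [1100.0, 1400.0],
          "amplitude": 100.0},
         {"kind": "sphere", "radius": 200.0, "center": [2100.0, 1800.0],
          "amplitude": 80.0}],
        (32, 32), (100.0, 100.0))


@pytest.fixture(scope="session")
def sphere_signal(tissue):
    """Simulated waveform from a uniform sphere (R = 0.5 mm, spacing R/20)
    observed at 5 mm, with the matching analytic N-wave ingredients."""
    radius_um, spacing, n = 500.0, 25.0, 48
    center = [(n - 1) / 2 * spacing] * 3
    amap = pakit.make_uniform_sphere(radius_um, center, 100.0,
                                     (n, n, n), (spacing,) * 3)
    pressure = pakit.PressureField(values=amap.values, spacing=amap.spacing)
    distance_um = 5000.0
    elem = np.array([[center[0] + distance_um, center[1], center[2]]])
    array = pakit.TransducerArray(element_positions=elem, axis_dirs=-elem)
    dt = fwd.default_dt(amap, tissue)
    n_t = fwd.required_time_samples(amap, array, dt, tissue)
    pulse = pakit.PulseShape(kind="gaussian", width=4 * dt)
    signals = fwd.simulate_signals(pressure, array, pulse, dt, n_t, tissue)
    return dict(signals=signals, pulse=pulse, radius_m=radius_um * 1e-6,
                distance_m=distance_um * 1e-6, p0=100.0, c=tissue.sound_speed)


@pytest.fixture(scope="session")
def oral_scan(tissue):
    """Default three-layer oral phantom scanned with the default spot."""
    from pakit import orpam, phantoms

    amap = phantoms.make_vessel_network(
        phantoms.default_oral_layers(0), (128, 128, 56),
        (10.0, 10.0, 20.0), seed=0)
    config = orpam.ScanConfig(spot_fwhm=9.9, step=10.0, trajectory="raster",
                              pixels=(120, 120), axial_kernel_fwhm=30.0)
    volume = orpam.scan(amap, config, tissue)
    return amap, config, volume
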