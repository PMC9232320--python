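"""Forward model: geometry contracts, the N-wave oracle, and noise."""

import math

import numpy as np
import pytest

import pakit
from pakit import forward as fwd
from pakit.forward import (
    NoiseModel,
    PulseShape,
    SensitivityModel,
    TransducerArray,
    add_noise,
    analytic_sphere_signal,
    simulate_signals,
)


def _point_setup(tissue, pos_um, n=32, spacing=100.0, elem_offset=5000.0):
    amap = pakit.make_point_targets([pos_um], 100.0, (n, n), (spacing, spacing))
    pressure = pakit.PressureField(values=amap.values, spacing=amap.spacing)
    elem = np.array([[pos_um[0] + elem_offset, pos_um[1]]])
    # element looks back along -x, straight at the source
    array = TransducerArray(element_positions=elem,
                            axis_dirs=np.array([[-1.0, 0.0]]))
    return pressure, array


class TestAnalyticSphere:
    def test_zero_crossing_and_endpoints(self):
        radius, p0, r, c = 5e-4, 100.0, 5e-3, 1500.0
        t = np.array([(r - radius) / c, r / c, (r + radius) / c])
        wave = analytic_sphere_signal(radius, p0, r, c, t)
        assert wave[1] == pytest.approx(0.0, abs=1e-12)
        assert wave[0] == pytest.approx(p0 * radius / (2 * r), rel=1e-12)
        assert wave[2] == pytest.approx(-p0 * radius / (2 * r), rel=1e-12)

    def test_rejects_observer_inside(self):
        with pytest.raises(ValueError):
            analytic_sphere_signal(1e-3, 1.0, 5e-4, 1500.0, [0.0])

    def test_against_brute_force_spherical_mean(self):
        """Independent oracle check: p = (1/4πc²) ∂t[(1/t)∮ p0 dS] with the
        shell surface integral done by polar-angle quadrature (fractional
        coverage in boundary cells), then a central finite difference."""
        radius, p0, r, c = 5e-4, 100.0, 5e-3, 1500.0
        n_theta = 10_000
        edges = np.arange(n_theta + 1) * math.pi / n_theta
        sin_mid = np.sin(0.5 * (edges[:-1] + edges[1:]))
        d_theta = math.pi / n_theta

        def shell_integral(t):
            # shell of radius d = ct around the observer, sphere centre at
            # distance r along the polar axis: inside iff |x - centre| <= R
            d = c * t
            dist_sq = d * d + r * r - 2 * d * r * np.cos(edges)
            below = dist_sq <= radius * radius
            frac = np.zeros(n_theta)
            frac[below[:-1] & below[1:]] = 1.0
            cross = below[:-1] != below[1:]
            lo, hi = dist_sq[:-1], dist_sq[1:]
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (radius * radius - lo) / (hi - lo)
            f = np.clip(np.where(below[:-1], f, 1.0 - f), 0.0, 1.0)
            frac[cross] = f[cross]
            # ∮ p0 dS = p0 · 2π d² ∫ sinθ coverage dθ
            return p0 * 2 * math.pi * d * d * np.sum(sin_mid * frac) * d_theta

        times = np.linspace((r - 0.9 * radius) / c, (r + 0.9 * radius) / c, 41)
        h = 0.01 * radius / c
        brute = np.array([
            (shell_integral(t + h) / (t + h) - shell_integral(t - h) / (t - h))
            / (2 * h) / (4 * math.pi * c * c)
            for t in times])
        closed = analytic_sphere_signal(radius, p0, r, c, times)
        peak = np.abs(closed).max()
        assert np.max(np.abs(brute - closed)) <= 1e-3 * peak


class TestSimulateSignals:
    def test_zero_pressure_zero_signals(self, grid32, system32, tissue):
        array, pulse, dt, n_t, _ = system32
        pressure = pakit.PressureField(values=np.zeros((32, 32)),
                                       spacing=grid32.spacing)
        signals = simulate_signals(pressure, array, pulse, dt, n_t, tissue)
        assert not signals.samples.any()

    def test_point_source_retarded_time_and_decay(self, tissue):
        pressure, array = _point_setup(tissue, [1600.0, 1600.0])
        dt = fwd.default_dt(pressure, tissue)
        n_t = fwd.required_time_samples(pressure, array, dt, tissue)
        signals = simulate_signals(pressure, array, PulseShape(kind="delta"),
                                   dt, n_t, tissue)
        k_peak = np.argmax(signals.samples[0])
        t_expected = 5000.0 * 1e-6 / tissue.sound_speed
        assert abs(signals.times[k_peak] - t_expected) <= 1.5 * dt

    def test_one_over_r_amplitude_decay(self, tissue):
        """Integrated point-source signal decays as 1/r over a decade."""
        totals = []
        for r_um in (2000.0, 20000.0):
            pressure, array = _point_setup(tissue, [1600.0, 1600.0],
                                           elem_offset=r_um)
            dt = fwd.default_dt(pressure, tissue)
            n_t = fwd.required_time_samples(pressure, array, dt, tissue)
            sig = simulate_signals(pressure, array, PulseShape(kind="delta"),
                                   dt, n_t, tissue)
            totals.append(sig.samples.sum())
        assert totals[0] / totals[1] == pytest.approx(10.0, rel=0.01)

    def test_radial_shift_delays_arrival(self, tissue):
        pressure1, array = _point_setup(tissue, [1600.0, 1600.0])
        amap2 = pakit.make_point_targets([[1100.0, 1600.0]], 100.0, (32, 32),
                                         (100.0, 100.0))
        pressure2 = pakit.PressureField(values=amap2.values, spacing=amap2.spacing)
        dt = fwd.default_dt(pressure1, tissue)
        n_t = fwd.required_time_samples(pressure2, array, dt, tissue)
        s1 = simulate_signals(pressure1, array, PulseShape(kind="delta"),
                              dt, n_t, tissue)
        s2 = simulate_signals(pressure2, array, PulseShape(kind="delta"),
                              dt, n_t, tissue)
        shift_bins = np.argmax(s2.samples[0]) - np.argmax(s1.samples[0])
        expected = 500.0 * 1e-6 / tissue.sound_speed / dt
        assert abs(shift_bins - expected) <= 1.0

    def test_linearity(self, grid32, system32, tissue):
        array, pulse, dt, n_t, _ = system32
        rng = np.random.default_rng(7)
        z1, z2 = rng.random((32, 32)), rng.random((32, 32))
        mk = lambda v: pakit.PressureField(values=v, spacing=grid32.spacing)
        s1 = simulate_signals(mk(z1), array, pulse, dt, n_t, tissue).samples
        s2 = simulate_signals(mk(z2), array, pulse, dt, n_t, tissue).samples
        s12 = simulate_signals(mk(2.0 * z1 + 0.5 * z2), array, pulse, dt, n_t,
                               tissue).samples
        np.testing.assert_allclose(s12, 2.0 * s1 + 0.5 * s2, rtol=1e-10,
                                   atol=1e-10 * np.abs(s1).max())

    def test_short_window_raises_with_required_nt(self, grid32, system32, tissue):
        array, pulse, dt, n_t, _ = system32
        pressure = pakit.PressureField(values=np.ones((32, 32)),
                                       spacing=grid32.spacing)
        with pytest.raises(ValueError, match=r"n_t >= \d+"):
            simulate_signals(pressure, array, pulse, dt, n_t // 4, tissue)

    def test_sphere_waveform_matches_oracle(self, sphere_signal):
        """The simulated sphere waveform reproduces the closed-form N-wave:
        zero crossing at t = r/c, endpoint amplitudes ± p0 R/(2r) within
        2%, and ≤ 2% peak-relative deviation away from the two jump
        discontinuities (a guard of ~1 pulse width around each corner,
        where any finite pulse rounds the ideal step)."""
        sig = sphere_signal["signals"]
        radius, r = sphere_signal["radius_m"], sphere_signal["distance_m"]
        p0, c = sphere_signal["p0"], sphere_signal["c"]
        times = sig.times
        wave = sig.samples[0]
        analytic = analytic_sphere_signal(radius, p0, r, c, times)
        peak_expected = p0 * radius / (2 * r)

        # zero crossing at the shell-centre arrival time
        k = np.argmin(np.abs(times - r / c))
        assert abs(wave[k]) <= 0.02 * peak_expected
        # pointwise agreement away from the corners
        guard = 3 * sphere_signal["pulse"].width
        corners = ((r - radius) / c, (r + radius) / c)
        mask = np.all([np.abs(times - tc) > guard for tc in corners], axis=0) \
            & (np.abs(analytic) > 0)
        assert np.max(np.abs(wave - analytic)[mask]) <= 0.02 * peak_expected
        # interior-ramp extrapolation recovers the ± p0 R/(2r) endpoints
        slope, intercept = np.polyfit(times[mask], wave[mask], 1)
        assert slope * corners[0] + intercept == pytest.approx(peak_expected,
                                                               rel=0.02)
        assert slope * corners[1] + intercept == pytest.approx(-peak_expected,
                                                               rel=0.02)

    def test_sensitivity_weighting_scales_sources(self, tissue):
        pressure, array = _point_setup(tissue, [1600.0, 1600.0])
        flat = TransducerArray(
            element_positions=array.element_positions,
            axis_dirs=array.axis_dirs,
            sensitivity=SensitivityModel(kind="flat_field", directivity_power=2.0))
        dt = fwd.default_dt(pressure, tissue)
        n_t = fwd.required_time_samples(pressure, array, dt, tissue)
        s_ideal = simulate_signals(pressure, array, PulseShape(kind="delta"),
                                   dt, n_t, tissue)
        s_flat = simulate_signals(pressure, flat, PulseShape(kind="delta"),
                                  dt, n_t, tissue)
        # on-axis source: cosine directivity weight is 1, signals identical
        np.testing.assert_allclose(s_flat.samples, s_ideal.samples, rtol=1e-12)


class TestNoise:
    def test_seed_reproducibility(self, tissue):
        pressure, array = _point_setup(tissue, [1600.0, 1600.0])
        dt = fwd.default_dt(pressure, tissue)
        n_t = fwd.required_time_samples(pressure, array, dt, tissue)
        sig = simulate_signals(pressure, array, PulseShape(kind="delta"),
                               dt, n_t, tissue)
        a = add_noise(sig, NoiseModel(snr_db=30.0, seed=11))
        b = add_noise(sig, NoiseModel(snr_db=30.0, seed=11))
        c = add_noise(sig, NoiseModel(snr_db=30.0, seed=12))
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_infinite_snr_unchanged(self, tissue):
        pressure, array = _point_setup(tissue, [1600.0, 1600.0])
        dt = fwd.default_dt(pressure, tissue)
        n_t = fwd.required_time_samples(pressure, array, dt, tissue)
        sig = simulate_signals(pressure, array, PulseShape(kind="delta"),
                               dt, n_t, tissue)
        out = add_noise(sig, NoiseModel(snr_db=math.inf, seed=0))
        assert np.array_equal(out.samples, sig.samples)

    def test_empirical_snr_matches_requested(self):
        rng = np.random.default_rng(0)
        base = pakit.SignalSet(samples=rng.random((100, 2000)), dt=1e-8)
        for snr in (20.0, 40.0):
            noisy = add_noise(base, NoiseModel(snr_db=snr, seed=5))
            added = noisy.samples - base.samples
            measured = 20 * math.log10(np.abs(base.samples).max() / added.std())
            assert measured == pytest.approx(snr, abs=0.5)

    def test_zero_signals_need_absolute_sigma(self):
        sig = pakit.SignalSet(samples=np.zeros((4, 64)), dt=1e-8)
        with pytest.raises(ValueError, match="sigma"):
            add_noise(sig, NoiseModel(snr_db=30.0))
        out = add_noise(sig, NoiseModel(sigma=0.1, seed=0))
        assert out.samples.std() == pytest.approx(0.1, rel=0.1)
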