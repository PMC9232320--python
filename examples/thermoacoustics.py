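"""Thermoacoustic basics: confinement check and the initial-pressure chain.

A 150 μm absorber in soft tissue has a stress relaxation time of 100 ns
and a thermal relaxation time of ~0.16 s; a nanosecond laser pulse is far
shorter than both, so the absorbed energy converts to pressure before any
conduction — the regime every photoacoustic imaging model assumes.
"""

import numpy as np

import pakit

tissue = pakit.get_preset("soft_tissue")
water = pakit.get_preset("water")

t_thermal, t_stress = pakit.relaxation_times(tissue, char_length=150e-6)
pulse = 5e-9
print(f"thermal relaxation time : {t_thermal:.4f} s")
print(f"stress relaxation time  : {t_stress * 1e9:.1f} ns")
print(f"5 ns pulse confined     : "
      f"{pakit.confinement_satisfied(pulse, t_thermal, t_stress)}")

print(f"\nGruneisen coefficient, water       : {pakit.gruneisen(water)}")
print(f"Gruneisen coefficient, soft tissue : {pakit.gruneisen(tissue)}")

# absorbed energy density -> temperature rise -> initial pressure
xp = np.full((2, 2), 4.18e6)  # J/m³
w = pakit.temperature_rise(xp, tissue)
p0 = pakit.initial_pressure(xp, pakit.gruneisen(tissue))
print(f"\nX_p = 4.18 MJ/m³ gives a temperature rise of {w.values[0, 0]:.2f} K")
print(f"and an initial pressure of {p0.values[0, 0] / 1e6:.3f} MPa "
      f"(p0 = Γ · X_p with Γ = 0.25)")
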