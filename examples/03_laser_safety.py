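"""Laser-safety energy limits at a fiber tip under the skin MPE.

The per-pulse energy limit is the skin maximum permissible exposure
(fluence) times the fiber core area.  At 900 nm a 1-mm core allows
394.6 uJ per pulse; a 0.6-mm core only 142 uJ.
"""

from paslsc.safety import energy_limit, mpe_skin_fluence

for wavelength, diameter in [(900.0, 1.0), (900.0, 0.6), (750.0, 1.0)]:
    limit = energy_limit(wavelength, diameter)
    print(f"{wavelength:.0f} nm, {diameter:.1f} mm core: "
          f"MPE {limit.mpe_fluence_mj_cm2:6.2f} mJ/cm^2 -> "
          f"max {limit.max_energy_uj:7.1f} uJ per pulse")

print()
print(f"Skin MPE at 750 nm: {mpe_skin_fluence(750.0):.2f} mJ/cm^2 "
      "(prints as 25.2)")
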