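"""Laser-safety limits: skin MPE fluence and per-pulse fiber energy.

For nanosecond pulsed light in the 700-1050 nm band, the skin maximum
permissible exposure (MPE) per the ANSI Z136.1 laser-safety standard is

    MPE = 2.0 * C_A * 1e-2 J/cm^2,   C_A = 10^(2 * (lambda_um - 0.700)),

i.e. 20 mJ/cm^2 at 700 nm rising to ~100 mJ/cm^2 at 1050 nm.  Spread as a
flat-top beam over the core of an optical fiber of diameter D (mm), this
fluence bounds the per-pulse energy at the fiber tip:

    E_max = MPE * pi * (D/2)^2  (with cm^2 / uJ unit conversions).

A 1-mm core at 900 nm yields 394.6 uJ; a 0.6-mm core yields 142 uJ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["EnergyLimit", "mpe_skin_fluence", "max_pulse_energy", "energy_limit"]


@dataclass(frozen=True)
class EnergyLimit:
    wavelength_nm: float
    mpe_fluence_mj_cm2: float
    fiber_diameter_mm: float
    max_energy_uj: float

    def __post_init__(self) -> None:
        if min(self.wavelength_nm, self.mpe_fluence_mj_cm2,
               self.fiber_diameter_mm, self.max_energy_uj) < 0:
            raise ValueError("all fields must be nonnegative")


def mpe_skin_fluence(wavelength_nm: float) -> float:
    """Skin MPE fluence in mJ/cm^2 for nanosecond pulses, 700-1050 nm only."""
    if not 700.0 <= wavelength_nm <= 1050.0:
        raise ValueError(
            "only the 700-1050 nm nanosecond-pulse skin MPE band is supported"
        )
    wavelength_um = wavelength_nm / 1000.0
    c_a = 10.0 ** (2.0 * (wavelength_um - 0.700))
    return 20.0 * c_a  # 2.0 * C_A * 1e-2 J/cm^2, expressed in mJ/cm^2


def max_pulse_energy(fluence_mj_cm2: float, fiber_diameter_mm: float) -> float:
    """Per-pulse energy limit in uJ for a flat-top beam over the fiber core."""
    if fluence_mj_cm2 < 0:
        raise ValueError("fluence must be >= 0")
    if fiber_diameter_mm <= 0:
        raise ValueError("fiber diameter must be positive")
    area_cm2 = math.pi * (fiber_diameter_mm / 20.0) ** 2
    return fluence_mj_cm2 * area_cm2 * 1000.0


def energy_limit(wavelength_nm: float, fiber_diameter_mm: float) -> EnergyLimit:
    """MPE fluence and per-pulse energy limit for a wavelength/fiber pair."""
    fluence = mpe_skin_fluence(wavelength_nm)
    return EnergyLimit(
        wavelength_nm=wavelength_nm,
        mpe_fluence_mj_cm2=fluence,
        fiber_diameter_mm=fiber_diameter_mm,
        max_energy_uj=max_pulse_energy(fluence, fiber_diameter_mm),
    )
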