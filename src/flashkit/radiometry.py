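"""Radiometric power <-> photon (quantum) flux conversion.

The stimulus levels of the experiment are defined in quantum flux
(photons per unit area per second, expressed in µmol m⁻² s⁻¹) so that
exposures of different wavelength deliver the same number of photons.
A power meter reads irradiance in µW/cm²; at wavelength λ each photon
carries energy hc/λ, so

    flux [mol m⁻² s⁻¹] = P [W m⁻²] · λ [m] / (h · c · N_A)

with P [W m⁻²] = irradiance [µW cm⁻²] × 10⁻².  Constants are CODATA
values from :mod:`scipy.constants`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy import constants

#: Joule-metres per photon-mole: h * c * N_A.
_HC_NA = constants.h * constants.c * constants.N_A

#: Plausible optical range accepted by the converters, nm.
WAVELENGTH_RANGE = (100.0, 1500.0)

#: Default equalized quantum-flux levels, µmol m⁻² s⁻¹ (bright = 10 × dim).
DIM_FLUX = 0.107
BRIGHT_FLUX = 1.075


def _check_wavelength(wavelength_nm: float) -> float:
    wl = float(wavelength_nm)
    lo, hi = WAVELENGTH_RANGE
    if not (lo <= wl <= hi):
        raise ValueError(
            f"wavelength {wl} nm outside plausible optical range [{lo}, {hi}] nm"
        )
    return wl


def irradiance_to_quantum_flux(power_uw_cm2: float, wavelength_nm: float) -> float:
    """Convert irradiance (µW/cm²) to photon flux density (µmol m⁻² s⁻¹).

    Linear in both power and wavelength: at fixed power, longer-wavelength
    light carries more (lower-energy) photons in exact proportion to λ.

    >>> round(irradiance_to_quantum_flux(100.0, 500.0), 2)
    4.18
    """
    wl_m = _check_wavelength(wavelength_nm) * 1e-9
    power = float(power_uw_cm2)
    if power < 0:
        raise ValueError("power must be non-negative")
    p_w_m2 = power * 1e-2
    return p_w_m2 * wl_m / _HC_NA * 1e6


def equalize_power(target_flux_umol: float, wavelength_nm: float) -> float:
    """Irradiance (µW/cm²) required to reach a target quantum flux.

    Exact inverse of :func:`irradiance_to_quantum_flux`; shorter
    wavelengths need proportionally more power for the same photon count.
    """
    wl_m = _check_wavelength(wavelength_nm) * 1e-9
    flux = float(target_flux_umol)
    if flux < 0:
        raise ValueError("target flux must be non-negative")
    return flux * 1e-6 * _HC_NA / wl_m / 1e-2


@dataclass(frozen=True)
class LightLevel:
    """A stimulus level at one wavelength, in both radiometric units.

    Either quantity may be given; the other is filled in from the
    conversion.  Supplying both checks their consistency.
    """

    wavelength: float
    irradiance: Optional[float] = None
    quantum_flux: Optional[float] = None

    def __post_init__(self) -> None:
        _check_wavelength(self.wavelength)
        if self.irradiance is None and self.quantum_flux is None:
            raise ValueError("give irradiance and/or quantum_flux")
        if self.irradiance is None:
            object.__setattr__(
                self, "irradiance", equalize_power(self.quantum_flux, self.wavelength)
            )
        elif self.quantum_flux is None:
            object.__setattr__(
                self,
                "quantum_flux",
                irradiance_to_quantum_flux(self.irradiance, self.wavelength),
            )
        else:
            implied = irradiance_to_quantum_flux(self.irradiance, self.wavelength)
            if abs(implied - self.quantum_flux) > 1e-9 * max(1.0, abs(implied)):
                raise ValueError(
                    "irradiance and quantum_flux are inconsistent "
                    f"({implied} vs {self.quantum_flux} µmol m⁻² s⁻¹)"
                )
        if self.irradiance < 0 or self.quantum_flux < 0:
            raise ValueError("light level quantities must be non-negative")
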