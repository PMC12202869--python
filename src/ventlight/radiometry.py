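"""Blackbody photon radiometry.

Planck-law photon radiance of a grey-body thermal source (a hydrothermal
vent orifice at up to 400 °C), band-integrated photon fluxes, and the unit
conversions that tie laboratory irradiance figures (µmol photons m⁻² s⁻¹)
to the photon radiance scale (photons cm⁻² s⁻¹ sr⁻¹) used throughout the
photon budget.

All temperatures are kelvin, all wavelengths nanometres.  Physical
constants are CODATA 2018, taken from :mod:`scipy.constants`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const
from scipy import integrate

__all__ = [
    "HC_EV_NM",
    "SpectralBand",
    "BlackbodySource",
    "PhotonFlux",
    "planck_photon_radiance",
    "band_photon_flux",
    "total_photon_radiance",
    "photon_energy_ev",
    "ev_to_wavelength",
    "mol_flux_to_photon_radiance",
    "CELSIUS_400_K",
    "VISIBLE_BLACKBODY_LIMIT",
    "LAB_GROWTH_REQUIREMENT",
    "LOW_LIGHT_REQUIREMENT_UMOL",
]

#: hc in eV·nm (CODATA 2018), fixing the wavelength↔photon-energy conversion.
HC_EV_NM = 1239.841984

#: 400 °C expressed in kelvin; the canonical vent-fluid temperature.
CELSIUS_400_K = 673.15

#: Literature upper limit of thermal blackbody radiation in the 400–600 nm
#: band at vents, photons·cm⁻²·s⁻¹·sr⁻¹ (external constant, not recomputed).
VISIBLE_BLACKBODY_LIMIT = 1e3

#: Photon radiance commonly required for cyanobacterial growth in the
#: laboratory, photons·cm⁻²·s⁻¹·sr⁻¹ (external constant).
LAB_GROWTH_REQUIREMENT = 1e13

#: Lowest irradiance at which oxygenic photosynthesis has been observed to
#: persist, µmol photons·m⁻²·s⁻¹.
LOW_LIGHT_REQUIREMENT_UMOL = 0.04


@dataclass(frozen=True)
class SpectralBand:
    """Closed wavelength interval [lambda_min, lambda_max] in nm."""

    lambda_min: float
    lambda_max: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lambda_min) and math.isfinite(self.lambda_max)):
            raise ValueError("band edges must be finite")
        if not 0 < self.lambda_min < self.lambda_max:
            raise ValueError(
                f"require 0 < lambda_min < lambda_max, got "
                f"[{self.lambda_min}, {self.lambda_max}]"
            )

    @property
    def width(self) -> float:
        return self.lambda_max - self.lambda_min

    def halved(self) -> "SpectralBand":
        """The band of second-harmonic wavelengths (both edges halved)."""
        return SpectralBand(self.lambda_min / 2.0, self.lambda_max / 2.0)


@dataclass(frozen=True)
class BlackbodySource:
    """Grey-body thermal emitter: temperature (K) and scalar emissivity."""

    temperature: float
    emissivity: float = 1.0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if not 0 < self.emissivity <= 1:
            raise ValueError(f"emissivity must be in (0, 1], got {self.emissivity}")


@dataclass(frozen=True)
class PhotonFlux:
    """Band-integrated photon radiance, photons·cm⁻²·s⁻¹·sr⁻¹."""

    value: float
    band: SpectralBand | None = None
    source_description: str = ""

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"photon flux must be >= 0, got {self.value}")

    def to_json_record(self, source: BlackbodySource | None = None) -> dict:
        rec: dict = {"flux_photons_cm2_s_sr": self.value}
        if self.band is not None:
            rec["band_nm"] = [self.band.lambda_min, self.band.lambda_max]
        if source is not None:
            rec["temperature_K"] = source.temperature
            rec["emissivity"] = source.emissivity
        if self.source_description:
            rec["source"] = self.source_description
        return rec

    def to_json(self, source: BlackbodySource | None = None) -> str:
        return json.dumps(self.to_json_record(source))


def planck_photon_radiance(lambda_nm, source: BlackbodySource):
    """Spectral photon radiance of a grey body.

    Evaluates ε · (2c/λ⁴) / (exp(hc/λkT) − 1) in
    photons·s⁻¹·cm⁻²·sr⁻¹·nm⁻¹.  Vectorized over ``lambda_nm``.
    """
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be > 0 nm")
    lam_m = lam * 1e-9
    x = _const.h * _const.c / (lam_m * _const.k * source.temperature)
    # 1/(e^x - 1) computed as e^(-x)/(1 - e^(-x)) to stay finite for x >> 1
    bose = np.exp(-x) / (-np.expm1(-x))
    out = source.emissivity * (2.0 * _const.c / lam_m**4) * bose
    # photons s^-1 m^-2 sr^-1 m^-1  ->  per cm^2 (1e-4) and per nm (1e-9)
    out = out * 1e-13
    if np.isscalar(lambda_nm) or np.ndim(lambda_nm) == 0:
        return float(out)
    return out


def band_photon_flux(band: SpectralBand, source: BlackbodySource,
                     rtol: float = 1e-9) -> PhotonFlux:
    """Photon radiance integrated over a wavelength band.

    Adaptive Gauss–Kronrod quadrature of :func:`planck_photon_radiance`
    over [lambda_min, lambda_max].
    """
    value, _ = integrate.quad(
        lambda lam: planck_photon_radiance(lam, source),
        band.lambda_min, band.lambda_max,
        epsrel=rtol, epsabs=0.0, limit=200,
    )
    desc = f"blackbody T={source.temperature} K, emissivity={source.emissivity}"
    return PhotonFlux(value=value, band=band, source_description=desc)


def total_photon_radiance(source: BlackbodySource) -> float:
    """Closed-form photon radiance over all wavelengths.

    ∫₀^∞ of the Planck photon radiance equals 4 ζ(3) c (kT/hc)³ per
    steradian (the Bose integral ∫ x²/(eˣ−1) dx = 2 ζ(3)); returned in
    photons·cm⁻²·s⁻¹·sr⁻¹.
    """
    zeta3 = 1.2020569031595942854
    kt_hc = _const.k * source.temperature / (_const.h * _const.c)
    return source.emissivity * 4.0 * zeta3 * _const.c * kt_hc**3 * 1e-4


def photon_energy_ev(lambda_nm: float) -> float:
    """Photon energy hc/λ in eV for a wavelength in nm."""
    if lambda_nm <= 0:
        raise ValueError("wavelength must be > 0 nm")
    return HC_EV_NM / lambda_nm


def ev_to_wavelength(energy_ev: float) -> float:
    """Wavelength hc/E in nm for a photon energy in eV."""
    if energy_ev <= 0:
        raise ValueError("photon energy must be > 0 eV")
    return HC_EV_NM / energy_ev


def mol_flux_to_photon_radiance(flux_umol_m2_s: float,
                                solid_angle_sr: float = 2.0 * math.pi) -> float:
    """Convert µmol photons·m⁻²·s⁻¹ to photons·cm⁻²·s⁻¹·sr⁻¹.

    Multiplies by Avogadro's number and 10⁻⁶ (µmol → photons), divides by
    10⁴ (m² → cm²) and by the solid angle the irradiance is spread over
    (hemispherical 2π sr by default).
    """
    if flux_umol_m2_s < 0:
        raise ValueError("flux must be >= 0")
    if not 0 < solid_angle_sr <= 4.0 * math.pi:
        raise ValueError("solid angle must be in (0, 4*pi] sr")
    return flux_umol_m2_s * _const.N_A * 1e-6 / 1e4 / solid_angle_sr
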