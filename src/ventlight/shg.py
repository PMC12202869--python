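"""Second-harmonic-generation phenomenology.

Half-wavelength mapping, the quadratic excitation-power law, instrument
loss correction, energy-conversion efficiency, pressure enhancement in a
diamond anvil cell (DAC) series, and the multiplicative photon budget that
links the vent's infrared radiance to the up-converted visible flux.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .radiometry import PhotonFlux, SpectralBand

__all__ = [
    "PowerSeries",
    "LossBudget",
    "PowerLawFit",
    "PressureSeries",
    "PhotonBudget",
    "shg_wavelength",
    "fit_power_law",
    "correct_output_power",
    "conversion_efficiency",
    "pressure_enhancement",
    "photon_budget",
    "orders_of_magnitude_ratio",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerSeries:
    """SHG intensity versus excitation power at one excitation wavelength.

    ``points`` is a sequence of (P_ex in mW, intensity in detector counts
    or mW).  At least three points, strictly positive powers.
    """

    excitation_wavelength: float
    points: tuple

    def __post_init__(self) -> None:
        pts = tuple((float(p), float(i)) for p, i in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 3:
            raise ValueError("a power series needs at least 3 points")
        if any(p <= 0 for p, _ in pts):
            raise ValueError("all excitation powers must be > 0 mW")
        if any(i < 0 for _, i in pts):
            raise ValueError("intensities must be >= 0")

    @property
    def powers(self) -> np.ndarray:
        return np.array([p for p, _ in self.points])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.points])

    @classmethod
    def from_tsv(cls, path, excitation_wavelength: float) -> "PowerSeries":
        df = _read_series_tsv(path, 2)
        return cls(excitation_wavelength, list(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.points, columns=["power_mw", "intensity"]).to_csv(
            path, sep="\t", index=False)


@dataclass(frozen=True)
class LossBudget:
    """Multiplicative instrument losses between sample and detector.

    Defaults are the detection chain of a reflective SHG microscope:
    ~55% spectrometer+CCD quantum-harvesting efficiency, 60% fiber
    coupling, 50% beamsplitter transmission.
    """

    detector_qe: float = 0.55
    fiber_coupling: float = 0.60
    beamsplitter_transmission: float = 0.50

    def __post_init__(self) -> None:
        for name in ("detector_qe", "fiber_coupling", "beamsplitter_transmission"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    @property
    def throughput(self) -> float:
        return self.detector_qe * self.fiber_coupling * self.beamsplitter_transmission


@dataclass(frozen=True)
class PowerLawFit:
    """log10 I = exponent · log10 P + log_prefactor."""

    exponent: float
    log_prefactor: float
    r_squared: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1:
            raise ValueError("r_squared must be in [0, 1]")

    def to_json(self) -> str:
        return json.dumps({
            "exponent": self.exponent,
            "log10_prefactor": self.log_prefactor,
            "r_squared": self.r_squared,
        })


@dataclass(frozen=True)
class PressureSeries:
    """Integrated SHG intensity versus hydrostatic pressure in a DAC.

    ``points`` is a sequence of (pressure GPa, integrated intensity,
    excitation power mW); pressures strictly increasing, intensities > 0.
    """

    points: tuple

    def __post_init__(self) -> None:
        pts = tuple((float(p), float(i), float(pw)) for p, i, pw in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 2:
            raise ValueError("a pressure series needs at least 2 points")
        pres = [p for p, _, _ in pts]
        if any(b <= a for a, b in zip(pres, pres[1:])):
            raise ValueError("pressures must be strictly increasing")
        if any(i <= 0 for _, i, _ in pts):
            raise ValueError("intensities must be > 0")

    @property
    def pressures(self) -> np.ndarray:
        return np.array([p for p, _, _ in self.points])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i, _ in self.points])

    @property
    def excitation_powers(self) -> np.ndarray:
        return np.array([pw for _, _, pw in self.points])

    @classmethod
    def from_tsv(cls, path) -> "PressureSeries":
        df = _read_series_tsv(path, 3)
        return cls(list(zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.points,
                     columns=["pressure_gpa", "intensity", "power_mw"]).to_csv(
            path, sep="\t", index=False)


@dataclass(frozen=True)
class PhotonBudget:
    """Factors of the multiplicative infrared→visible photon budget."""

    ir_flux: PhotonFlux
    efficiency: float
    enhancement: float = 1.0
    extra_factors: tuple = ()

    def __post_init__(self) -> None:
        if not 0 <= self.efficiency <= 1:
            raise ValueError("efficiency must be in [0, 1]")
        if self.enhancement <= 0:
            raise ValueError("enhancement must be > 0")
        facs = tuple(self.extra_factors)
        object.__setattr__(self, "extra_factors", facs)
        for name, value in facs:
            if value <= 0:
                raise ValueError(f"extra factor {name!r} must be > 0")


def shg_wavelength(lambda_ex: float) -> float:
    """Second-harmonic emission wavelength: half the excitation wavelength."""
    if lambda_ex <= 0:
        raise ValueError("excitation wavelength must be > 0 nm")
    return lambda_ex / 2.0


def fit_power_law(series: PowerSeries) -> PowerLawFit:
    """Fit I = a·P^b by OLS of log10 I on log10 P_ex.

    Points with non-positive intensity carry no log-domain information and
    are dropped with a warning; at least 3 usable points are required.
    The slope b is 2 for an ideal second-harmonic process.
    """
    P, I = series.powers, series.intensities
    usable = I > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning("fit_power_law: dropping %d non-positive intensity point(s)",
                       n_dropped)
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable (positive-intensity) points")
    x, y = np.log10(P[usable]), np.log10(I[usable])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / ss_tot)
    return PowerLawFit(exponent=float(slope), log_prefactor=float(intercept),
                       r_squared=min(1.0, r2))


def correct_output_power(measured_mw: float, losses: LossBudget) -> float:
    """Undo instrument losses: measured / (QE · fiber · beamsplitter)."""
    if measured_mw < 0:
        raise ValueError("measured power must be >= 0")
    t = losses.throughput
    if t == 0:
        raise ValueError("loss budget throughput is zero")
    return measured_mw / t


def conversion_efficiency(corrected_output_mw: float, p_ex_mw: float) -> float:
    """η = loss-corrected SHG output power / excitation power."""
    if p_ex_mw <= 0:
        raise ValueError("excitation power must be > 0 mW")
    return corrected_output_mw / p_ex_mw


def pressure_enhancement(series: PressureSeries) -> float:
    """Efficiency gain between the first and the highest-pressure point.

    Each point's intensity is normalized by P_ex² before taking the ratio,
    so the result reflects the change in nonlinear susceptibility rather
    than differences in excitation power between pressure points.
    """
    eff = series.intensities / series.excitation_powers**2
    if eff[0] <= 0:
        raise ValueError("initial (lowest-pressure) efficiency is zero")
    return float(eff[-1] / eff[0])


def photon_budget(budget: PhotonBudget) -> PhotonFlux:
    """Visible photon flux = IR flux × η × enhancement × Π extra factors.

    The output band defaults to the second-harmonic (half-wavelength) band
    of the input flux's band.
    """
    value = budget.ir_flux.value * budget.efficiency * budget.enhancement
    for _, factor in budget.extra_factors:
        value *= factor
    out_band = budget.ir_flux.band.halved() if budget.ir_flux.band else None
    names = "".join(f" x {n}={v:g}" for n, v in budget.extra_factors)
    desc = (f"SHG budget: {budget.ir_flux.value:g} x eta={budget.efficiency:g}"
            f" x enh={budget.enhancement:g}{names}")
    return PhotonFlux(value=value, band=out_band, source_description=desc)


def orders_of_magnitude_ratio(a: PhotonFlux, b: PhotonFlux) -> float:
    """log10 of the flux ratio a/b."""
    if a.value <= 0 or b.value <= 0:
        raise ValueError("both fluxes must be > 0")
    return math.log10(a.value / b.value)


def _read_series_tsv(path, min_cols: int) -> pd.DataFrame:
    """Read a numeric TSV with a one-line header, skipping '#' comments."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < min_cols:
        raise ValueError(
            f"{path}: expected >= {min_cols} columns, found {df.shape[1]}")
    return df
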