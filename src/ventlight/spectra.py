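"""Spectrum handling, peak detection, Gaussian decomposition, pigment overlap.

The fluorescence emission of *Synechococcus* sp. PCC 7002 pumped through a
chalcopyrite second-harmonic substrate is a narrow 532 nm line plus a broad
610–810 nm band; the band decomposes into three Gaussian components near
656 nm (phycobilisome), 685 nm (photosystem II) and 713 nm (photosystem I).
This module fits that decomposition and scores how well mineral emission
spectra overlap photosynthetic pigment absorption bands.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal

__all__ = [
    "Spectrum",
    "GaussianComponent",
    "DecompositionResult",
    "PigmentTemplate",
    "FWHM_PER_SIGMA",
    "detect_peaks",
    "narrowest_peak",
    "decompose_gaussians",
    "overlap_score",
    "match_pigments",
    "substrate_control_classify",
    "default_pigment_templates",
]

logger = logging.getLogger(__name__)

#: FWHM = 2 sqrt(2 ln 2) sigma
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class Spectrum:
    """Intensity versus wavelength on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "intensities", i)
        if w.ndim != 1 or i.ndim != 1 or w.size != i.size:
            raise ValueError("wavelengths and intensities must be 1-D, equal length")
        if w.size < 8:
            raise ValueError("a spectrum needs at least 8 samples")
        if np.any(~np.isfinite(w)) or np.any(~np.isfinite(i)):
            raise ValueError("NaN/inf in spectrum")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(i < 0):
            raise ValueError("intensities must be non-negative")

    def window(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to wavelengths in [lo, hi]."""
        m = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        return Spectrum(self.wavelengths[m], self.intensities[m], self.label)

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "Spectrum":
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["wavelength_nm", "intensity"], header=None)
        # tolerate an optional non-numeric header line
        df = df.apply(pd.to_numeric, errors="coerce").dropna()
        return cls(df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy(),
                   label=label or str(path))

    def to_tsv(self, path) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelengths,
                      "intensity": self.intensities}).to_csv(
            path, sep="\t", index=False, header=False)


@dataclass(frozen=True)
class GaussianComponent:
    center: float
    sigma: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def fwhm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma

    def __call__(self, lam):
        return self.amplitude * np.exp(-0.5 * ((np.asarray(lam) - self.center)
                                               / self.sigma) ** 2)


@dataclass(frozen=True)
class DecompositionResult:
    """Sum-of-Gaussians + constant baseline fit, components sorted by center."""

    components: tuple
    baseline: float
    residual_rms: float

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        if any(b.center < a.center for a, b in zip(comps, comps[1:])):
            comps = tuple(sorted(comps, key=lambda c: c.center))
        object.__setattr__(self, "components", comps)
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be >= 0")

    def model(self, lam):
        out = np.full_like(np.asarray(lam, dtype=float), self.baseline)
        for c in self.components:
            out = out + c(lam)
        return out

    def to_json(self) -> str:
        return json.dumps({
            "baseline": self.baseline,
            "residual_rms": self.residual_rms,
            "components": [
                {"center_nm": c.center, "sigma_nm": c.sigma,
                 "fwhm_nm": c.fwhm, "amplitude": c.amplitude}
                for c in self.components
            ],
        })


@dataclass(frozen=True)
class PigmentTemplate:
    """Named pigment absorption template, normalized to unit maximum."""

    name: str
    absorption: Spectrum
    nominal_peaks: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "nominal_peaks", tuple(self.nominal_peaks))
        if not math.isclose(float(self.absorption.intensities.max()), 1.0,
                            rel_tol=1e-9):
            raise ValueError(f"{self.name}: absorption must be normalized to max 1")


def detect_peaks(s: Spectrum, min_prominence: float = 0.05) -> list[float]:
    """Local maxima with prominence above ``min_prominence`` × max intensity.

    Returns peak wavelengths (on the grid) sorted ascending; may be empty.
    """
    if s.intensities.max() <= 0:
        return []
    idx, _ = signal.find_peaks(
        s.intensities, prominence=min_prominence * float(s.intensities.max()))
    return [float(s.wavelengths[i]) for i in idx]


def narrowest_peak(s: Spectrum, min_prominence: float = 0.05) -> float:
    """Wavelength of the detected peak with the smallest half-max width.

    Distinguishes a narrow second-harmonic line from broad fluorescence
    bands.  Raises if no peak is detected.
    """
    if s.intensities.max() <= 0:
        raise ValueError("no peaks in an all-zero spectrum")
    idx, _ = signal.find_peaks(
        s.intensities, prominence=min_prominence * float(s.intensities.max()))
    if idx.size == 0:
        raise ValueError("no peaks above the prominence threshold")
    widths = signal.peak_widths(s.intensities, idx, rel_height=0.5)[0]
    return float(s.wavelengths[idx[int(np.argmin(widths))]])


def _gauss_sum(lam, params, k):
    # params = [baseline, c1, s1, a1, c2, s2, a2, ...]
    out = np.full_like(lam, params[0])
    for j in range(k):
        c, sg, a = params[1 + 3 * j: 4 + 3 * j]
        out = out + a * np.exp(-0.5 * ((lam - c) / sg) ** 2)
    return out


def decompose_gaussians(s: Spectrum, k: int, init: str = "peaks",
                        seed: int = 0, n_restarts: int = 10) -> DecompositionResult:
    """Fit k Gaussians plus a constant baseline by nonlinear least squares.

    Initialization places components at the ``k`` most prominent detected
    peaks (remaining centers spread uniformly across the window when fewer
    are found); a seeded multi-start perturbs the initial centers and the
    best of the restarts is kept, so the result is deterministic given
    ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if init not in ("peaks", "uniform"):
        raise ValueError(f"unknown init strategy {init!r}")
    lam = s.wavelengths
    y = s.intensities
    lo, hi = float(lam[0]), float(lam[-1])
    span = hi - lo

    centers: list[float] = []
    if init == "peaks":
        idx, props = signal.find_peaks(y, prominence=0.01 * max(y.max(), 1e-300))
        order = np.argsort(props["prominences"])[::-1]
        centers = [float(lam[idx[i]]) for i in order[:k]]
    missing = k - len(centers)
    if missing > 0:
        centers += list(np.linspace(lo + span / (missing + 1), hi - span / (missing + 1),
                                    missing))
    centers = sorted(centers)

    sigma0 = max(span / (4.0 * k), 1.0)
    amp0 = max(float(y.max() - y.min()), 1e-12)
    base0 = float(np.percentile(y, 5))

    lower = [-np.inf] + [lo, 0.2, 0.0] * k
    upper = [np.inf] + [hi, span, np.inf] * k

    def residuals(p):
        return _gauss_sum(lam, p, k) - y

    rng = np.random.default_rng(seed)
    best = None
    for trial in range(max(1, n_restarts)):
        c_init = list(centers)
        if trial > 0:
            c_init = [float(np.clip(c + rng.normal(0, 0.05 * span), lo, hi))
                      for c in centers]
        p0 = [base0]
        for c in sorted(c_init):
            p0 += [c, sigma0, amp0]
        try:
            res = optimize.least_squares(residuals, p0, bounds=(lower, upper),
                                         method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:  # singular start; try next restart
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("Gaussian decomposition failed to converge from any start")

    p = best.x
    comps = tuple(
        GaussianComponent(center=float(p[1 + 3 * j]), sigma=float(p[2 + 3 * j]),
                          amplitude=float(p[3 + 3 * j]))
        for j in range(k)
    )
    rms = float(np.sqrt(np.mean(residuals(p) ** 2)))
    return DecompositionResult(components=comps, baseline=float(p[0]),
                               residual_rms=rms)


def overlap_score(emission: Spectrum, absorption: Spectrum) -> float:
    """Normalized spectral overlap ∫e·a dλ / √(∫e²dλ · ∫a²dλ) in [0, 1].

    Both spectra are linearly resampled onto the union grid restricted to
    the intersection of their supports; 1 iff the shapes are proportional
    there, 0 (with a warning) for disjoint supports.
    """
    lo = max(emission.wavelengths[0], absorption.wavelengths[0])
    hi = min(emission.wavelengths[-1], absorption.wavelengths[-1])
    if lo >= hi:
        warnings.warn("overlap_score: spectra have disjoint wavelength supports")
        return 0.0
    grid = np.union1d(emission.wavelengths, absorption.wavelengths)
    grid = grid[(grid >= lo) & (grid <= hi)]
    e = np.interp(grid, emission.wavelengths, emission.intensities)
    a = np.interp(grid, absorption.wavelengths, absorption.intensities)
    num = np.trapezoid(e * a, grid)
    den = math.sqrt(np.trapezoid(e * e, grid) * np.trapezoid(a * a, grid))
    if den == 0:
        return 0.0
    return float(min(1.0, num / den))


def match_pigments(peak_lambda: float, pigments: list[PigmentTemplate] | None = None,
                   tolerance: float = 20.0) -> list[tuple[PigmentTemplate, float]]:
    """Pigments with a nominal absorption peak within ``tolerance`` nm.

    Returns (template, distance) pairs sorted by |peak − nearest nominal
    peak| ascending; may be empty.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if pigments is None:
        pigments = default_pigment_templates()
    scored = []
    for pig in pigments:
        d = min(abs(peak_lambda - p) for p in pig.nominal_peaks)
        if d <= tolerance:
            scored.append((pig, d))
    scored.sort(key=lambda t: t[1])
    return scored


def substrate_control_classify(spectra: dict[str, Spectrum],
                               lambda_ex: float = 1064.0,
                               shg_tolerance: float = 3.0,
                               band: tuple[float, float] = (610.0, 810.0),
                               snr_factor: float = 5.0) -> dict[str, dict[str, bool]]:
    """Per-condition flags: is the SHG line there, is the cell band there?

    ``has_shg_line`` — a detected peak lies within ±``shg_tolerance`` nm of
    λ_ex/2 and rises ``snr_factor`` noise sigmas above the local baseline
    (both estimated from the flanks of the line, median and MAD-based).
    ``has_cell_band`` — the baseline-subtracted signal integrated over
    ``band`` exceeds ``snr_factor`` times the expected integrated noise,
    with baseline and noise scale estimated from the flanks of the band.
    """
    out = {}
    for label, s in spectra.items():
        shg_nm = lambda_ex / 2.0
        peaks = detect_peaks(s, min_prominence=0.05)
        near = ((np.abs(s.wavelengths - shg_nm) > 10)
                & (np.abs(s.wavelengths - shg_nm) <= 40))
        if not near.any():
            near = np.ones_like(s.wavelengths, dtype=bool)
        line_base = float(np.median(s.intensities[near]))
        line_mad = float(np.median(np.abs(s.intensities[near] - line_base)))
        line_sigma = max(1.4826 * line_mad, 1e-12)
        in_win = np.abs(s.wavelengths - shg_nm) <= shg_tolerance
        line_height = (float(s.intensities[in_win].max()) - line_base
                       if in_win.any() else 0.0)
        has_line = (line_height > snr_factor * line_sigma
                    and any(abs(p - shg_nm) <= shg_tolerance for p in peaks))

        lo, hi = band
        flank = ((s.wavelengths >= lo - 50) & (s.wavelengths < lo)) | \
                ((s.wavelengths > hi) & (s.wavelengths <= hi + 40))
        if not flank.any():
            flank = s.wavelengths < lo
        base = float(np.median(s.intensities[flank]))
        mad = float(np.median(np.abs(s.intensities[flank] - base)))
        sigma = max(1.4826 * mad, 1e-12)

        inband = (s.wavelengths >= lo) & (s.wavelengths <= hi)
        w, y = s.wavelengths[inband], s.intensities[inband]
        integral = float(np.trapezoid(y - base, w))
        step = float(np.median(np.diff(w))) if w.size > 1 else 1.0
        # variance of the integral: per-sample noise plus the error of the
        # flank-median baseline propagated across all n in-band samples
        n = max(w.size, 1)
        n_flank = max(int(flank.sum()), 1)
        noise_integral = sigma * step * math.sqrt(n + (math.pi / 2) * n**2
                                                  / n_flank)
        has_band = integral > snr_factor * noise_integral

        out[label] = {"has_shg_line": has_line, "has_cell_band": has_band}
    return out


def _gaussian_spectrum(name: str, bands: list[tuple[float, float]],
                       grid=(350.0, 780.0, 1.0)) -> Spectrum:
    lo, hi, step = grid
    lam = np.arange(lo, hi + step / 2, step)
    y = np.zeros_like(lam)
    for center, sigma in bands:
        y += np.exp(-0.5 * ((lam - center) / sigma) ** 2)
    y /= y.max()
    return Spectrum(lam, y, label=name)


def default_pigment_templates() -> list[PigmentTemplate]:
    """Synthetic stand-in absorption templates for the major pigments.

    Gaussian bands at the nominal peak positions reported for cyanobacterial
    and algal pigments (Soret/Q_y bands of the chlorophylls, a carotenoid
    plateau, and the phycobilin chromophores); only the nominal peak
    positions are meaningful, the band shapes are idealized.
    """

    def make(name, bands, peaks):
        return PigmentTemplate(name=name,
                               absorption=_gaussian_spectrum(name, bands),
                               nominal_peaks=peaks)

    return [
        make("chlorophyll_a", [(430.0, 18.0), (662.0, 15.0)], (430.0, 662.0)),
        make("chlorophyll_b", [(453.0, 18.0), (642.0, 15.0)], (453.0, 642.0)),
        make("carotenoids", [(450.0, 20.0), (475.0, 20.0), (500.0, 20.0)],
             (450.0, 475.0, 500.0)),
        make("phycourobilin", [(495.0, 20.0)], (495.0,)),
        make("phycoerythrocyanin", [(575.0, 22.0)], (575.0,)),
        make("allophycocyanin", [(650.0, 18.0)], (650.0,)),
    ]
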