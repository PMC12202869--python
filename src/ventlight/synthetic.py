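"""Seeded generators for every input the analysis stages consume.

Each generator is a pure function of its arguments (including the seed),
emulating the study conditions of the measurements the pipeline analyses:
quadratic SHG power series, diamond-anvil-cell pressure series with an
embedded efficiency enhancement, cyanobacterial fluorescence spectra with
their substrate controls, mineral SHG emission templates, and DIAMOND-style
read-hit tables realizing designed per-apparatus presence profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .metagenome import (APPARATUS_CATEGORIES, GeneCatalog, HitRecord,
                         load_default_catalog)
from .shg import PowerSeries, PressureSeries
from .spectra import Spectrum

__all__ = [
    "SimulationConfig",
    "PresenceProfile",
    "DEFAULT_POWERS_MW",
    "DEFAULT_PROFILES",
    "FLUOR_CONDITIONS",
    "gen_power_series",
    "gen_pressure_series",
    "gen_fluorescence_spectrum",
    "gen_mineral_templates",
    "gen_hit_table",
]

#: Excitation powers spanning the measured 0.45–3.20 mW range.
DEFAULT_POWERS_MW = (0.45, 0.80, 1.20, 1.70, 2.40, 3.20)

FLUOR_CONDITIONS = ("cpy_7002", "glass_7002", "gal_7002", "cpy_medium")


@dataclass(frozen=True)
class SimulationConfig:
    """Shared knobs for the generators."""

    seed: int = 0
    noise_level: float = 0.02
    grid_step: float = 1.0
    library_size: int = 1_000_000
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class PresenceProfile:
    """Designed per-category completeness fraction for each vent type."""

    fractions: dict

    def __post_init__(self) -> None:
        for vtype, cats in self.fractions.items():
            for cat, f in cats.items():
                if cat not in APPARATUS_CATEGORIES:
                    raise ValueError(f"{vtype}: unknown category {cat!r}")
                if not 0 <= f <= 1:
                    raise ValueError(f"{vtype}/{cat}: fraction must be in [0,1]")


def _default_profiles() -> PresenceProfile:
    full = {"PSI": 1.0, "PSII": 1.0, "Cytb6f": 1.0, "PET": 1.0, "ATPase": 1.0}
    return PresenceProfile({
        # hot chalcopyrite-rich vent centres: near-complete apparatus,
        # phycobilisome genes around 80%, no far-red acclimation genes
        "C1": {**full, "PBS_APC": 0.8, "PBS_PC_PEC": 0.8, "PBS_PE": 0.8,
               "FaRLiP": 0.0},
        # cooler Pb/Zn vents: photosystems largely absent
        "C2": {"PSI": 0.2, "PSII": 0.2, "Cytb6f": 0.2, "PET": 0.5,
               "ATPase": 1.0, "PBS_APC": 0.3, "PBS_PC_PEC": 0.3,
               "PBS_PE": 0.2, "FaRLiP": 0.0},
        # shallow euphotic-zone deposits: relatively complete
        "S": {**full, "PBS_APC": 0.9, "PBS_PC_PEC": 0.9, "PBS_PE": 0.9,
              "FaRLiP": 0.0},
        # non-vent deep sea: phycobilisomes absent, photosystems incomplete
        "N": {"PSI": 0.3, "PSII": 0.3, "Cytb6f": 0.4, "PET": 0.5,
              "ATPase": 1.0, "PBS_APC": 0.0, "PBS_PC_PEC": 0.0,
              "PBS_PE": 0.0, "FaRLiP": 0.0},
        # oxidation zone: moderate apparatus, phycobiliproteins missing
        "O": {"PSI": 0.7, "PSII": 0.7, "Cytb6f": 0.7, "PET": 0.7,
              "ATPase": 1.0, "PBS_APC": 0.0, "PBS_PC_PEC": 0.0,
              "PBS_PE": 0.0, "FaRLiP": 0.0},
        # subsurface rock: half of PSII, rod phycobiliproteins missing
        "T1": {"PSI": 0.6, "PSII": 0.5, "Cytb6f": 0.6, "PET": 0.6,
               "ATPase": 1.0, "PBS_APC": 0.5, "PBS_PC_PEC": 0.0,
               "PBS_PE": 0.0, "FaRLiP": 0.0},
        # thermophilic enrichment cultures
        "T2": {"PSI": 0.7, "PSII": 0.7, "Cytb6f": 0.8, "PET": 0.8,
               "ATPase": 1.0, "PBS_APC": 0.6, "PBS_PC_PEC": 0.5,
               "PBS_PE": 0.4, "FaRLiP": 0.0},
    })


DEFAULT_PROFILES = _default_profiles()


def gen_power_series(lambda_ex: float = 928.0,
                     powers=DEFAULT_POWERS_MW,
                     prefactor: float = 1.0,
                     exponent: float = 2.0,
                     noise_level: float = 0.02,
                     seed: int = 0) -> PowerSeries:
    """SHG power series I = prefactor·P^exponent·(1 + ε), ε ~ N(0, noise)."""
    rng = np.random.default_rng(seed)
    P = np.asarray(powers, dtype=float)
    if np.any(P <= 0):
        raise ValueError("powers must be > 0 mW")
    eps = rng.normal(0.0, noise_level, size=P.size) if noise_level > 0 else 0.0
    I = np.clip(prefactor * P**exponent * (1.0 + eps), 1e-300, None)
    return PowerSeries(lambda_ex, list(zip(P, I)))


def gen_pressure_series(n_points: int = 8,
                        enhancement: float = 66.0,
                        noise_level: float = 0.05,
                        seed: int = 0,
                        p_ex_mw: float = 1.0,
                        base_intensity: float = 1.0) -> PressureSeries:
    """DAC series whose last/first P-normalized efficiency ratio is
    ``enhancement`` before noise.

    Pressures rise over 0.3–12 GPa (the published series does not print
    its pressure values); the efficiency profile is geometric in the point
    index, multiplicative Gaussian noise is applied per point.
    """
    if n_points < 2:
        raise ValueError("need at least 2 pressure points")
    rng = np.random.default_rng(seed)
    pressures = np.linspace(0.3, 12.0, n_points)
    gain = enhancement ** (np.arange(n_points) / (n_points - 1))
    eps = rng.normal(0.0, noise_level, size=n_points) if noise_level > 0 else 0.0
    intensity = np.clip(base_intensity * gain * p_ex_mw**2 * (1.0 + eps),
                        1e-300, None)
    return PressureSeries([(p, i, p_ex_mw) for p, i in zip(pressures, intensity)])


def _gauss(lam, center, sigma, amp):
    return amp * np.exp(-0.5 * ((lam - center) / sigma) ** 2)


def gen_fluorescence_spectrum(condition: str = "cpy_7002",
                              lambda_ex: float = 1064.0,
                              noise_level: float = 0.01,
                              seed: int = 0,
                              grid_step: float = 1.0) -> Spectrum:
    """Synthetic in-situ fluorescence spectrum on a 400–850 nm grid.

    ``cpy_7002``  — narrow second-harmonic line at λ_ex/2 (σ = 2 nm) plus
    the cell band: Gaussians at 656/685/713 nm (σ 15/15/16 nm, amplitudes
    0.6/1.0/0.5).  ``cpy_medium`` — the SHG line only (sterile medium).
    ``glass_7002`` / ``gal_7002`` — baseline noise only (no SHG substrate).
    Noise is multiplicative on the signal plus a small additive floor.
    """
    if condition not in FLUOR_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"expected one of {FLUOR_CONDITIONS}")
    rng = np.random.default_rng(seed)
    lam = np.arange(400.0, 850.0 + grid_step / 2, grid_step)
    signal = np.zeros_like(lam)
    if condition in ("cpy_7002", "cpy_medium"):
        signal += _gauss(lam, lambda_ex / 2.0, 2.0, 3.0)
    if condition == "cpy_7002":
        signal += _gauss(lam, 656.0, 15.0, 0.6)
        signal += _gauss(lam, 685.0, 15.0, 1.0)
        signal += _gauss(lam, 713.0, 16.0, 0.5)
    baseline = 0.01
    mult = rng.normal(0.0, noise_level, size=lam.size)
    floor = rng.normal(0.0, 0.002, size=lam.size)
    y = np.clip(signal * (1.0 + mult) + baseline + floor, 0.0, None)
    return Spectrum(lam, y, label=f"{condition} λ_ex={lambda_ex:g} nm")


# (band_min, band_max, peak_nm, sigma_nm) of each mineral's SHG emission
_MINERAL_BANDS = {
    "chalcopyrite": (420.0, 540.0, 471.0, 25.0),
    "bismuthinite": (420.0, 550.0, 490.0, 28.0),
    "orpiment": (420.0, 725.0, 560.0, 70.0),
    "molybdenite": (550.0, 700.0, 590.0, 22.0),
    "stibnite": (550.0, 700.0, 610.0, 24.0),
}


def gen_mineral_templates(grid_step: float = 1.0) -> dict[str, Spectrum]:
    """Idealized SHG emission templates of the five up-converting sulfides.

    Gaussian bands truncated to each mineral's reported emission window,
    normalized to unit maximum, on a 400–750 nm grid; deterministic.
    """
    lam = np.arange(400.0, 750.0 + grid_step / 2, grid_step)
    out = {}
    for name, (lo, hi, peak, sigma) in _MINERAL_BANDS.items():
        y = _gauss(lam, peak, sigma, 1.0)
        y[(lam < lo) | (lam > hi)] = 0.0
        y /= y.max()
        out[name] = Spectrum(lam, y, label=name)
    return out


_READ_LEN_AA = 60
_READ_STRIDE_AA = 30  # 2x tiling: any single dropped read leaves no gap


def _reads_for_present_gene(length: int):
    """Subject intervals tiling [1, length] with two-fold redundancy."""
    if length <= _READ_LEN_AA:
        return [(1, length), (1, length)]
    starts = list(range(1, length - _READ_LEN_AA + 2, _READ_STRIDE_AA))
    if starts[-1] + _READ_LEN_AA - 1 < length:
        starts.append(length - _READ_LEN_AA + 1)
    return [(s, s + _READ_LEN_AA - 1) for s in starts]


def _designed_presence(profile: PresenceProfile, catalog: GeneCatalog,
                       vtype: str) -> tuple[dict[str, bool], dict[str, float]]:
    present: dict[str, bool] = {}
    design: dict[str, float] = {}
    for cat in APPARATUS_CATEGORIES:
        genes = sorted(catalog.genes_in(cat))
        frac = profile.fractions.get(vtype, {}).get(cat, 0.0)
        n_present = int(round(frac * len(genes)))
        for j, g in enumerate(genes):
            present[g] = j < n_present
        design[cat] = n_present / len(genes) if genes else 0.0
    return present, design


def gen_hit_table(profile: PresenceProfile | None = None,
                  catalog: GeneCatalog | None = None,
                  config: SimulationConfig = SimulationConfig(),
                  datasets_per_type: int = 1,
                  out_dir=None):
    """Simulated DIAMOND outfmt-6 hit tables realizing a presence design.

    For every vent type in ``profile`` generates ``datasets_per_type``
    datasets.  Genes designated present receive reads tiling the full gene
    (two-fold redundant, so breadth stays ≥ 0.8 under moderate Bernoulli
    read dropout); absent genes receive a single sub-threshold hit covering
    30% of the gene.  Returns ``(hits_by_dataset, library_sizes, meta,
    design_matrix)``; with ``out_dir`` the same content is written as
    per-dataset ``<id>.hits.tsv`` plus ``library_sizes.tsv`` and
    ``metadata.tsv``.
    """
    profile = profile or DEFAULT_PROFILES
    catalog = catalog or load_default_catalog()
    rng = np.random.default_rng(config.seed)

    hits_by_dataset: dict[str, list[HitRecord]] = {}
    library_sizes: dict[str, int] = {}
    meta: dict[str, str] = {}
    design_rows = {}

    for vtype in profile.fractions:
        present, design = _designed_presence(profile, catalog, vtype)
        for rep in range(1, datasets_per_type + 1):
            ds = f"{vtype}_{rep}"
            records: list[HitRecord] = []
            ridx = 0
            for gene in sorted(catalog.gene_ids):
                length = catalog.length(gene)
                if present[gene]:
                    intervals = _reads_for_present_gene(length)
                else:
                    end = max(1, int(0.3 * length))
                    intervals = [(1, end)]
                for s, e in intervals:
                    if config.dropout and rng.random() < config.dropout:
                        continue
                    ridx += 1
                    pid = float(np.clip(92.0 + rng.normal(0, 3.0), 60.0, 100.0))
                    bits = float(np.clip(120.0 + rng.normal(0, 10.0), 40.0, None))
                    records.append(HitRecord(
                        read_id=f"{ds}_r{ridx}", gene_id=gene,
                        percent_identity=pid, align_length=e - s + 1,
                        bitscore=bits, subject_start=s, subject_end=e))
            hits_by_dataset[ds] = records
            library_sizes[ds] = config.library_size
            meta[ds] = vtype
            design_rows[ds] = dict(design)

    design_matrix = pd.DataFrame.from_dict(design_rows, orient="index")
    design_matrix.index.name = "dataset"

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for ds, records in hits_by_dataset.items():
            with open(out_dir / f"{ds}.hits.tsv", "w") as fh:
                for r in records:
                    qlen_nt = r.align_length * 3
                    fh.write("\t".join(map(str, (
                        r.read_id, r.gene_id, f"{r.percent_identity:.1f}",
                        r.align_length, 0, 0, 1, qlen_nt,
                        r.subject_start, r.subject_end, "1e-30",
                        f"{r.bitscore:.1f}"))) + "\n")
        pd.DataFrame(sorted(library_sizes.items()),
                     columns=["dataset", "library_size"]).to_csv(
            out_dir / "library_sizes.tsv", sep="\t", index=False)
        pd.DataFrame([(ds, vt, "hot" if vt == "C1" else "other")
                      for ds, vt in sorted(meta.items())],
                     columns=["dataset", "vent_type", "temperature_class"]).to_csv(
            out_dir / "metadata.tsv", sep="\t", index=False)

    return hits_by_dataset, library_sizes, meta, design_matrix
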