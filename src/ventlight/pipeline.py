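"""End-to-end orchestration: the photon budget report and the full demo.

Ties the stages together: a vent's blackbody infrared radiance, the
pressure-enhanced SHG conversion to visible light, the comparison against
the thermal visible-light ceiling and the photon requirements of low-light
and laboratory phototrophs, plus a seeded all-stages demonstration run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import radiometry as rad
from . import shg
from . import spectra as spec
from . import metagenome as mg
from . import synthetic as syn

__all__ = ["RunConfig", "ConfigError", "run_photon_budget", "run_full_demo"]

#: The rounded literature infrared photon flux the headline budget starts from.
NOMINAL_IR_FLUX = 1e12


class ConfigError(ValueError):
    """Raised with every validation problem listed at once."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


@dataclass(frozen=True)
class RunConfig:
    """Inputs of the photon-budget report.

    ``use_planck_integral`` switches the infrared flux from the rounded
    literature constant 10¹² to this package's own Planck band integral.
    """

    temperature_c: float = 400.0
    ir_band: rad.SpectralBand = field(
        default_factory=lambda: rad.SpectralBand(800.0, 1100.0))
    visible_band: rad.SpectralBand | None = None
    efficiency: float = 1e-7
    enhancement: float = 66.0
    extra_factors: tuple = ()
    emissivity: float = 1.0
    reference_visible_limit: float = rad.VISIBLE_BLACKBODY_LIMIT
    use_planck_integral: bool = False

    def validate(self) -> None:
        problems = []
        if self.temperature_c <= -273.15:
            problems.append(f"temperature {self.temperature_c} °C is below 0 K")
        if not 0 <= self.efficiency <= 1:
            problems.append(f"efficiency {self.efficiency} outside [0, 1]")
        if self.enhancement <= 0:
            problems.append(f"enhancement {self.enhancement} must be > 0")
        for name, v in self.extra_factors:
            if v <= 0:
                problems.append(f"extra factor {name!r} = {v} must be > 0")
        if self.reference_visible_limit <= 0:
            problems.append("reference visible limit must be > 0")
        if not 0 < self.emissivity <= 1:
            problems.append(f"emissivity {self.emissivity} outside (0, 1]")
        if problems:
            raise ConfigError(problems)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "temperature_c" in raw:
            kwargs["temperature_c"] = float(raw["temperature_c"])
        if "ir_band" in raw:
            lo, hi = raw["ir_band"]
            kwargs["ir_band"] = rad.SpectralBand(float(lo), float(hi))
        for key in ("efficiency", "enhancement", "reference_visible_limit",
                    "emissivity"):
            if key in raw:
                kwargs[key] = float(raw[key])
        if "extra_factors" in raw:
            kwargs["extra_factors"] = tuple(
                (str(k), float(v)) for k, v in dict(raw["extra_factors"]).items())
        if "use_planck_integral" in raw:
            kwargs["use_planck_integral"] = bool(raw["use_planck_integral"])
        return cls(**kwargs)


def run_photon_budget(config: RunConfig = RunConfig()) -> dict:
    """The quantitative core of the argument, as one JSON-ready report.

    Computes the vent's infrared photon radiance (Planck integral and the
    rounded constant actually used downstream), the SHG visible flux, the
    log₁₀ excess over the thermal visible ceiling, and the comparison with
    the low-light (∼10¹¹) and laboratory (∼10¹³) photon requirements.
    """
    config.validate()
    t_k = config.temperature_c + 273.15
    source = rad.BlackbodySource(temperature=t_k, emissivity=config.emissivity)
    planck = rad.band_photon_flux(config.ir_band, source)
    ir_value = planck.value if config.use_planck_integral else NOMINAL_IR_FLUX
    ir_flux = rad.PhotonFlux(ir_value, band=config.ir_band,
                             source_description="vent infrared radiance")

    budget = shg.PhotonBudget(ir_flux=ir_flux, efficiency=config.efficiency,
                              enhancement=config.enhancement,
                              extra_factors=config.extra_factors)
    visible = shg.photon_budget(budget)
    if config.visible_band is not None:
        visible = rad.PhotonFlux(visible.value, band=config.visible_band,
                                 source_description=visible.source_description)

    ref = rad.PhotonFlux(config.reference_visible_limit,
                         source_description="thermal visible ceiling")
    low_light = rad.mol_flux_to_photon_radiance(rad.LOW_LIGHT_REQUIREMENT_UMOL)

    report = {
        "temperature_K": t_k,
        "ir_band_nm": [config.ir_band.lambda_min, config.ir_band.lambda_max],
        "ir_flux_planck": planck.value,
        "ir_flux_used": ir_flux.value,
        "efficiency": config.efficiency,
        "enhancement": config.enhancement,
        "extra_factors": {n: v for n, v in config.extra_factors},
        "visible_flux": visible.value,
        "visible_band_nm": ([visible.band.lambda_min, visible.band.lambda_max]
                            if visible.band else None),
        "reference_visible_limit": ref.value,
        "log10_excess_over_thermal": (
            shg.orders_of_magnitude_ratio(visible, ref)
            if visible.value > 0 else None),
        "low_light_requirement": low_light,
        "lab_growth_requirement": rad.LAB_GROWTH_REQUIREMENT,
        "meets_low_light_requirement": visible.value >= low_light,
        "meets_lab_growth_requirement": visible.value >= rad.LAB_GROWTH_REQUIREMENT,
    }
    return report


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {exc}")


def run_full_demo(seed: int = 0, out_dir="ventlight_demo") -> dict:
    """Generate every synthetic input, run every stage, write all artifacts.

    Returns a summary dict of the headline numbers; raises
    :class:`StageError` naming the stage if any check misses its tolerance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)
    summary: dict = {"seed": seed}

    def _fmt(x):  # 6 significant digits for diffable artifacts
        return float(f"{x:.6g}")

    try:
        report = run_photon_budget(RunConfig())
        (out / "photon_budget.json").write_text(
            json.dumps({k: (_fmt(v) if isinstance(v, float) else v)
                        for k, v in report.items()}, indent=1))
        summary["visible_flux"] = report["visible_flux"]
        summary["log10_excess_over_thermal"] = report["log10_excess_over_thermal"]
        if not report["log10_excess_over_thermal"] >= 3.0:
            raise RuntimeError("visible flux fails the three-orders check")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("photon_budget", exc)

    try:
        series = syn.gen_power_series(lambda_ex=928.0, noise_level=0.02,
                                      seed=int(seeds[0]))
        series.to_tsv(out / "power_series.tsv")
        fit = shg.fit_power_law(series)
        (out / "power_law_fit.json").write_text(fit.to_json())
        summary["power_law_exponent"] = fit.exponent
        if abs(fit.exponent - 2.0) > 0.05:
            raise RuntimeError(f"exponent {fit.exponent:.4f} not within 2 ± 0.05")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("power_law", exc)

    try:
        pseries = syn.gen_pressure_series(noise_level=0.05, seed=int(seeds[1]))
        pseries.to_tsv(out / "pressure_series.tsv")
        enh = shg.pressure_enhancement(pseries)
        summary["pressure_enhancement"] = enh
        if not 0.9 * 66 <= enh <= 1.1 * 66:
            raise RuntimeError(f"enhancement {enh:.2f} not within 66 ± 10%")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("pressure_enhancement", exc)

    try:
        conditions = {}
        for i, cond in enumerate(syn.FLUOR_CONDITIONS):
            s = syn.gen_fluorescence_spectrum(cond, seed=int(seeds[2]) + i)
            s.to_tsv(out / f"fluorescence_{cond}.tsv")
            conditions[cond] = s
        flags = spec.substrate_control_classify(conditions, lambda_ex=1064.0)
        (out / "substrate_controls.json").write_text(json.dumps(flags, indent=1))
        expected = {"cpy_7002": (True, True), "glass_7002": (False, False),
                    "gal_7002": (False, False), "cpy_medium": (True, False)}
        for cond, (line, band) in expected.items():
            got = flags[cond]
            if (got["has_shg_line"], got["has_cell_band"]) != (line, band):
                raise RuntimeError(f"{cond}: control flags {got} != {(line, band)}")
        decomp = spec.decompose_gaussians(
            conditions["cpy_7002"].window(600.0, 810.0), k=3,
            seed=int(seeds[3]))
        (out / "fluorescence_decomposition.json").write_text(decomp.to_json())
        centers = [c.center for c in decomp.components]
        summary["fluorescence_centers"] = centers
        for got, want in zip(centers, (656.0, 685.0, 713.0)):
            if abs(got - want) > 2.0:
                raise RuntimeError(f"component {got:.2f} nm not within "
                                   f"{want} ± 2 nm")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("fluorescence", exc)

    try:
        minerals = syn.gen_mineral_templates()
        pigments = spec.default_pigment_templates()
        matches = {}
        for name, template in minerals.items():
            template.to_tsv(out / f"mineral_{name}.tsv")
            peak = max(zip(template.intensities, template.wavelengths))[1]
            ranked = spec.match_pigments(peak, pigments, tolerance=40.0)
            matches[name] = {
                "peak_nm": peak,
                "pigments": [{"name": p.name, "distance_nm": _fmt(d)}
                             for p, d in ranked],
                "overlap": {p.name: _fmt(spec.overlap_score(template, p.absorption))
                            for p in pigments},
            }
        (out / "pigment_matches.json").write_text(json.dumps(matches, indent=1))
        summary["chalcopyrite_peak_nm"] = matches["chalcopyrite"]["peak_nm"]
    except Exception as exc:
        raise StageError("pigment_matching", exc)

    try:
        catalog = mg.load_default_catalog()
        cfg = syn.SimulationConfig(seed=int(seeds[4]), dropout=0.0)
        hits, libs, meta, design = syn.gen_hit_table(
            catalog=catalog, config=cfg, out_dir=out / "metagenome")
        cov = mg.coverage_table(hits, catalog, libs)
        presence = mg.gene_presence(cov, threshold=0.8)
        matrix = mg.apparatus_completeness(presence, catalog, meta=meta)
        mg.export_matrix(matrix, out / "completeness.tsv")
        mismatch = (matrix.values[design.columns.drop("FaRLiP")]
                    - design.drop(columns="FaRLiP")).abs().max().max()
        summary["completeness_max_design_error"] = float(mismatch)
        if mismatch > 1e-12:
            raise RuntimeError(f"completeness deviates from design by {mismatch}")
        farlip = mg.farlip_check(presence, catalog)
        if bool(farlip.get("C1_1", False)):
            raise RuntimeError("far-red probe genes unexpectedly present in C1")
        summary["pbs_mean_completeness_C1"] = float(
            matrix.values.loc["C1_1", ["PBS_APC", "PBS_PC_PEC", "PBS_PE"]].mean())
    except StageError:
        raise
    except Exception as exc:
        raise StageError("metagenome", exc)

    try:
        counts = {"Synechococcus": 40.0, "Prochlorococcus": 25.0,
                  "Thermosynechococcus": 20.0, "Gloeobacter": 15.0}
        abund, h = mg.community_profile(counts)
        (out / "community.json").write_text(json.dumps(
            {"abundances": {k: _fmt(v) for k, v in abund.items()},
             "shannon_index": _fmt(h)}, indent=1))
        summary["shannon_index"] = h
    except Exception as exc:
        raise StageError("community", exc)

    (out / "summary.json").write_text(json.dumps(
        {k: (_fmt(v) if isinstance(v, float) else v) for k, v in summary.items()},
        indent=1))
    return summary
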