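# ventlight

Deep-sea hydrothermal vents emit more blue–green light (400–550 nm) than a
thermal emitter at the vent's temperature can account for, and cyanobacteria
and their photosynthesis genes keep turning up in sulfide deposits far below
the photic zone. `ventlight` is a quantitative toolkit for one proposed
explanation: non-centrosymmetric sulfide minerals — chalcopyrite (CuFeS₂)
above all — up-convert the vent's abundant geothermal infrared radiation
into visible photons by second harmonic generation (SHG), and the resulting
flux sits in the absorption bands of cyanobacterial light-harvesting
pigments.

The package is aimed at geomicrobiologists and biophysicists who want to
reproduce, probe, or extend each link of that argument on their own data or
on the packaged synthetic study conditions.

## The model

The chain of quantities, in the field's standard notation:

1. **Geothermal photon supply.** A vent orifice at temperature *T* radiates
   as a grey body; its spectral photon radiance is

   *n(λ, T) = ε · (2c/λ⁴) / (exp(hc/λk_BT) − 1)*

   in photons·s⁻¹·cm⁻²·sr⁻¹·nm⁻¹. Integrated over the 800–1100 nm band at
   *T* = 673.15 K (400 °C) this gives an infrared photon radiance of order
   10¹² photons·cm⁻²·s⁻¹·sr⁻¹.

2. **SHG up-conversion.** Two photons at frequency ω combine into one at
   2ω: emission at λ/2, with intensity *I* ∝ *P*²_ex (log–log slope 2) and
   energy-conversion efficiency η = *P*_out/*P*_ex rising linearly with
   *P*_ex. Measured output is corrected for the instrument loss chain
   (detector quantum efficiency × fiber coupling × beamsplitter
   transmission). Under hydrostatic pressure in a diamond anvil cell the
   *P*²-normalized efficiency grows by a factor *E* (≈66× with a maximum
   η ≈ 10⁻⁷).

3. **Photon budget.** Visible flux = IR flux × η × *E* (× any optional
   extra factors such as microcavity resonance):
   10¹² × 10⁻⁷ × 66 = 6.6 × 10⁶ photons·cm⁻²·s⁻¹·sr⁻¹, about 3.8 orders of
   magnitude above the ~10³ thermal ceiling for visible blackbody emission
   at vents.

4. **Biological uptake.** Under 1064 nm irradiation on a chalcopyrite
   substrate, *Synechococcus* sp. PCC 7002 fluoresces: a sharp 532 nm SHG
   line plus a broad 610–810 nm band that decomposes into Gaussian
   components near 656 nm (phycobilisome), 685 nm (photosystem II) and
   713 nm (photosystem I). Substrate controls (glass, galena, sterile
   medium) isolate which feature comes from the mineral and which from the
   cells. Mineral SHG emission spectra are scored against pigment
   absorption templates by normalized spectral overlap.

5. **Genomic footprint.** From DIAMOND/BLAST tabular alignments of
   metagenomic reads against a KEGG-orthology catalog, the pipeline keeps
   per-read best hits (bitscore ties shared 1/k), computes per-gene breadth
   of coverage (union of aligned intervals / gene length), calls a gene
   present at ≥80% coverage, and reports per-apparatus completeness
   (PSI, PSII, cytochrome b₆f, electron transport, ATPase, phycobilisome
   families) per dataset, grouped by vent type — plus a far-red
   photoacclimation (FaRLiP) probe and an ATPase-read Shannon diversity.

Every input the stages consume can be generated synthetically with seeded
generators (`ventlight.synthetic`), so the full pipeline runs without any
downloads.

## Worked example

```bash
$ ventlight budget
{"temperature_K": 673.15, "ir_band_nm": [800.0, 1100.0],
 "ir_flux_planck": 9345670000000.0, "ir_flux_used": 1000000000000.0,
 "efficiency": 1e-07, "enhancement": 66.0, "visible_flux": 6600000.0,
 "visible_band_nm": [400.0, 550.0], "reference_visible_limit": 1000.0,
 "log10_excess_over_thermal": 3.81954, ...}
```

The vent's Planck integral over 800–1100 nm is ≈9.35 × 10¹²; the budget
uses the rounded 10¹² constant by default (`--use-planck-integral`
switches), multiplies by η = 10⁻⁷ and the 66× pressure gain, and lands at
6.6 × 10⁶ visible photons·cm⁻²·s⁻¹·sr⁻¹ — 3.8 orders above the 10³
thermal ceiling.

The all-stages demo generates every synthetic input, runs every stage and
checks its tolerances:

```bash
$ ventlight demo --seed 0 --out demo/
{"seed": 0, "visible_flux": 6600000.0, "log10_excess_over_thermal": 3.81954,
 "power_law_exponent": 2.00649, "pressure_enhancement": 61.9828,
 "fluorescence_centers": [655.49, 684.77, 713.04],
 "chalcopyrite_peak_nm": 471.0, "completeness_max_design_error": 0.0,
 "pbs_mean_completeness_C1": 0.794444, "shannon_index": 1.31955}
```

Reading the numbers: the fitted SHG power-law exponent is 2.006 (quadratic,
as SHG requires); the recovered pressure enhancement 62.0 is the embedded
66× within detector noise; the three fluorescence components come back at
655.5/684.8/713.0 nm; the chalcopyrite emission template peaks at 471 nm
(the ~2.63 eV resonance); the metagenomic completeness matrix reproduces
its designed presence profiles exactly at zero read dropout, with mean
phycobilisome completeness in the hot-vent profile at 79% and an ATPase
community Shannon index of 1.32.

Individual stages are available as subcommands (`radiometry`, `shg`,
`fluor`, `pigments`, `metagenome`, `simulate`, `budget`, `demo`); see
`ventlight --help`.

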