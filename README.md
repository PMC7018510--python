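# irlego

Simulation and inference toolkit for single-cell infrared laser-evoked
gene-operator (IR-LEGO) experiments: a focused continuous-wave IR laser
locally heats tissue, drives a heat-shock promoter (e.g. *hsp70l*) to
express CreER in one targeted cell, and a Cre-loxP color switch then marks
that cell and all of its progeny. The package covers the three
computational problems such an experiment poses:

1. **Ratiometric two-photon thermometry** — how hot did the target actually
   get? Mixed emission spectra of a temperature-sensitive probe dye
   (TAMRA-dextran) and a temperature-insensitive reference dye
   (FITC-dextran) are decomposed by nonnegative least squares onto pure-dye
   basis spectra; the coefficient ratio R = a_TAMRA/a_FITC falls linearly
   with temperature, R(T) = b + mT, so a linear calibration converts ratio
   changes into temperature rises that are immune to excitation-power
   fluctuations.
2. **Heat diffusion around the focus** — is the heating confined to one
   cell? Conductive transfer ρc ∂T/∂t = κ∇²T + q with a focal volumetric
   source, solved both in closed form for an ideal point source
   (ΔT = Q/(4πκr), transient factor erfc(r/(2√(αt)))) and by a
   finite-difference solver for extended/scanned sources, with the
   confinement radius of the 38 °C gene-induction contour as the summary.
3. **Lineage inference under background labeling** — what did the labeled
   cell become? Each fish is scored 2×2 by presence/absence of GFP⁺ T
   lymphocytes and myeloid cells; spontaneous promoter activation also
   produces positives in unheated controls. The lineage simplex
   θ = (θ_TM, θ_M, θ_T, θ_0) over {bipotent, myeloid-only, T-only, no
   progeny} and per-channel background rates (β_T, β_M) are estimated by
   maximizing the joint multinomial likelihood of labeled and control
   category counts, with bootstrap confidence intervals and
   Mann–Whitney–Wilcoxon rank-sum comparisons of the raw counts.

A synthetic-data module generates spectra, calibration ramps, temperature
fields and fish cohorts with known ground truth, so every stage is testable
without access to microscope data. It is first-class, seeded and pure:
identical configs give bitwise-identical data.

Intended users: microscopists tuning single-cell heat-shock protocols, and
developmental/hematopoiesis groups analyzing clonal fate-mapping cohorts
with non-negligible background labeling.

## Worked example

A full synthetic run — calibrate the thermometer, simulate an optimized
95 mW heating session in tissue, generate a 27-labeled/109-control
cohort and fit the lineage model:

```python
from irlego import pipeline

cfg = pipeline.RunConfig(
    seed=7,
    output_dir="irlego_demo",
    spectra={"replicates": 5},
    heatsim={
        "grid": {"spacing": 2.0, "half_extent": 60.0},
        "deposition_radius": 2.0, "duration": 32.0,
        "incident_power": 0.095, "medium": "tissue",
        "absorbed_power_fraction": 0.0044,   # calibrated so the focus peaks near 50 degC
    },
    cohort={"n_labeled": 27, "n_control": 109},
)
manifest = pipeline.run_pipeline(cfg)
```

The manifest this prints (seed 7) contains, per stage:

```
spectra:  calibration_slope_per_degC = -0.007352   # ratio falls with T
          relative_sensitivity_pct_per_degC = -0.735, r_squared = 0.996
heatsim:  peak_temperature_degC = 50.59
          confinement_radius_um = 4.42             # 38 degC contour
lineage:  theta_tm = 0.434, theta_m = 0.360, theta_t = 0.000, theta_0 = 0.206
          beta_t = 0.026, beta_m = 0.101
          ranksum_t_p = 2.4e-10, ranksum_m_p = 9.8e-17
```

Reading: the fitted ratio sensitivity (−0.735 %/°C) is the difference of
the two dye sensitivities as expected; the optimized beam keeps the 38 °C
induction region inside a ~4 µm radius, i.e. within one cell; and from only
27 labeled fish the MLE recovers a bipotent-dominant lineage mix while
attributing the control-group positives to background rates of a few
percent. The tiny rank-sum p-values confirm labeled fish carry far more
GFP⁺ cells than controls. Every stage writes its artifacts (TSV spectra
and cohorts, JSON calibration and estimates, NPY+JSON fields) plus a
manifest with the derived per-stage seeds.

The same operations are available from the shell:

```bash
irlego synth cohort --n-labeled 500 --n-control 1000 --seed 4 -o cohort.tsv
irlego lineage fit cohort.tsv
irlego heatsim confine --medium tissue --power 0.095 --deposition-radius 2 --spacing 2
```

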