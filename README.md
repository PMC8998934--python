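# t2flux

Quantitative imaging analysis for preclinical orthotopic brain-tumor
studies: T2-relaxometry tumor volumetry from multi-slice multi-echo (MSME)
MRI, cross-modality calibration against bioluminescence imaging (BLI), and
treatment-group survival analysis — exercised end to end on a synthetic
digital-phantom cohort with known ground truth, so the whole chain is
testable without animal data.

It is written for researchers running longitudinal tumor-growth monitoring
in mouse models (e.g. medulloblastoma xenografts) who quantify tumor burden
with both MRI and luciferase-based BLI and need the two readouts processed,
compared and calibrated reproducibly.

## What it computes

**T2 maps.** A spin echo decays mono-exponentially with echo time TE:

    S(TE) = S0 · exp(−TE / T2)

Fitting (S0, T2) per pixel over the 10-echo time course (TE = 12.5 … 162.5
ms, mean spacing 16.67 ms) by sum-squared-error minimization yields a T2
map. Healthy brain sits near 47 ms, medulloblastoma near 68 ms and CSF near
125 ms, so tumor is bright against brain. A noise-reduced anatomical
contrast (the *T2 average image*) is the pixel-wise mean of the 45.8, 62.5
and 79.2 ms echoes.

**Tumor volumes.** Per slice, rectangular ROIs are binarized with
ROI-individual lower/upper thresholds, the largest 8-connected component of
each ROI is kept, and retained pixels are summed over ROIs and slices. With
the default geometry (20×20 mm FOV, 256×256 matrix, 0.8 mm slices) one
voxel is 0.0048828125 mm³ (0.0048 truncated to 4 decimals).

**Method agreement.** Volumes from T2-map and T2-average contrast are
compared with Bland-Altman limits of agreement (mean ± 1.96 SD of the
paired differences) and a two-sided paired t-test.

**BLI photometry.** Per measurement, a caudal background flux is subtracted
from the tumor-ROI total flux (p/s); the best of the three exposures per
timepoint is kept and each animal's series is normalized to week 1.

**Calibration.** Flux and volume follow a power law `flux = a · V^b`,
fitted as ordinary least squares on the decadic-log scale with R², Spearman
ρ and the regression F-test; expected fluxes and absolute/relative
residuals follow by inverse transformation.

**Survival.** Kaplan-Meier product-limit curves with the median defined as
the first time S(t) ≤ 0.5, two-group log-rank tests, exact two-sided
Mann-Whitney tests (full enumeration up to combined n = 20), and percent
median-survival enhancement over control.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (4 animals, weeks 1–8, down-scaled 48×48 grid, 3% image noise;
conditions in `analysis/config.yaml`):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_fit_t2_maps.py
python analysis/03_measure_volumes.py
python analysis/04_compare_methods.py
python analysis/05_process_bli.py
python analysis/06_calibrate_flux_volume.py
python analysis/07_analyze_survival.py
```

Output of a run (tables and plots land in `results/cohort/`):

```
32 MRI sessions, 96 BLI measurements, 30 animals in survival table
tumor volumes span 0.56-47.36 mm^3 over weeks 1-8
  t2_average : mean error -0.0000 mm^3, max |error| 0.0000 mm^3
  t2_map     : mean error +0.0087 mm^3, max |error| 0.1389 mm^3
32 paired sessions; mean difference (map - average) +0.0087 mm^3
paired t-test: t(31) = 1.44, p = 0.16 (no evidence of a method difference)
log10(flux) = 5.79 + 1.06 log10(V)   [generator: 5.81 + 1.04 x]
R^2 = 0.979, Spearman rho = 0.987
RT/DEC/ABC vs sham: median enhanced +59%; log-rank p = 0.00166
```

Reading it: both contrast methods recover the phantom's ground-truth
volumes to within a boundary voxel (their Bland-Altman differences scatter
around zero with a non-significant t-test); the log-log calibration
recovers the generating power-law coefficients (5.81, 1.04) from noisy
data; and the simulated multimodal-treatment arm shows the expected
median-survival gain over sham.

The same stages are available as `t2flux` subcommands
(`phantom`, `relax`, `volume`, `compare`, `bli`, `correlate`, `survive`,
`run`) for use on individual files. Fitting a full 256×256×20 session is
deliberately faithful to the per-pixel simplex procedure and takes many
minutes; the bundled configs use down-scaled grids.

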