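# tendonswe

Freehand 3D shear-wave-elastography (SWE) compounding and regional
patellar-tendon analysis, with the cohort-level statistics used to compare
tendon stiffness between heavily loaded athletes (elite alpine skiers) and
healthy controls.

2D SWE maps tissue shear-wave velocity (SWV, m/s — higher = stiffer) on a
grid superimposed on the B-mode image, but a single frame's limited field of
view makes tendon measurements position dependent. Tracking the transducer
pose during a freehand sweep and compounding the frames into a 3D voxel
volume removes that dependence and enables off-line analysis of distinct
tendon subregions. This package implements that pipeline end to end on
synthetic data — a digital tendon phantom with known regional SWV, a
simulated pose-tracked sweep, weighted-average voxel compounding, masking and
landmark-based regional statistics — plus a subject-level cohort simulator
and the inference layer (best-subset linear models, t tests, regional-delta
comparisons). It is aimed at people developing or validating 3D-SWE analysis
chains who need a fully controlled ground truth.

## Method

**Compounding.** Each pixel (r, c) of frame *k* sits at frame coordinate
(cΔ, rΔ, 0) and maps to world space through the tracked rigid pose,
x = R_k p + t_k. Every valid pixel deposits (w·v, w) into voxels within a
truncation radius, with Gaussian weight w = exp(−d²/2σ²) in the
pixel-to-voxel-center distance d (σ = voxel spacing, truncated at 2σ). A
voxel's value is Σwv / Σw; voxels with no deposits stay undefined (no hole
filling).

**Regions.** The masked volume is split by two planes perpendicular to the
proximal→distal landmark axis, 10 mm from each insertion: scalar projection
s ≤ 10 mm → proximal, s ≥ L−10 → distal, else mid-portion. Regional SWV is
the arithmetic mean over defined masked voxels.

**Cohort model.** Regional SWV per subject follows
`swv = β₀ + β_g·skier + β_s·male + β_a·age + β_L·L + ε`, ε ~ N(0, σ²),
with per-group sex effects available (the sex effect appears only under
heavy tendon loading in the default parameterization). Inference uses OLS
(normal equations), exhaustive best-subset selection by adjusted R² or
leave-one-out predictive R² (PRESS via the leverage identity
e_i/(1−h_ii)), Welch t tests, and between-group tests on per-subject
regional deltas (distal−mid, proximal−mid).

## Worked example

`python examples/03_regional_means.py` — sweep the default phantom
(regions 9.5 / 9.0 / 10.0 m/s, 0.5 m/s pixel noise, 0.5°/0.5 mm pose
jitter), compound at 0.5 mm voxels, and recover regional means:

```
full mask: 27464 voxels
 proximal: estimated 8.70 m/s  (truth 9.50, bias -0.80)
      mid: estimated 8.27 m/s  (truth 9.00, bias -0.73)
   distal: estimated 9.02 m/s  (truth 10.00, bias -0.98)

interior (1.25 mm inset): 8963 voxels
 proximal: estimated 9.50 m/s  (truth 9.50, bias +0.00)
      mid: estimated 9.00 m/s  (truth 9.00, bias +0.00)
   distal: estimated 9.95 m/s  (truth 10.00, bias -0.05)
```

Full-mask means are biased low because surface voxels blend the 2 m/s
background through the compounding kernel (a partial-volume effect that real
masked reconstructions share); one kernel radius inside the surface the
plateaus are recovered to within 0.05 m/s. The other examples cover sweep
simulation, volume compounding, cohort inference
(`examples/04_cohort_inference.py` prints the selected model, the Welch
group test and both regional-delta tests for one simulated cohort) and a
full reproducible pipeline run.

A thin CLI mirrors the library:
`tendonswe run-all --seed 0 --outdir run/` executes
simulate → reconstruct → regions → analyze and writes volumes (NRRD),
poses/cohort/regional CSVs, fit JSONs and a log.

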