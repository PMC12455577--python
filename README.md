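# cestpipe

Quantification pipeline for CEST-MRI (chemical exchange saturation
transfer) Z-spectra, built for preclinical group studies of
neuro-metabolic change — e.g. antiretroviral-therapy and nicotine
effects on the mouse brain.  It covers the full analysis chain:

1. **WASSR B0 correction** — per-voxel water-center localization by a
   maximum-symmetry search on a low-power water-only saturation stack,
   then re-alignment of each voxel's Z-spectrum onto the nominal offset
   axis.
2. **5-pool Lorentzian decomposition** — bounded nonlinear least
   squares of `Z(ω) = 1 − Σᵢ Aᵢ (Γᵢ/2)² / ((Γᵢ/2)² + (ω − δᵢ)²)` with
   pools for water (0 ppm), the semisolid magnetization-transfer
   background (−2.5 ppm), creatine (+2 ppm), glutamate (+3 ppm) and the
   nuclear Overhauser effect (−3.5 ppm).
3. **AUC contrast maps** — the per-pool CEST value is the area under
   the fitted Lorentzian, `AUC = A·Γ·π/2` (a windowed arctan form is
   also available).
4. **ROI group statistics** — per-subject region means (cortex,
   hippocampus, piriform cortex, thalamus, whole brain), Tukey 1.5×IQR
   outlier exclusion within group, ordinary one-way ANOVA plus
   two-tailed pooled-variance t-tests, mean ± SEM summaries with `*`
   (p < 0.05) and `#` (0.05 < p < 0.1) flags.

Because real scans are rarely shareable, the package ships a
first-class **synthetic study generator** (Lorentzian-generative
phantoms with known ground truth, group × region effects, smooth B0
fields and seeded noise) and an independent **Bloch–McConnell
simulator** that integrates the coupled magnetization equations of
exchanging proton pools under continuous-wave saturation — a physics
oracle the Lorentzian model does not assume.

## Worked example

```sh
python examples/04_group_stats.py
```

simulates a 16-subject study (4 groups × 4) carrying a ground-truth 30%
thalamic glutamate deficit in the treated groups, runs the full
pipeline, and prints:

```
thalamus / GLU (AUC, ppm units):
    vehicle: 0.0552 +/- 0.0008 (SEM)
        ART: 0.0394 +/- 0.0009 (SEM)
   nicotine: 0.0434 +/- 0.0013 (SEM)
    cotreat: 0.0398 +/- 0.0013 (SEM)
  ANOVA: F = 47.19, p = 6.446e-07
  ART_vs_vehicle: p = 1.034e-05 *
```

The group means are the ROI-averaged glutamate AUCs; the treated means
sit ~30% below vehicle — the analysis rediscovers the configured
deficit from the spectra alone, and the `*` flag marks the significant
pairwise comparison.  The other examples demonstrate phantom
generation, B0 mapping, single-voxel fitting and the Bloch–McConnell
cross-check.

A thin CLI wraps the same library calls:

```sh
cest-zspec simulate --out study/ --seed 1
cest-zspec analyze study/ --out results/
cest-zspec recover --out recovery.csv
```

## Layout

- `src/cestpipe/spectra.py` — offset axis, saturation schedules, pools,
  the Lorentzian kernel
- `src/cestpipe/synthetic.py` — phantom studies, WASSR stacks,
  Bloch–McConnell oracle
- `src/cestpipe/io.py` — NIfTI/CSV/JSON study IO, the shared data model
- `src/cestpipe/b0.py` — WASSR field mapping and spectral re-alignment
- `src/cestpipe/fitting.py` — multipool decomposition and AUC contrasts
- `src/cestpipe/stats.py` — ROI aggregation, outlier fences, group tests
- `src/cestpipe/pipeline.py` — orchestration and Monte-Carlo harnesses
- `docs/methods.md` — models, assumptions, parameter choices, limitations
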