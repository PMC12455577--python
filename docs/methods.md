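# Methods

## The measurement being modeled

CEST MRI saturates exchangeable solute protons with a long, frequency-
selective RF pulse; exchange transfers the saturation to water, so
low-concentration metabolites appear as dips in the normalized water
signal Z(ω) = S(ω)/S0 plotted against saturation offset ω (ppm, water
at 0, positive downfield).  The default acquisition schedule is 51
offsets from −5 to +5 ppm in 0.2 ppm steps, continuous-wave saturation
of 2 µT for 1 s, matching a typical preclinical mouse protocol at high
field.  Five resonances are quantified: water (direct saturation,
0 ppm), the broad semisolid magnetization-transfer (MT) background,
creatine (+2 ppm), glutamate (+3 ppm) and the aliphatic nuclear
Overhauser effect (−3.5 ppm).

## Spectral model

Each pool is a Lorentzian dip parameterized by peak depth A (normalized
signal units), full width at half maximum Γ (ppm) and center δ (ppm):

    L(ω) = A (Γ/2)² / ((Γ/2)² + (ω − δ)²),   Z(ω) = 1 − Σᵢ Lᵢ(ω)

This parameterization (rather than area-normalized forms) makes the
FWHM directly testable — L(δ ± Γ/2) = A/2 exactly — and is the common
convention in multi-pool CEST work.  The per-pool "CEST value" is the
area under the fitted line; the default convention integrates the full
line analytically, AUC = A·Γ·π/2, with a windowed arctan form available
because integration limits are a reporting choice.  Group-difference
*directions* are invariant to that choice (AUC is exactly linear in A);
absolute values are not.

The fit target is Z directly (not 1−Z, not an asymmetry), with
unweighted residuals, bounded trust-region least squares
(scipy `least_squares`, analytic Jacobian) and an optional multistart
(default 3 starts; extra starts jitter initial amplitudes ±50%,
ties broken by residual then iteration count).  Default initialization
and box bounds per pool (amplitude init, bounds; FWHM init, bounds in
ppm; center slack in ppm):

| pool  | A init | A bounds | Γ init | Γ bounds | center ± slack |
|-------|--------|----------|--------|----------|----------------|
| water | 0.80   | 0.02–1   | 1.4    | 0.3–10   | 0.0 ± 0.2      |
| MT    | 0.10   | 0–0.5    | 25     | 10–100   | −2.5 ± 2.0     |
| CR    | 0.02   | 0–0.3    | 0.5    | 0.2–3    | +2.0 ± 0.1     |
| GLU   | 0.03   | 0–0.3    | 1.0    | 0.2–3    | +3.0 ± 0.1     |
| NOE   | 0.05   | 0–0.5    | 3.0    | 0.5–8    | −3.5 ± 0.2     |

The narrow center slacks keep the pools identifiable; the MT center at
−2.5 ppm and its width range are conventions, surfaced in config, since
broad-pool placement varies across the literature.  Non-converged
voxels propagate NaN into every contrast map; ROI statistics use
converged voxels only and record the exclusion count.

Single-voxel precision is information-limited: at Gaussian noise
σ = 0.005 on Z, the Cramér–Rao bound for the full 15-parameter model
puts the median relative error of the glutamate amplitude near 10%,
and the fitter operates at that limit (slightly below it, thanks to the
box constraints).  Region-level estimates are correspondingly tighter
because ROI averaging reduces the effective noise by roughly the square
root of the region size.

## B0 correction

Field inhomogeneity shifts each voxel's spectrum along the offset
axis.  The WASSR stack (low-power 0.25 µT water-only saturation over
−1…+1 ppm in 0.02 ppm steps — the acquisition itself rarely reports a
schedule, so these defaults are config-exposed) samples a narrow,
symmetric water line per voxel.  The center is located by a
maximum-symmetry cost function: over candidate centers c, minimize the
mean squared difference between the cubic-spline-interpolated spectrum
at the mirrored offsets 2c − ω and the measured values, counting only
offsets whose mirror lies inside the acquired range (≥ 5 pairs
required).  A coarse grid (default step 0.01 ppm over ±0.5 ppm) is
refined by a parabolic fit through the three lowest cost points.  The
symmetry formulation is robust to the line minimum falling between
samples, where a spline-minimum search is not; flat spectra and
minima at the range edge are flagged failed/edge and excluded
downstream.  Correction re-samples each CEST spectrum at (nominal
offset + shift) with a cubic spline; offsets whose source lies outside
the acquired range are marked missing, never extrapolated, and the
fitter simply drops them.

## Group statistics

Per subject, region and pool, the ROI value is the mean AUC over
converged voxels; the whole brain is always the union of the four
labeled regions, never its own label.  Outliers are excluded once per
(group, region, pool) with the Tukey fence rule (k = 1.5: outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR]).  Quartiles default to **Tukey hinges**
(medians of the lower/upper halves, halves including the overall
median at odd n).  This choice matters at the study's n = 4 per group:
hinge quartiles give {1,2,3,4,100} → Q1 = 2, Q3 = 4, fences [−1, 7],
excluding exactly the gross outlier, while leaving Gaussian samples of
4 essentially untrimmed — which keeps the downstream two-sample t-test
calibrated (measured rejection rate ≈ 0.05 at α = 0.05).  Linearly
interpolated quartiles (numpy's default) trim about a fifth of Gaussian
groups of 4 and inflate the false-positive rate to ≈ 0.10; they remain
available via `quartile_method` for users matching other software.  If
the IQR is zero nothing is excluded.

Group comparisons use ordinary (fixed-effects) one-way ANOVA and
two-tailed pooled-variance (Student) t-tests — pooled rather than
Welch for consistency with "ordinary" ANOVA (F = t² holds exactly for
two groups); Welch is a config flag.  No multiple-comparison
adjustment is applied by default, mirroring common preclinical
reporting; a Holm option exists but is off and labeled.  Summaries are
mean ± SEM (sd/√n after exclusions); flags are `*` for p < 0.05 and
`#` for 0.05 < p < 0.1.

## Synthetic studies

`generate_phantom_study` draws every voxel's spectrum from the same
Lorentzian-generative model the fitter assumes: baseline pools (water
0.80/1.4 ppm, MT 0.08/25 ppm at −2.5, CR 0.025/0.6 at +2, GLU
0.035/1.0 at +3, NOE 0.05/3.0 at −3.5 — amplitudes summing to 0.99 so
Z stays non-negative), scaled per (group, region, pool) by
multiplicative effect factors.  Defaults mirror the study design being
emulated: 4 groups (vehicle, ART, nicotine, co-treatment) × 4
subjects, a 30% thalamic glutamate deficit in ART and co-treatment
(25% in nicotine) and a 30% hippocampal NOE elevation under
co-treatment.  The B0 field is a smooth deterministic sinusoidal
surface bounded by ±0.1 ppm; noise is Gaussian on the normalized
signal (σ = 0.005 by default — magnitude data at moderate SNR is
near-Gaussian; a Rician option exists).  The ROI layout stacks four
rectangular regions inside an elliptical brain on a 64×64 grid
(single slice; slice thickness is metadata only).  All randomness
derives from one root seed via `SeedSequence` spawning, so identical
seeds give bit-identical bundles and different seeds share identical
ground truth.

What the phantom does **not** emulate: readout and k-space effects,
coil sensitivity, motion, partial-volume anatomy, B1 inhomogeneity,
non-Lorentzian in-vivo lineshapes, or between-subject anatomical
variability.  Passing tests therefore demonstrate the correctness and
calibration of the *analysis*, not the biological validity of any
in-vivo finding.

## Bloch–McConnell oracle

For model-mismatch testing, `simulate_bloch_mcconnell` integrates the
coupled Bloch–McConnell equations for N exchanging pools under
continuous-wave saturation: per offset, one matrix exponential of the
augmented (3N+1) evolution matrix propagates thermal-equilibrium
magnetization over the saturation duration; the output is water Mz/M0.
Exchange obeys detailed balance (water→solute rate = pool fraction ×
solute→water rate); ppm converts to rad/s at a 300 MHz Larmor
frequency (7 T).  The default physics table is a dilute-solution-like
system (water T1/T2 = 1.8/0.2 s; CR f = 0.001, k = 100 s⁻¹; GLU
f = 0.0015, k = 150 s⁻¹; NOE f = 0.005, k = 20 s⁻¹; MT f = 0.02,
k = 30 s⁻¹, T2 = 0.1 ms) chosen so that the solute peaks are spectrally
resolved at 2 µT — the regime where a Lorentzian decomposition is a
sensible reduced model.  Under these conditions the fitted water, CR,
GLU and NOE centers land within 0.1 ppm of the physics ground truth
despite the model mismatch.  The MT center is intentionally not held to
that tolerance: a line whose half-width exceeds the sampled ±5 ppm
window has no localizable center, and the fit config accordingly allows
it ±2 ppm of slack.

## Monte-Carlo calibration harnesses

Type-I error and effect-direction recovery are measured by simulating
many complete studies and running the full analysis on each.  These
harnesses use a reduced 16×16 grid, ROI-averaged-spectrum fitting (one
5-pool fit per region instead of per voxel) and a zero-amplitude B0
field, so that the statistical property under test is isolated from
interpolation error and a 500-study calibration completes in minutes;
voxelwise fitting and nonzero B0 fields are the pipeline defaults and
are exercised end-to-end elsewhere.  With the default conditions the
pairwise rejection rate on null studies is ≈ 0.05 at α = 0.05, and a
0.7× thalamic glutamate effect at noise σ = 0.005 is recovered in the
correct direction in ≈ 100% of studies.

## Numerical conventions and degenerate inputs

- Offsets ascending everywhere; descending sidecars are reversed on
  load with the signal reordered consistently.
- Interpolation (mirroring and correction) is cubic; linear is a
  config fallback.
- Zero shift short-circuits to an exact copy; grid-aligned shifts
  reproduce index shifts to machine precision.
- Spectra with fewer than 20 usable offsets are skipped; all-NaN
  spectra are unusable; > 20% non-converged voxels in a stack raise a
  prominent warning, > 50% failed B0 voxels a hard error.
- Zero within-group variance: t-test p = 1 for equal means, p = 0 with
  a warning otherwise; zero IQR skips exclusion.
- Amplitude sums above 1 warn (Z may go negative) and can be made
  strict.

## Known limitations

- The analysis assumes ideal S0 normalization; no B1 correction is
  implemented.
- The Lorentzian MT background is a convenience lineshape; semisolid
  pools are better described by super-Lorentzians, which would bias
  absolute MT amplitudes (listed as an extension, not implemented).
- Absolute AUC values depend on the integration convention; only the
  full-line default is used in the shipped statistics.
- The windowed-fit precision analysis above is for the default
  schedule; sparser schedules degrade identifiability of CR (narrow,
  0.6 ppm) first.
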