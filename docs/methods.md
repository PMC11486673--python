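# Methods

## Signal model and T1 correction

All dynamic data are treated as spoiled gradient-echo (SPGR) steady-state
magnitude signal,

    S = M0 · sinα · (1 − E1) / (1 − E1 · cosα),   E1 = exp(−TR/T1),

with TR in ms and α in degrees (defaults mirror a 3 T TWIST-like brain
protocol: TR 4.83 ms, TE 1.87 ms, α 12°, 70 frames at 5 s spacing, bolus
arrival at frame 3). Pre-contrast T1 comes either from a supplied T1 map or
from a variable-flip-angle (DESPOT1) fit — the linearised regression of
S/sinα on S/tanα, whose slope is E1. The T1-mapping sequence type in the
motivating clinical protocol is not specified by its vendor tooling; VFA is
this package's explicit stand-in, and the phantom generator produces VFA
stacks to match.

Concentration conversion anchors the per-voxel equilibrium signal M0 to the
baseline signal S0 (mean of the pre-bolus frames) through the known
pre-contrast T1 — this is the baseline-T1 correction — then inverts the SPGR
equation per frame and applies

    C(t) = (1/T1(t) − 1/T1₀) / r1,

with r1 = 3.7 s⁻¹mM⁻¹ by default (gadopentetate dimeglumine at 3 T;
configurable — the agent and dose are standard, its relaxivity is a
literature value). Frames whose signal lies outside the invertible range
return NaN and are ignored by the fits. Negative concentrations from noisy
pre-bolus frames are retained rather than clamped: clamping rectifies
zero-mean noise and biases the fits; exclusion happens only through the
zero-signal rule below.

## Arterial input function

The subject-specific AIF is measured from an artery mask: each voxel's
concentration curve is scored as

    score = 0.7 · max(corr with template, 0) + 0.3 · normalised peak,

where the template is the Parker population AIF evaluated on the subject's
frame grid (a weighted sum rather than a product; pure correlation ignores
partial-volume amplitude loss, pure amplitude ignores shape). The k = 10
best voxels are averaged (configurable — clinical practice in this setting
ranges from 5 to 15), and whole blood becomes plasma via
Cp = Cb/((1−Hct)·pv) with Hct = 0.45 and pv = 1 by default. A population
(analytic) AIF is available only as an explicit fallback flag: measured
AIFs are the default because arterial curves vary substantially between
subjects.

## Kinetic models and fitting

Extended Tofts: Ct = vp·Cp + Ktrans·∫Cp(τ)e^(−kep(t−τ))dτ, kep = Ktrans/ve.
Two-compartment uptake (2CU): Ct = Fp(R ⊛ Cp), R(t) = E + (1−E)e^(−t/Tp),
E = PS/(Fp+PS), Tp = vp/(Fp+PS). Both convolutions treat Cp as piecewise
linear between frames and integrate the exponential kernel exactly per
segment (a stable recursion, series-expanded for small λΔt). This is exact
for the closed-form test cases, matches adaptive quadrature to 1e-6 on
sparse 10-frame grids, and behaves well on irregular clinical frame
schedules without resampling. The clinical protocol this emulates states
two mutually inconsistent frame schedules (70 uniform measurements vs a
short nonuniform burst); the frame schedule is therefore configuration, not
a constant.

Fits are bounded trust-region least squares (SciPy TRF) with bounds
Ktrans ∈ [0,5] min⁻¹, ve ∈ (1e-4,1], vp ∈ [0,1], Fp ∈ (1e-4,20] min⁻¹,
PS ∈ [0,5] min⁻¹, and 5 deterministic multi-starts (log-normal jitter
around a physiological start, seeded per voxel by (run seed, voxel index)
so results are bit-reproducible regardless of iteration order). A start
achieving negligible residual stops the search early. The optimiser, bounds
and start strategy are this package's choices; the source workflow names
only the models.

Two rBF estimators are emitted because both definitions are in circulation
for this workflow and they are not equivalent: the model-based Fp from the
2CU fit (the default fed to VOI statistics) and the area-based
CBV/MTT — CBV ≈ AUC(Ct)/AUC(Cp), MTT = difference of first temporal
moments, floored at 1 s (flagged) to avoid division blow-ups. rBF is
reported in min⁻¹ (flow per unit tissue volume); published values in this
setting are unitless and all group comparisons are rank-based, so the unit
convention does not affect any statistic.

Exclusion rule: a voxel is excluded when its maximum dynamic signal is
≤ 1e-9 × the series maximum ("zero signal"), when concentration conversion
fails, or when every fitted model is degenerate/non-convergent. Excluded
voxels are NaN in all maps and recorded in an exclusion mask; VOI means use
only the remainder.

## VOIs and statistics

Control VOIs mirror the tumour mask across the sagittal midplane, clipped
to brain; if the reflection under-fills (clipping, or a midline-crossing
tumour, which is warned about), the control is topped up by deterministic
dilation within brain-minus-tumour to match the tumour voxel count.
Mirroring is an operationalisation — the clinical description ("similar
size, contralateral side") does not fix an algorithm.

Wilcoxon signed-rank and Mann–Whitney U use fully enumerated nulls
(practical up to 20 observations; the cohorts of interest are 6 and 3):
mid-ranks for ties, zero differences dropped, U counts ties as ½, and
two-sided p = min(1, 2·min(tails)) — the convention under which the
published cohort's printed p-values (0.0313 = 2/64, 0.0238 = 2/84) are
reproduced exactly. The default is two-sided even though the source
analysis is described as one-tailed, precisely because the printed values
are the two-sided exact probabilities for the printed data; `sidedness=one`
tests the directional hypotheses (tumour > control, meningioma > other).
Display rounding is half-up (0.03125 → 0.0313), 4 decimals for p, 3 for
medians; CSV output keeps full precision. The median of paired differences
is reported as control − tumour. Pearson correlations (parameter vs VOI
volume) use the standard t reference; they run only when ≥ 3 finite,
non-constant volumes are supplied, since the reference cohort's per-subject
volumes are not published.

## Digital phantom

The generator emulates the study conditions: a 32×32×8 ellipsoidal "brain"
of low-leakage white-matter-like tissue (Ktrans 0.002 min⁻¹, ve 0.1,
vp 0.02, T1₀ 1100 ms), a spherical tumour (defaults Ktrans 0.25 min⁻¹,
ve 0.4, vp 0.05, T1₀ 1400 ms — meningioma-like leakage; or Fp 0.6 min⁻¹,
vp 0.05, PS 0.05 min⁻¹ under the 2CU model), and a 2×2-voxel arterial
column (blood T1₀ 1650 ms) carrying (1−Hct)× the analytic plasma AIF.
Voxel size 1.4×1.4×3 mm. Noise is additive Gaussian on magnitude signal at
a default 2% of per-voxel baseline, applied only where signal exists so
background stays exactly zero; a seed is mandatory whenever noise is on.
Rician bias, motion, B1 inhomogeneity, T2* losses and water exchange are
deliberately not simulated — phantom-passing therefore demonstrates
correctness of the estimation chain, not robustness to those real-data
effects. Motion correction has a hook in the pipeline ordering but no
algorithm (the phantom is motion-free and masks are inputs).

## Problem sizes and numerical choices

Recovery checks fit the model that generated each phantom (fitting the
Tofts model to 2CU-generated data estimates a different quantity and says
nothing about recovery). Tumour-region medians on noiseless 32×32×8×70
phantoms recover Ktrans/ve/vp to well under 2% and Fp under 5%; with 5%
baseline noise the median |relative error| of Ktrans over 50 replicate
voxels stays under 10%. The acceptance script runs the two full phantom
pipelines (~3.5k fitted voxels each) in about half a minute with the numba
kernel, a few minutes without. Exact-test implementations are
cross-validated against an independent exact implementation over hundreds
of random small-sample fixtures, and the end-to-end pipeline is
byte-deterministic under a fixed seed.

## Known limitations

* VFA is the only T1-mapping method; no B1 correction.
* The AIF is taken where the mask says; no automatic artery localisation or
  dispersion correction.
* Partial-volume correction is a single scalar applied to the AIF.
* No spatial regularisation across voxels; each voxel is fitted
  independently.
* Exact tests are limited to ≤ 20 observations by design; larger samples
  should use asymptotic or resampling tests from a general statistics
  package.
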