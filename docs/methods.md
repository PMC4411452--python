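# Methods

## Signal model and relaxometry

Magnitude gradient-echo signal in a voxel with effective transverse
relaxation time T2* decays monoexponentially with echo time t:

    S(t) = S(0) · exp(−t / T2*)

The emulated acquisition samples seven echoes (TE = 1.83, 3, 5, 7, 10, 12,
15 ms) on a 192×128 matrix over a 35×35 mm field of view, a single 1-mm
coronal slice.  Each voxel is fitted by unweighted nonlinear least squares
on the exponential itself, over S(0) > 0 and T2* ∈ [0.1, 1000] ms
(`scipy.optimize.least_squares`, trust-region reflective, analytic
Jacobian).  A log-linear regression of ln S on t over strictly positive
signals provides the starting point only — fitting in the signal domain
avoids the noise-floor bias that a pure log-linear fit acquires at late
echoes.

Goodness of fit is the coefficient of determination in the signal domain,
r² = 1 − SS_res/SS_tot against the mean-signal null model over all echoes.
A voxel is **valid** iff the optimiser converged, T2* lies strictly inside
its bounds (bound-pinned fits are background or pure noise), SS_tot > 0
(constant signal leaves r² undefined), and r² > 0.85.  Invalid voxels
carry NaN in the S(0)/T2*/R2* maps and `false` in the validity map.

Rates are reported as R2* = 1000 / T2*[ms], i.e. in s⁻¹.  Reported
kidney baselines of ≈40 with echo times of a few milliseconds are
dimensionally consistent only on this scale; the package uses s⁻¹
throughout and the unit bridge is part of the `TissueParams`/`VoxelFit`
contracts.

Out of scope: susceptibility-gradient-mapping post-processing,
multi-compartment or stretched-exponential decay, and pre/post voxelwise
registration — ΔR2* is computed at ROI level, matching an ROI-per-scan
workflow.

## ROI quantification

The ROI statistic is the **mean** R2* over valid voxels (configurable to
median; the reference workflow does not state its choice).  ROIs with
fewer than 10 valid voxels are flagged, not dropped — the default protects
the stability of the mean.  Per animal and tissue, ΔR2* = R2*(48 h) −
R2*(baseline); the graft's ΔR2* is indexed to the native kidney's and to
skeletal muscle's.  A reference delta ≤ 0 makes the ratio undefined: the
record is flagged and retained so cohort assembly survives degenerate
animals.  Note the distinction the pipeline preserves: the median of
per-animal ratios is not the ratio of group-median deltas (30.15/15.7 ≈
1.92 vs an indexed median of 1.24).

The spleen is rendered in the phantom (high baseline rate, large USPIO
delta, emulating reticuloendothelial uptake) but never summarised:
concentrated iron blooms into neighbouring tissue, so regions of interest
avoid it.

## Exact nonparametric inference

At group sizes of nine and six, large-sample approximations to rank-test
nulls are inaccurate, so both tests enumerate their permutation null
completely:

- **Mann-Whitney U** (unpaired): U from pooled mid-ranks; the null
  distribution of the rank sum over all C(n₁+n₂, n₁) group assignments is
  computed exactly via the generating function ∏ᵢ(1 + z·x^{rᵢ}) — a
  dynamic programme equivalent to literal enumeration, including under
  ties (doubled mid-ranks keep all arithmetic integral).
- **Wilcoxon signed rank** (paired): zero differences dropped, mid-ranks
  on tied magnitudes, null over all 2ⁿ sign assignments via the analogous
  one-variable generating function (n ≤ 20).

Two-sided p-values use the doubling convention
`min(1, 2·min(P(T ≤ t), P(T ≥ t)))`; the tie-handling computes the null on
the observed (tied) rank configuration, which preserves exactness.  When
enumeration exceeds 10⁶ assignments, a seeded Monte-Carlo permutation null
(10⁵ resamples, add-one correction) is used and flagged in the result —
never silently.  Group summaries report median and quartiles by linear
interpolation between order statistics (the inclusive convention of
`numpy.percentile`), stated so reported IQRs are reproducible.  No
multiple-testing correction is applied; each comparison is marginal, with
two-sided significance at α = 0.05.

## Digital phantom and cohort simulation

**Geometry** is schematic: ellipses for the transplanted kidney, native
kidney and spleen, a rectangle for paraspinal muscle, on the acquisition
matrix with deterministic layering (later primitives overwrite earlier
ones).  Manual ROI placement cannot be emulated faithfully, so label masks
are generated alongside the images.  Default tissue parameters: kidney
S(0) = 1000 (a.u.), baseline R2* 44.2 (graft) and 42.8 (native) s⁻¹ with
USPIO deltas 30.15 and 15.7 s⁻¹ (the reference group medians); muscle
S(0) = 800, baseline 40 s⁻¹ (T2* = 25 ms, a typical skeletal-muscle value
at 7 T — the reference study does not report it), delta 4.8 s⁻¹; spleen
S(0) = 900, baseline 80 s⁻¹, delta 120 s⁻¹.

**Noise** is Rician, the standard model for magnitude-reconstructed MRI
(the acquisition protocol states none): measured = √((S+n₁)² + n₂²) with
independent zero-mean Gaussians of scale σ.  Signal-free background then
follows a Rayleigh distribution with mean σ√(π/2), which the tests verify
by Monte Carlo.  Pre- and post-contrast renders draw independent noise
streams from the spec's seed.

**Cohort simulation.**  Per-animal values cannot be recovered from
published group summaries, so each reported "median (IQR)" triple
(q1, m, q3) is turned into a **two-piece uniform** sampler: with
probability ½ a draw is uniform on [q1, m], otherwise uniform on [m, q3].
The population median is exactly m and the support exactly [q1, q3].
This deliberately does *not* reproduce q1/q3 as population quartiles; it
was chosen because it guarantees exact median recovery and keeps the
allograft (1.12–1.36) and isograft (0.92–1.04) indexed supports disjoint,
making the headline group separation — and hence the reproduced p < 0.01 —
deterministic rather than seed-dependent.  Whether real between-animal
variation extended beyond the reported IQRs is unknowable from the
summaries; the bounded sampler is the conservative choice.

Per animal the simulator draws the native-kidney delta, the
graft-to-native ratio and the graft-to-muscle ratio from their calibrated
samplers, then derives the graft and muscle deltas by consistency
(graft = ratio × native; muscle = graft / muscle-ratio), so ROI arithmetic
recovers every drawn ratio identically.  Default cohort: 9 allograft vs 6
isograft animals, the analysable cohort after infarct exclusions.  The
fast path emits tabular records directly; the slow path builds a phantom
per animal from its drawn parameters, renders and fits both phases, and
rebuilds records from ROI summaries — the end-to-end tests require the
slow path to recover each drawn ΔR2* within 2 % (noiseless).

## Histology quantification

Percent-area staining is `100 · (pixels above threshold) / (field pixels)`,
summarised per specimen as mean ± sample sd over ten equal-sized
nonoverlapping fields.  The synthetic generator places disc-shaped blobs
by a seeded point process until a target positive fraction is reached
(final blob trimmed pixel-wise, so the achieved fraction is exact to
1/field-size); per-field fractions are drawn from a normal distribution
truncated to [0, 1], emulating field-to-field heterogeneity.  Colour
deconvolution and the original thresholding procedure are out of scope —
thresholding is a parameter of the assay.

## Problem sizes and numerical choices

The full-slice relaxometry checks run on the complete 192×128 matrix
(≈5200 foreground voxel fits, a couple of seconds); end-to-end imaging
tests use a three-animal mini-cohort; type-I calibration uses 2000 null
cohorts at the study sizes (the exact test is conservative at discrete
thresholds, so the rejection rate sits at or below nominal); sampler
median checks use 10⁵ draws (Monte-Carlo error ≈ 0.001–0.01 depending on
IQR width, against a ±0.02 tolerance).  The voxel-fit oracle in the tests
is an independent coarse-to-fine grid search over (S(0), T2*) — 400 points
per axis, three refinement rounds — whose objective the nonlinear fit must
match or beat.

## Known limitations

- Geometry is schematic, single-slice and motion-free; blooming is not a
  physical susceptibility field, only an avoidance rule.
- Uniform parameters within each tissue: no intra-ROI heterogeneity, so
  phantom ROI variance understates biological variance.
- The two-piece sampler bounds cohort variation at the reported IQR;
  passing cohort tests demonstrates correctness of the analysis chain
  under those calibrated conditions, not robustness to real-data tails.
- The exact-p doubling convention is one of several; minlike-style
  definitions can differ in discrete nulls.
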