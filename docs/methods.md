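# Methods

This note documents what `silenttrack` computes, the assumptions behind
each stage, the defaults and why they were chosen, and what the synthetic
data do and do not establish about real recordings.

## 1. Stimulus features

Four feature tracks are extracted per stimulus and aligned on a common
150-Hz timeline (the analysis rate of the neural data).

**Acoustic envelope.**  Nine band-pass channels spaced equidistantly on the
cochlear frequency map span 100–10 000 Hz; the default cutoffs are the
fixed constants (101, 220, 402, 680, 1103, 1748, 2732, 4231, 6517,
10 000 Hz).  For other band counts or ranges, edges are placed equidistant
in Greenwood position `f(x) = A(10^{αx} − k)` with human constants
A = 165.4, α = 2.1, k = 0.88.  Each band is filtered with a fourth-order
Butterworth band-pass applied forward–backward (zero phase — envelope
*timing* matters for coherence phase), the envelope is the magnitude of the
analytic signal, and the nine envelopes are averaged before anti-aliased
resampling to 150 Hz.

**Formants.**  Audio is resampled to 11 kHz (twice the 5500-Hz formant
ceiling), pre-emphasized (first difference, coefficient 0.98), windowed
with 25-ms Gaussian tapers hopped at 5 ms (200 Hz frame rate), and an
AR(2·n_formants) model is fitted per frame by Burg's method.  Polynomial
roots give candidates `f = ∠root·fs/2π`, `b = −ln|root|·fs/π`; candidates
with 50 < f < 5500 Hz and b < 400 Hz are kept, sorted, and labelled
F1…F5.  The downstream track is the per-frame mean of F2 and F3 (the two
resonances modulated near the lips, which tend to merge toward ~2.5 kHz);
frames with no valid candidate are linearly interpolated so trials stay
rectangular.  With the default order 2·5 the model expects five resonances
below the ceiling, as in real speech; on sparser synthetic spectra the
surplus pole pairs can bias estimates by a few tens of Hz, which is a
model-order property, not an implementation defect.

**Pitch.**  Normalized autocorrelation over 52-ms frames hopped at 10 ms
(100 Hz), search range 50–400 Hz.  Because subharmonic lags (2T, 3T, …)
score as high as the true period, the estimate is the *shortest* locally
maximal lag reaching 90% of the frame's best correlation, refined by
parabolic interpolation.  There is no voicing gate: coherence needs a
gap-free regressor, so every frame yields a value and the final 150-Hz
track is clipped to the search range.

**Lip area.**  Per video frame, pixels above an intensity threshold (0.5)
are labelled; the area is the pixel count of the largest connected
component.  Frames with no bright pixel get area 0 (closed mouth).  The
50-Hz series is linearly interpolated to 150 Hz.

Resampling between the non-integer rate pairs (50→150, 100→150, 200→150)
uses linear interpolation on a shared absolute time axis, preceded by a
zero-phase Butterworth low-pass at 90% of the target Nyquist whenever the
rate decreases.  Features are z-scored per stimulus before coherence
(coherence is scale-invariant; standardization only stabilizes numerics).

## 2. Sensor preprocessing and source projection

Sensor recordings (nominally 1 kHz) are high-pass filtered at 1 Hz with a
zero-phase FIR of order 440 (scaled proportionally at other rates).  A
direct window design of this length cannot produce a true spectral zero at
DC with so low a cutoff, so the high-pass is built by spectral inversion
of a unity-DC Kaiser-window low-pass: DC is nulled exactly and the
passband is flat (|H| ≈ 1) above ~5 Hz.  The low-pass at 30 Hz is a
Kaiser-window FIR with its transition band from 30 to 50 Hz and ≥ 50 dB
single-pass stopband attenuation (doubled by the forward–backward
application).  Data are then polyphase-resampled to 150 Hz, shifted by the
9-ms stimulus-presentation delay (one sample at 150 Hz), and cut into
consecutive, non-overlapping 2-s trials of 300 samples.

Source projection uses an LCMV beamformer on a fixed-orientation toy lead
field (Gaussian distance falloff from each voxel to sensors on a jittered
shell; unit-norm columns).  The channel covariance is pooled over all
trials of both conditions (population normalization, so pooling a set with
itself is a no-op) and regularized as `C_r = C + λ·mean(diag C)·I` with
λ = 0.05 by default (standard practice; configurable).  Weights
`w_v = (l_v' C_r⁻¹ l_v)⁻¹ l_v' C_r⁻¹` satisfy the unit-gain constraint
`w_v·l_v = 1` to ≤ 1e-8 for every voxel.  Using one common filter for both
conditions guarantees that condition differences downstream cannot be an
artifact of different spatial filters.

## 3. Coherence and the intelligibility index

Spectra are estimated per 2-s trial with DPSS tapers at time-bandwidth
T·W = 6 (±3 Hz smoothing): K = 2·T·W − 1 = 11 tapers, all with spectral
concentration ≥ 0.9 at these settings (any below 0.9 would be dropped).
Trials are demeaned per channel, tapered, and transformed at the 49 target
frequencies 1–25 Hz in 0.5-Hz steps — exactly the Rayleigh grid of a 2-s
trial; off-grid requests are rejected rather than interpolated.  Complex
cross-spectra are averaged across tapers and trials with uniform weights
*before* normalization (averaging coherency magnitudes per taper instead
would bias upward), and coherence is the magnitude of the normalized
cross-spectrum; a squared variant sits behind a flag.

Band averages are arithmetic means over the inclusive bins of delta
(1–3 Hz, 5 bins), theta (4–7 Hz, 7 bins) or the combined band (1–7 Hz,
13 bins).  The intelligibility index is the per-voxel band-averaged
natural-minus-reversed coherence.  The top-coherence overlap map marks,
per feature, voxels reaching 90% of that feature's maximum band-averaged
coherence, and counts per voxel how many features include it.

## 4. Statistics

**Feature × naturalness model.**  Per-subject occipital-ROI coherence
values (4 features × 2 conditions, balanced by construction) are fitted by
OLS with fixed effects for feature, naturalness and subject.  For balanced
designs the per-subject fixed intercepts give the same fixed-effect
estimates and F tests as a random-intercept fit, without needing an REML
engine; unbalanced tables are refused rather than approximated.  The
factors are orthogonal under balance, so Type-II and Type-III sums of
squares coincide.  An exact cell-mean fit (residual variance at rounding
level) is reported as F = ∞, p = 0.

**Contrasts.**  Pairwise feature contrasts (6) or natural-vs-reversed
within feature (4) are formed from marginal/cell means with standard
errors from the pooled residual variance, referred to the normal (z)
distribution, and Benjamini–Hochberg-adjusted within family.  BH adjusted
values are monotone in the raw ranks, ≥ the raw p, and capped at 1; the
adjusted-value map is *not* idempotent in general (re-adjusting adjusted
values can change them), so only the former properties are guaranteed.

**Age-correlation cluster test.**  Voxel-wise Pearson r between the index
and age; t = r·√((n−2)/(1−r²)), with exactly collinear voxels reported as
signed infinities and zero-variance voxels as r = 0 with a warning.
Cluster forming: two-sided parametric threshold p < 0.05 (df = n − 2);
positive and negative suprathreshold voxels are clustered separately under
18-connectivity (edges + faces; 6 or 26 configurable); cluster mass is the
sum of member t values.  The null distribution records, per permutation of
the age vector, the maximum |mass| across both signs, so the resulting
p values control the familywise error over the grid and both tails.
p = (1 + #{null ≥ |mass|}) / (n_perm + 1) — never zero, resolution
1/(n_perm + 1).  All shuffles are drawn sequentially from a single
`default_rng(seed)`, so any procedure sharing the seed sees the identical
shuffle sequence (the single-voxel case reduces *exactly* to a brute-force
permutation test of the correlation, which the tests verify).

**ROI and follow-ups.**  Data-driven ROIs are the significant formant-
cluster voxels split by region label; per subject the index is averaged
over the ROI and regressed on age (OLS), reporting slope, F(1, n−2), p,
R² and η² (equal to R² for a single predictor).  The per-band follow-up
extracts the voxel with the most negative t (ties broken toward the lowest
voxel index) and refits.  Within-subject error bars use the
Cousineau–Morey recipe: remove subject means, restore the grand mean, and
scale the per-condition SE by √(C/(C−1)).

## 5. Synthetic cohort: what it emulates and what it does not

`simulate_cohort` draws ages uniformly on [19, 63] (n = 50 by default,
matching the scale of an adult aging cohort), builds per-voxel source
series

    x_v(t) = Σ_f g(age; f, region(v), condition) · feature_f(t)
             + d_v·distractor_v(t) + σ·η_β(t)

with `g = max(0, α₀ + α₁·age)` and 1/f^β Gaussian noise (β = 1, σ = 1 —
the canonical spectral shape of neural background activity), and epochs
them into 2-s trials.  Feature tracks are band-limited (1–7 Hz) Gaussian
processes with a requested cross-correlation structure, drawn
independently per subject and condition.

Two generator design choices exist specifically to make "age-flat
coupling" translate into a genuinely age-flat coherence index, which a
naive construction does not deliver:

* **Independent stimuli per subject** (default; `shared_stimuli=True`
  reuses one draw, as a fixed stimulus set would).  With shared tracks,
  the finite-sample cross-coherence between, say, the lip and formant
  tracks is one fixed number that enters *every* subject's lip-coherence
  numerator weighted by that subject's age-dependent formant gain — a
  common-mode, age-correlated error that the permutation null cannot see
  and that showed up as spurious positive lip clusters in pilot runs.
* **Band-power equalization** (default).  A declining coupling gain thins
  the total power — the coherence denominator — of every other feature
  coupled into the same voxel, so nominally age-flat features inherit a
  spurious positive age trend.  An independent band-limited distractor
  process per voxel tops the total stimulus-band drive up to its age-range
  maximum: an age-varying gain then changes *which* signal a voxel
  follows, never how much total band power it carries.

Neural data are generated directly in source space by default, so the
statistical claims do not depend on beamformer quality; the sensor-space
detour (project → add noise → beamform back) is exercised separately and
agrees with the direct path within 10% at coupled voxels.

The default *headline* coupling plants the pattern of interest: all four
features couple in occipital voxels (natural gain 0.06, reversed 0.04);
only the natural-formant gain declines with age (intercept 0.12 at the
young end of the configured formula, slope −0.0016/year, also in the
cingulate region), approaching zero by age 63.  These gains put
single-subject coherences in the 0.05–0.2 range typical of
stimulus–brain coupling and give the formant index a per-voxel
correlation with age near −0.6 — a strong but not deterministic planted
effect.

Default problem sizes (6×6×6 grid at 10-mm spacing with posterior
"occipital" and midline "cingulate" slabs standing in for an atlas
parcellation; 60 trials per condition, 30 in the recovery experiments;
5×5×5 grids in the calibration runs) were chosen as the smallest scales at
which every stage's behavior is measurable with comfortable margins; all
are configurable upward.

What passing tests show: the estimators are correct against closed forms
and planted parameters, the cluster test is calibrated under the
exchangeable null and recovers a planted age-declining coupling with the
correct sign and location, and the whole chain is deterministic given a
seed.  What they do not show: robustness to real-MEG nuisance structure —
head movement, myogenic/ocular artifacts, correlated sensor noise,
inter-subject anatomical variability, or violations of the
fixed-orientation lead-field idealization.

## 6. Numerical conventions

* Every generator and the permutation engine are pure functions of
  (parameters, seed); per-stream seeds are derived from the master seed by
  hashing a readable path (e.g. `seed/noise/sub007/natural`), keeping all
  derived seeds below 2³¹.
* Degenerate inputs fail loudly with typed exceptions
  (`InvalidParameterError`, `TooShortInputError`, `EmptyTrackError`,
  `FormatError`, `NumericalError`) rather than returning NaN.
* Coherence at zero-power bins is defined as 0 (with a warning); |r| within
  1e-12 of 1 is treated as exact collinearity.
* Trial stacks may be float32 (the cohort generator's default) to keep
  50-subject cohorts within desktop memory; all spectral accumulation is
  float64.
* The full run writes a manifest with the config hash, seed, package
  version and stage timings; a rerun with an unchanged config + seed is
  refused unless forced, and forced reruns reproduce all stochastic
  outputs bit-identically.
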