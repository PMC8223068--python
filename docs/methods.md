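# Methods

This note documents the models, numerical conventions and design choices
behind `hrvfc`, in the spirit of a statistical package's model description.

## Cardiac metrics

**Input.** A beat record: strictly increasing R-wave times (s), with
RR intervals RRᵢ = 1000·(tᵢ₊₁ − tᵢ) in ms attributed to the *completing*
beat tᵢ₊₁. An R-peak detector is provided for band-passed (0.5–40 Hz,
zero-phase Butterworth) single-channel ECG: local maxima above half the
90th percentile of the rectified trace, separated by a minimum distance
that defaults to 0.7× the subject's estimated mean RR clipped to
[0.5, 0.9] s — appropriate for resting adult heart rates.

**Windowing.** All windowed statistics use 100-s windows *centered* on the
evaluation grid (default 1-s steps; the model evaluates directly at fMRI
volume times, which is the same computation on a coarser grid). Windows
that would extend past either end of the record yield missing values rather
than silently shrinking. Within each window, RR values more than 3 *unscaled*
median absolute deviations from the window median are linearly interpolated
between the nearest non-outlier neighbours (boundary outliers take the
nearest valid value) before *any* statistic — including the moving-average
RR — is computed. The unscaled MAD (no 1.4826 normal-consistency factor) is
the plain reading of a "3-MAD" rule. A window in which every value would be
flagged is marked invalid rather than fabricated; with the 3-MAD rule this
can only arise for degenerate thresholds, since at least half of any window
is within one MAD of the median.

**Spectral HRV.** The successive differences ΔRRᵢ, placed at their
completing beat times, are linearly interpolated to a uniform 10-Hz grid
spanning the window, de-meaned, and fed to a Welch estimator (50-s Hann
segments, 50% overlap — i.e., three segments per 100-s window; both choices
configurable in `cardiac.WELCH_SEGMENT_S`). Band powers integrate PSD bins
whose centers fall in half-open bands: LF [0.04, 0.15), HF [0.15, 0.40),
denominator [0.04, 0.50), so the 0.15-Hz edge is never double-counted and
LF% + HF% ≤ 100 holds identically. Linear interpolation of a roughly 1-Hz
beat process attenuates a tone at frequency f by ≈ sinc²(f·RR̄): HF power is
measured through a slightly darker window than LF. This is a property of
the resample-then-Welch recipe itself, shared by any implementation of it,
and is why spectral tests compare against a direct-DFT oracle of the same
resampled series rather than against continuous-time band power.

**Other metrics.** RMSSD = √mean(ΔRRᵢ²) (≥ 2 beats required); instantaneous
heart rate 60/RR(s) defined beat-wise and linearly interpolated to the
grid; moving-average RR is the window mean. The three HRV courses (RMSSD,
LF%, HF%) are orthogonalized against the moving-average RR course by least
squares over the whole scan (not per window): the residual is exactly
uncorrelated with mean RR, which disentangles variability changes from
heart-rate level changes. A constant reference degenerates to de-meaning,
with a warning.

## fMRI preprocessing

Framewise displacement uses the backward-difference convention
FD_t = Σ|Δtrans| + r·Σ|Δrot| with r = 50 mm and FD₁ = 0. Subjects with
mean FD > 0.25 mm are excluded; volumes with FD > 0.2 mm and the first five
volumes of every scan are censored. Censored volumes are *deleted* from all
fits and correlations, never interpolated.

Cleanup is one joint least-squares regression over retained volumes on:

* a discrete-cosine high-pass basis of order ⌊2·T·0.008⌋ (cutoff 0.008 Hz) —
  combining the filter with the nuisance fit avoids the classic artifact of
  sequential regression reintroducing filtered frequencies;
* the first ten principal components of the white-matter voxel matrix
  (de-meaned SVD, unit-norm variance-ordered scores, sign fixed so each
  component's largest-magnitude loading is positive — a deterministic
  convention);
* six cardiac-pulsatility regressors: sin/cos of orders 1–3 of a cardiac
  phase that ramps 0 → 2π between successive R-waves, sampled at volume
  times. This is a deliberately simple phase basis; the regression interface
  accepts externally supplied regressor matrices so a more elaborate
  pulsatility model can be dropped in unchanged;
* the gray-matter mean series.

Collinear design columns are dropped with a warning rather than fitted.

## HRV states and state FC

For a chosen metric the scan's *low*/*high* states are the ⌊n/4⌋ retained
volumes with the smallest/largest metric values, by rank with ties broken
by time index. Exact-count rank selection (rather than value-threshold
quantiles) guarantees equal, reproducible state sizes: 353 retained volumes
give exactly 88 volumes per state. The state course is the *raw*
(orthogonalized) metric resampled at volume acquisition times — not
HRF-convolved; convolution is applied only in the GLM arm, and a convolved
state course can be supplied through the same interface if a hemodynamic
lag is wanted. Missing edge values of the metric course are filled from the
nearest finite value before ranking.

State FC is the Pearson matrix over the state's volumes. Network-level
connectivity averages *raw* correlations over all parcel pairs spanning the
two networks (within-network: unordered distinct pairs; the three
unassigned parcels are excluded). Fisher z = atanh(r) is used for
seed-based state contrasts, where differences of z-values are the natural
scale.

## Group model

Per network pair, subject-by-state values are first residualized on sex,
age and state-specific mean FD in one pooled regression (mean-centered
covariates, grand mean restored); per-state adjustment is available as an
option. The split-plot ANOVA then decomposes, for two states, into closed
forms on subject means Sᵢ and differences Dᵢ = highᵢ − lowᵢ:
SS_state = N·D̄²/2 and SS_int = Σ_g n_g(D̄_g − D̄)²/2 against the
subject × state error Σ(Dᵢ − D̄_g)²/2 on N − 2 df, and the group effect is
the one-way ANOVA on Sᵢ. The interaction F equals the squared two-sample t
comparing Dᵢ between groups — an exact identity used as the test oracle.
The analogous state-F/one-sample-t identity is exact only when the group
means of Dᵢ coincide (e.g., a single group), and is tested in that regime.
An exact-zero effect with zero error variance is reported as F = 0; a
nonzero effect with zero error variance is degenerate and reported NaN.
Sphericity corrections are moot with two within-subject levels; extending
to more states would require them.

The 66-pair family (11 within-network + 55 between-network cells, matching
the annotated upper-triangular network matrix) is controlled by
Benjamini–Hochberg FDR at α = 0.0125 = 0.05/4, the Bonferroni division over
the four cardiac metrics whose states are analysed. Post-hoc parcel-pair
interaction F tables within a flagged network pair are descriptive —
ranked, no inference attached. Scan-level cardiac summaries are compared
between groups by a permutation test on |difference of sex/age-adjusted
means| with p = (1 + #{|Δ*| ≥ |Δ|})/(q + 1), q = 10,000; covariates are
residualized once before permuting (a Freedman–Lane-style simplification).

The GLM arm convolves each 1-s metric course with a canonical double-gamma
HRF (gamma-density lobes peaking at 6 s with a 16-s undershoot at ratio
6:1, 32-s support, peak-normalized), samples at volume times, censors,
z-scores, and fits per-parcel least squares; group maps are
covariate-adjusted intercept/contrast t-tests on the per-subject betas with
parcel-level Bonferroni or BH correction. The package operates at parcel
resolution throughout; voxel-wise random-field-theory FWE correction of
voxel maps is out of scope by design.

## Synthetic-data generator

The generator emulates the statistical structure of a two-group concurrent
ECG-fMRI study: 16 controls and 28 patients (configurable), 400 volumes at
TR = 3 s, group baseline RR ≈ 1100 ± 200 ms (controls) vs 950 ± 100 ms
(patients) with the ± spread realised across subjects.

* **RR series** are generated directly as modulated intervals:
  RRᵢ = baseline + a_LF(tᵢ)·sin(2π·0.10·tᵢ) + a_HF(tᵢ)·sin(2π·0.30·tᵢ) +
  white noise (5 ms), beats accumulated until 120 s past scan end so edge
  windows fill. This is a stand-in for an integral-pulse-frequency-
  modulation cardiac model — simpler, and sufficient to exercise every HRV
  formula. The LF amplitude alternates between 40 and 8 ms in 150-s blocks
  (no within-scan dynamics model exists to copy; the block profile is a
  free design choice that gives each scan balanced high/low-LF epochs); HF
  amplitude is constant at 25 ms. A toy ECG (Gaussian bumps at beat times)
  exists solely as a fixture for the R-peak detector.
* **Motion** is a smooth random-walk drift plus one-volume translation
  spikes of ≈ 0.35–0.5 mm at rate 0.05/volume. Each spike censors two
  volumes (the jump and the return), so a default scan retains ≈ 355 of 395
  post-dummy volumes — the retention level the analysis is designed around
  (quartile states of ≈ 88 volumes).
* **BOLD** is built from 11 shared network latents: parcel = latent +
  N(0, 0.65²) noise; the three unassigned parcels are pure noise. The
  designated network pair (ventral attention–thalamus by default) has
  latent correlation r₀ + s·Δr/2 with r₀ = 0.3, Δr = 0.4, where s = ±1
  follows the *ground-truth* LF-amplitude state of each volume and the sign
  of Δr flips between groups (controls lose connectivity in the high state,
  patients gain it). Planting from ground truth rather than estimated HRV
  makes state-estimation error measurable. Optional components: an
  HRF-convolved heart-rate signal injected into one parcel (for GLM
  recovery), a global signal, and white-matter voxel series for the PCA
  regressors.
* The parcel→network partition bundled by `default_partition()` is
  **synthetic**: contiguous ID blocks with the published network sizes
  (34/33/30/22/26/26/36 cortical + 4/4/12/16 subcortical, 3 unassigned of
  246). The pipeline depends only on the counts, not on anatomy.

All randomness derives from `SeedSequence([seed, subject, stream])`:
identical configurations reproduce byte-identical datasets.

**What passing tests show — and don't.** The generator matches the
analysis' *assumptions* (stationary Gaussian parcel noise, block-wise state
structure, spike-like motion). Real data add slow physiological drifts,
respiration coupling (unmodelled here, as in any recording without a
respiration belt), non-Gaussian motion, imperfect parcellations and
hemodynamic lag between autonomic state and BOLD. Recovery of planted
effects therefore validates the estimator chain, not the biological claim.

## Problem sizes and numerical choices

End-to-end validation uses the full default cohort (44 subjects, 400
volumes); the replicate recovery study runs 50 such cohorts with windowed
metrics evaluated at volume times and Welch PSDs batched across windows,
which keeps a full replicate under ~4 s. Unit tests use reduced cohorts
(≈ 11 subjects) where cohort size is not the point. Tolerances: spectral
examples allow 5 percentage points for leakage against the DFT oracle (0.5
for the in-band sum); exact algebraic identities are asserted at 1e-10
relative; correlation-orthogonality guarantees at 1e-10 absolute.
Permutation draws use full re-randomization in blocks of ≤ 2000 to bound
memory. Degenerate inputs (constant regressors, constant metric courses,
all-outlier windows, rank-deficient designs) are flagged or rejected, never
silently fitted.

## Known limitations

* The pulsatility basis is a phase model, not a full beat-shape convolution
  model; the interface accepts external regressors for a faithful drop-in.
* The quartile-state rule assumes the metric course is meaningful at volume
  resolution; no hemodynamic lag is applied to state definition by default.
* Network aggregation averages raw correlations (per the definition used in
  the mixed ANOVA); averaging Fisher-z values would weight extreme
  correlations differently.
* The bundled partition is synthetic; analyses of real data must supply the
  real atlas-to-network table in the same TSV format.
* With two states the split-plot model needs no sphericity correction;
  more than two states would.
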