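# Methods

`craniosemg` implements a craniofacial surface-EMG (sEMG) assessment
pipeline for bulbar involvement in ALS: six muscle channels recorded
during oral diadochokinetic (DDK) tasks are reduced to 60 features,
clustered into factor-analytic composite measures, linked to functional
outcomes through a stiffness-mediated path model, and fed to multiclass
classifiers. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic data do and do not
establish.

## Signal model and conditioning

Signals are stored channels × samples in "gained mV" (hardware gain
×2000); the acquisition front end is assumed to band-pass 5–500 Hz and
digitize at 2 kHz. Conditioning is:

1. **Filtering** — a 2nd-order IIR notch at 60 Hz (Q = 30) and a
   4th-order Butterworth high-pass at 20 Hz, each applied
   forward-backward (zero phase). Only the corner frequencies are
   dictated by the acquisition design; order and Q follow common sEMG
   practice. Zero-phase filtering leaves edge transients of roughly
   0.5 s; burst detection is robust to them, but spectral estimates on
   very short recordings (< 2 s) should be treated with caution.
2. **Crosstalk attenuation** — kurtosis-based independent-component
   estimation (FastICA, fixed seed). Estimated sources are re-assigned
   to channel labels by maximal |correlation| with the corresponding
   input channel (Hungarian assignment), sign-aligned, and re-scaled to
   the input channel's RMS, so downstream amplitude features remain in
   the input units. Rank-deficient inputs pass through with a warning.
   The step is configurable off (`crosstalk.enabled`).
3. **MVC normalization** — each channel is divided by its
   maximum-voluntary-contraction RMS reference. Per trial the reference
   is the overall RMS of the most stable 3-s interval, where "most
   stable" means minimum variance of the 500-ms moving-window RMS
   values inside the interval (100-ms hop); references are averaged
   over trials (three in the intended protocol). Pipeline order is
   filter → crosstalk → normalize; normalization is a positive per-
   channel scaling, so its position relative to the linear filters is
   immaterial for all scale-invariant features.

Amplitude thresholds stated in gained mV — the 4 mV deadband for zero
crossings and slope sign changes (4 µV peak-to-peak intrinsic system
noise × 2000 gain / 2) — are divided by the per-channel MVC reference
whenever the signal is in %MVC units, keeping the features
unit-consistent.

## Burst segmentation

DDK repetitions produce trains of myoelectric bursts at roughly 4–7 Hz.
No standard recipe exists for detecting them, so the module defines its
own, with every constant in `BurstConfig`:

- RMS envelope with a 25-ms moving window;
- baseline level = 10th-percentile envelope; baseline spread = SD of
  the sub-median envelope samples; candidate regions where the envelope
  exceeds baseline + k·SD with k = 3;
- regions shorter than 30 ms are discarded (noise blips outlast the
  envelope's ~25-ms correlation length but not real bursts);
- a region must also peak above baseline + 10·SD (dual-threshold
  criterion), so stationary noise with no true excursions yields zero
  bursts;
- regions closer than 80 ms are merged; the burst center is the
  envelope argmax.

The threshold is relative, making burst counts invariant to amplitude
scaling. Time-domain features use 100-ms segments centered on the
bursts; recurrence and coherence use stationary 1-s epochs centered on
the bursts, where overlapping epochs of adjacent bursts are merged into
their union and re-tiled into non-overlapping 1-s windows so that no
sample is double-weighted in Welch averaging (configurable off).
Windows that would overrun the signal are dropped, never padded —
padding would bias spectral content. A channel with no usable bursts
propagates missing values for its burst-dependent features, never
silent zeros.

## Features

Per channel (9 × 6 = 54):

- **MAV** and **WL** on 100-ms burst segments, averaged across
  segments; both scale linearly with amplitude.
- **ZR** and **SlpSignChange**: deadband-guarded zero crossings
  (sign change and |xᵢ − xᵢ₊₁| ≥ threshold) and slope sign changes
  ((xᵢ−xᵢ₋₁)(xᵢ−xᵢ₊₁) > 0 and the larger adjacent excursion ≥
  threshold). The published compound conditions are typographically
  ambiguous; the standard Hudgins-style deadband definitions are
  adopted, with the threshold configurable.
- **MNF**: power-weighted mean frequency of a Welch spectrum of the
  full preprocessed signal (100-ms, 50%-overlap Hamming windows,
  1024-point FFT). Frequency analysis is applied per signal, not per
  burst (a per-burst mode exists).
- **ShanEn**: 3-level wavelet-packet decomposition (5th-order Symlets,
  symmetric extension); per level-3 sub-band the entropy
  −Σ sᵢ² ln sᵢ² of the coefficients (0·ln 0 := 0), summed over the
  8 sub-bands. Natural log; sub-band entropies are summed without
  normalization.
- **RR/DET**: recurrence plots of z-scored 1-s epochs, delay embedding
  m = 30, τ = 5 samples, Euclidean norm. ε = 0.1 is interpreted as a
  fraction of the maximum phase-space distance of the epoch (absolute
  mode available); together with z-scoring this makes RR and DET
  amplitude-invariant. RR counts all recurrent pairs over M² (the
  self-recurrent main diagonal included); DET is the fraction of
  off-diagonal recurrence points on diagonal lines of length ≥ 2, with
  the main diagonal excluded from numerator and denominator. RR/DET are
  averaged over at most `rqa.max_epochs` (default 6) epochs per
  channel; beyond that the estimates change negligibly while the
  M×M distance matrices dominate runtime.
- **density**: the signal is reduced to a local-SD series (sample SD of
  non-overlapping 100-sample blocks, ddof = 1, computed on the whole
  recording), converted to a natural visibility graph under the strict
  slope criterion (collinear intermediates block visibility), and
  summarized by density 2E/(M(M−1)). Adjacent samples are always
  mutually visible.

Network level (2 × 3 = 6): for each channel pair the signals are
full-wave rectified and reconstructed by concatenating the pair's
shared (consensus-burst) 1-s epochs; magnitude-squared coherence uses
1024-point, 75%-overlap Hamming windows with a 4096-point FFT.
Coherence below the independence threshold S = 1 − 0.05^{1/(L̂−1)} is
zeroed within the θ/α (4–12 Hz), β (12–30 Hz) and low-γ (30–60 Hz)
bands; the edge weight is atanh of the band-mean pruned coherence
(clamped at 1−10⁻⁶; a √MSC variant is available). L̂, the adjusted
number of overlapped segments, is computed as the effective number of
independent segments for overlapped tapered Welch estimates — the raw
window count divided by 1 + 2Σ(1 − m/K)c_m², with c_m the normalized
Hamming autocorrelation at lag m·hop. This calibration is verified
empirically: on independent noise ~5% (±2) of in-band bins survive S.
Bins within ±1 Hz of the 60 Hz notch are excluded from the low-γ band
mean. Mean nodal strength is the average row sum of the 6×6 weight
matrix; global efficiency is the mean inverse shortest-path length
over node pairs with edge lengths 1/w (unreachable pairs contribute 0).

## Cohort statistics

- **Cleaning**: Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR), closed at
  the boundaries; flagged cells are imputed by iterated single-tree
  CART regression (depth ≤ 5, min leaf 5, ≤ 5 sweeps, seeded), one
  completed dataset.
- **Group effects**: per feature, a linear mixed model (REML) with
  group (ALS vs HC) fixed and a subject random intercept; Cohen's d =
  coefficient / √(σ²_subject + σ²_residual); singular fits fall back
  to the pooled two-sample d with a warning.
- **Composites**: the number of factors comes from parallel analysis
  (observed correlation-matrix eigenvalues vs the 95th percentile of
  Gaussian-null eigenvalues, leading run counted, 100 simulations,
  seeded). Extraction is minimum-residual (uniquenesses optimized by
  L-BFGS-B over the off-diagonal residual sum of squares, started at
  1 − SMC), rotation promax with power 4 after varimax, component
  features are those with |pattern loading| > 0.40, and scores use the
  Ten Berge correlation-preserving weights (their sample correlations
  reproduce the factor correlation matrix). Factor reliability is
  Cronbach's α over each factor's sign-aligned component features.
- **Integrated outcome**: Out = c₁·z(Bulb_ALSFRS) +
  c₂·z(log₁₀(max(Intell)+1 − Intell)) + c₃·z(1/SR), with healthy
  controls assigned the bulbar-subscore ceiling of 12 before z-scoring
  and the intelligibility ceiling taken within cohort. The combination
  weights are under-determined in the source analysis; defaults are
  equal weights with a caller override and an optional first-principal-
  axis mode.
- **Mediation**: full structural-equation modeling is replaced by
  per-composite two-regression path analysis — a: stiffness ~
  composite; (direct, b): outcome ~ composite + stiffness; indirect =
  a·b with a percentile bootstrap CI resampling subjects (not
  recordings), seeded. On planted linear paths the 95% CI covers the
  true indirect effect in ≈94% of replicates.
- **Confounder adjustment**: composites are residualized on age, sex,
  and cognitive status (MoCA < 26). Inside cross-validation the
  adjustment is re-fit on each training fold and applied to the
  held-out row. Note that residualizing on subject-level covariates
  removes, by chance alone, about p/(n_subjects−1) of the
  between-subject variance — with 26 subjects and 3 covariates ≈ 12% —
  so some post-adjustment accuracy loss is expected even for
  confounder-free covariates.

## Classification

Mixture discriminant analysis models each class as a K-component
Gaussian mixture with one covariance matrix shared across all
subclasses of all classes — flexible enough for within-class
heterogeneity (e.g. severity spectra), parsimonious enough for small
cohorts. Fitting is EM with k-means initialization (seeded), shared
covariance updated from responsibility-weighted within-subclass
scatter, convergence at a relative log-likelihood gain < 10⁻⁶ or 200
iterations; a small diagonal ridge keeps the covariance well
conditioned. K defaults to 2 (BIC selection over {1,2,3} available);
with K = 1 decisions coincide with linear discriminant analysis. The
RBF-kernel SVM is delegated to scikit-learn (C = 1, gamma = 1/(d·var)),
as a commodity reference classifier.

Evaluation is leave-one-out at the recording level (one fold per
recording; an optional leave-one-subject-out mode quantifies subject
leakage — with 4 recordings per subject, recording-level LOOCV leaves
the held-out subject's siblings in training, which inflates absolute
accuracy; comparisons across conditions remain meaningful). Metrics are
macro-averaged one-vs-rest sensitivity/specificity/PPV/NPV plus overall
accuracy; pairwise ROC curves use the posterior contrast
p(c₁)/(p(c₁)+p(c₂)) with the tie-aware rank-statistic AUC.

## Synthetic data

The recording simulator emulates burst-structured DDK sEMG: per channel
a band-shaped Gaussian carrier (default 80–450 Hz, the energetic range
of craniofacial sEMG) is gated by a Gaussian-envelope burst train
(default 5 Hz rate, 12-ms envelope SD, 3% timing jitter, 10% amplitude
CV) riding on a 2% muscle-tone floor, with burst amplitude 100 gained
mV against 8 mV peak-to-peak instrument noise (~30 dB). Band-limited
common drives (θ/α, β, low-γ) are shared narrowband amplitude
modulators applied to the burst-gated activity — not additive signals —
since intermuscular coherence in rectified sEMG reflects shared
modulation of motor-unit activity; the quiescent floor is unmodulated.
Linear crosstalk mixing (5% off-diagonal), 60 Hz line interference, and
sub-2-Hz baseline wander complete the acquisition model. Severity maps
to physiologically signed parameter changes: left-agonist amplitude up,
right-masseter amplitude down, submental spectral content up,
left-agonist spectra down, θ/α and β drives down, burst irregularity
up; functional metrics (bulbar subscore, intelligibility, speaking
rate, stiffness) degrade linearly in severity with Gaussian noise and
physiological clipping. Recovered Cohen's d signs rank-correlate with
the injected directions (Spearman ρ ≈ 0.88 in a 32-recording check).

The feature-level cohort generator plants the canonical 10-factor
structure directly in the 60-feature space: markers load 0.8–0.95 on
their factor (0.9–0.95 for factors with ≤ 3 markers, which are
otherwise undetectable at 104 rows), the two low-γ network features
stay unassigned, factor scores are shared within subject (30% of
variance; recordings are different DDK tasks, so between-task
variability dominates), and group effects enter as standardized shifts
— per construct or per feature — scaled by severity 0/1/2 for
HC/ALS-B/ALS+B. A "large effect" preset shifts the 20 features of four
constructs by 1.5 SD in their declared directions.

What passing tests show: the pipeline's operations are correct against
independent oracles and closed forms, its statistical calibrations
(coherence threshold, bootstrap coverage, parallel-analysis null) hold,
and planted structure of realistic size is recovered. What they do not
show: that real craniofacial sEMG satisfies the generative assumptions
(Gaussian carriers, multiplicative drives, linear severity maps), nor
that clinical effect sizes would replicate — clinical recordings of
this kind are not public, so no clinical headline value (composite
reliability, classification accuracy, variance explained) is asserted
by any test; the suite asserts only the calibrations and recoveries
that the synthetic conditions define.

## Problem sizes and determinism

Simulation sizes used by the validation suite — cohorts of 26 subjects
× 4 recordings at the feature level, 12 subjects × 2 recordings of 5 s
for signal-level end-to-end runs, 200-seed coherence calibration,
20-seed factor recovery, 500-replicate bootstrap coverage — were chosen
so each estimate's sampling error is small relative to its acceptance
band. Every stochastic step (simulation, ICA, k-means, CART, bootstrap,
parallel analysis) takes an explicit seed; a fixed seed reproduces
every artifact byte-for-byte, and run manifests record the config hash
and library versions.

## Known limitations

- Burst detection assumes clear burst/quiet alternation; continuous or
  severely disordered activation (very high jitter, merged syllables)
  degrades segmentation, which then propagates to segment-based
  features — mirroring the real measurement problem.
- The recurrence ε convention (fraction of maximum phase-space
  distance) differs from fixed-distance conventions; absolute mode is
  provided but RR/DET values are not comparable across conventions.
- ICA-based crosstalk attenuation is a stand-in for the original
  (unspecified) source-separation procedure and can redistribute
  low-variance components; it is off-switchable and all tests pass
  with it enabled.
- The SEM-based mediation of the source framework is simplified to
  per-composite path models; fit indices (CFI/RMSEA/SRMR) are not
  computed.
- With ≤ 3-marker factors at n = 104, the 95th-percentile parallel-
  analysis rule cannot retain a 2-marker factor (its eigenvalue bound
  1 + λ² < the null percentile); retention of 9 of 10 planted factors
  is the attainable ceiling under this rule.
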