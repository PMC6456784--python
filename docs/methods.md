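# Methods

This note documents the statistical model, the estimators, the numerical
choices and the known limitations of `dynfc`.

## The sliding-window dFC model

Input is a subject's region-by-time matrix `X` (n regions × T samples at
repetition time TR).  A rectangular window of `w` samples slides along the
time axis in steps of one sample; window `k` covers columns `[k, k + w)`
(0-based, half-open), giving `T − w + 1` positions.  An FC metric is
evaluated on each segment, and the **dFC strength** of a pair is the sample
variance σ² (divisor count − 1) of its windowed metric series.  Under
stationary connectivity the true σ² is zero up to estimation noise; the
hypothesis test is one-sided,

    H0: σ² = 0    vs.    H1: σ² > 0.

Window lengths are specified in seconds and converted by
`floor(seconds / TR)`; the default grid is 20–150 s in steps of 10 s
(14 lengths).  Weighted (tapered) windows are not implemented: the shape
field exists for forward compatibility but only `rectangular` is accepted.

## Metrics

* **Pearson, Spearman, Kendall.**  Spearman is exactly
  Pearson-on-average-ranks (ties get the mean of the covered ranks).
  Kendall uses the literal concordance rule set: strictly
  concordant/discordant pairs by sign agreement, pairs tied in either
  coordinate contribute zero, denominator `N(N−1)/2`.  With single-
  coordinate ties this is the tau-a normalization, not tau-b; this is
  deliberate and tested as such.
* **Partial correlations** regress each target row (with intercept) on the
  other `n − 2` rows of the *same segment* and correlate the residuals.
  Conditioning uses in-window samples of all other regions — the only
  self-consistent windowed reading.  A rank-deficient conditioning set is
  an error, not a silent pseudo-inverse.
* **ICOV** is the L1-penalized maximum-likelihood precision matrix of the
  segment's sample covariance (population convention), solved by graphical
  lasso at λ = 0.1; the pairwise value is the off-diagonal precision entry.
  λ = 0 falls back to direct inversion.  An optional Ledoit–Wolf shrinkage
  preconditioning of the covariance is available (off by default: the
  plain penalized-likelihood solve is the better-defined estimator and the
  shrinkage variant changes the estimand).  Convergence: duality-gap
  tolerance 1e-4, iteration cap 1000.  The solver's gap estimate can stall
  at a small (occasionally negative) value once the primal has stabilized,
  so only a final |gap| above max(100·tol, 1e-2) raises a convergence
  error.
* **MI / VI** are plug-in histogram estimators in bits.  Bins per axis
  equal the number of samples in the segment (configurable); marginal and
  joint histograms share equal-width bins over each variable's observed
  range, rightmost bin closed.  VI = H(X) + H(Y) − 2·I(X,Y) from the same
  histogram configuration, clamped at 0 against rounding.  With `w` bins
  for `w` samples these estimators are strongly biased upward as density
  estimates; that is intentional — the test statistic is the *variance* of
  the windowed values, and data and surrogates share the bias.
* **Symmetrized KL** compares the two *marginal* PDFs on a common set of
  equal-width edges spanning the union range.  Zero probabilities are
  replaced by a floor (1e-12) without renormalization before the
  log-ratio, keeping the divergence finite and the treatment of both
  arguments symmetric.
* **MTD** is the centered moving average (half-width `w`, i.e. 2w+1 terms)
  of the product of the two regions' first differences, each normalized by
  its full-series derivative standard deviation (population convention,
  configurable).  Only positions where the centered window fits are
  produced — no padding.  In the sliding-window layer MTD's inner
  half-width defaults to the outer window length in samples.
* Degenerate segments (a constant region where a correlation or MTD is
  requested) raise errors rather than returning 0: silent zeros would bias
  σ² downward.

Vectorized kernels implement windowed Pearson (cumulative sums), windowed
MI/VI (per-window bin indices, batched sorting and run-length counting of
joint histogram cells) and MTD (convolution).  They are exact
reimplementations, tested to agree with the per-segment definitions to
1e-9, and they make surrogate null construction tractable (about 14 ms per
8-region × 800-sample subject for windowed MI at 60 s windows).

## Surrogates

* **MVPR**: every row's discrete Fourier transform is multiplied by one
  common random phase vector, uniform on [0, 2π) per nonnegative
  frequency, with the DC (and Nyquist, for even T) phase fixed at 0 and
  Hermitian symmetry implied by the real-input rFFT — a mathematical
  requirement for a real inverse transform.  Each copy preserves all
  per-row amplitude spectra and all pairwise circular cross-spectra
  exactly; only the common phase — hence any time-locked nonstationarity —
  is destroyed.  The property report quantifies preservation of
  autocovariance, stationary cross-correlation, PSD, cross-PSD magnitude
  (all exact for MVPR) and the amplitude distribution (not preserved:
  phase randomization Gaussianizes).  Circular (FFT) definitions of the
  lagged statistics are used throughout, which is the sense in which MVPR
  preservation is exact.
* **MVAR**: a VAR(p) model is fitted by least squares without intercept
  (signals are assumed zero-mean; the generator and the high-pass both
  enforce this in practice), with p chosen by minimizing
  `ln det Σ̂_p + ln(T_eff)·p·n²/T_eff`, `T_eff = T − p` — the standard VAR
  form of the Schwarz criterion; constant-term variants do not change the
  argmin in our tests.  Surrogates seed with p consecutive original
  columns starting at a uniform position, then iterate the fitted
  recursion driven by residual *columns* drawn uniformly with replacement
  (joint draws preserve contemporaneous residual correlation).  The
  companion spectral radius is checked; an unstable fit triggers a warning
  since its surrogates are not covariance-stationary.
* One root seed per ensemble; per-surrogate streams are spawned from a
  seed sequence, so results do not depend on generation order.

## Inference

For surrogate index s and pair (i, j), the null sample is the mean over
subjects of σ² computed on each subject's s-th surrogate, giving
`n_surrogates` subject-averaged samples per pair (19,500 pooled samples
for 13 regions × 250 surrogates).  Two null modes exist: per-pair, and the
default aggregated mode pooling all pairs into one highly resolved
distribution.  The critical value T* is the nearest-rank empirical
quantile at level 1 − α′ with α′ = α/m under Bonferroni (m = tested
pairs); the upper tail follows from the one-sided alternative σ² > 0.  If
α′ falls below 1/(sample count) the quantile saturates at the maximum null
sample and a warning is emitted.  Rejection requires the group-mean
observed strength to *strictly* exceed T*; inference is group-level only
(subject-averaged observed vs. subject-averaged surrogate strengths).

Detection profiles summarize a window grid: per pair, the minimum window
length at which H₀ is rejected, a contiguity flag that is true exactly
when the detected set is the suffix {w : w ≥ minimum} of the grid, and the
explicit detected list otherwise (the dagger convention for bounded or
gapped detection ranges).  Test-retest reproducibility is the Pearson
correlation between two groups' vectorized upper-triangle strength
matrices.

## Synthetic cohorts

`SimSpec` generates cohorts from a stable VAR(1) with diagonal coefficient
0.4 and unit-variance Gaussian innovations (a Student-t option with
configurable df stresses the information metrics), 13 regions × 1,200
samples at TR 0.72 s by default, discarding a 200-sample burn-in.  A
designed dynamic pair adds one shared white standardized latent signal to
both rows: row i with constant gain a, row j with gain
a·sin(2π·f_mod·t·TR), producing a pairwise correlation that oscillates at
f_mod (default 0.016 Hz) with amplitude ≈ a²/(v + a²)·(sin term), v the
base signal variance.  The mechanism is a continuously varying true
correlation rather than switching covariance regimes; regime switching is
future work.

What the generator does *not* emulate: hemodynamic convolution and the
1/f-like BOLD spectrum, physiological noise, spatial structure, and
amplitude distributions of real data.  Passing tests on these cohorts
demonstrate the statistical machinery (calibration, determinism,
detection of a known modulation), not performance on real fMRI.

### Window length versus modulation frequency

A rectangular window of W seconds low-pass filters the coupling series
with transfer magnitude |sin(πfW)/(πfW)|, whose first null sits at
W = 1/f_mod.  At the default f_mod = 0.016 Hz (62.5 s period), windows of
60 s or more suppress the designed oscillation almost entirely; power
experiments therefore use windows of 20–40 s.  This is also the
field-standard guidance — the window must be shorter than the connectivity
fluctuation one hopes to track.  A related sensitivity limit is intrinsic
to windowed MI: its null σ² is dominated by histogram-collision noise that
exceeds the σ² contributed by a correlation oscillation of amplitude
a²/(1+a²) by two orders of magnitude at moderate gains, so MI-based
detection of the generator's designed pairs needs implausibly large
cohorts, while windowed Pearson detects them reliably.  The acceptance
suite reports this honestly: the MI power check fails under the study
conditions while the Pearson power and monotonicity checks pass.

## Problem sizes used by the test and acceptance runs

Type-I calibration: 8 regions, 10 subjects, T = 800 at TR 0.72 s, 100 MVPR
surrogates, 60 s windows, 25 replicates.  Power: 6 regions, 10 subjects,
T = 800, 40 surrogates, gains {0, 0.3, 0.6}, windows 20–40 s.  The
acceptance script uses the same designs at smaller replicate counts so a
full run stays within a few minutes on one CPU.

## Known limitations

- Circular (not linear) lagged statistics in the surrogate property
  report; the two differ at large lags for short series.
- The Kendall variant is tau-a-normalized under ties (documented above).
- No FDR or permutation corrections; no per-subject inference; no
  state-clustering of windowed matrices; no wavelet (time-frequency)
  analysis; no volumetric image handling — inputs are ROI × time matrices.
- ICOV on very short segments (≲ 20 samples with few regions) can stall
  the graphical-lasso duality gap; such segments are near the estimator's
  breakdown regime and a convergence error is raised when the gap is
  genuinely large.
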