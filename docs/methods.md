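# Methods

`maldimix` quantifies the level of cross-contamination in a two-component
cell culture (host line A, contaminating line B) from intact-cell MALDI-TOF
mass-spectral fingerprints by multivariate calibration. This note documents
the models, the numerical choices, and what the synthetic test bed does and
does not establish.

## The calibration problem

A sample of known total cell count (10⁶ or 0.5×10⁶ cells) contains `n_A`
host and `n_B` contaminant cells. Its linear-mode mass spectrum in the
2000–20000 m/z range is a fingerprint of many unresolved protein peaks,
most shared between the two cell types and a few unique to one of them.
Peak intensity is not proportional to analyte load ("MALDI effects":
matrix/analyte interaction variability, ionization suppression and
enhancement), so single-marker ratio methods fail, particularly at low
contamination. The calibration route instead treats the whole preprocessed
fingerprint as the predictor and the contaminant cell count `n_B` as the
response, trained on mixtures of known composition.

## Preprocessing chain

Spectra are processed in a fixed order:

1. **Resampling** to a uniform grid of 30000 m/z values over 2000–20000
   (linear interpolation; input points outside the range dropped; grid
   points outside the input support set to 0).
2. **Alignment**: each spectrum is shifted by the integer bin offset
   (|offset| ≤ 50 bins ≈ 30 Da by default) that maximizes its
   cross-correlation with the element-wise median spectrum of the set.
   Integer-bin shifting with zero fill keeps the operation exactly
   invertible and idempotent; ties prefer the smallest shift.
3. **Baseline subtraction**: a rolling minimum (default half-window 250
   bins ≈ 150 Da) smoothed by a moving average of the same window. By
   construction this baseline never exceeds the signal, so the output is
   non-negative without distorting peak heights.
4. **Smoothing**: Savitzky–Golay, window 21 bins, polynomial order 3.
   Small negative excursions are clipped to zero to preserve the
   non-negativity established by step 3.
5. **Normalization** to ΣXᵢ = 1 (total-ion-current normalization). The
   sum-to-one convention is the default because it is the operational
   formula of the protocol; an L2 (unit Euclidean norm) mode is available.

Rows of the resulting m × 30000 matrix follow the sample manifest; each
technical replicate is its own row. Columns whose maximum over all rows
never exceeds 10⁻³ (strict comparison) are discarded as latent noise.
The column maximum (rather than a per-row rule) keeps a peak that is
informative in *any* mixture.

## Informative-peak selection

Three selectors run on the thresholded matrix:

* **Normalized SD**: score_j = SD(column j) / SD(all entries pooled),
  ranked descending, ties broken by ascending m/z. Scale-free and
  invariant to row permutation.
* **Lasso**: L1-penalized regression of `n_B` on the standardized matrix
  over a logarithmic penalty path (100 values), penalty chosen by 5-fold
  cross-validation with the one-standard-error rule. The fold shuffle is
  seeded, so selection is deterministic.
* **Sparse PLS**: PLS1 whose weight vector is soft-thresholded at a
  fraction (default 0.8) of its largest magnitude per component (2
  components by default); columns with nonzero weight in any component
  are selected.

The final panel (10 or 30 peaks depending on the series) is assembled by
vote: a column chosen by more methods outranks one chosen by fewer; ties
fall back to the SD score, then ascending m/z. Because columns are grid
bins rather than centroided peaks, the pipeline first merges bins closer
than a minimum spacing (default 15 Da) into one peak cluster, represented
by its highest-SD bin and credited with the votes of all its bins; with
spacing 0 the literal per-bin rule applies. Without this, the adjacent
bins of one strong peak fill the whole panel and the three selectors'
votes never coincide on exactly the same bin.

## Calibrators

**PLS1 (baseline)**: NIPALS on centered (unscaled) data, 10 components by
default (capped at min(m−1, panel size)); extraction stops early when the
residual covariance vanishes, so exact low-rank data is handled cleanly.
The implementation is cross-checked against
`sklearn.cross_decomposition.PLSRegression(scale=False)` in the tests.

**Back-propagation ANN**: one hidden layer of 4 neurons, logistic sigmoid
on hidden and output units, inputs and target min-max scaled to
[0.1, 0.9]. Weights start uniform in [−0.5, 0.5] from a seeded generator,
biases at zero. Training is per-pattern (online) gradient descent with
momentum, patterns visited in a freshly shuffled order each epoch (the
shuffle stream derives from the model seed, so training is bit-for-bit
reproducible); a batch mode (one momentum update per epoch on the mean
gradient) is available. Defaults: learning rate 0.01, momentum 0.9. The
training trace records the Eq-1 RMS after every epoch (computed from each
pattern's pre-update forward pass, so it costs nothing extra) in original
cell-count units, plus the verification-set RMS when one is supplied.

The error criterion throughout is

    RMS = sqrt( Σ_p Σ_k (o_pk − o*_pk)² / (N·M) )

over N spectra and M outputs (M = 1), with o the experimental and o* the
calculated contaminant count. Validation reports this RMS together with
the slope k and R² of the ordinary least-squares line of predicted vs
experimental counts (free intercept), and a Wald–Wolfowitz runs test on
the signs of the residuals ordered by experimental value as an
operational check for systematic trends (the original assessment of
residual randomness was visual; the runs test is this package's
formalization). If every residual has the same sign the trend is treated
as maximal (p = 0).

**Leave-one-out validation** retrains from scratch for every left-out
spectrum with a fresh fold-derived seed and assembles the predictions in
row order. Each technical replicate is one row; a grouped mode that
leaves out all replicates of a mixture together is provided. The
architecture scan repeats the LOO run over a range of hidden-layer sizes
and flags the minimum.

### Training budgets (problem-size choices)

The network architecture is validated over training runs of up to 100 000
epochs, and the no-overfitting property (verification RMS stays within
10% of its running minimum, checkpointed every 100 epochs) is asserted at
that budget on a small calibration set. For leave-one-out runs over
~180-row datasets the pipeline default is 2000 epochs: on the synthetic
task the online updates converge well before that, and the LOO loop
retrains once per row. In the exactly linear noiseless limit, where there
is no noise to overfit, the acceptance test trains each fold to
convergence (10⁶ epochs at learning rate 0.1) to measure the model
family's closed-form-limit agreement rather than its optimization
transient.

### A structural note on the linear limit

In the exactly linear limit PLS is numerically exact (LOO errors of order
10⁻⁵ of the sample total). The sigmoid *output* unit bounds how exactly
the network can represent an affine map: with targets scaled to
[0.1, 0.9] the hidden layer must reproduce a logit-shaped curve, and from
the standard [−0.5, 0.5] initialization the reachable optima leave a
residual fit error of a few 10⁻⁴ of the target range, concentrated at the
low end of the calibration range. The network therefore agrees with PLS
to R² ≥ 0.999 in this limit but cannot match its (essentially zero) RMS;
the corresponding factor-of-two RMS agreement assertion in the acceptance
suite documents this bound rather than a removable defect.

## Synthetic data generator

The generator exists so that every pipeline stage is testable without
deposited spectra. It emulates the study conditions, not the physics:

* **Profiles**: 24 peaks per cell type, 75% of peak locations shared
  (with an A-vs-B abundance contrast of ±30% on shared peaks), the rest
  unique, of which 4 per component are designated markers drawn from the
  prominent end of the intensity range. Locations are uniform with a
  40 Da minimum separation in 2100–19500; Gaussian peak widths
  σ = max(m/z / 2500, 4) Da, as in low-resolution linear TOF. Both
  profiles are scaled to the same per-cell total ion current (one shared
  constant), so that sum-normalized fingerprints are exactly affine in
  `n_B` in the linear limit rather than a ratio of affine functions.
* **Mixing and response**: each peak's linear loading
  u = (n_A·I_A/(1+s·n_B) + n_B·I_B/(1+s·n_A)) / (n_A+n_B) combines the
  per-cell intensities with cross-component ionization suppression
  (s = 5×10⁻⁷ per cell). The loading passes through a per-peak saturating
  response r(u) = full·(1+K)·x^γ/(x^γ+K), x = u/full, with γ = 0.6,
  K = 0.5 and `full` the peak's full-load amplitude. γ = 1 is the
  documented linear switch (identity response). Saturation relative to
  each peak's own full amplitude preserves peak-height diversity — a
  single global response curve compresses every normalized apex toward
  the 10⁻³ threshold — while keeping the response strongly concave at low
  loadings, which is what makes a 0.5% contaminant clearly visible and
  linear calibration systematically biased.
* **Acquisition artifacts**: a fixed irregular digitization axis per
  dataset (~18000 points, ~1 Da spacing, derived from the seed), a global
  m/z jitter per spot (SD 1.5 Da), an exponentially decaying baseline
  (amplitude 0.05, decay constant 3000 Da), multiplicative per-peak noise
  (CV 3%) and additive noise (SD 2×10⁻³), intensities clipped at zero.
* **Designs**: presets mirror the study structure — `mef28` (28 mixtures
  + both pures, total 10⁶ cells, pentaplicates), `mesc34` (34 mixtures +
  pures, total 0.5×10⁶, pentaplicates), `valid50` (50 independent
  validation mixtures, single replicate). Validation presets share the
  cell-type profiles of the training seed but draw per-spot noise from a
  separate stream. The mixture fractions are denser at the low end
  (0.1–10%), where contamination detection matters most.

Noise magnitudes are not reported quantities; the defaults above were
fixed once so that the synthetic task sits in the difficulty regime of
the reported endpoints (e.g. LOO RMS near 1% of the sample total for the
network and several-fold worse for PLS) and are labeled as such. The
generator does not model isotope envelopes, adducts, detector saturation,
chemical-noise structure, or spot-morphology effects; passing tests
demonstrate that the pipeline and calibrators behave correctly under the
stated mixing-plus-noise model, not that they meet any accuracy figure on
real instrument data.

## Numerical and degenerate-input choices

* Threshold comparisons are strict; filtering twice is idempotent.
* PCA is a mean-centered SVD; explained fractions are relative to the
  total variance, component signs fixed by making the largest-magnitude
  loading entry positive; asking for more components than the rank
  truncates with a warning.
* Constant targets train to the degenerate midpoint scaling (the network
  predicts the constant exactly); all-zero spectra, zero-variance
  responses and single-row matrices raise typed errors rather than
  producing NaNs.
* Exact duplicate m/z values in an input file are merged by averaging;
  rows are sorted stably.
* All stochastic steps (initialization, fold shuffling, CV splits, the
  generator) consume explicit integer seeds; derived seeds come from
  `numpy.random.SeedSequence` spawning and stay below 2³¹.

## Limitations

* No vendor raw-file support; inputs are mzML (a common subset: MS1,
  64/32-bit float arrays, zlib or uncompressed) or two-column text.
* The mzML writer emits that same minimal subset, sufficient for
  round-tripping within this toolchain, not a full schema implementation.
* The ANN is deliberately the classic small regressor of the protocol;
  no regularization, early stopping beyond trace reporting, or deeper
  architectures.
* Predictions for unknown samples require the contaminating cell type to
  be the one the calibration was built for; the method quantifies a
  known contaminant, it does not identify an unknown one.
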