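# Methods

`semenc` implements a semantic-encoding analysis of electrocorticographic
(ECoG) responses to a short film, built as a parameter-recovery study on
synthetic data: every stage of the pipeline is exercised against planted
ground truth because the original recordings and the commercial
concept-recognition outputs that such analyses depend on are not publicly
distributable.

## The model

Let `s_f ⊂ V` be the set of concept labels recognized in film frame `f`
(vocabulary `V`, |V| = 129 after curation), and `v(ℓ) ∈ R^300` a word
embedding per label. The stimulus representation is

1. **frame embedding**: `x_f = mean_{ℓ∈s_f} v(ℓ)` after keeping only labels
   with recognition probability strictly above 0.9 that belong to the
   curated vocabulary;
2. **semantic components**: PCA of `{x_f}` (column centering, no variance
   scaling) to `K = 50` scores `c_f ∈ R^50`, ordered by explained variance
   with a deterministic sign convention (largest-magnitude loading
   coefficient positive);
3. **encoding**: per electrode `e`, ridge regression
   `hfb_e(t) ≈ β_e · c(t − τ)` at a candidate neural delay `τ`, with the
   penalty chosen per electrode by five-fold nested cross-validation on
   held-out Pearson correlation. The reported accuracy `r_cv` is the mean
   held-out correlation over five outer folds, transformed to a t value with
   `t = r√((n−2)/(1−r²))` (`n` = held-out samples per fold) and Bonferroni
   corrected over electrodes (α = 0.001 by default; a stricter 1e−5 flag is
   available).

Block design (alternating 30-s speech/music blocks) and the audio envelope
are removed before fitting: from each electrode's HFB at an
electrode-specific optimal lag (best linear fit over a ±5 s lag grid for the
block design; peak normalized cross-correlation for the envelope, removed
sequentially in that order), and from the component scores at lag 0, since
stimulus-side confounds are stimulus-locked. Binary-label feature sets are
deliberately not residualized.

Cross-validation folds are concatenations of 6-s fragments dealt round-robin
within every block, so each test set spans several speech and music blocks;
this guards against block-locked leakage under strong temporal
autocorrelation. Folds that cannot be filled raise instead of silently
shrinking.

### Networks

Significantly predicted electrodes are clustered by affinity propagation on
the pairwise Pearson correlation of their weight profiles (z-scored per
component over electrodes), shared preference `min(A) − 2`, damping 0.9, at
most 1,000 iterations. Clusters are kept only if they span at least a third
of the subjects and no subject holds more than a third of the members (a
share of exactly 1/3 passes). Each cluster's activation time course is the
dot product of the component scores with the exemplar's weights; we use the
raw-unit weights here (clustering and exemplar choice still use z-scored
profiles) so activations live on the scale of predicted responses and are
comparable across clusters against the shuffled null. Peaks and dips are
frames beyond the 2.5th/97.5th percentiles of a pooled null built by
permuting cluster labels (default 10,000 shuffles; smaller counts are used in
tests and noted there), keeping the top/bottom 10% of candidates. Per
component, peak and dip frames (paired by descending extremity, trimmed to
equal length) are compared with a two-sided Wilcoxon signed-rank test,
Bonferroni corrected by clusters × components. Because the rank statistic
saturates once all pairs move the same way, a graded effect size — median
peak−dip difference in units of the component's score SD — is reported
alongside; component attribution ranks by it. The variance-adjusted
statistic (z divided by percent explained variance) is reported for display,
never used for significance.

The signed-rank z is computed explicitly (`(W⁺ − E[W⁺])/sd(W⁺)`, ties
averaged, zeros dropped) because library implementations report a min-based
statistic whose z loses the sign of the effect.

### Surface smoothing

Per-electrode scalars are projected to a regular spherical grid with a
Gaussian-process smoother: `g = K_cᵀ (K_s + ηI)⁻¹ y` with
`K = exp(−D²/(2σ²))` on great-circle distances `d(u,v) = r·arccos(uᵀv)`.
Defaults σ = 8 mm (the scale of the usual volumetric overlay smoothing) and
η = 1e−3; η > 0 is required whenever electrodes coincide. A subdivided
icosahedron generator stands in for the FreeSurfer ico5 grid. The kernel
squares the distance as the projection equations require, although the
kernel family is conventionally called "exponential" in this context.

### HFB extraction

Raw traces (512 Hz) are notch-filtered at 50/100 Hz (zero-phase IIR, Q=35),
common-average referenced per grid, decomposed with complex Morlet wavelets
in 1-Hz bins whose Gaussian envelope has a temporal FWHM of four wavelengths
of the center frequency, averaged over 60–120 Hz inclusive, and polyphase
resampled (anti-aliased) to the 25 Hz frame rate. Edges use reflect padding;
the first/last second should be treated with caution. Filter order/type for
the acquisition band are not modelled.

## The synthetic study

`synth` + `pipeline.simulate_experiment` generate the full experiment:

- **lexicon**: 129 labels in 8 topics; each vector is a unit-normalized topic
  centroid plus isotropic noise (spread 0.35), so within-topic cosine
  similarity exceeds between-topic — the property of real embeddings the
  pipeline exploits.
- **stimulus**: 13 alternating 30-s blocks at 25 frames/s (9,750 frames),
  20 labels/frame with recognition probabilities Uniform(0.85, 1), so the
  90% filter has work to do. Scene topics follow a sticky Markov chain
  (persistence 0.98) reproducing the strong temporal autocorrelation of film
  semantics, and freshly sampled topics prefer a block-type-specific half of
  the topics (bias 0.6): speech and music scenes of a real film also differ
  visually, which is exactly what makes confound control non-trivial.
- **neural data**: 15 subjects × 8 electrodes on per-subject grid-like
  patches of the unit sphere. HFB is the planted linear model at a lag of
  320 ms (8 frames) plus per-electrode block/envelope gains and AR(1) noise
  (coefficient 0.3) scaled per electrode to the requested signal-to-noise
  variance ratio (default 1). A configurable fraction of electrodes (default
  0.1) is null. Non-null weight rows come from five orthogonalized cluster
  prototypes concentrated on the top five components, expressed in the
  standardized parameterization (weight per unit component SD) and mapped to
  raw units by dividing by each component's score SD. Planting in raw units
  instead would make the prototype structure on late components vanish
  relative to estimation noise after the per-component z-scoring that
  clustering requires; the standardized parameterization keeps every planted
  component contribution at equal signal strength, as in real data where the
  per-component spread of weights across electrodes is genuine signal.
- **frames**: procedural RGB textures keyed to labels (frames sharing labels
  are more pixel-correlated), sufficient for the pixel/Gabor controls; no
  attempt at realistic imagery.

What the generator does **not** emulate: non-Gaussian or nonstationary
noise, inter-electrode noise correlations, imperfect embedding coverage,
label noise beyond the probability filter, eye movements, or any true
nonlinearity between stimulus and response. Passing tests therefore show
that the pipeline recovers its own generative assumptions at realistic
sizes and noise levels — not that those assumptions hold for cortex.

## Encoding-weight scale

The ridge is solved on standardized features. `EncodingFit.betas` stays in
that parameterization (response change per feature SD): it is the scale on
which weight profiles are compared across electrodes and the one clustering
consumes. `EncodingFit.betas_raw` rescales per fold to original feature
units and equals the generating weights exactly in the noiseless
unregularized limit. Recovery tests compare in the standardized
parameterization because raw-unit comparisons divide by near-zero trailing
component SDs and measure mostly noise amplification.

## Numerical choices

- Ridge path: one SVD per training fold serves all penalties
  (grid 1e−3…1e6, 10 log-spaced points) and all electrodes at once.
- Time-shift convention: positive shift = neural response lags the stimulus;
  shifted features are trimmed (not padded) before fitting. The generator
  holds edge values when shifting, and the noise-free equality test uses the
  same convention.
- Best shift: maximal significant-electrode count, mean significant
  correlation as tiebreak, then smallest |shift|.
- Degenerate electrodes (constant test response) get r = 0 and are flagged;
  zero-label frames are excluded from the PCA fit and given zero scores;
  rank-deficient label designs fall back to minimum-norm OLS with a warning.
- Percentile thresholds pool baseline values over frames and shuffles
  (per-frame thresholds were considered and rejected as the default: the
  pooled variant matches the description of a single pair of highlighted
  threshold values).
- Z-scoring treats a column whose SD is within 1e−12 (relative) of rounding
  error as constant.
- RSA bootstrap resamples frames with replacement (standard bootstrap);
  percentile CIs are widened minimally to always bracket the point estimate.

## Problem sizes in tests and the acceptance script

The acceptance checks run the study at its native 9,750 frames and 50
components with 60–200 electrodes; replicated checks (lag recovery over 10
seeds, null calibration over 20 seeds, 500-replicate test calibrations) use
those sizes directly. Shuffle counts for the peak/dip null are 300–1,000 in
scripted runs (10,000 is the package default); RSA bootstraps use 200–300
resamples of 400 frames. These sizes were chosen so each analysis completes
in minutes on a single core while leaving the Monte-Carlo error well inside
the asserted margins.

## Known limitations

- The attribution ground truth is defined as what the identical pipeline
  reports on the planted (noise-free) weights, because the mapping from a
  planted weight profile to the dominant peak/dip component is mediated by
  the discrete scene-topic structure and has no closed form.
- Affinity propagation convergence is not guaranteed; non-convergence raises
  with partial labels attached rather than returning a silent partition.
- The Gabor pyramid follows a standard complex-cell energy design
  (configurable scales/orientations/positions); it is not a reimplementation
  of any specific published filter bank.
- `best_envelope_lag` picks the peak of the absolute normalized
  cross-correlation on a discrete frame grid; sub-frame lags are not
  estimated.
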