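# semenc

Semantic-component encoding models for film-watching ECoG.

How does the human cortex track the *meaning* of a continuously unfolding
visual scene? One productive answer treats a feature film as the stimulus,
describes every frame by the concepts visible in it, embeds those concept
labels in a word-embedding space, reduces the frame-averaged embeddings to a
few **semantic components** by PCA, and asks how well those components
predict high-frequency-band (HFB, 60–120 Hz) activity at each
electrocorticography electrode. Electrodes that are predicted well can then
be grouped — by the similarity of their regression weights — into functional
cortical networks, each tied to particular semantic contrasts (people vs.
nature, movement vs. still scenes, faces vs. bodies, …).

`semenc` is a complete, tested implementation of that pipeline for
researchers working on naturalistic neural encoding models. Clinical ECoG
recordings and commercial concept-recognizer outputs cannot be
redistributed, so the package pairs the analysis code with a first-class
synthetic-data module that generates the whole experiment — stimulus,
embeddings, electrode geometry, HFB with confounds — from planted ground
truth, turning every stage into a parameter-recovery problem.

## The model

With frame labels `s_f`, embeddings `v(ℓ) ∈ R^300`, frame vectors
`x_f = mean_{ℓ∈s_f} v(ℓ)`, and PCA scores `c_f ∈ R^50`:

```
hfb_e(t) = β_e · c(t − τ) + γ_e·block(t) + δ_e·env(t) + ε_e(t)
```

Per electrode, block-design and audio-envelope confounds are removed at
electrode-specific optimal lags; ridge weights `β_e` are fit by five-fold
nested cross-validation (penalty chosen on held-out correlation, folds built
from 6-s fragments spanning every speech and music block); accuracy is the
cross-validated Pearson `r`, tested via the t transform with Bonferroni
correction; the delay `τ` is found by refitting over a grid of time shifts.
Significant electrodes are clustered with affinity propagation on their
z-scored weight profiles (preference `min(A) − 2`), clusters are screened
for subject-specificity, and each network's activation time course is tested
for per-component peak-vs-dip contrasts against a cluster-label-shuffling
null. Controls include pixel and Gabor-energy models, a binary-label model,
layer-wise representational similarity with a bootstrap, and
Gaussian-process smoothing of electrode values onto a spherical grid.

## Worked example

```python
import numpy as np
from semenc import encoding, pipeline

study = pipeline.simulate_experiment(seed=1)       # 9,750 frames, 120 electrodes
sweep = encoding.sweep_time_shifts(
    study.features, study.residual_recording.hfb, study.plan,
    shifts_seconds=np.arange(-10, 11) * 0.04,
)
print(f"best time shift: {1000 * sweep.best_shift:.0f} ms")
fit = encoding.fit_ridge_cv(
    study.features, study.residual_recording.hfb, study.plan, time_shift=0.32
)
corrs = pipeline.beta_recovery(study, fit)
print(f"{fit.significant.sum()}/{fit.r_cv.size} electrodes significant; "
      f"beta recovery median r = {np.median(corrs):.3f}")
```

prints

```
best time shift: 320 ms
106/120 electrodes significant; beta recovery median r = 0.997
```

i.e. the shift sweep recovers the planted 320 ms stimulus-to-cortex delay
exactly, the encoding model flags the ~90% of electrodes that carry planted
semantic signal at signal-to-noise ratio 1, and the fitted weight profiles
match the planted ones almost perfectly in the standardized
parameterization. The numbered scripts under `analysis/` run the same study
end to end (component interpretation, encoding, controls, network
clustering, surface maps) and write their tables under `results/`; for
instance `analysis/02_semantic_components.py` reports that 50 components
keep 99.6% of the embedding variance and that each of the top components
contrasts two planted scene topics.

## Layout

```
src/semenc/        library: synth, semantic, preprocess, confounds,
                   encoding, controls, clusters, surface, pipeline, io
analysis/          numbered narrative drivers writing results/ tables
tests/             pytest suite incl. acceptance checks
scripts/           acceptance.py
docs/methods.md    methods note
```
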