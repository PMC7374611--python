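"""Control analyses: low-level visual features, model comparison, RSA.

The semantic encoding result is only interesting if it is not explained by
low-level image statistics.  This module builds pixel and Gabor-energy
feature sets from the frame images, reduces any feature set to 50 principal
components so model complexity is matched, compares two encoding fits with a
one-sided Wilcoxon signed-rank test over the union of their significant
electrodes, and measures layer-wise representational similarity (correlation
of pairwise-frame similarity matrices) with a bootstrap over frames.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps
from skimage.filters import gabor_kernel

from .datatypes import EncodingFit, FeatureSet, RsaResult, SemanticComponents
from .semantic import fit_components
from .wstats import signed_rank_z

__all__ = [
    "pixel_features",
    "gabor_features",
    "reduce_features",
    "compare_models",
    "representational_similarity",
    "synthetic_layer_hierarchy",
]


def pixel_features(images: np.ndarray) -> FeatureSet:
    """Raw colored pixel values, one row per frame (row-major, channels last)."""
    images = np.asarray(images)
    return FeatureSet(name="pixel", values=images.reshape(images.shape[0], -1).astype(float))


def gabor_features(
    images: np.ndarray,
    scales: int = 4,
    orientations: int = 8,
    positions_per_scale: int = 4,
    base_frequency: float = 0.25,
) -> FeatureSet:
    """Complex-cell energy of a Gabor wavelet pyramid on luminance images.

    For each scale (spatial frequency ``base_frequency / 2**s`` cycles/px)
    and orientation, the image is convolved with a quadrature Gabor pair and
    the energy ``sqrt(even^2 + odd^2)`` is sampled on a
    ``positions_per_scale x positions_per_scale`` grid.  Scales whose kernel
    exceeds the image are skipped with a warning.
    """
    images = np.asarray(images, dtype=float)
    gray = images.mean(axis=3) if images.ndim == 4 else images
    n, H, W = gray.shape
    cols: list[np.ndarray] = []
    ys = np.linspace(0, H - 1, positions_per_scale + 2)[1:-1].round().astype(int)
    xs = np.linspace(0, W - 1, positions_per_scale + 2)[1:-1].round().astype(int)
    for s in range(scales):
        freq = base_frequency / 2**s
        kernel = gabor_kernel(frequency=freq, theta=0.0)
        if kernel.shape[0] > H or kernel.shape[1] > W:
            warnings.warn(f"skipping scale {s}: kernel {kernel.shape} larger than image")
            continue
        for o in range(orientations):
            theta = np.pi * o / orientations
            k = np.asarray(gabor_kernel(frequency=freq, theta=theta))
            resp = sps.fftconvolve(gray, k[None, :, :], mode="same", axes=(1, 2))
            energy = np.abs(resp)  # |even + i*odd| of the quadrature pair
            cols.append(energy[:, ys][:, :, xs].reshape(n, -1))
    if not cols:
        raise ValueError("no Gabor scale fits the image")
    return FeatureSet(name="gabor", values=np.concatenate(cols, axis=1))


def reduce_features(fs: FeatureSet, n_components: int = 50) -> FeatureSet:
    """Project a feature set onto its top principal components.

    Matches the complexity of the 50-component semantic model; uses the same
    PCA contract (centering only, deterministic signs) as the semantic stage.
    """
    k = min(n_components, min(fs.values.shape) - 1)
    comps = fit_components(fs.values, n_components=k)
    return FeatureSet(name=fs.name, values=fs.values, reduced=comps.scores)


def compare_models(
    fit_a: EncodingFit, fit_b: EncodingFit, alpha: float = 0.001
) -> dict:
    """One-sided Wilcoxon signed-rank test that model A predicts better than B.

    Paired over the union of electrodes significant in either model; the
    alternative is ``r_a > r_b``.  Returns z, one-sided p, the electrode set
    and the per-model medians over that set.
    """
    if fit_a.r_cv.shape != fit_b.r_cv.shape:
        raise ValueError("fits must cover the same electrodes")
    if fit_a.time_shift != fit_b.time_shift:
        raise ValueError("fits must share the time shift")
    electrode_set = np.flatnonzero(fit_a.significant | fit_b.significant)
    if electrode_set.size == 0:
        raise ValueError("no electrode is significant in either model")
    a = fit_a.r_cv[electrode_set]
    b = fit_b.r_cv[electrode_set]
    z, _, p = signed_rank_z(a - b)  # one-sided: a > b
    return {
        "z": z,
        "p": p,
        "electrode_set": electrode_set,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "alpha": alpha,
    }


def _upper_triangle_similarity(layer: np.ndarray, target: np.ndarray) -> float:
    """Correlate the upper triangles of the two pairwise-frame similarity matrices."""
    iu = np.triu_indices(layer.shape[0], k=1)
    cl = np.corrcoef(layer)[iu]
    ct = np.corrcoef(target)[iu]
    return float(np.corrcoef(cl, ct)[0, 1])


def representational_similarity(
    layers: list[FeatureSet],
    target: SemanticComponents,
    k_subset: int | None = None,
    n_boot: int = 1000,
    boot_frames: int | None = None,
    seed: int = 0,
) -> RsaResult:
    """Layer-wise similarity of frame representations to the semantic components.

    Per layer: the frames x frames Pearson similarity matrix is computed, its
    upper triangle (diagonal excluded) is correlated with the target's.
    ``k_subset`` restricts the target to its top-k components.  Percentile
    confidence intervals come from re-computing the score in bootstrap
    samples of ``boot_frames`` frames drawn with replacement.
    """
    T = target.scores if k_subset is None else target.scores[:, :k_subset]
    n = T.shape[0]
    if n < 3:
        raise ValueError("need at least 3 frames")
    mats = [np.asarray(l.values, dtype=float) for l in layers]
    ok = T.std(axis=1) > 0
    for M in mats:
        ok &= M.std(axis=1) > 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} constant-representation frames")
    T = T[ok]
    mats = [M[ok] for M in mats]
    n = T.shape[0]
    if boot_frames is None:
        boot_frames = min(1000, n)
    if boot_frames > n:
        raise ValueError("boot_frames exceeds available frames")

    point = np.array([_upper_triangle_similarity(M, T) for M in mats])
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(mats)))
    for b in range(n_boot):
        idx = rng.integers(n, size=boot_frames)
        for j, M in enumerate(mats):
            boots[b, j] = _upper_triangle_similarity(M[idx], T[idx])
    ci = np.percentile(boots, [2.5, 97.5], axis=0).T
    # a percentile CI from a skewed bootstrap can exclude the point estimate;
    # widen minimally so the reported interval always brackets it
    ci[:, 0] = np.minimum(ci[:, 0], point)
    ci[:, 1] = np.maximum(ci[:, 1], point)
    return RsaResult(
        per_layer_similarity=point, bootstrap_ci=ci, n_boot=n_boot, n_frames_sampled=boot_frames
    )


def synthetic_layer_hierarchy(
    target: SemanticComponents,
    n_layers: int = 5,
    n_features: int = 64,
    weights: np.ndarray | None = None,
    seed: int = 0,
) -> list[FeatureSet]:
    """Synthetic stand-in for a deep network's layer stack.

    Layer i mixes frame-independent noise features with a random linear
    read-out of the target components at mixture weight ``weights[i]``
    (default linearly increasing), emulating the gradual emergence of
    semantic structure along a visual hierarchy.
    """
    rng = np.random.default_rng(seed)
    n, K = target.scores.shape
    if weights is None:
        weights = np.linspace(0.1, 0.9, n_layers)
    scores = target.scores / target.scores.std(axis=0, keepdims=True)
    layers = []
    for i, w in enumerate(weights):
        R = rng.standard_normal((K, n_features)) / np.sqrt(K)
        noise = rng.standard_normal((n, n_features))
        vals = w * (scores @ R) + (1.0 - w) * noise
        layers.append(FeatureSet(name=f"layer{i + 1}", values=vals))
    return layers
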