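"""Stimulus-side semantic pipeline: label filtering, embedding, PCA.

Stages: (I) keep only confidently recognized labels from a curated
vocabulary, (II) look up each label's word-embedding vector and average over
the labels of a frame, (III) reduce the frame-averaged vectors to K principal
semantic components.  Interpretation helpers rank frames along a component
and regress components on binary label indicators post hoc.
"""
from __future__ import annotations

import warnings

import numpy as np
from sklearn.decomposition import PCA

from .datatypes import (
    BinaryLabelMatrix,
    EmbeddingLexicon,
    FrameEmbeddingMatrix,
    FrameLabelTable,
    SemanticComponents,
)

__all__ = [
    "filter_labels",
    "embed_frames",
    "fit_components",
    "transform_embeddings",
    "binary_label_matrix",
    "rank_frames",
    "posthoc_label_regression",
]


def filter_labels(
    table: FrameLabelTable,
    min_probability: float = 0.9,
    keep_list: set[str] | None = None,
) -> FrameLabelTable:
    """Keep labels with probability strictly above threshold and in the vocabulary.

    The strict ``>`` mirrors a "more than 90%" confidence cut; ``keep_list``
    is the curated vocabulary (manual curation itself is outside this
    package's scope).  Per-frame duplicates are collapsed, keeping the highest
    probability.
    """
    if not (0.0 <= min_probability <= 1.0):
        raise ValueError("min_probability must be in [0, 1]")
    if keep_list is not None and len(keep_list) == 0:
        raise ValueError("keep_list must be non-empty (pass None to keep all)")
    out: list[list[tuple[str, float]]] = []
    for entries in table.labels_per_frame:
        best: dict[str, float] = {}
        for lab, p in entries:
            if p <= min_probability:
                continue
            if keep_list is not None and lab not in keep_list:
                continue
            if lab not in best or p > best[lab]:
                best[lab] = p
        out.append(sorted(best.items()))
    return FrameLabelTable(
        n_frames=table.n_frames, frame_rate=table.frame_rate, labels_per_frame=out
    )


def embed_frames(table: FrameLabelTable, lexicon: EmbeddingLexicon) -> FrameEmbeddingMatrix:
    """Average the embedding vectors of each frame's labels (unweighted).

    Averaging in embedding space lands between the constituent labels, which
    is what lets a single vector represent the combined meaning of a frame.
    Frames with zero labels get an all-zero row and ``n_labels_used == 0``.
    """
    values = np.zeros((table.n_frames, lexicon.dim))
    counts = np.zeros(table.n_frames, dtype=int)
    for f, entries in enumerate(table.labels_per_frame):
        if not entries:
            continue
        vecs = [lexicon.vector(lab) for lab, _p in entries]
        values[f] = np.mean(vecs, axis=0)
        counts[f] = len(vecs)
    return FrameEmbeddingMatrix(values=values, n_labels_used=counts)


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Sign convention: largest-magnitude loading coefficient positive per column."""
    signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def fit_components(
    embeddings: FrameEmbeddingMatrix | np.ndarray, n_components: int = 50
) -> SemanticComponents:
    """PCA of frame-averaged embeddings: centering only, no variance scaling.

    Embedding dimensions share a scale, so columns are mean-centered but not
    standardized.  Components are ordered by explained variance; PCA signs are
    arbitrary, so a deterministic convention (largest-magnitude loading
    coefficient positive) is applied for reproducible frame rankings.

    Zero-label frames are excluded from the fit; their scores are the
    projection of the global mean, i.e. exactly zero.
    """
    if isinstance(embeddings, FrameEmbeddingMatrix):
        X = embeddings.values
        fit_mask = ~embeddings.empty_frames
    else:
        X = np.asarray(embeddings, dtype=float)
        fit_mask = np.ones(X.shape[0], dtype=bool)
    n_fit = int(fit_mask.sum())
    if n_components > min(n_fit, X.shape[1]):
        raise ValueError("n_components exceeds min(n_frames, dim)")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X[fit_mask])
    loadings = pca.components_.T  # (D, K)
    signs = _fix_signs(loadings)
    loadings = loadings * signs
    scores = np.zeros((X.shape[0], n_components))
    scores[fit_mask] = (X[fit_mask] - pca.mean_) @ loadings
    return SemanticComponents(
        scores=scores,
        loadings=loadings,
        mean=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def transform_embeddings(
    components: SemanticComponents, X: np.ndarray
) -> np.ndarray:
    """Project new frame-averaged embeddings onto fitted components."""
    return (np.asarray(X, dtype=float) - components.mean) @ components.loadings


def binary_label_matrix(table: FrameLabelTable, label_ids: list[str] | None = None) -> BinaryLabelMatrix:
    """Frames x labels presence indicator with a fixed, recorded column order."""
    if label_ids is None:
        seen: set[str] = set()
        for entries in table.labels_per_frame:
            seen.update(lab for lab, _ in entries)
        label_ids = sorted(seen)
    col = {lab: j for j, lab in enumerate(label_ids)}
    values = np.zeros((table.n_frames, len(label_ids)), dtype=int)
    for f, entries in enumerate(table.labels_per_frame):
        for lab, _p in entries:
            if lab in col:
                values[f, col[lab]] = 1
    return BinaryLabelMatrix(values=values, label_ids=list(label_ids))


def rank_frames(
    components: SemanticComponents,
    component_idx: int,
    fraction: float = 0.10,
    table: FrameLabelTable | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[dict[str, int], dict[str, int]] | None]:
    """Bottom/top ``fraction`` of frames along one component, with label histograms.

    Returns ``(bottom_frames, top_frames, histograms)`` where each set has
    ``ceil(fraction * n_frames)`` frames and ties are broken by ascending
    frame index.  If a label table is supplied, per-set label occurrence
    histograms are returned (else ``None``).
    """
    if not (0.0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    K = components.n_components
    if not (0 <= component_idx < K):
        raise ValueError(f"component_idx out of range [0, {K})")
    vals = components.scores[:, component_idx]
    n = vals.size
    n_sel = int(np.ceil(fraction * n))
    # stable sorts => ties broken by ascending frame index in both sets
    bottom = np.sort(np.argsort(vals, kind="stable")[:n_sel])
    top = np.sort(np.argsort(-vals, kind="stable")[:n_sel])
    hists = None
    if table is not None:
        def _hist(idx: np.ndarray) -> dict[str, int]:
            h: dict[str, int] = {}
            for f in idx:
                for lab, _p in table.labels_per_frame[f]:
                    h[lab] = h.get(lab, 0) + 1
            return h

        hists = (_hist(bottom), _hist(top))
    return bottom, top, hists


def posthoc_label_regression(
    components: SemanticComponents,
    labels: BinaryLabelMatrix,
    k_top: int = 5,
) -> tuple[np.ndarray, float, float]:
    """OLS of the top components on binary label indicators (interpretation aid).

    Fits, per component, an intercept plus one weight per label; label
    rankings from most negative to most positive weight describe what the
    component contrasts.  Returns ``(weights (L x k_top), R^2, F)`` where R^2
    and F are pooled over the ``k_top`` components.
    """
    if k_top > components.n_components:
        raise ValueError("k_top exceeds number of components")
    Y = components.scores[:, :k_top]
    B = np.asarray(labels.values, dtype=float)
    if B.shape[0] != Y.shape[0]:
        raise ValueError("frame count mismatch between components and labels")
    n, L = B.shape
    X = np.column_stack([np.ones(n), B])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient label matrix; using minimum-norm solution")
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    sse = float((resid**2).sum())
    sst = float(((Y - Y.mean(axis=0)) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    df1 = rank - 1
    df2 = n - rank
    if df2 <= 0 or r2 >= 1.0:
        f_stat = np.inf
    else:
        f_stat = (r2 / df1) / ((1.0 - r2) / df2)
    return coef[1:], r2, f_stat
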