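"""Synthetic film-watching experiment with planted ground truth.

The real study paired a short feature film (13 alternating 30-s speech and
music blocks at 25 frames/s) with subdural ECoG from 37 subjects; neither the
film-frame concept labels, the embedding lexicon nor the neural recordings
are publicly available.  This module emulates all of them with known planted
structure so that every downstream stage — semantic PCA, confound removal,
ridge encoding, clustering, surface smoothing — can be tested as a parameter
recovery problem.

Every generator is a pure function of its arguments including ``seed``.
"""
from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .datatypes import (
    ElectrodeGeometry,
    EmbeddingLexicon,
    FrameLabelTable,
    GroundTruth,
    NeuralRecording,
    SemanticComponents,
    StimulusConfounds,
)

__all__ = [
    "generate_lexicon",
    "generate_stimulus",
    "render_frames",
    "generate_geometry",
    "generate_neural",
]


def generate_lexicon(
    n_labels: int = 129,
    n_topics: int = 8,
    dim: int = 300,
    spread: float = 0.35,
    seed: int = 0,
) -> EmbeddingLexicon:
    """Draw a topic-structured embedding lexicon.

    Labels are grouped into ``n_topics`` semantic topics; each label vector is
    a unit-normalized topic centroid plus isotropic noise of scale ``spread``,
    so within-topic cosine similarity exceeds between-topic similarity in
    expectation — the property of real word embeddings the pipeline relies on.
    """
    if n_labels <= 0 or n_topics <= 0 or dim < 2:
        raise ValueError("counts must be positive and dim >= 2")
    if n_topics > n_labels:
        raise ValueError("n_topics must not exceed n_labels")
    if spread <= 0:
        raise ValueError("spread must be positive")
    rng = np.random.default_rng(seed)
    centroids = rng.standard_normal((n_topics, dim))
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    topic_of = np.arange(n_labels) % n_topics
    noise = rng.standard_normal((n_labels, dim)) * spread / np.sqrt(dim)
    vectors = centroids[topic_of] + noise
    vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
    labels = [f"concept{i:03d}_t{topic_of[i]}" for i in range(n_labels)]
    return EmbeddingLexicon(labels=labels, vectors=vectors, topic_of=topic_of)


def generate_stimulus(
    lexicon: EmbeddingLexicon,
    n_blocks: int = 13,
    block_seconds: float = 30.0,
    frame_rate: float = 25.0,
    labels_per_frame: int = 20,
    scene_persistence: float = 0.98,
    seed: int = 0,
    topic_label_fraction: float = 0.75,
    block_topic_bias: float = 0.6,
) -> tuple[FrameLabelTable, StimulusConfounds]:
    """Generate a film-like label stream plus block/envelope confounds.

    Scenes are modelled as a sticky Markov chain over lexicon topics: the
    current topic persists from frame to frame with probability
    ``scene_persistence``, which induces the strong temporal autocorrelation
    of frame-averaged embeddings seen in real film material.  Each frame
    receives ``labels_per_frame`` distinct labels, a ``topic_label_fraction``
    share from the scene topic and the rest from the whole vocabulary, with
    recognition probabilities drawn Uniform(0.85, 1.0).

    The block design alternates -1 (music) / +1 (speech) every
    ``block_seconds`` starting with music; the audio envelope is a rectified
    smoothed Gaussian process whose mean is higher during speech blocks.
    Scene topics are mildly coupled to the block type (a freshly sampled
    topic comes from the block-preferred half of the topics with probability
    ``block_topic_bias``), emulating that speech and music scenes of a film
    also differ visually — this is what makes confound control non-trivial.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if not (0.0 <= scene_persistence < 1.0):
        raise ValueError("scene_persistence must be in [0, 1)")
    n_labels = len(lexicon.labels)
    if labels_per_frame > n_labels:
        raise ValueError("labels_per_frame exceeds lexicon size")
    if lexicon.topic_of is None:
        raise ValueError("lexicon must carry topic assignments")

    if not (0.0 <= block_topic_bias <= 1.0):
        raise ValueError("block_topic_bias must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_frames = round(n_blocks * block_seconds * frame_rate)
    frames_per_block = int(round(block_seconds * frame_rate))
    n_topics = int(lexicon.topic_of.max()) + 1
    topic_pools = [np.flatnonzero(lexicon.topic_of == t) for t in range(n_topics)]

    block_idx = np.minimum(np.arange(n_frames) // frames_per_block, n_blocks - 1)
    is_speech = block_idx % 2 == 1  # music first
    half = max(1, n_topics // 2)
    preferred = [np.arange(half), np.arange(half, n_topics) if half < n_topics else np.arange(n_topics)]

    # sticky scene-topic chain with block-preferred resampling
    scene = np.empty(n_frames, dtype=int)
    scene[0] = rng.integers(n_topics)
    stay = rng.random(n_frames - 1) < scene_persistence
    for f in range(1, n_frames):
        if stay[f - 1]:
            scene[f] = scene[f - 1]
        elif rng.random() < block_topic_bias:
            scene[f] = rng.choice(preferred[int(is_speech[f])])
        else:
            scene[f] = rng.integers(n_topics)

    all_idx = np.arange(n_labels)
    labels_per_frame_list: list[list[tuple[str, float]]] = []
    for f in range(n_frames):
        pool = topic_pools[scene[f]]
        k_topic = min(int(np.ceil(topic_label_fraction * labels_per_frame)), pool.size)
        chosen = rng.choice(pool, size=k_topic, replace=False)
        remaining = np.setdiff1d(all_idx, chosen, assume_unique=False)
        k_rest = labels_per_frame - k_topic
        if k_rest > 0:
            chosen = np.concatenate([chosen, rng.choice(remaining, size=k_rest, replace=False)])
        probs = rng.uniform(0.85, 1.0, size=chosen.size)
        labels_per_frame_list.append(
            [(lexicon.labels[i], float(p)) for i, p in zip(chosen, probs)]
        )

    table = FrameLabelTable(
        n_frames=n_frames, frame_rate=frame_rate, labels_per_frame=labels_per_frame_list
    )

    block_design = np.where(is_speech, 1.0, -1.0)
    block_mean = np.where(block_design > 0, 1.0, 0.6)
    envelope = block_mean + gaussian_filter1d(
        rng.standard_normal(n_frames), sigma=0.2 * frame_rate
    )
    envelope = np.clip(envelope, 0.0, None)
    confounds = StimulusConfounds(block_design=block_design, audio_envelope=envelope)
    return table, confounds


def _label_pattern(label_index: int, height: int, width: int, seed: int) -> np.ndarray:
    """Deterministic smooth RGB texture keyed to one label."""
    rng = np.random.default_rng((seed, label_index))
    coarse = rng.random((6, 5, 3))
    zy = height / coarse.shape[0]
    zx = width / coarse.shape[1]
    img = np.repeat(np.repeat(coarse, int(np.ceil(zy)), axis=0), int(np.ceil(zx)), axis=1)
    img = img[:height, :width]
    return gaussian_filter(img, sigma=(height / 16, width / 16, 0))


def render_frames(
    table: FrameLabelTable,
    lexicon: EmbeddingLexicon,
    height: int = 64,
    width: int = 48,
    seed: int = 0,
) -> np.ndarray:
    """Render procedural RGB frames (n_frames, H, W, 3) in [0, 1].

    Each label maps deterministically to a smooth texture; a frame is the
    unweighted mean of its labels' textures, so frames that share labels are
    more pixel-correlated than frames that share none.  This stands in for
    real film imagery only as far as the low-level control features need.
    """
    if height < 16 or width < 16:
        raise ValueError("height and width must be >= 16")
    index = {lab: i for i, lab in enumerate(lexicon.labels)}
    cache: dict[int, np.ndarray] = {}
    out = np.zeros((table.n_frames, height, width, 3))
    for f, entries in enumerate(table.labels_per_frame):
        if not entries:
            continue
        acc = np.zeros((height, width, 3))
        for lab, _p in entries:
            i = index[lab]
            if i not in cache:
                cache[i] = _label_pattern(i, height, width, seed)
            acc += cache[i]
        out[f] = acc / len(entries)
    return np.clip(out, 0.0, 1.0)


def generate_geometry(
    n_subjects: int = 10,
    electrodes_per_subject: int = 6,
    seed: int = 0,
    patch_radius: float = 0.25,
) -> ElectrodeGeometry:
    """Per-subject contiguous grid-like electrode patches on the unit sphere.

    Emulates subdural grids: each subject gets a square grid of electrodes in
    the tangent plane of a random sphere point, projected back to the sphere.
    Anatomical labels are the nearest of eight fixed octant anchors.
    """
    rng = np.random.default_rng(seed)
    anchors = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
    )
    anchors /= np.linalg.norm(anchors, axis=1, keepdims=True)
    anchor_names = [f"region{j}" for j in range(len(anchors))]

    side = int(np.ceil(np.sqrt(electrodes_per_subject)))
    offsets = np.linspace(-patch_radius, patch_radius, side)
    xyz_list, subj_list, anat = [], [], []
    for s in range(n_subjects):
        center = rng.standard_normal(3)
        center /= np.linalg.norm(center)
        # orthonormal tangent basis at the patch center
        helper = np.array([1.0, 0.0, 0.0])
        if abs(center @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(center, helper)
        u /= np.linalg.norm(u)
        v = np.cross(center, u)
        count = 0
        for oy in offsets:
            for ox in offsets:
                if count >= electrodes_per_subject:
                    break
                p = center + ox * u + oy * v
                p /= np.linalg.norm(p)
                xyz_list.append(p)
                subj_list.append(s)
                anat.append(anchor_names[int(np.argmax(anchors @ p))])
                count += 1
    return ElectrodeGeometry(
        subject_of=np.array(subj_list), sphere_xyz=np.array(xyz_list), anat_label=anat
    )


def shift_series(x: np.ndarray, lag_frames: int) -> np.ndarray:
    """Shift a (frames,) or (frames, K) series forward in time by ``lag_frames``.

    Positive lag delays the series (sample t of the output is sample
    t - lag of the input); edges are held at the first/last value.  This is
    the single shift convention shared by the generator and the encoding
    model, so planted and recovered lags are directly comparable.
    """
    n = x.shape[0]
    idx = np.clip(np.arange(n) - lag_frames, 0, n - 1)
    return x[idx]


def make_prototypes(
    n_prototypes: int, n_components: int, seed: int, tail_scale: float = 0.05
) -> np.ndarray:
    """Orthogonalized planted weight patterns concentrated on the top 5 components."""
    if n_prototypes > 5:
        raise ValueError("at most 5 orthogonal prototypes fit in the top-5 subspace")
    rng = np.random.default_rng(seed)
    head = np.linalg.qr(rng.standard_normal((5, n_prototypes)))[0].T  # (n_proto, 5)
    protos = np.zeros((n_prototypes, n_components))
    protos[:, :5] = head
    if n_components > 5:
        protos[:, 5:] = tail_scale * rng.standard_normal((n_prototypes, n_components - 5))
    return protos / np.linalg.norm(protos, axis=1, keepdims=True)


def generate_neural(
    components: SemanticComponents,
    confounds: StimulusConfounds,
    geometry: ElectrodeGeometry,
    lag_true: float = 0.32,
    snr: float = 1.0,
    frac_null: float = 0.0,
    ar1: float = 0.3,
    seed: int = 0,
    frame_rate: float = 25.0,
    n_prototypes: int = 5,
    confound_strength: float = 1.0,
) -> tuple[NeuralRecording, GroundTruth]:
    """Generate HFB responses from planted component weights at a planted lag.

    The generative model mirrors the encoding model's assumption::

        hfb(e, t) = sum_k beta(e, k) * comp(k, t - lag)
                    + g_blk(e) * block(t) + g_env(e) * envelope(t)
                    + AR(1) noise

    Non-null electrodes draw their weight row from a small set of
    orthogonalized cluster prototypes (times a positive gain plus jitter); a
    ``frac_null`` fraction of electrodes has an all-zero weight row.  Noise is
    per-electrode AR(1) Gaussian scaled so the semantic-signal/noise variance
    ratio equals ``snr``; null electrodes get noise at the mean signal scale.

    Prototypes are expressed in the standardized component parameterization
    (weight per unit score SD) and converted to raw-unit weights by dividing
    by each component's score SD: every component contributes to the neural
    signal in proportion to its prototype entry, not to its share of stimulus
    variance.  ``beta_true`` is returned in raw units, so
    ``beta_true * score_sd`` recovers the planted standardized profiles.
    """
    if not (-1.0 < ar1 < 1.0):
        raise ValueError("|ar1| must be < 1")
    if snr <= 0:
        raise ValueError("snr must be positive")
    n_frames, K = components.scores.shape
    lag_frames_f = lag_true * frame_rate
    lag_frames = int(round(lag_frames_f))
    if abs(lag_frames_f - lag_frames) > 1e-9:
        raise ValueError("lag_true must be an integer number of frames")
    if abs(lag_frames) >= n_frames:
        raise ValueError("lag_true outside stimulus duration")
    if confounds.n_frames != n_frames:
        raise ValueError("confounds length != number of frames")

    rng = np.random.default_rng(seed)
    n_el = geometry.n_electrodes
    protos = make_prototypes(n_prototypes, K, seed=rng.integers(2**31))

    null_mask = rng.random(n_el) < frac_null
    assignment = rng.integers(n_prototypes, size=n_el)
    assignment[null_mask] = -1
    gains = rng.uniform(0.8, 1.2, size=n_el)
    beta_std = np.zeros((n_el, K))
    active = ~null_mask
    beta_std[active] = gains[active, None] * protos[assignment[active]]
    beta_std[active] += 0.02 * rng.standard_normal((active.sum(), K))
    score_sd = components.scores.std(axis=0)
    score_sd = np.where(score_sd > 0, score_sd, 1.0)
    beta = beta_std / score_sd[None, :]

    shifted = shift_series(components.scores, lag_frames)  # (frames, K)
    signal = beta @ shifted.T  # (electrodes, frames)
    sig_var = signal.var(axis=1)
    ref_var = sig_var[active].mean() if active.any() else 1.0
    noise_var = np.where(active, sig_var, ref_var) / snr

    g_blk = np.zeros(n_el)
    g_env = np.zeros(n_el)
    if confound_strength > 0:
        scale = confound_strength * np.sqrt(np.where(active, sig_var, ref_var))
        g_blk = scale * rng.uniform(0.5, 1.5, size=n_el) * rng.choice([-1, 1], size=n_el)
        g_env = scale * rng.uniform(0.5, 1.5, size=n_el) * rng.choice([-1, 1], size=n_el)
    block = confounds.block_design - confounds.block_design.mean()
    env = confounds.audio_envelope - confounds.audio_envelope.mean()
    confound_part = np.outer(g_blk, block) + np.outer(g_env, env)

    innov_sd = np.sqrt(noise_var * (1.0 - ar1**2))
    innov = rng.standard_normal((n_el, n_frames)) * innov_sd[:, None]
    noise = np.empty_like(innov)
    noise[:, 0] = innov[:, 0] / np.sqrt(1.0 - ar1**2)
    for t in range(1, n_frames):
        noise[:, t] = ar1 * noise[:, t - 1] + innov[:, t]

    hfb = signal + confound_part + noise
    rec = NeuralRecording(hfb=hfb, frame_rate=frame_rate, geometry=geometry)
    truth = GroundTruth(
        beta_true=beta,
        lag_true=lag_true,
        block_gain=g_blk,
        envelope_gain=g_env,
        null_electrodes=null_mask,
        cluster_assignment_true=assignment,
    )
    return rec, truth
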