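"""Shared container types for the semantic-encoding pipeline.

All containers are plain frozen-ish dataclasses over numpy arrays; heavy
computation lives in the stage modules.  Validation that is cheap (shape and
range checks) happens in ``__post_init__``; anything requiring real work is
done by the constructing function.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# stimulus side
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingLexicon:
    """Word-embedding lexicon: one D-dimensional vector per concept label.

    ``topic_of`` is ground truth planted by the generator (topic index per
    label); it is ``None`` for lexicons read from disk.
    """

    labels: list[str]
    vectors: np.ndarray  # (n_labels, dim)
    topic_of: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.labels):
            raise ValueError("need one vector per label")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate label IDs in lexicon")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, label: str) -> np.ndarray:
        try:
            return self.vectors[self._index[label]]
        except KeyError:
            raise KeyError(f"label not in lexicon: {label!r}") from None


@dataclass
class FrameLabelTable:
    """Per-frame concept labels with recognition probabilities.

    ``labels_per_frame[f]`` is a list of ``(label, probability)`` pairs; a
    frame may end up with zero labels after filtering.
    """

    n_frames: int
    frame_rate: float
    labels_per_frame: list[list[tuple[str, float]]]

    def __post_init__(self) -> None:
        if len(self.labels_per_frame) != self.n_frames:
            raise ValueError("labels_per_frame length != n_frames")
        for f, entries in enumerate(self.labels_per_frame):
            for lab, p in entries:
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"probability out of [0,1] at frame {f}")


@dataclass
class StimulusConfounds:
    """Block-design indicator (+1 speech / -1 music) and audio envelope."""

    block_design: np.ndarray  # (n_frames,)
    audio_envelope: np.ndarray  # (n_frames,) non-negative

    def __post_init__(self) -> None:
        self.block_design = np.asarray(self.block_design, dtype=float)
        self.audio_envelope = np.asarray(self.audio_envelope, dtype=float)
        if self.block_design.shape != self.audio_envelope.shape:
            raise ValueError("confound series length mismatch")
        if np.any(self.audio_envelope < 0):
            raise ValueError("audio envelope must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.block_design.size


@dataclass
class ElectrodeGeometry:
    """Electrode metadata: owning subject, unit-sphere location, anatomy."""

    subject_of: np.ndarray  # (n_electrodes,) int subject index
    sphere_xyz: np.ndarray  # (n_electrodes, 3) unit vectors
    anat_label: list[str]

    def __post_init__(self) -> None:
        self.subject_of = np.asarray(self.subject_of)
        self.sphere_xyz = np.asarray(self.sphere_xyz, dtype=float)
        norms = np.linalg.norm(self.sphere_xyz, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("electrode coordinates must lie on the unit sphere")
        if len(self.anat_label) != self.subject_of.size:
            raise ValueError("anat_label length mismatch")

    @property
    def n_electrodes(self) -> int:
        return self.subject_of.size

    @property
    def n_subjects(self) -> int:
        return int(np.unique(self.subject_of).size)


@dataclass
class GroundTruth:
    """Planted parameters behind a synthetic recording (for recovery tests)."""

    beta_true: np.ndarray  # (n_electrodes, K)
    lag_true: float  # seconds
    block_gain: np.ndarray  # (n_electrodes,)
    envelope_gain: np.ndarray  # (n_electrodes,)
    null_electrodes: np.ndarray  # bool mask
    cluster_assignment_true: np.ndarray  # (n_electrodes,) int, -1 for null


# ---------------------------------------------------------------------------
# semantic features
# ---------------------------------------------------------------------------

@dataclass
class FrameEmbeddingMatrix:
    """Frame-averaged embedding vectors (frames x D) with per-frame label counts."""

    values: np.ndarray
    n_labels_used: np.ndarray  # (n_frames,) int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_labels_used = np.asarray(self.n_labels_used, dtype=int)
        if self.values.shape[0] != self.n_labels_used.size:
            raise ValueError("shape mismatch")

    @property
    def empty_frames(self) -> np.ndarray:
        """Boolean mask of frames that had no labels after filtering."""
        return self.n_labels_used == 0


@dataclass
class SemanticComponents:
    """PCA of frame-averaged embeddings: scores, loadings, variance ratios."""

    scores: np.ndarray  # (n_frames, K)
    loadings: np.ndarray  # (D, K), orthonormal columns
    mean: np.ndarray  # (D,)
    explained_variance_ratio: np.ndarray  # (K,)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    @property
    def n_frames(self) -> int:
        return self.scores.shape[0]


@dataclass
class BinaryLabelMatrix:
    """Frames x labels 0/1 indicator of label presence, fixed column order."""

    values: np.ndarray
    label_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary label matrix entries must be 0/1")
        if self.values.shape[1] != len(self.label_ids):
            raise ValueError("label_ids length mismatch")


# ---------------------------------------------------------------------------
# neural side
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """Raw multichannel voltage traces (channels x samples, microvolts)."""

    signal: np.ndarray
    fs: float
    bad_channels: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")


@dataclass
class NeuralRecording:
    """HFB amplitude (electrodes x frames) at the stimulus frame rate."""

    hfb: np.ndarray
    frame_rate: float
    geometry: ElectrodeGeometry | None = None

    def __post_init__(self) -> None:
        self.hfb = np.asarray(self.hfb, dtype=float)
        if self.hfb.ndim != 2:
            raise ValueError("hfb must be electrodes x frames")

    @property
    def n_electrodes(self) -> int:
        return self.hfb.shape[0]

    @property
    def n_frames(self) -> int:
        return self.hfb.shape[1]


# ---------------------------------------------------------------------------
# encoding model
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Block-stratified cross-validation plan over frames.

    ``outer_folds[i]`` is the array of test-frame indices of outer fold i;
    ``inner_folds[i][j]`` the validation frames of inner fold j within outer
    fold i's training set.  Test sets are concatenations of short fragments
    drawn from every stimulus block, so each fold spans both block types.
    """

    outer_folds: list[np.ndarray]
    inner_folds: list[list[np.ndarray]]
    block_of: np.ndarray  # (n_frames,) block index per frame

    @property
    def n_frames(self) -> int:
        return self.block_of.size


@dataclass
class EncodingFit:
    """Cross-validated ridge encoding fit for one feature set / time shift.

    ``betas`` are in standardized-feature units (response change per feature
    SD), the scale on which the ridge is solved and on which weight profiles
    are compared across electrodes; ``betas_raw`` are rescaled to original
    feature units (per-fold, then averaged), so in the unregularized
    noiseless limit they equal the generating weights.
    """

    betas: np.ndarray  # (n_electrodes, K), standardized units, fold-averaged
    betas_raw: np.ndarray  # (n_electrodes, K), original feature units
    lambda_per_electrode: np.ndarray  # (n_electrodes,) modal selected lambda
    r_cv: np.ndarray  # (n_electrodes,) mean held-out Pearson r
    p_value: np.ndarray  # (n_electrodes,) Bonferroni-corrected
    significant: np.ndarray  # bool
    time_shift: float  # seconds
    n_eff: int  # held-out samples per fold used for the t transform


@dataclass
class ShiftSweep:
    """Summary curves of a time-shift sweep of the encoding model."""

    shifts: np.ndarray  # seconds
    mean_r_significant: np.ndarray
    n_significant: np.ndarray
    best_shift: float
    fits: list[EncodingFit] | None = None


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Named frames x features matrix, optionally with a 50-PC reduction."""

    name: str
    values: np.ndarray
    reduced: np.ndarray | None = None


@dataclass
class RsaResult:
    """Layer-wise representational similarity to the semantic components."""

    per_layer_similarity: np.ndarray
    bootstrap_ci: np.ndarray  # (n_layers, 2) percentile CI
    n_boot: int
    n_frames_sampled: int


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterProfile:
    """One functional network: members, exemplar, activation, statistics."""

    members: np.ndarray  # electrode indices
    exemplar: int
    activation: np.ndarray  # (n_frames,)
    sem_band: np.ndarray  # (n_frames,) SEM over member dot products
    subject_counts: dict[int, int]
    anat_counts: dict[str, int]
    component_stats: list[dict] | None = None


@dataclass
class PeakDipSelection:
    """Peak/dip frames of a cluster activation against a shuffled-null band."""

    peak_frames: np.ndarray
    dip_frames: np.ndarray
    upper_threshold: float
    lower_threshold: float
    n_shuffles: int


# ---------------------------------------------------------------------------
# surface projection
# ---------------------------------------------------------------------------

@dataclass
class SphereGrid:
    """Regular grid of unit vectors on a sphere of physical radius (mm)."""

    points: np.ndarray  # (G, 3) unit vectors
    radius: float = 100.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.size == 0:
            raise ValueError("empty grid")
        norms = np.linalg.norm(self.points, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("grid points must be unit vectors")


@dataclass
class GpConfig:
    """Gaussian-process smoother parameters: length scale and noise."""

    sigma: float = 8.0  # mm, kernel length scale
    eta: float = 1e-3  # noise ridge added to the electrode kernel

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
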