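"""Functional networks from encoding weights via affinity propagation.

Electrodes whose HFB responses are well predicted are grouped by the
similarity (Pearson correlation) of their ridge weight profiles across the
semantic components.  Affinity propagation is used because it needs no
preset cluster count and returns an exemplar electrode per cluster; the
shared preference is set to ``min(A) - 2`` of the affinity matrix.  Clusters
driven by single subjects are filtered out, each cluster gets an activation
time course (components dotted with the exemplar's weights), and the
contribution of individual components is assessed by comparing component
values at activation peaks versus dips against a cluster-label-shuffling
null.
"""
from __future__ import annotations

import numpy as np
from sklearn.cluster import AffinityPropagation

from .datatypes import (
    ClusterProfile,
    ElectrodeGeometry,
    PeakDipSelection,
    SemanticComponents,
)
from .wstats import signed_rank_z

__all__ = [
    "zscore_columns",
    "beta_affinity",
    "cluster_betas",
    "filter_clusters",
    "activation_time_course",
    "pick_exemplar",
    "peak_dip_null",
    "component_contribution",
    "build_cluster_profiles",
]


class ClusteringNotConverged(RuntimeError):
    """Affinity propagation failed to converge; carries the partial labels."""

    def __init__(self, message: str, partial_labels: np.ndarray):
        super().__init__(message)
        self.partial_labels = partial_labels


def zscore_columns(X: np.ndarray) -> np.ndarray:
    """Z-score each column (component) over electrodes; constant columns -> 0."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    # relative tolerance: rounding residue of a constant column is not variance
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    Z = (X - mean) / np.where(constant, 1.0, sd)
    Z[:, constant] = 0.0
    return Z


def beta_affinity(Z: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of weight rows, defined for constant rows.

    A zero-variance row correlates 1 with an identical row and 0 with
    anything else, so fully degenerate inputs still cluster.
    """
    Z = np.asarray(Z, dtype=float)
    sd = Z.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.corrcoef(Z)
    bad = np.flatnonzero(sd == 0)
    for i in bad:
        A[i] = [1.0 if np.allclose(Z[i], Z[j]) else 0.0 for j in range(Z.shape[0])]
        A[:, i] = A[i]
    return A


def cluster_betas(
    betas: np.ndarray,
    seed: int = 0,
    damping: float = 0.9,
    max_iter: int = 1000,
    preference_offset: float = -2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Affinity-propagation clustering of z-scored weight profiles.

    Weights are first z-scored over electrodes per component, the affinity is
    row-wise Pearson correlation, and every point's preference is
    ``min(A) + preference_offset`` (default ``min(A) - 2``).  Returns
    ``(assignment, exemplars, affinity)``.
    """
    Z = zscore_columns(betas)
    A = beta_affinity(Z)
    pref = float(A.min()) + preference_offset
    ap = AffinityPropagation(
        damping=damping,
        max_iter=max_iter,
        affinity="precomputed",
        preference=pref,
        random_state=seed,
    )
    labels = ap.fit_predict(A)
    if np.any(labels == -1):
        raise ClusteringNotConverged(
            f"affinity propagation did not converge in {max_iter} iterations",
            partial_labels=labels,
        )
    return labels, ap.cluster_centers_indices_, A


def filter_clusters(
    assignment: np.ndarray,
    geometry: ElectrodeGeometry,
    min_subject_fraction: float = 1.0 / 3.0,
    max_single_subject_fraction: float = 1.0 / 3.0,
    n_subjects: int | None = None,
) -> tuple[list[int], list[tuple[int, str]]]:
    """Retain clusters that are not subject-specific.

    A cluster survives iff it contains electrodes from at least
    ``ceil(min_subject_fraction * n_subjects)`` distinct subjects AND no
    single subject contributes more than ``max_single_subject_fraction`` of
    its electrodes (a share of exactly the threshold is retained).  Returns
    ``(retained_cluster_ids, discarded_with_reasons)``.
    """
    if n_subjects is None:
        n_subjects = geometry.n_subjects
    need = int(np.ceil(min_subject_fraction * n_subjects))
    retained: list[int] = []
    discarded: list[tuple[int, str]] = []
    for c in np.unique(assignment):
        members = np.flatnonzero(assignment == c)
        subs, counts = np.unique(geometry.subject_of[members], return_counts=True)
        share = counts.max() / members.size
        if subs.size < need:
            discarded.append((int(c), f"only {subs.size}/{need} subjects"))
        elif share > max_single_subject_fraction + 1e-12:
            discarded.append((int(c), f"single subject holds {share:.0%} of electrodes"))
        else:
            retained.append(int(c))
    return retained, discarded


def pick_exemplar(affinity: np.ndarray, members: np.ndarray) -> int:
    """Member maximizing its summed affinity to the other members."""
    sub = affinity[np.ix_(members, members)]
    return int(members[np.argmax(sub.sum(axis=1))])


def activation_time_course(
    components: SemanticComponents,
    exemplar_betas: np.ndarray,
    member_betas: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exemplar activation and the SEM band over member-wise activations.

    ``activation(t) = sum_k scores(t, k) * beta_exemplar(k)``; the band is the
    standard error over members of the per-member dot products (zero for a
    single-member cluster).
    """
    exemplar_betas = np.asarray(exemplar_betas, dtype=float)
    member_betas = np.atleast_2d(np.asarray(member_betas, dtype=float))
    if exemplar_betas.size != components.n_components:
        raise ValueError("beta length != number of components")
    activation = components.scores @ exemplar_betas
    dots = components.scores @ member_betas.T  # (frames, members)
    m = member_betas.shape[0]
    if m < 2:
        sem = np.zeros(components.n_frames)
    else:
        sem = dots.std(axis=1, ddof=1) / np.sqrt(m)
    return activation, sem


def peak_dip_null(
    activation: np.ndarray,
    assignment: np.ndarray,
    all_betas: np.ndarray,
    components: SemanticComponents,
    cluster_id: int,
    n_shuffles: int = 10000,
    fraction: float = 0.10,
    seed: int = 0,
    activation_betas: np.ndarray | None = None,
) -> PeakDipSelection:
    """Peak/dip frames of one cluster's activation against a shuffled null.

    For each shuffle the cluster labels are permuted over electrodes, the
    exemplar of the permuted cluster is recomputed (max summed within-cluster
    affinity of z-scored weights) and its activation time course forms the
    baseline.  Thresholds are the 2.5th/97.5th percentiles of the pooled
    baseline values; candidate peaks(dips) lie above(below) them, and the
    final sets are the top/bottom ``fraction`` of candidates by activation.

    ``activation_betas`` is the weight matrix used to build activation time
    courses (defaults to the z-scored ``all_betas``); pass the raw-unit
    weights to keep activations on the scale of predicted responses while
    exemplars are still found on z-scored profiles.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    rng = np.random.default_rng(seed)
    activation = np.asarray(activation, dtype=float)
    Z = zscore_columns(all_betas)
    A = beta_affinity(Z)
    W = Z if activation_betas is None else np.asarray(activation_betas, dtype=float)
    n_el = Z.shape[0]
    exemplar_betas = np.empty((n_shuffles, Z.shape[1]))
    for s in range(n_shuffles):
        perm = rng.permutation(n_el)
        members = np.flatnonzero(assignment[perm] == cluster_id)
        exemplar_betas[s] = W[pick_exemplar(A, members)]
    baseline = (components.scores @ exemplar_betas.T).astype(np.float32)
    lower, upper = np.percentile(baseline.ravel(), [2.5, 97.5])
    cand_peaks = np.flatnonzero(activation > upper)
    cand_dips = np.flatnonzero(activation < lower)
    n_p = int(np.ceil(fraction * cand_peaks.size))
    n_d = int(np.ceil(fraction * cand_dips.size))
    peaks = cand_peaks[np.argsort(-activation[cand_peaks], kind="stable")[:n_p]]
    dips = cand_dips[np.argsort(activation[cand_dips], kind="stable")[:n_d]]
    return PeakDipSelection(
        peak_frames=peaks,
        dip_frames=dips,
        upper_threshold=float(upper),
        lower_threshold=float(lower),
        n_shuffles=n_shuffles,
    )


def component_contribution(
    selection: PeakDipSelection,
    components: SemanticComponents,
    activation: np.ndarray,
    k_top: int = 5,
    alpha: float = 0.001,
    n_clusters: int = 1,
) -> list[dict]:
    """Per-component peak-versus-dip contrast for one cluster.

    Peaks and dips are paired by descending activation extremity and trimmed
    to equal length; per component a two-sided Wilcoxon signed-rank test
    compares the component values at peak versus dip frames.  p values are
    Bonferroni-corrected by ``n_clusters * k_top``.  The signed z statistic is
    also reported divided by the component's percentage of explained variance
    (the magnitude of scores shrinks with explained variance, which would
    otherwise understate late components).  Because the rank statistic
    saturates once every pair moves the same way, a graded
    ``effect_size`` — median peak-dip difference in units of the component's
    score SD — is reported as well; it is the quantity to rank components by.
    """
    act = np.asarray(activation, dtype=float)
    peaks = selection.peak_frames[np.argsort(-act[selection.peak_frames], kind="stable")]
    dips = selection.dip_frames[np.argsort(act[selection.dip_frames], kind="stable")]
    m = min(peaks.size, dips.size)
    peaks, dips = peaks[:m], dips[:m]
    out: list[dict] = []
    n_tests = n_clusters * k_top
    for k in range(k_top):
        if m == 0:
            out.append(dict(component=k, statistic=0.0, p=1.0, significant=False,
                            variance_adjusted_statistic=0.0, effect_size=0.0))
            continue
        x = components.scores[peaks, k]
        y = components.scores[dips, k]
        z, p, _ = signed_rank_z(x - y)
        p_corr = min(1.0, p * n_tests)
        evr_pct = 100.0 * components.explained_variance_ratio[k]
        score_sd = components.scores[:, k].std()
        out.append(
            dict(
                component=k,
                statistic=z,
                p=p_corr,
                significant=p_corr < alpha,
                variance_adjusted_statistic=z / evr_pct if evr_pct > 0 else np.inf,
                effect_size=float(np.median(x) - np.median(y)) / score_sd
                if score_sd > 0 else 0.0,
            )
        )
    return out


def build_cluster_profiles(
    betas: np.ndarray,
    components: SemanticComponents,
    geometry: ElectrodeGeometry,
    seed: int = 0,
    n_shuffles: int = 1000,
    k_top: int = 5,
    alpha: float = 0.001,
    apply_filters: bool = True,
    activation_betas: np.ndarray | None = None,
) -> list[ClusterProfile]:
    """End-to-end: cluster weights, filter, and profile each retained network.

    Clustering and exemplar choice run on z-scored ``betas``; activation time
    courses use ``activation_betas`` (typically the raw-unit encoding weights,
    so activations live on the scale of predicted responses) and fall back to
    the z-scored profiles when not given.
    """
    assignment, _exemplars, affinity = cluster_betas(betas, seed=seed)
    if apply_filters:
        retained, _ = filter_clusters(assignment, geometry)
    else:
        retained = [int(c) for c in np.unique(assignment)]
    Z = zscore_columns(betas)
    W = Z if activation_betas is None else np.asarray(activation_betas, dtype=float)
    profiles: list[ClusterProfile] = []
    for c in retained:
        members = np.flatnonzero(assignment == c)
        exemplar = pick_exemplar(affinity, members)
        activation, sem = activation_time_course(components, W[exemplar], W[members])
        selection = peak_dip_null(
            activation, assignment, betas, components, cluster_id=c,
            n_shuffles=n_shuffles, seed=seed, activation_betas=activation_betas,
        )
        comp_stats = component_contribution(
            selection, components, activation, k_top=k_top, alpha=alpha,
            n_clusters=len(retained),
        )
        subs, scounts = np.unique(geometry.subject_of[members], return_counts=True)
        anats, acounts = np.unique([geometry.anat_label[i] for i in members], return_counts=True)
        profiles.append(
            ClusterProfile(
                members=members,
                exemplar=exemplar,
                activation=activation,
                sem_band=sem,
                subject_counts={int(s): int(n) for s, n in zip(subs, scounts)},
                anat_counts={str(a): int(n) for a, n in zip(anats, acounts)},
                component_stats=comp_stats,
            )
        )
    return profiles
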