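"""Affinity-propagation networks, filters, activations and peak/dip statistics."""
import numpy as np
import pytest

from semenc import clusters
from semenc.datatypes import SemanticComponents


def _comps(scores, evr=None):
    K = scores.shape[1]
    if evr is None:
        evr = np.full(K, 1.0 / K)
    return SemanticComponents(
        scores=scores, loadings=np.eye(K), mean=np.zeros(K),
        explained_variance_ratio=np.asarray(evr, dtype=float),
    )


def _planted_betas(rng, n_per=20, n_proto=3, K=8, noise=0.02):
    protos = np.linalg.qr(rng.standard_normal((K, n_proto)))[0].T
    B = np.repeat(protos, n_per, axis=0) + noise * rng.standard_normal((n_per * n_proto, K))
    truth = np.repeat(np.arange(n_proto), n_per)
    return B, truth


class TestClusterBetas:
    def test_planted_prototypes_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        B, truth = _planted_betas(rng)
        Z = clusters.zscore_columns(B)
        A = clusters.beta_affinity(Z)
        within = [A[i, j] for i in range(60) for j in range(i + 1, 60) if truth[i] == truth[j]]
        between = [A[i, j] for i in range(60) for j in range(i + 1, 60) if truth[i] != truth[j]]
        assert np.mean(within) > 0.9 and abs(np.mean(between)) < 0.6
        labels, exemplars, _ = clusters.cluster_betas(B, seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_zscoring_applied_first(self, rng):
        B, _ = _planted_betas(rng)
        Z = clusters.zscore_columns(B)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_identical_rows_single_cluster(self):
        B = np.tile(np.array([1.0, -2.0, 0.5]), (10, 1))
        labels, exemplars, _ = clusters.cluster_betas(B, seed=0)
        assert len(set(labels)) == 1

    def test_exemplar_matches_bruteforce_oracle(self, rng):
        B, _ = _planted_betas(rng, n_per=15)
        labels, exemplars, A = clusters.cluster_betas(B, seed=0)
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            best, best_val = None, -np.inf
            for i in members:
                val = sum(A[i, j] for j in members)
                if val > best_val:
                    best, best_val = i, val
            assert clusters.pick_exemplar(A, members) == best

    def test_cluster_count_nondecreasing_in_preference(self, rng):
        """Higher (less negative) preference yields at least as many clusters."""
        from sklearn.cluster import AffinityPropagation

        B, _ = _planted_betas(rng, noise=0.3)
        A = clusters.beta_affinity(clusters.zscore_columns(B))
        counts = []
        for off in (-20.0, -2.0, 3.0):
            ap = AffinityPropagation(
                damping=0.9, max_iter=1000, affinity="precomputed",
                preference=A.min() + off, random_state=0,
            ).fit(A)
            counts.append(len(set(ap.labels_)))
        assert counts[0] <= counts[1] <= counts[2]


class TestFilterClusters:
    def _geometry(self, subjects):
        n = len(subjects)
        xyz = np.zeros((n, 3))
        xyz[:, 2] = 1.0
        from semenc.datatypes import ElectrodeGeometry

        return ElectrodeGeometry(
            subject_of=np.array(subjects), sphere_xyz=xyz, anat_label=["x"] * n
        )

    def test_single_subject_dominated_discarded(self):
        # 65% of electrodes from one subject, 7 distinct subjects
        subjects = [0] * 13 + [1, 2, 3, 4, 5, 6, 0]  # 20 electrodes, 14 from subject 0
        geom = self._geometry(subjects)
        retained, discarded = clusters.filter_clusters(
            np.zeros(20, dtype=int), geom, n_subjects=21
        )
        assert retained == []
        assert "single subject" in discarded[0][1]

    def test_evenly_spread_retained(self):
        subjects = list(range(10)) * 2
        geom = self._geometry(subjects)
        retained, _ = clusters.filter_clusters(np.zeros(20, dtype=int), geom)
        assert retained == [0]

    def test_exact_one_third_share_retained(self):
        # subject 0 holds exactly 1/3 of 9 electrodes; 5 subjects of 12 total
        subjects = [0, 0, 0, 1, 1, 2, 2, 3, 4]
        geom = self._geometry(subjects)
        retained, _ = clusters.filter_clusters(
            np.zeros(9, dtype=int), geom, n_subjects=12
        )
        assert retained == [0]

    def test_too_few_subjects_discarded(self):
        subjects = [0, 0, 1, 1, 2, 2]
        geom = self._geometry(subjects)
        retained, discarded = clusters.filter_clusters(
            np.zeros(6, dtype=int), geom, n_subjects=37
        )
        assert retained == [] and "subjects" in discarded[0][1]


class TestActivation:
    def test_unit_vector_projects_component(self, rng):
        scores = rng.standard_normal((50, 4))
        comps = _comps(scores)
        beta = np.array([0.0, 1.0, 0.0, 0.0])
        act, sem = clusters.activation_time_course(comps, beta, beta[None, :])
        np.testing.assert_allclose(act, scores[:, 1], atol=1e-12)
        np.testing.assert_array_equal(sem, 0.0)  # single member

    def test_matches_loop_oracle(self, rng):
        scores = rng.standard_normal((30, 5))
        comps = _comps(scores)
        members = rng.standard_normal((4, 5))
        act, sem = clusters.activation_time_course(comps, members[2], members)
        for t in range(30):
            assert act[t] == pytest.approx(float(scores[t] @ members[2]))
            dots = [float(scores[t] @ members[m]) for m in range(4)]
            assert sem[t] == pytest.approx(np.std(dots, ddof=1) / 2.0)


class TestPeakDipNull:
    def test_thresholds_match_sort_oracle(self, rng):
        scores = rng.standard_normal((40, 3))
        comps = _comps(scores)
        B, truth = _planted_betas(rng, n_per=8, K=3)
        act, _ = clusters.activation_time_course(
            comps, clusters.zscore_columns(B)[0], clusters.zscore_columns(B)[:8]
        )
        sel = clusters.peak_dip_null(act, truth, B, comps, cluster_id=0,
                                     n_shuffles=100, seed=0)
        # recompute the pooled baseline with an explicit loop + sort oracle
        rng2 = np.random.default_rng(0)
        Z = clusters.zscore_columns(B)
        A = clusters.beta_affinity(Z)
        pooled = []
        for _ in range(100):
            perm = rng2.permutation(B.shape[0])
            members = np.flatnonzero(truth[perm] == 0)
            ex = clusters.pick_exemplar(A, members)
            pooled.extend(scores @ Z[ex])
        lo, hi = np.percentile(np.array(pooled, dtype=np.float32), [2.5, 97.5])
        assert sel.lower_threshold == pytest.approx(lo, rel=1e-5)
        assert sel.upper_threshold == pytest.approx(hi, rel=1e-5)
        assert (act[sel.peak_frames] > sel.upper_threshold).all()
        assert (act[sel.dip_frames] < sel.lower_threshold).all()
        assert np.intersect1d(sel.peak_frames, sel.dip_frames).size == 0

    def test_degenerate_betas_no_peaks(self, rng):
        scores = rng.standard_normal((30, 3))
        comps = _comps(scores)
        B = np.tile([1.0, 0.5, -0.3], (12, 1))
        assignment = np.repeat([0, 1], 6)
        act, _ = clusters.activation_time_course(
            comps, clusters.zscore_columns(B)[0], clusters.zscore_columns(B)[:6]
        )
        sel = clusters.peak_dip_null(act, assignment, B, comps, cluster_id=0,
                                     n_shuffles=100, seed=0)
        assert sel.peak_frames.size == 0 and sel.dip_frames.size == 0

    def test_too_few_shuffles_rejected(self, rng):
        comps = _comps(rng.standard_normal((10, 2)))
        with pytest.raises(ValueError):
            clusters.peak_dip_null(np.zeros(10), np.zeros(4, int),
                                   rng.standard_normal((4, 2)), comps, 0, n_shuffles=10)


class TestComponentContribution:
    def _selection(self, peaks, dips):
        from semenc.datatypes import PeakDipSelection

        return PeakDipSelection(
            peak_frames=np.asarray(peaks), dip_frames=np.asarray(dips),
            upper_threshold=0.0, lower_threshold=0.0, n_shuffles=100,
        )

    def test_identical_values_null_statistic(self, rng):
        scores = np.vstack([rng.standard_normal((10, 2))] * 2)
        comps = _comps(scores)
        act = np.concatenate([np.arange(10, 0, -1.0), -np.arange(10, 0, -1.0)])
        sel = self._selection(np.arange(10), np.arange(10, 20))
        stats_ = clusters.component_contribution(sel, comps, act, k_top=2)
        for st in stats_:
            assert st["statistic"] == 0.0 and st["p"] == 1.0 and not st["significant"]

    def test_planted_shift_detected_with_sign(self, rng):
        n = 40
        peak_vals = rng.standard_normal(n) + 2.0  # 2 sd shift on component 0
        dip_vals = rng.standard_normal(n)
        scores = np.zeros((2 * n, 2))
        scores[:n, 0] = peak_vals
        scores[n:, 0] = dip_vals
        scores[:, 1] = rng.standard_normal(2 * n)
        comps = _comps(scores, evr=[0.7, 0.3])
        act = np.concatenate([np.linspace(3, 2, n), np.linspace(-2, -3, n)])
        sel = self._selection(np.arange(n), np.arange(n, 2 * n))
        stats_ = clusters.component_contribution(sel, comps, act, k_top=2,
                                                 alpha=0.001, n_clusters=1)
        assert stats_[0]["significant"]
        assert stats_[0]["statistic"] > 0  # peaks larger than dips
        assert not stats_[1]["significant"]
        # variance adjustment divides by the percent explained variance
        assert stats_[0]["variance_adjusted_statistic"] == pytest.approx(
            stats_[0]["statistic"] / 70.0
        )

    def test_unequal_sets_trimmed_to_extremes(self, rng):
        scores = rng.standard_normal((30, 1))
        comps = _comps(scores, evr=[1.0])
        act = np.linspace(-1, 1, 30)
        sel = self._selection(peaks=[29, 28, 27], dips=[0, 1])
        stats_ = clusters.component_contribution(sel, comps, act, k_top=1)
        assert np.isfinite(stats_[0]["statistic"])


def test_end_to_end_profiles_smoke(small_study, rng):
    """Full clustering path on recovered encoding weights produces sane profiles."""
    from semenc import encoding

    s = small_study
    fit = encoding.fit_ridge_cv(
        s["features"], s["residual_recording"].hfb, s["plan"], time_shift=0.32
    )
    sig = np.flatnonzero(fit.significant)
    assert sig.size >= 10
    profiles = clusters.build_cluster_profiles(
        fit.betas[sig], s["components"],
        _subset_geometry(s["geometry"], sig), seed=0, n_shuffles=200,
        apply_filters=False,
    )
    assert len(profiles) >= 1
    for p in profiles:
        assert p.exemplar in p.members
        assert p.activation.size == s["components"].n_frames
        assert sum(p.subject_counts.values()) == p.members.size


def _subset_geometry(geometry, idx):
    from semenc.datatypes import ElectrodeGeometry

    return ElectrodeGeometry(
        subject_of=geometry.subject_of[idx],
        sphere_xyz=geometry.sphere_xyz[idx],
        anat_label=[geometry.anat_label[i] for i in idx],
    )
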