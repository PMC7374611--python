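"""Label filtering, frame embedding, PCA, and interpretation analyses."""
import numpy as np
import pytest

from semenc import semantic, synth
from semenc.datatypes import EmbeddingLexicon, FrameLabelTable


def _table(entries, frame_rate=25.0):
    return FrameLabelTable(len(entries), frame_rate, entries)


class TestFilterLabels:
    def test_strict_threshold_and_hand_enumeration(self):
        """Probabilities {0.95, 0.91, 0.80} at a 0.9 cut leave exactly 2 labels."""
        entries = [[("a", 0.95), ("b", 0.91), ("c", 0.80)] for _ in range(5)]
        out = semantic.filter_labels(_table(entries), 0.9, {"a", "b", "c"})
        for e in out.labels_per_frame:
            assert [lab for lab, _ in e] == ["a", "b"]

    def test_boundary_is_strict(self):
        out = semantic.filter_labels(_table([[("a", 0.90), ("b", 0.89)]]), 0.9, {"a", "b"})
        assert out.labels_per_frame[0] == []

    def test_identity_with_zero_threshold(self):
        entries = [[("a", 0.5), ("b", 0.2)], [("c", 0.99)]]
        out = semantic.filter_labels(_table(entries), 0.0, {"a", "b", "c"})
        assert [[l for l, _ in e] for e in out.labels_per_frame] == [["a", "b"], ["c"]]

    def test_keep_list_and_duplicates(self):
        entries = [[("a", 0.95), ("a", 0.97), ("z", 0.99)]]
        out = semantic.filter_labels(_table(entries), 0.9, {"a"})
        assert out.labels_per_frame[0] == [("a", 0.97)]

    def test_empty_keep_list_rejected(self):
        with pytest.raises(ValueError):
            semantic.filter_labels(_table([[]]), 0.9, set())


class TestEmbedFrames:
    def test_single_label_is_its_vector(self, tiny_lexicon):
        lab = tiny_lexicon.labels[3]
        out = semantic.embed_frames(_table([[(lab, 0.95)]]), tiny_lexicon)
        np.testing.assert_array_equal(out.values[0], tiny_lexicon.vector(lab))
        assert out.n_labels_used[0] == 1

    def test_pair_average_between_both_labels(self, tiny_lexicon):
        """The averaged point is closer (cosine) to both labels than an unrelated one."""
        a, b = tiny_lexicon.labels[0], tiny_lexicon.labels[3]  # same topic
        other = tiny_lexicon.labels[1]  # different topic
        out = semantic.embed_frames(_table([[(a, 0.9), (b, 0.9)]]), tiny_lexicon)
        np.testing.assert_allclose(
            out.values[0], (tiny_lexicon.vector(a) + tiny_lexicon.vector(b)) / 2
        )

        def cos(u, v):
            return u @ v / (np.linalg.norm(u) * np.linalg.norm(v))

        m = out.values[0]
        assert cos(m, tiny_lexicon.vector(a)) > cos(m, tiny_lexicon.vector(other))
        assert cos(m, tiny_lexicon.vector(b)) > cos(m, tiny_lexicon.vector(other))

    def test_matches_loop_oracle(self, rng):
        lex = EmbeddingLexicon(
            labels=[f"l{i}" for i in range(6)], vectors=rng.standard_normal((6, 6))
        )
        entries = []
        for _ in range(10):
            k = rng.integers(1, 5)
            labs = rng.choice(6, size=k, replace=False)
            entries.append([(f"l{i}", 0.9) for i in labs])
        out = semantic.embed_frames(_table(entries), lex)
        for f, e in enumerate(entries):
            acc = np.zeros(6)
            for lab, _ in e:
                acc += lex.vector(lab)
            np.testing.assert_allclose(out.values[f], acc / len(e), rtol=1e-12)

    def test_label_order_invariance(self, tiny_lexicon):
        labs = [(l, 0.9) for l in tiny_lexicon.labels[:4]]
        out1 = semantic.embed_frames(_table([labs]), tiny_lexicon)
        out2 = semantic.embed_frames(_table([labs[::-1]]), tiny_lexicon)
        np.testing.assert_allclose(out1.values, out2.values, atol=1e-12)

    def test_missing_label_named_in_error(self, tiny_lexicon):
        with pytest.raises(KeyError, match="nosuchlabel"):
            semantic.embed_frames(_table([[("nosuchlabel", 0.9)]]), tiny_lexicon)

    def test_zero_label_frame_flagged(self, tiny_lexicon):
        out = semantic.embed_frames(_table([[], [(tiny_lexicon.labels[0], 0.9)]]), tiny_lexicon)
        assert out.empty_frames.tolist() == [True, False]
        np.testing.assert_array_equal(out.values[0], 0.0)


class TestFitComponents:
    def test_complete_basis_explains_everything(self, rng):
        X = rng.standard_normal((40, 6))
        comps = semantic.fit_components(X, n_components=6)
        assert abs(comps.explained_variance_ratio.sum() - 1.0) < 1e-10

    def test_ratios_match_eigendecomposition_oracle(self, rng):
        """Rank-2 data: variance ratios equal covariance eigenvalues (dense oracle)."""
        basis = rng.standard_normal((2, 5))
        X = rng.standard_normal((60, 2)) @ basis
        comps = semantic.fit_components(X, n_components=2)
        C = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(
            comps.explained_variance_ratio, eig[:2] / eig.sum(), rtol=1e-8
        )
        assert abs(comps.explained_variance_ratio.sum() - 1.0) < 1e-8

    def test_contract_orthonormal_nonincreasing_scores(self, small_study):
        comps = small_study["components"]
        K = comps.n_components
        np.testing.assert_allclose(comps.loadings.T @ comps.loadings, np.eye(K), atol=1e-8)
        assert (np.diff(comps.explained_variance_ratio) <= 1e-12).all()
        assert (comps.explained_variance_ratio >= 0).all()
        # scores = (X - mean) @ loadings
        emb = small_study["embeddings"]
        np.testing.assert_allclose(
            comps.scores, (emb.values - comps.mean) @ comps.loadings, atol=1e-8
        )

    def test_sign_convention_deterministic(self, rng):
        X = rng.standard_normal((30, 5))
        c1 = semantic.fit_components(X, 3)
        c2 = semantic.fit_components(X.copy(), 3)
        np.testing.assert_array_equal(c1.loadings, c2.loadings)
        for k in range(3):
            col = c1.loadings[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_reconstruction_error_equals_discarded_variance(self, rng):
        X = rng.standard_normal((50, 8))
        full = semantic.fit_components(X, 8)
        trunc = semantic.fit_components(X, 3)
        recon = trunc.mean + trunc.scores @ trunc.loadings.T
        err = ((X - recon) ** 2).sum() / (X.shape[0] - 1)
        discarded = (
            full.explained_variance_ratio[3:].sum()
            * np.cov(X, rowvar=False, ddof=1).trace()
        )
        np.testing.assert_allclose(err, discarded, rtol=1e-8)

    def test_frame_permutation_permutes_scores_only(self, rng):
        X = rng.standard_normal((25, 6))
        perm = rng.permutation(25)
        c1 = semantic.fit_components(X, 4)
        c2 = semantic.fit_components(X[perm], 4)
        np.testing.assert_allclose(c2.loadings, c1.loadings, atol=1e-9)
        np.testing.assert_allclose(c2.scores, c1.scores[perm], atol=1e-9)

    def test_zero_label_frames_excluded_and_zero_scores(self, tiny_lexicon):
        entries = [[] if f % 5 == 0 else [(tiny_lexicon.labels[f % 12], 0.9),
                                          (tiny_lexicon.labels[(f + 3) % 12], 0.9)]
                   for f in range(30)]
        emb = semantic.embed_frames(_table(entries), tiny_lexicon)
        comps = semantic.fit_components(emb, n_components=3)
        np.testing.assert_array_equal(comps.scores[emb.empty_frames], 0.0)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            semantic.fit_components(rng.standard_normal((5, 10)), 8)


class TestRankFrames:
    def _comps(self, scores):
        from semenc.datatypes import SemanticComponents

        K = scores.shape[1]
        return SemanticComponents(
            scores=scores, loadings=np.eye(K), mean=np.zeros(K),
            explained_variance_ratio=np.full(K, 1.0 / K),
        )

    def test_ten_percent_of_hundred(self, rng):
        comps = self._comps(rng.standard_normal((100, 3)))
        bottom, top, _ = semantic.rank_frames(comps, 0, 0.10)
        assert len(bottom) == len(top) == 10
        assert comps.scores[top, 0].min() >= comps.scores[bottom, 0].max()

    def test_half_fraction_covers_all(self, rng):
        comps = self._comps(rng.standard_normal((40, 2)))
        bottom, top, _ = semantic.rank_frames(comps, 1, 0.5)
        assert sorted(np.concatenate([bottom, top])) == list(range(40))

    def test_planted_topic_contrast_recovered(self):
        """A component contrasting two topics puts those topics' labels in its tails."""
        lex = synth.generate_lexicon(n_labels=20, n_topics=2, dim=12, spread=0.1, seed=2)
        table, _ = synth.generate_stimulus(
            lex, n_blocks=2, block_seconds=8, labels_per_frame=4,
            scene_persistence=0.8, seed=2, topic_label_fraction=1.0,
        )
        emb = semantic.embed_frames(table, lex)
        comps = semantic.fit_components(emb, 2)
        bottom, top, hists = semantic.rank_frames(comps, 0, 0.10, table=table)

        def dominant_topic(hist):
            counts = np.zeros(2)
            for lab, n in hist.items():
                counts[lex.topic_of[lex.labels.index(lab)]] += n
            return counts.argmax(), counts.max() / counts.sum()

    # the two tails must be dominated by the two different planted topics
        t_bot, share_bot = dominant_topic(hists[0])
        t_top, share_top = dominant_topic(hists[1])
        assert t_bot != t_top
        assert share_bot > 0.8 and share_top > 0.8

    def test_out_of_range_component(self, rng):
        comps = self._comps(rng.standard_normal((10, 2)))
        with pytest.raises(ValueError):
            semantic.rank_frames(comps, 5, 0.1)


class TestPosthocLabelRegression:
    def test_noiseless_linear_perfect_fit(self, rng):
        B = (rng.random((60, 8)) < 0.3).astype(int)
        W = rng.standard_normal((8, 3))
        from semenc.datatypes import BinaryLabelMatrix, SemanticComponents

        scores = B @ W + 0.5
        comps = SemanticComponents(
            scores=scores, loadings=np.eye(3), mean=np.zeros(3),
            explained_variance_ratio=np.array([0.5, 0.3, 0.2]),
        )
        labels = BinaryLabelMatrix(values=B, label_ids=[f"l{i}" for i in range(8)])
        weights, r2, f = semantic.posthoc_label_regression(comps, labels, k_top=3)
        assert r2 > 1 - 1e-10
        assert weights.shape == (8, 3)

    def test_weights_match_pseudoinverse_oracle(self, rng):
        from semenc.datatypes import BinaryLabelMatrix, SemanticComponents

        B = (rng.random((20, 4)) < 0.5).astype(int)
        scores = rng.standard_normal((20, 2))
        comps = SemanticComponents(
            scores=scores, loadings=np.eye(2), mean=np.zeros(2),
            explained_variance_ratio=np.array([0.6, 0.4]),
        )
        labels = BinaryLabelMatrix(values=B, label_ids=list("abcd"))
        weights, _, _ = semantic.posthoc_label_regression(comps, labels, k_top=2)
        X = np.column_stack([np.ones(20), B])
        oracle = np.linalg.pinv(X) @ scores
        np.testing.assert_allclose(weights, oracle[1:], atol=1e-8)

    def test_paper_scale_shape(self, rng):
        """A 129-label vocabulary yields a 129-row weight matrix."""
        from semenc.datatypes import BinaryLabelMatrix, SemanticComponents

        B = (rng.random((200, 129)) < 0.15).astype(int)
        scores = rng.standard_normal((200, 5))
        comps = SemanticComponents(
            scores=scores, loadings=np.eye(5), mean=np.zeros(5),
            explained_variance_ratio=np.full(5, 0.2),
        )
        labels = BinaryLabelMatrix(values=B, label_ids=[f"l{i}" for i in range(129)])
        weights, _, _ = semantic.posthoc_label_regression(comps, labels, k_top=5)
        assert weights.shape == (129, 5)


def test_binary_label_matrix_fixed_order(tiny_lexicon):
    entries = [[(tiny_lexicon.labels[2], 0.9)], [(tiny_lexicon.labels[0], 0.9)]]
    m = semantic.binary_label_matrix(_table(entries))
    assert m.label_ids == sorted({tiny_lexicon.labels[0], tiny_lexicon.labels[2]})
    np.testing.assert_array_equal(m.values.sum(axis=1), [1, 1])
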