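"""Shared fixtures: a tiny lexicon for oracle tests and a mid-scale study.

The mid-scale study is one fully generated synthetic experiment (stimulus,
semantic components, electrode geometry, planted HFB) reused read-only by
several test modules to keep the suite fast.
"""
from __future__ import annotations

import numpy as np
import pytest

from semenc import confounds, encoding, semantic, synth


@pytest.fixture(scope="session")
def tiny_lexicon():
    return synth.generate_lexicon(n_labels=12, n_topics=3, dim=8, spread=0.2, seed=0)


@pytest.fixture(scope="session")
def small_study():
    """Mid-scale planted experiment: 7 blocks x 30 s, 20 components, 30 electrodes."""
    lex = synth.generate_lexicon(n_labels=60, n_topics=6, dim=50, seed=7)
    table, conf = synth.generate_stimulus(
        lex, n_blocks=7, block_seconds=30, frame_rate=25,
        labels_per_frame=10, scene_persistence=0.97, seed=7,
    )
    filtered = semantic.filter_labels(table, 0.9, set(lex.labels))
    emb = semantic.embed_frames(filtered, lex)
    comps = semantic.fit_components(emb, n_components=20)
    geom = synth.generate_geometry(n_subjects=6, electrodes_per_subject=5, seed=7)
    rec, truth = synth.generate_neural(
        comps, conf, geom, lag_true=0.32, snr=1.0, frac_null=0.2, ar1=0.3, seed=7
    )
    feats = confounds.residualize_features(comps.scores, conf)
    rrec, lags = confounds.residualize_recording(rec, conf, max_lag_seconds=2.0)
    plan = encoding.make_fold_plan(table.n_frames, 25, conf.block_design, seed=0)
    return dict(
        lexicon=lex, table=table, confounds=conf, embeddings=emb, components=comps,
        geometry=geom, recording=rec, truth=truth, features=feats,
        residual_recording=rrec, confound_lags=lags, plan=plan, frame_rate=25.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
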