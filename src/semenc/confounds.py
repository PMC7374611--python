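"""Removal of block-design and audio-envelope confounds.

The film alternates speech and music blocks, so any electrode tracking the
soundtrack shows block-locked structure that would masquerade as semantic
encoding.  Neural responses are cleaned per electrode at an electrode-specific
optimal lag (linear fit over a lag grid for the block design, peak normalized
cross-correlation for the envelope); stimulus-side features are residualized
at lag zero, since the confounds are stimulus-locked by construction.
"""
from __future__ import annotations

import numpy as np

from .datatypes import NeuralRecording, StimulusConfounds
from .synth import shift_series

__all__ = [
    "best_block_lag",
    "best_envelope_lag",
    "residualize_features",
    "residualize_recording",
]


def _ols_residual(y: np.ndarray, regressors: np.ndarray) -> tuple[np.ndarray, float]:
    """Residual of y on [intercept, regressors]; returns (residual, R^2)."""
    X = np.column_stack([np.ones(y.size), regressors])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 0.0
    return resid, r2


def best_block_lag(
    hfb_row: np.ndarray,
    block: np.ndarray,
    frame_rate: float,
    lag_grid_seconds: np.ndarray | None = None,
) -> tuple[float, np.ndarray, float]:
    """Regress out the block design at the lag that maximizes the OLS fit.

    The block regressor is shifted over a grid of lags (default +-5 s at the
    frame period); the lag with the highest R-squared wins, ties broken toward
    the smallest absolute lag.  Returns ``(lag_seconds, residual, r2)``.
    """
    y = np.asarray(hfb_row, dtype=float)
    if np.allclose(y, y[0]):
        return 0.0, y - y.mean(), 0.0
    if lag_grid_seconds is None:
        max_frames = int(round(5 * frame_rate))
        lags = np.arange(-max_frames, max_frames + 1)
    else:
        lags_f = np.asarray(lag_grid_seconds) * frame_rate
        lags = np.round(lags_f).astype(int)
        if not np.allclose(lags_f, lags, atol=1e-9):
            raise ValueError("lag grid must be integer multiples of the frame period")
    # order by |lag| so the first maximum wins ties toward the smallest |lag|;
    # for a single regressor plus intercept, OLS R^2 equals corr^2, so the
    # scan is done on correlations and OLS is solved once at the winning lag
    order = np.argsort(np.abs(lags), kind="stable")
    yc = y - y.mean()
    y_ss = float((yc**2).sum())
    best_r2, best_lag = -np.inf, 0
    for lag in lags[order]:
        b = shift_series(block, int(lag))
        bc = b - b.mean()
        denom = y_ss * float((bc**2).sum())
        r2 = float((yc * bc).sum()) ** 2 / denom if denom > 0 else 0.0
        if r2 > best_r2 + 1e-15:
            best_r2, best_lag = r2, int(lag)
    resid, r2 = _ols_residual(y, shift_series(block, best_lag))
    return best_lag / frame_rate, resid, r2


def best_envelope_lag(
    hfb_row: np.ndarray,
    envelope: np.ndarray,
    frame_rate: float,
    max_lag_seconds: float = 5.0,
) -> tuple[float, np.ndarray, float]:
    """Regress out the audio envelope at the lag of peak cross-correlation.

    The lag within +-``max_lag_seconds`` maximizing the absolute normalized
    cross-correlation is found first; the envelope shifted to that lag is then
    removed by OLS.  Returns ``(lag_seconds, residual, r)``.
    """
    y = np.asarray(hfb_row, dtype=float)
    env = np.asarray(envelope, dtype=float)
    if env.std() == 0:
        raise ValueError("zero-variance envelope")
    n = y.size
    if max_lag_seconds >= n / frame_rate / 4:
        raise ValueError("max_lag must be below a quarter of the recording duration")
    max_frames = int(round(max_lag_seconds * frame_rate))
    lags = np.arange(-max_frames, max_frames + 1)
    order = np.argsort(np.abs(lags), kind="stable")
    best_absr, best_lag, best_r = -np.inf, 0, 0.0
    yc = y - y.mean()
    for lag in lags[order]:
        e = shift_series(env, int(lag))
        ec = e - e.mean()
        denom = np.sqrt((yc**2).sum() * (ec**2).sum())
        r = float((yc * ec).sum() / denom) if denom > 0 else 0.0
        if abs(r) > best_absr + 1e-15:
            best_absr, best_lag, best_r = abs(r), int(lag), r
    resid, _ = _ols_residual(y, shift_series(env, best_lag))
    return best_lag / frame_rate, resid, best_r


def residualize_features(
    features: np.ndarray, confounds: StimulusConfounds
) -> np.ndarray:
    """Residualize each feature column on [intercept, block, envelope] at lag 0."""
    X = np.asarray(features, dtype=float)
    if X.shape[0] != confounds.n_frames:
        raise ValueError("feature/confound length mismatch")
    C = np.column_stack(
        [np.ones(confounds.n_frames), confounds.block_design, confounds.audio_envelope]
    )
    coef, *_ = np.linalg.lstsq(C, X, rcond=None)
    return X - C @ coef


def residualize_recording(
    rec: NeuralRecording, confounds: StimulusConfounds, max_lag_seconds: float = 5.0
) -> tuple[NeuralRecording, np.ndarray]:
    """Per-electrode sequential confound removal (block first, then envelope).

    Block and envelope are removed independently per electrode at their own
    optimal lags, mirroring a sequential two-step clean-up rather than a joint
    fit.  Returns the residual recording and a (n_electrodes, 2) array of the
    chosen lags in seconds.
    """
    out = np.empty_like(rec.hfb)
    lags = np.zeros((rec.n_electrodes, 2))
    for e in range(rec.n_electrodes):
        lag_b, resid, _ = best_block_lag(
            rec.hfb[e], confounds.block_design, rec.frame_rate
        )
        lag_e, resid, _ = best_envelope_lag(
            resid, confounds.audio_envelope, rec.frame_rate, max_lag_seconds
        )
        out[e] = resid
        lags[e] = (lag_b, lag_e)
    return NeuralRecording(hfb=out, frame_rate=rec.frame_rate, geometry=rec.geometry), lags
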