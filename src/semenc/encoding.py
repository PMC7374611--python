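"""Cross-validated ridge encoding of HFB responses from stimulus features.

The model predicts each electrode's (confound-residualized) HFB time course
from the semantic components shifted by a candidate neural delay.  The
regularization strength is chosen per electrode by five-fold nested
cross-validation on held-out Pearson correlation; reported accuracy is the
mean held-out correlation over the five outer folds.  Because both features
and responses are temporally autocorrelated, test sets are concatenations of
short fragments drawn from every speech and music block rather than
contiguous chunks.

A sweep over time shifts (the stimulus-to-cortex delay) refits the full
model per shift and summarizes the accuracy curve.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import EncodingFit, FoldPlan, ShiftSweep

__all__ = [
    "make_fold_plan",
    "fit_ridge_cv",
    "sweep_time_shifts",
    "significance",
    "default_lambda_grid",
]


def default_lambda_grid() -> np.ndarray:
    """Log-spaced ridge penalty grid, 1e-3 ... 1e6 (10 points)."""
    return np.logspace(-3, 6, 10)


def _block_runs(block_design: np.ndarray) -> np.ndarray:
    """Block index per frame from runs of constant block-design value."""
    b = np.asarray(block_design)
    changes = np.flatnonzero(b[1:] != b[:-1]) + 1
    block_of = np.zeros(b.size, dtype=int)
    for i, c in enumerate(changes):
        block_of[c:] = i + 1
    return block_of


def make_fold_plan(
    n_frames: int,
    frame_rate: float,
    block_design: np.ndarray,
    n_folds: int = 5,
    fragment_seconds: float = 6.0,
    seed: int = 0,
) -> FoldPlan:
    """Block-stratified fold plan from fragments tiled within each block.

    Each block is tiled into ``fragment_seconds`` fragments; fragments are
    dealt round-robin to folds within each block (with a per-block random
    rotation), so every fold's test set contains fragments from every block —
    speech and music alike.  The outer folds partition all frames.  Inner
    folds re-deal each outer fold's training fragments the same way.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2 (need held-out data)")
    frag_len = int(round(fragment_seconds * frame_rate))
    if frag_len < 1:
        raise ValueError("fragment shorter than one frame")
    block_of = _block_runs(np.asarray(block_design)[:n_frames])
    rng = np.random.default_rng(seed)

    fragments: list[tuple[int, np.ndarray]] = []  # (block, frame indices)
    for b in np.unique(block_of):
        frames = np.flatnonzero(block_of == b)
        if frames.size < frag_len:
            raise ValueError(f"block {b} shorter than one fragment")
        n_frag = frames.size // frag_len
        for j in range(n_frag):
            start = j * frag_len
            stop = frames.size if j == n_frag - 1 else start + frag_len
            fragments.append((int(b), frames[start:stop]))

    def _deal(frag_ids: list[int], n_ways: int) -> list[list[int]]:
        """Round-robin fragments to folds within each block, random rotation."""
        folds: list[list[int]] = [[] for _ in range(n_ways)]
        by_block: dict[int, list[int]] = {}
        for fid in frag_ids:
            by_block.setdefault(fragments[fid][0], []).append(fid)
        for _b, fids in sorted(by_block.items()):
            rot = int(rng.integers(n_ways))
            for j, fid in enumerate(fids):
                folds[(j + rot) % n_ways].append(fid)
        return folds

    def _frames(fold: list[int]) -> np.ndarray:
        if not fold:
            return np.array([], dtype=int)
        return np.sort(np.concatenate([fragments[fid][1] for fid in fold]))

    all_ids = list(range(len(fragments)))
    outer_ids = _deal(all_ids, n_folds)
    if any(not fold for fold in outer_ids):
        raise ValueError(
            "not enough fragments to fill every fold; use longer blocks, "
            "shorter fragments or fewer folds"
        )
    outer_folds = [_frames(fold) for fold in outer_ids]
    inner_folds: list[list[np.ndarray]] = []
    for i in range(n_folds):
        train_ids = [fid for fid in all_ids if fid not in set(outer_ids[i])]
        inner_ids = _deal(train_ids, n_folds)
        inner_folds.append([_frames(fold) for fold in inner_ids if fold])
    return FoldPlan(outer_folds=outer_folds, inner_folds=inner_folds, block_of=block_of)


def _ridge_betas(
    U: np.ndarray, s: np.ndarray, Vt: np.ndarray, Y: np.ndarray, lambdas: np.ndarray
) -> np.ndarray:
    """Closed-form ridge solutions for all penalties at once via one SVD.

    Returns an array (n_lambdas, K, n_targets) of coefficients for centered,
    standardized X (SVD U s Vt) and centered Y.
    """
    UtY = U.T @ Y  # (rank, n_targets)
    shrink = s[None, :] / (s[None, :] ** 2 + lambdas[:, None])  # (L, rank)
    return np.einsum("kr,lr,rt->lkt", Vt.T, shrink, UtY)


def _corr_cols(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of two equally shaped matrices."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    denom = np.sqrt((Ac**2).sum(axis=0) * (Bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac * Bc).sum(axis=0) / denom
    return np.where(denom > 0, r, 0.0)


def _standardize(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (X - mean) / sd


def fit_ridge_cv(
    features: np.ndarray,
    hfb: np.ndarray,
    plan: FoldPlan,
    time_shift: float = 0.0,
    lambda_grid: np.ndarray | None = None,
    frame_rate: float = 25.0,
    alpha: float = 0.001,
    n_tests: int | None = None,
) -> EncodingFit:
    """Nested-CV ridge fit of every electrode at one time shift.

    Features are shifted by ``time_shift`` (positive = neural response lags
    the stimulus) and frames without a valid shifted feature are trimmed.
    Within each outer fold, the inner folds select the ridge penalty per
    electrode by mean validation correlation; the model is refit on the outer
    training set and scored by Pearson r on the outer test set.  Features are
    standardized (train statistics) with the intercept handled by centering.
    Betas are fold-averaged and reported both in standardized units
    (``betas``) and rescaled per fold to original feature units
    (``betas_raw``).
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambdas = np.asarray(lambda_grid, dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty lambda grid")
    X_full = np.asarray(features, dtype=float)
    Y_full = np.asarray(hfb, dtype=float).T  # (frames, electrodes)
    n_frames, K = X_full.shape
    if Y_full.shape[0] != n_frames:
        raise ValueError("features and hfb frame counts differ")
    shift_f = time_shift * frame_rate
    shift = int(round(shift_f))
    if abs(shift_f - shift) > 1e-9:
        raise ValueError("time_shift must be an integer number of frames")

    # trim frames whose shifted feature index falls outside the recording
    valid = np.zeros(n_frames, dtype=bool)
    lo = max(0, shift)
    hi = min(n_frames, n_frames + shift)
    valid[lo:hi] = True
    pos = np.full(n_frames, -1)
    pos[valid] = np.arange(valid.sum())
    Xv = X_full[np.flatnonzero(valid) - shift]
    Yv = Y_full[valid]
    n_el = Yv.shape[1]

    def _sub(idx: np.ndarray) -> np.ndarray:
        """Map full-frame indices to trimmed-frame indices, dropping invalid ones."""
        mapped = pos[idx]
        return mapped[mapped >= 0]

    n_folds = len(plan.outer_folds)
    betas_folds = np.zeros((n_folds, n_el, K))
    betas_raw_folds = np.zeros((n_folds, n_el, K))
    r_folds = np.zeros((n_folds, n_el))
    lam_folds = np.zeros((n_folds, n_el))
    test_sizes = []
    degenerate = np.zeros(n_el, dtype=bool)

    all_idx = np.arange(Xv.shape[0])
    for i in range(n_folds):
        test = _sub(plan.outer_folds[i])
        train = np.setdiff1d(all_idx, test)
        # inner CV: mean validation correlation per (lambda, electrode)
        val_r = np.zeros((lambdas.size, n_el))
        for val_frames in plan.inner_folds[i]:
            val = _sub(val_frames)
            inner_train = np.setdiff1d(train, val)
            Xt = Xv[inner_train]
            mean, sd = Xt.mean(axis=0), Xt.std(axis=0)
            sd[sd == 0] = 1.0
            Xs = _standardize(Xt, mean, sd)
            Yt = Yv[inner_train]
            Ytc = Yt - Yt.mean(axis=0)
            U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
            B = _ridge_betas(U, s, Vt, Ytc, lambdas)  # (L, K, E)
            Xval = _standardize(Xv[val], mean, sd)
            for li in range(lambdas.size):
                val_r[li] += _corr_cols(Xval @ B[li], Yv[val])
        best_li = np.argmax(val_r, axis=0)  # per electrode
        lam_folds[i] = lambdas[best_li]

        Xt = Xv[train]
        mean, sd = Xt.mean(axis=0), Xt.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = _standardize(Xt, mean, sd)
        Yt = Yv[train]
        Ytc = Yt - Yt.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        B = _ridge_betas(U, s, Vt, Ytc, lambdas)  # (L, K, E)
        beta_std = B[best_li, :, np.arange(n_el)]  # (E, K)
        Xtest = _standardize(Xv[test], mean, sd)
        pred = Xtest @ beta_std.T
        ytest = Yv[test]
        const = ytest.std(axis=0) == 0
        degenerate |= const
        r_folds[i] = np.where(const, 0.0, _corr_cols(pred, ytest))
        betas_folds[i] = beta_std
        betas_raw_folds[i] = beta_std / sd[None, :]
        test_sizes.append(test.size)

    betas = betas_folds.mean(axis=0)
    betas_raw = betas_raw_folds.mean(axis=0)
    r_cv = r_folds.mean(axis=0)
    r_cv = np.clip(r_cv, -1.0, 1.0)
    n_eff = int(round(float(np.mean(test_sizes))))
    if n_tests is None:
        n_tests = n_el
    p, sig = significance(r_cv, n_eff=n_eff, n_tests=n_tests, alpha=alpha)
    # modal selected lambda per electrode (smallest wins ties)
    lam = np.empty(n_el)
    for e in range(n_el):
        vals, counts = np.unique(lam_folds[:, e], return_counts=True)
        lam[e] = vals[np.argmax(counts)]
    return EncodingFit(
        betas=betas,
        betas_raw=betas_raw,
        lambda_per_electrode=lam,
        r_cv=r_cv,
        p_value=p,
        significant=sig,
        time_shift=time_shift,
        n_eff=n_eff,
    )


def significance(
    r_cv: np.ndarray, n_eff: int, n_tests: int, alpha: float = 0.001
) -> tuple[np.ndarray, np.ndarray]:
    """Transform fold-averaged correlations to t values and Bonferroni-correct.

    ``t = r * sqrt((n_eff - 2) / (1 - r^2))`` with ``n_eff`` the held-out
    sample count per fold; two-sided p from the t distribution with
    ``n_eff - 2`` degrees of freedom, multiplied by ``n_tests`` (capped at 1).
    """
    if n_eff <= 2:
        raise ValueError("n_eff must exceed 2")
    r = np.clip(np.asarray(r_cv, dtype=float), -1.0, 1.0)
    p = np.zeros_like(r)
    exact = np.abs(r) >= 1.0
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n_eff - 2) / (1.0 - r**2))
    p[~exact] = 2.0 * stats.t.sf(np.abs(t[~exact]), df=n_eff - 2)
    p = np.minimum(p * n_tests, 1.0)
    p[exact] = 0.0
    return p, p < alpha


def sweep_time_shifts(
    features: np.ndarray,
    hfb: np.ndarray,
    plan: FoldPlan,
    shifts_seconds: np.ndarray,
    frame_rate: float = 25.0,
    lambda_grid: np.ndarray | None = None,
    alpha: float = 0.001,
    keep_fits: bool = False,
) -> ShiftSweep:
    """Refit the full encoding model at every candidate time shift.

    ``best_shift`` maximizes the significant-electrode count, with mean
    significant-electrode correlation as tiebreak (ties beyond that go to the
    smallest absolute shift).
    """
    shifts = np.asarray(shifts_seconds, dtype=float)
    frame_period = 1.0 / frame_rate
    if not np.allclose(np.round(shifts / frame_period), shifts / frame_period, atol=1e-9):
        raise ValueError("shifts must be integer multiples of the frame period")
    mean_r = np.zeros(shifts.size)
    n_sig = np.zeros(shifts.size, dtype=int)
    fits = [] if keep_fits else None
    for i, sh in enumerate(shifts):
        fit = fit_ridge_cv(
            features, hfb, plan, time_shift=float(sh),
            lambda_grid=lambda_grid, frame_rate=frame_rate, alpha=alpha,
        )
        n_sig[i] = int(fit.significant.sum())
        mean_r[i] = float(fit.r_cv[fit.significant].mean()) if n_sig[i] else 0.0
        if keep_fits:
            fits.append(fit)
    # lexicographic: count, then mean r, then smallest |shift|
    order = sorted(
        range(shifts.size),
        key=lambda i: (-n_sig[i], -mean_r[i], abs(shifts[i])),
    )
    best = shifts[order[0]]
    return ShiftSweep(
        shifts=shifts,
        mean_r_significant=mean_r,
        n_significant=n_sig,
        best_shift=float(best),
        fits=fits,
    )
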