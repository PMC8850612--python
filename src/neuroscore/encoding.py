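"""Ridge encoding models and brain scores.

The brain score of an embedding is the cross-validated Pearson correlation
between held-out brain responses and the predictions of a linear map fitted
from the embedding:

    W = (Xᵀ X + λ I)⁻¹ Xᵀ Y          (ridge, per target dimension)
    R = Corr(Y_test, X_test W)        (Pearson, per voxel / channel / time)

λ is chosen per target dimension among 20 values log-spaced between 1e−3
and 1e8 by exact leave-one-out cross-validation on the training split,
computed in closed form from one SVD of X (the hat-matrix identity
e_i = (y_i − ŷ_i)/(1 − h_ii)); this matches an explicit LOO refit loop to
numerical precision.

For fMRI, word-level features are expanded to the scan grid with a finite
impulse response (FIR) design of five delayed copies (2–10 s), so the
hemodynamic lag is estimated rather than assumed. Cross-validation folds
are blocked on 5-sentence blocks, and fMRI scans at block seams that mix
train- and test-block contributions are dropped, so no information leaks
across the split. For MEG, the model is fitted independently at each
peri-word time sample.

The inter-subject noise ceiling replaces the embedding with the average
response of all other subjects to the same sentences (a shared response
model) and runs the identical pipeline; an optional linear source
projection K is applied to both measured and predicted responses before
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (
    AlignmentError,
    BrainRecording,
    EmbeddingMatrix,
    ModelCard,
    ProjectionOperator,
    ScoreMap,
    StimulusSet,
)

__all__ = [
    "DEFAULT_ALPHAS",
    "DEFAULT_DELAYS",
    "CVScheme",
    "RidgeFit",
    "Scaler",
    "RobustScaler",
    "ridge_fit",
    "pearson_score",
    "fir_expand",
    "fir_delay_profile",
    "brain_score_fmri",
    "brain_score_meg",
    "noise_ceiling",
    "meg_subsample_indices",
]

#: 20 λ values log-spaced between 1e−3 and 1e8.
DEFAULT_ALPHAS: np.ndarray = np.logspace(-3, 8, 20)

#: FIR delays in seconds, 2–10 s.
DEFAULT_DELAYS: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0)


def meg_subsample_indices(
    times: np.ndarray, n: int = 10, window: tuple[float, float] = (0.0, 2.0)
) -> np.ndarray:
    """Indices of n time samples regularly distributed over ``window``.

    The default — ten samples over [0, 2] s — is the convenience grid
    used when model comparison restricts the MEG time axis.
    """
    times = np.asarray(times, dtype=float)
    targets = np.linspace(window[0], window[1], n)
    idx = np.unique([int(np.argmin(np.abs(times - t))) for t in targets])
    return idx


class CVError(ValueError):
    """Cross-validation cannot be constructed as requested."""


@dataclass(frozen=True)
class CVScheme:
    """Blocked cross-validation: folds partition 5-sentence blocks."""

    n_folds: int = 5
    seed: int = 0

    def assign(self, block_ids: list[int]) -> dict[int, int]:
        """Map each block id to a fold index; every fold gets ≥1 block."""
        blocks = list(dict.fromkeys(block_ids))
        if len(blocks) < self.n_folds:
            raise CVError(
                f"{len(blocks)} blocks cannot fill {self.n_folds} folds"
            )
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(blocks))
        return {blocks[j]: i % self.n_folds for i, j in enumerate(order)}


# ---------------------------------------------------------------------------
# Scalers (fitted on the training split only)
# ---------------------------------------------------------------------------

@dataclass
class Scaler:
    """Z-score columns using train-split mean/std; constant columns → 0."""

    mean_: np.ndarray = field(default=None, repr=False)  # type: ignore
    std_: np.ndarray = field(default=None, repr=False)  # type: ignore
    constant_: np.ndarray = field(default=None, repr=False)  # type: ignore

    def fit(self, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples to fit a scaler")
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0)
        self.constant_ = self.std_ == 0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        std = np.where(self.constant_, 1.0, self.std_)
        out = (np.asarray(X, dtype=np.float64) - self.mean_) / std
        out[:, self.constant_] = 0.0
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


@dataclass
class RobustScaler:
    """Clip at the train 0.01st/99.99th percentiles, then standardize.

    Standardization uses the mean/std of the clipped training data (the
    median/IQR alternative is available via ``center="median"``).
    """

    lower_q: float = 0.0001
    upper_q: float = 0.9999
    center: str = "mean"
    lo_: np.ndarray = field(default=None, repr=False)  # type: ignore
    hi_: np.ndarray = field(default=None, repr=False)  # type: ignore
    mean_: np.ndarray = field(default=None, repr=False)  # type: ignore
    std_: np.ndarray = field(default=None, repr=False)  # type: ignore
    constant_: np.ndarray = field(default=None, repr=False)  # type: ignore

    def fit(self, X: np.ndarray) -> "RobustScaler":
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples to fit a scaler")
        self.lo_ = np.quantile(X, self.lower_q, axis=0)
        self.hi_ = np.quantile(X, self.upper_q, axis=0)
        clipped = np.clip(X, self.lo_, self.hi_)
        if self.center == "median":
            self.mean_ = np.median(clipped, axis=0)
            q75, q25 = np.percentile(clipped, [75, 25], axis=0)
            self.std_ = q75 - q25
        else:
            self.mean_ = clipped.mean(axis=0)
            self.std_ = clipped.std(axis=0)
        self.constant_ = self.std_ == 0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        clipped = np.clip(np.asarray(X, dtype=np.float64), self.lo_, self.hi_)
        std = np.where(self.constant_, 1.0, self.std_)
        out = (clipped - self.mean_) / std
        out[:, self.constant_] = 0.0
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# Ridge with exact per-target LOO λ selection
# ---------------------------------------------------------------------------

@dataclass
class RidgeFit:
    """Ridge solution with per-target λ selected by training-split LOO."""

    W: np.ndarray  # features × targets
    alphas: np.ndarray  # the λ grid
    alpha_per_target: np.ndarray  # selected λ, per target
    loo_mse: np.ndarray  # grid × targets, exact LOO mean squared error

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64) @ self.W


def ridge_fit(
    X: np.ndarray,
    Y: np.ndarray,
    alphas: np.ndarray | None = None,
) -> RidgeFit:
    """Fit ridge regressions with exact leave-one-out λ selection.

    For each λ on the grid, the leave-one-out residual of sample i is
    computed in closed form as (y_i − ŷ_i) / (1 − h_ii) with
    H = X (XᵀX + λI)⁻¹ Xᵀ obtained from a single SVD of X. The λ with
    minimal LOO mean squared error is selected independently for every
    target dimension, and the final weights solve the ridge normal
    equations at that λ on the full training set.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching sample counts")
    n = X.shape[0]
    if n < 2:
        raise ValueError("ridge_fit requires at least 2 training samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("ridge_fit requires finite inputs")
    grid = DEFAULT_ALPHAS if alphas is None else np.asarray(alphas, float)

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    UtY = U.T @ Y  # r × t
    s2 = s**2
    U2 = U**2

    n_targets = Y.shape[1]
    loo_mse = np.empty((grid.size, n_targets))
    for a, lam in enumerate(grid):
        d = s2 / (s2 + lam)  # shrinkage per singular direction
        Hy = U @ (d[:, None] * UtY)
        h = U2 @ d  # diag of the hat matrix
        denom = np.maximum(1.0 - h, 1e-300)
        resid = (Y - Hy) / denom[:, None]
        loo_mse[a] = np.mean(resid**2, axis=0)

    best = np.argmin(loo_mse, axis=0)
    alpha_per_target = grid[best]

    W = np.empty((X.shape[1], n_targets))
    for a in np.unique(best):
        cols = np.nonzero(best == a)[0]
        coef = s / (s2 + grid[a])
        W[:, cols] = Vt.T @ (coef[:, None] * UtY[:, cols])
    return RidgeFit(W=W, alphas=grid, alpha_per_target=alpha_per_target,
                    loo_mse=loo_mse)


def ridge_closed_form(
    X: np.ndarray, Y: np.ndarray, lam: float
) -> np.ndarray:
    """Direct normal-equation ridge solution (reference path)."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    p = X.shape[1]
    return np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ Y)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def pearson_score(
    Y: np.ndarray, Yhat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r per column; zero-variance columns score 0 and are flagged.

    Returns ``(r, degenerate)`` arrays of shape (n_targets,).
    """
    Y = np.asarray(Y, dtype=np.float64)
    Yhat = np.asarray(Yhat, dtype=np.float64)
    if Y.shape != Yhat.shape:
        raise ValueError("shape mismatch between truth and prediction")
    if Y.ndim == 1:
        Y, Yhat = Y[:, None], Yhat[:, None]
    yc = Y - Y.mean(axis=0)
    pc = Yhat - Yhat.mean(axis=0)
    sy = np.sqrt((yc**2).sum(axis=0))
    sp = np.sqrt((pc**2).sum(axis=0))
    degenerate = (sy == 0) | (sp == 0)
    denom = np.where(degenerate, 1.0, sy * sp)
    r = (yc * pc).sum(axis=0) / denom
    r[degenerate] = 0.0
    return np.clip(r, -1.0, 1.0), degenerate


# ---------------------------------------------------------------------------
# FIR expansion (fMRI)
# ---------------------------------------------------------------------------

def _delay_shifts(tr: float, delays) -> list[int]:
    shifts = []
    for d in delays:
        k = d / tr
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"delay {d} s is not a multiple of TR {tr} s")
        shifts.append(int(round(k)))
    return shifts


def bin_words(
    X: np.ndarray, onsets: np.ndarray, n_scans: int, tr: float
) -> np.ndarray:
    """Sum word-level features into the scan bin containing their onset."""
    X = np.asarray(X, dtype=np.float64)
    bins = np.floor(np.asarray(onsets, float) / tr).astype(int)
    if (bins < 0).any() or (bins >= n_scans).any():
        raise ValueError("word onset falls outside the scan grid")
    out = np.zeros((n_scans, X.shape[1]))
    np.add.at(out, bins, X)
    return out


def fir_expand(
    X: np.ndarray,
    onsets: np.ndarray,
    n_scans: int,
    tr: float = 2.0,
    delays=DEFAULT_DELAYS,
) -> np.ndarray:
    """FIR design matrix X*: horizontally stacked delayed copies of X.

    Word features are first summed into the scan bin containing their onset,
    then each delay block holds the binned features shifted by delay/TR
    scans (zeros before the first valid scan). Output: n_scans × (o·n_delays).
    """
    shifts = _delay_shifts(tr, delays)
    binned = bin_words(X, onsets, n_scans, tr)
    o = binned.shape[1]
    out = np.zeros((n_scans, o * len(shifts)))
    for j, k in enumerate(shifts):
        if k < n_scans:
            out[k:, j * o:(j + 1) * o] = binned[: n_scans - k]
    return out


def fir_delay_profile(
    fit: RidgeFit, n_features: int, delays=DEFAULT_DELAYS
) -> np.ndarray:
    """Frobenius norm of the ridge weights within each FIR delay block."""
    n_delays = len(delays)
    if fit.W.shape[0] != n_features * n_delays:
        raise ValueError("weight rows do not factor into delay blocks")
    blocks = fit.W.reshape(n_delays, n_features, -1)
    return np.sqrt((blocks**2).sum(axis=(1, 2)))


def scan_fold_assignment(
    onsets: np.ndarray,
    block_ids: np.ndarray,
    fold_of_block: dict[int, int],
    n_scans: int,
    tr: float,
    delays=DEFAULT_DELAYS,
) -> np.ndarray:
    """Attribute each scan to a CV fold, or −1 for mixed/empty scans.

    A scan belongs to fold f iff it receives a delayed contribution from at
    least one word of a fold-f block and from no word of any other fold.
    Scans mixing folds at block seams, and scans receiving no contribution
    at all, are excluded from both training and testing.
    """
    shifts = _delay_shifts(tr, delays)
    bins = np.floor(np.asarray(onsets, float) / tr).astype(int)
    folds = np.asarray([fold_of_block[b] for b in block_ids])
    # fold sets contributing to each source bin
    contrib = [set() for _ in range(n_scans)]
    for b, f in zip(bins, folds):
        contrib[b].add(int(f))
    out = np.full(n_scans, -1, dtype=int)
    for t in range(n_scans):
        seen: set[int] = set()
        for k in shifts:
            src = t - k
            if 0 <= src < n_scans:
                seen |= contrib[src]
        if len(seen) == 1:
            out[t] = seen.pop()
    return out


# ---------------------------------------------------------------------------
# Brain scores
# ---------------------------------------------------------------------------

def _check_disjoint(train_idx: np.ndarray, test_idx: np.ndarray) -> None:
    # leakage guard: hard failure, part of the scoring contract
    if np.intersect1d(train_idx, test_idx).size:
        raise AssertionError("train/test overlap — leakage")


def brain_score_fmri(
    embedding: EmbeddingMatrix,
    recording: BrainRecording,
    stimuli: StimulusSet,
    cv: CVScheme | None = None,
    alphas: np.ndarray | None = None,
    delays=DEFAULT_DELAYS,
    return_fits: bool = False,
):
    """Cross-validated fMRI brain score, one Pearson R per voxel.

    Per fold: z-score X on the training words, FIR-expand to the scan grid,
    robust-scale Y on the training scans, fit ridge with LOO λ selection,
    predict the held-out scans (those attributable purely to test blocks)
    and correlate per voxel. Fold scores are averaged.
    """
    if recording.modality != "fmri":
        raise ValueError("brain_score_fmri requires an fMRI recording")
    cv = cv or CVScheme()
    embedding.check_aligned(stimuli)
    blocks = stimuli.block_ids
    fold_of_block = cv.assign(list(blocks))
    scan_folds = scan_fold_assignment(
        stimuli.onsets, blocks, fold_of_block, recording.n_scans,
        recording.tr, delays,
    )
    word_folds = np.asarray([fold_of_block[b] for b in blocks])

    n_vox = recording.n_targets
    fold_scores = np.zeros((cv.n_folds, n_vox))
    degenerate = np.zeros(n_vox, dtype=bool)
    fits = []
    for f in range(cv.n_folds):
        train_words = word_folds != f
        Xs = Scaler().fit(embedding.values[train_words]).transform(
            embedding.values
        )
        Xstar = fir_expand(Xs, stimuli.onsets, recording.n_scans,
                           recording.tr, delays)
        train_scans = np.nonzero((scan_folds != f) & (scan_folds >= 0))[0]
        test_scans = np.nonzero(scan_folds == f)[0]
        _check_disjoint(train_scans, test_scans)
        if train_scans.size < 2 or test_scans.size < 2:
            raise CVError(f"fold {f} has too few usable scans")
        Ys = RobustScaler().fit(recording.data[train_scans]).transform(
            recording.data
        )
        fit = ridge_fit(Xstar[train_scans], Ys[train_scans], alphas)
        r, dg = pearson_score(Ys[test_scans], fit.predict(Xstar[test_scans]))
        fold_scores[f] = r
        degenerate |= dg
        if return_fits:
            fits.append(fit)
    scores = fold_scores.mean(axis=0)
    scores[degenerate] = 0.0
    smap = ScoreMap(
        subject_id=recording.subject_id, scores=scores, card=embedding.card,
        modality="fmri", degenerate=degenerate, fold_of_block=fold_of_block,
    )
    return (smap, fits) if return_fits else smap


def brain_score_meg(
    embedding: EmbeddingMatrix,
    recording: BrainRecording,
    stimuli: StimulusSet,
    cv: CVScheme | None = None,
    alphas: np.ndarray | None = None,
    time_indices: np.ndarray | None = None,
    projection: ProjectionOperator | None = None,
) -> ScoreMap:
    """Cross-validated MEG brain score, fitted per epoch time sample.

    The fMRI pipeline minus the FIR step: at each (optionally subsampled)
    time sample, ridge maps word features to the channel vector of that
    sample; scores form a channels × times map. An optional projection K is
    applied to measured and predicted responses before correlation, in
    which case scores are per source rather than per sensor.
    """
    if recording.modality != "meg":
        raise ValueError("brain_score_meg requires a MEG recording")
    cv = cv or CVScheme()
    embedding.check_aligned(stimuli)
    if recording.data.shape[0] != len(stimuli):
        raise AlignmentError("MEG epochs do not align with stimulus words")
    fold_of_block = cv.assign(list(stimuli.block_ids))
    word_folds = np.asarray([fold_of_block[b] for b in stimuli.block_ids])
    t_idx = (np.arange(recording.data.shape[2]) if time_indices is None
             else np.asarray(time_indices, int))
    n_out = (recording.n_targets if projection is None
             else projection.matrix.shape[0])
    if projection is not None:
        projection.check_compatible(recording.n_targets)

    scores = np.zeros((n_out, t_idx.size))
    degenerate = np.zeros((n_out, t_idx.size), dtype=bool)
    for j, t in enumerate(t_idx):
        Yt = recording.data[:, :, t]
        fold_r = np.zeros((cv.n_folds, n_out))
        dg = np.zeros(n_out, dtype=bool)
        for f in range(cv.n_folds):
            train = np.nonzero(word_folds != f)[0]
            test = np.nonzero(word_folds == f)[0]
            _check_disjoint(train, test)
            Xs = Scaler().fit(embedding.values[train]).transform(
                embedding.values
            )
            Ys = RobustScaler().fit(Yt[train]).transform(Yt)
            fit = ridge_fit(Xs[train], Ys[train], alphas)
            truth, pred = Ys[test], fit.predict(Xs[test])
            if projection is not None:
                truth = truth @ projection.matrix.T
                pred = pred @ projection.matrix.T
            r, d = pearson_score(truth, pred)
            fold_r[f] = r
            dg |= d
        scores[:, j] = fold_r.mean(axis=0)
        scores[dg, j] = 0.0
        degenerate[:, j] = dg
    return ScoreMap(
        subject_id=recording.subject_id, scores=scores, card=embedding.card,
        modality="meg", degenerate=degenerate, fold_of_block=fold_of_block,
        times=recording.times[t_idx],
    )


# ---------------------------------------------------------------------------
# Inter-subject noise ceiling (shared response model)
# ---------------------------------------------------------------------------

def _shared_sentence_mask(
    stimuli: StimulusSet, target: int, others: list[int]
) -> np.ndarray:
    """Words whose sentence the target and ≥1 other subject both saw."""
    mask = np.zeros(len(stimuli), dtype=bool)
    for i, subs in enumerate(stimuli.words["subject_ids"]):
        if target in subs and any(o in subs for o in others):
            mask[i] = True
    return mask


def noise_ceiling(
    recordings: list[BrainRecording],
    target_subject: int,
    stimuli: StimulusSet,
    cv: CVScheme | None = None,
    alphas: np.ndarray | None = None,
    projection: ProjectionOperator | None = None,
    time_indices: np.ndarray | None = None,
    ceiling_delays=(0.0,) + tuple(DEFAULT_DELAYS),
) -> ScoreMap:
    """Shared-response-model noise ceiling for one subject.

    The predictor is the average response of all other subjects who read
    the same sentence (the template), robust-scaled, fed through the
    identical ridge + correlation pipeline. No FIR expansion is applied in
    fMRI mode: template and target live on the same scan grid and carry the
    same hemodynamic lag. ``ceiling_delays`` only widens the scan-to-block
    attribution window used to keep block seams out of both splits.
    """
    cv = cv or CVScheme()
    target = next(
        (r for r in recordings if r.subject_id == target_subject), None
    )
    if target is None:
        raise ValueError(f"no recording for subject {target_subject}")
    others = [r for r in recordings if r.subject_id != target_subject]
    if not others:
        raise ValueError("noise ceiling requires at least 2 subjects")
    shared = _shared_sentence_mask(
        stimuli, target_subject, [r.subject_id for r in others]
    )
    if not shared.any():
        raise ValueError(
            f"no sentence of subject {target_subject} is shared with others"
        )

    if target.modality == "fmri":
        if any(o.data.shape != target.data.shape for o in others):
            raise AlignmentError("fMRI ceiling requires a common scan grid")
        template = np.mean([o.data for o in others], axis=0)
        blocks = stimuli.block_ids[shared]
        onsets = stimuli.onsets[shared]
        fold_of_block = cv.assign(list(blocks))
        scan_folds = scan_fold_assignment(
            onsets, blocks, fold_of_block, target.n_scans, target.tr,
            ceiling_delays,
        )
        n_out = (target.n_targets if projection is None
                 else projection.matrix.shape[0])
        if projection is not None:
            projection.check_compatible(target.n_targets)
        fold_scores = np.zeros((cv.n_folds, n_out))
        degenerate = np.zeros(n_out, dtype=bool)
        for f in range(cv.n_folds):
            train = np.nonzero((scan_folds != f) & (scan_folds >= 0))[0]
            test = np.nonzero(scan_folds == f)[0]
            _check_disjoint(train, test)
            if train.size < 2 or test.size < 2:
                raise CVError(f"ceiling fold {f} has too few usable scans")
            Xs = RobustScaler().fit(template[train]).transform(template)
            Ys = RobustScaler().fit(target.data[train]).transform(target.data)
            fit = ridge_fit(Xs[train], Ys[train], alphas)
            truth, pred = Ys[test], fit.predict(Xs[test])
            if projection is not None:
                truth = truth @ projection.matrix.T
                pred = pred @ projection.matrix.T
            r, dg = pearson_score(truth, pred)
            fold_scores[f] = r
            degenerate |= dg
        scores = fold_scores.mean(axis=0)
        scores[degenerate] = 0.0
        return ScoreMap(
            subject_id=target_subject, scores=scores,
            card=ModelCard(name="noise-ceiling"), modality="fmri",
            degenerate=degenerate, fold_of_block=fold_of_block,
        )

    # MEG mode: word-epoch template, per-time fitting
    for o in others:
        if o.data.shape != target.data.shape:
            raise AlignmentError("MEG ceiling requires a common epoch grid")
    template = np.mean([o.data for o in others], axis=0)
    idx = np.nonzero(shared)[0]
    sub_words = stimuli.words.iloc[idx]
    fold_of_block = cv.assign(list(sub_words["block_id"]))
    word_folds = np.asarray(
        [fold_of_block[b] for b in sub_words["block_id"]]
    )
    t_idx = (np.arange(target.data.shape[2]) if time_indices is None
             else np.asarray(time_indices, int))
    n_out = (target.n_targets if projection is None
             else projection.matrix.shape[0])
    if projection is not None:
        projection.check_compatible(target.n_targets)
    scores = np.zeros((n_out, t_idx.size))
    degenerate = np.zeros((n_out, t_idx.size), dtype=bool)
    for j, t in enumerate(t_idx):
        Xt = template[idx, :, t]
        Yt = target.data[idx, :, t]
        fold_r = np.zeros((cv.n_folds, n_out))
        dg = np.zeros(n_out, dtype=bool)
        for f in range(cv.n_folds):
            train = np.nonzero(word_folds != f)[0]
            test = np.nonzero(word_folds == f)[0]
            _check_disjoint(train, test)
            Xs = RobustScaler().fit(Xt[train]).transform(Xt)
            Ys = RobustScaler().fit(Yt[train]).transform(Yt)
            fit = ridge_fit(Xs[train], Ys[train], alphas)
            truth, pred = Ys[test], fit.predict(Xs[test])
            if projection is not None:
                truth = truth @ projection.matrix.T
                pred = pred @ projection.matrix.T
            r, d = pearson_score(truth, pred)
            fold_r[f] = r
            dg |= d
        scores[:, j] = fold_r.mean(axis=0)
        scores[dg, j] = 0.0
        degenerate[:, j] = dg
    return ScoreMap(
        subject_id=target_subject, scores=scores,
        card=ModelCard(name="noise-ceiling"), modality="meg",
        degenerate=degenerate, fold_of_block=fold_of_block,
        times=target.times[t_idx],
    )
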