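"""Trial averaging and the PCA -> LDA dimensionality-reduction front end.

Responses enter as units x timepoints matrices (units are samples,
timepoints are variables). PCA accumulates second-order statistics across
units and keeps the leading eigenvectors of the 1/n-normalized time-axis
covariance; LDA then projects the retained principal coordinates onto at
most C-1 directions that maximize the Fisher ratio of between-area scatter
(1/C-normalized) to total covariance. Both transforms are deterministic
given the data.

Per-unit z-scoring (mean 0, SD 1 across time) is applied before PCA by the
pipeline helpers: it removes trivially classifiable brightness offsets so
classification reflects response shape, and, being a per-row operation, it
cannot leak information between training and test units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import scipy.linalg
from sklearn.utils.extmath import randomized_svd

from .errors import (
    AlignmentError,
    ClassSizeError,
    DegenerateCovarianceError,
    LengthError,
    ValidationError,
)
from .types import Recording

_EXACT_DIM_LIMIT = 1600  # largest matrix side for exact eigendecomposition


# ---------------------------------------------------------------------------
# response windows


def trial_average(rec: Recording, stimulus_ids: Iterable[int] | None = None) -> np.ndarray:
    """Average trial-aligned response windows per stimulus.

    Per-stimulus blocks are concatenated along time in ascending stimulus-id
    order (the request order is irrelevant). All trials of one stimulus must
    share the same window length.
    """
    available = set(int(t.stimulus_id) for t in rec.trials)
    if stimulus_ids is None:
        wanted = sorted(available)
    else:
        wanted = sorted(int(s) for s in set(stimulus_ids))
        unknown = [s for s in wanted if s not in available]
        if unknown:
            raise ValidationError(f"unknown stimulus ids {unknown}")
    if not wanted:
        raise ValidationError("no stimuli requested")
    blocks = []
    for s in wanted:
        windows = [t for t in rec.trials if t.stimulus_id == s]
        lengths = {t.n_frames for t in windows}
        if len(lengths) != 1:
            raise AlignmentError(f"stimulus {s} has mismatched trial lengths {sorted(lengths)}")
        stack = np.stack(
            [rec.responses[:, t.onset_frame : t.onset_frame + t.n_frames] for t in windows]
        )
        blocks.append(stack.mean(axis=0))
    return np.concatenate(blocks, axis=1)


def single_trial(
    rec: Recording, stimulus_ids: Iterable[int] | None = None, block: int = 0
) -> np.ndarray:
    """Concatenated single-trial windows (the ``block``-th presentation of each stimulus)."""
    available = set(int(t.stimulus_id) for t in rec.trials)
    wanted = sorted(available if stimulus_ids is None else set(int(s) for s in stimulus_ids))
    if not set(wanted) <= available:
        raise ValidationError("unknown stimulus id requested")
    blocks = []
    for s in wanted:
        windows = [t for t in rec.trials if t.stimulus_id == s]
        if block >= len(windows):
            raise ValidationError(f"stimulus {s} has only {len(windows)} trials")
        t = windows[block]
        blocks.append(rec.responses[:, t.onset_frame : t.onset_frame + t.n_frames])
    return np.concatenate(blocks, axis=1)


def take_resting(
    rec: Recording,
    trim_start_s: float,
    trim_end_s: float,
    duration_s: float | None = None,
) -> np.ndarray:
    """Extract the untrialed resting-state window.

    The untrialed segment starts after the last trial window; ``trim_start_s``
    and ``trim_end_s`` seconds are discarded at its edges (excluding
    non-stationary transients), then the window is truncated to
    ``duration_s`` from its start (``None`` keeps everything after trimming).
    """
    fr = rec.frame_rate
    start = rec.trial_end + int(round(trim_start_s * fr))
    end = rec.n_frames - int(round(trim_end_s * fr))
    if duration_s is not None:
        need = int(round(duration_s * fr))
        if start + need > end:
            raise LengthError(
                f"requested {duration_s} s after trimming, only "
                f"{(end - start) / fr:.1f} s available"
            )
        end = start + need
    if end <= start:
        raise LengthError("resting segment shorter than the requested trims")
    return rec.responses[:, start:end]


def zscore_rows(X: np.ndarray) -> np.ndarray:
    """Per-unit z-score across time; constant rows are mapped to zeros."""
    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    """Eigendecomposition of the 1/n time-axis covariance.

    ``components`` holds the kept eigenvectors as columns (orthonormal);
    ``eigenvalues`` is the full descending spectrum that was computed;
    ``total_variance`` is the trace of the covariance, so the eigenvalue mass
    equals it whenever the spectrum is complete.
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    n_kept: int
    total_variance: float

    @property
    def explained_fraction(self) -> float:
        return float(self.eigenvalues[: self.n_kept].sum() / self.total_variance)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Scale each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(components), axis=0)
    signs = np.sign(components[idx, np.arange(components.shape[1])])
    signs[signs == 0] = 1.0
    return components * signs


def fit_pca(
    X: np.ndarray,
    n_kept: int | float = 0.95,
    max_components: int = 50,
) -> PCAModel:
    """Fit PCA over the time axis of a units x timepoints matrix.

    ``n_kept`` is either an explicit component count or a variance fraction
    in (0, 1); in the latter case the smallest K whose eigenvalue mass
    reaches the fraction is kept, capped at ``max_components``. Covariance
    uses 1/n normalization.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 units and 2 timepoints")
    n, T = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float(np.sum(Xc * Xc) / n)
    if total_var <= 1e-300:
        raise DegenerateCovarianceError("data are constant: zero covariance")

    max_rank = min(n, T)
    if T <= _EXACT_DIM_LIMIT:
        cov = Xc.T @ Xc / n
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
    elif n <= _EXACT_DIM_LIMIT:
        gram = Xc @ Xc.T / n
        gvals, gvecs = np.linalg.eigh(gram)
        gvals, gvecs = gvals[::-1], gvecs[:, ::-1]
        keep = gvals > 1e-12 * gvals[0]
        evals = gvals
        evecs = Xc.T @ (gvecs[:, keep] / np.sqrt(n * gvals[keep]))
    else:
        # large in both dimensions: seeded randomized SVD of the centered data
        k = min(max_components, max_rank - 1)
        _, svals, vt = randomized_svd(Xc, n_components=k, n_oversamples=15, random_state=0)
        evals = svals**2 / n
        evecs = vt.T
    evals = np.clip(evals, 0.0, None)

    if isinstance(n_kept, (int, np.integer)) and not isinstance(n_kept, bool):
        K = int(n_kept)
        if K < 1:
            raise ValidationError("n_kept must be >= 1")
        K = min(K, max_rank, evecs.shape[1])
    else:
        frac = float(n_kept)
        if not 0 < frac < 1:
            raise ValidationError("variance fraction must lie in (0, 1)")
        cum = np.cumsum(evals[: evecs.shape[1]])
        reached = np.searchsorted(cum, frac * total_var) + 1
        K = int(min(reached, max_components, max_rank, evecs.shape[1]))

    components = _fix_signs(evecs[:, :K])
    return PCAModel(
        mean=mean,
        components=components,
        eigenvalues=evals,
        n_kept=K,
        total_variance=total_var,
    )


def project_pca(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Principal coordinates: (X - mean) V[:, :K]."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.mean.shape[0]:
        raise ValidationError(
            f"expected {model.mean.shape[0]} timepoints, got {X.shape[1]}"
        )
    return (X - model.mean) @ model.components


def reconstruct_pca(model: PCAModel, scores: np.ndarray, add_mean: bool = False) -> np.ndarray:
    """Map principal coordinates back to the time basis."""
    rec = np.asarray(scores) @ model.components.T
    return rec + model.mean if add_mean else rec


# ---------------------------------------------------------------------------
# LDA


@dataclass
class LDAModel:
    """Fisher discriminant directions maximizing between-area scatter.

    ``projection`` columns are the discriminant directions (unit Euclidean
    norm, largest-magnitude entry positive); at most C-1 are usable for C
    areas present in the training labels.
    """

    projection: np.ndarray
    class_means: dict[int, np.ndarray]
    global_mean: np.ndarray
    n_dims: int
    classes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def fit_lda(
    F: np.ndarray,
    labels: np.ndarray,
    n_dims: int | None = None,
    ridge_condition: float = 1e8,
) -> LDAModel:
    """Fit LDA on reduced features.

    Between-class scatter is the 1/C-normalized outer-product sum of class
    mean deviations; the denominator is the *total* covariance of the
    features (1/n), ridge-regularized by tau*I with
    tau = 1e-6 * trace / K when its condition number exceeds
    ``ridge_condition``.
    """
    F = np.asarray(F, dtype=np.float64)
    labels = np.asarray(labels)
    if F.ndim != 2 or F.shape[0] != labels.shape[0]:
        raise ValidationError("features and labels must align")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ClassSizeError("LDA needs at least 2 classes")
    counts = {int(c): int((labels == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise ClassSizeError(f"classes with < 2 samples: {small}")

    n, K = F.shape
    mu = F.mean(axis=0)
    class_means = {int(c): F[labels == c].mean(axis=0) for c in classes}
    C = classes.size
    dev = np.stack([class_means[int(c)] - mu for c in classes])
    Sb = dev.T @ dev / C
    if np.abs(Sb).max() <= 1e-12 * max(np.abs(F).max() ** 2, 1.0):
        raise DegenerateCovarianceError("all class means identical: zero between-class scatter")

    Fc = F - mu
    Sigma = Fc.T @ Fc / n
    svals = np.linalg.eigvalsh(Sigma)
    if svals[0] <= 0 or svals[-1] / max(svals[0], 1e-300) > ridge_condition:
        tau = 1e-6 * np.trace(Sigma) / K
        if tau <= 0:
            tau = 1e-10
        Sigma = Sigma + tau * np.eye(K)

    evals, evecs = scipy.linalg.eigh(Sb, Sigma)
    order = np.argsort(evals)[::-1]
    N = min(C - 1, K) if n_dims is None else min(n_dims, C - 1, K)
    W = evecs[:, order[:N]]
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    W = _fix_signs(W)
    return LDAModel(
        projection=W,
        class_means=class_means,
        global_mean=mu,
        n_dims=N,
        classes=classes,
    )


def project_lda(model: LDAModel, F: np.ndarray) -> np.ndarray:
    """Discriminant coordinates: (F - global mean) W."""
    F = np.asarray(F, dtype=np.float64)
    if F.ndim == 1:
        F = F[None, :]
    if F.shape[1] != model.global_mean.shape[0]:
        raise ValidationError(
            f"expected {model.global_mean.shape[0]} features, got {F.shape[1]}"
        )
    return (F - model.global_mean) @ model.projection


# ---------------------------------------------------------------------------
# pipeline helpers


@dataclass
class FeatureSet:
    """Reduced features aligned with a recording's unit order."""

    features: np.ndarray
    labels: np.ndarray
    transform_chain: dict = field(default_factory=dict)


def fit_transform_pipeline(
    X: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray | None = None,
    n_pcs: int | float = 0.95,
    max_pcs: int = 50,
    use_lda: bool = True,
    zscore: bool = True,
) -> tuple[FeatureSet, PCAModel, LDAModel | None]:
    """Z-score, then fit PCA (and LDA) on the training units only and
    transform every unit.

    ``train_idx`` defaults to all units. Returns the full-cohort FeatureSet
    plus the fitted transforms; no test-unit statistics enter the fits.
    """
    labels = np.asarray(labels)
    if train_idx is None:
        train_idx = np.arange(X.shape[0])
    Z = zscore_rows(X) if zscore else np.asarray(X, dtype=np.float64)
    pca = fit_pca(Z[train_idx], n_kept=n_pcs, max_components=max_pcs)
    P = project_pca(pca, Z)
    lda = None
    feats = P
    if use_lda:
        lda = fit_lda(P[train_idx], labels[train_idx])
        feats = project_lda(lda, P)
    fs = FeatureSet(
        features=feats,
        labels=labels,
        transform_chain={
            "zscore": zscore,
            "n_pcs": pca.n_kept,
            "n_lda": None if lda is None else lda.n_dims,
        },
    )
    return fs, pca, lda
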