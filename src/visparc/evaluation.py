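"""Evaluation protocols: splits, accuracy, chance levels, correlations, sweeps.

The supervised protocol samples a per-area training fraction (about 5% of
pixels for wide-field data, where neighboring pixels are correlated; 50% of
neurons for two-photon data, where few cells per area are available), fits
the PCA->LDA front end and a classifier on the training units only, and
scores held-out units by rank-1 accuracy, averaged over several random
initializations. Controls include a label-shuffle mode (training labels
permuted, test labels intact), radius-restricted training (training pixels
confined to the center of each area), and two random-guesser chance levels:
an unbiased one (100/C %) and a size-biased one (100 * sum p_i^2 %, the
accuracy of a die biased by area size).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .classifiers import fit_classifier
from .errors import RadiusError, ValidationError
from .features import FeatureSet, single_trial, take_resting, trial_average
from .types import AREA_CODES, Recording

logger = logging.getLogger(__name__)

#: Per-area neuron counts of the public two-photon (Allen Brain Observatory)
#: sessions analysed with this pipeline; keys use the canonical area codes
#: (1=V1, 2=LM, 3=AL, 4=RL, 5=AM, 6=PM). These unbalanced counts are the
#: worked example for the size-biased chance level.
ALLEN_NEURON_COUNTS: dict[str, dict[int, int]] = {
    "Emx1-IRES (Session A)": {3: 1235, 2: 1446, 4: 1963, 5: 241, 6: 536, 1: 2199},
    "Emx1-IRES (Session C2)": {3: 1148, 2: 1238, 4: 2085, 5: 226, 6: 552, 1: 964},
    "Nr5a1 (Session A)": {3: 178, 2: 256, 4: 1074, 5: 110, 6: 203, 1: 441},
    "Nr5a1 (Session C2)": {3: 106, 2: 267, 4: 1023, 5: 115, 6: 234, 1: 149},
}


# ---------------------------------------------------------------------------
# splits


@dataclass
class SplitSpec:
    """How to divide units into training and test sets.

    ``mode`` is ``fraction_per_area`` (simple per-area random sample),
    ``radius_restricted`` (training confined to the central
    ``sample_radius_frac`` of each area's radius) or ``shuffle_control``
    (fraction split with training labels permuted).
    """

    mode: str = "fraction_per_area"
    train_fraction: float = 0.05
    sample_radius_frac: float = 1.0
    n_repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        if self.mode not in ("fraction_per_area", "radius_restricted", "shuffle_control"):
            raise ValidationError(f"unknown split mode {self.mode!r}")
        if not 0 < self.sample_radius_frac <= 1:
            raise ValidationError("sample_radius_frac must lie in (0, 1]")


class Split(NamedTuple):
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_labels: np.ndarray  # shuffled in shuffle_control mode


def _area_pole_and_radius(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Interior pole (distance-transform argmax) and radius of one area."""
    rmin, cmin = coords.min(axis=0)
    local = coords - [rmin, cmin]
    shape = local.max(axis=0) + 1
    mask = np.zeros(shape, dtype=bool)
    mask[local[:, 0], local[:, 1]] = True
    # 1-pixel zero pad: everything outside the area counts as background
    dist = ndimage.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1]
    pole_local = np.unravel_index(np.argmax(dist), dist.shape)
    radius = float(dist[pole_local])
    return np.array([pole_local[0] + rmin, pole_local[1] + cmin]), radius


def split(
    labels: np.ndarray,
    coords: np.ndarray | None,
    spec: SplitSpec,
    seed: int | None = None,
) -> Split:
    """Per-area train/test split (see :class:`SplitSpec` for the modes)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    classes = np.unique(labels)
    train: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise ValidationError(f"area {c} has fewer than 2 units")
        n_tr = int(np.clip(round(spec.train_fraction * idx.size), 1, idx.size - 1))
        if spec.mode == "radius_restricted":
            if coords is None:
                raise ValidationError("radius-restricted split requires unit coordinates")
            pole, radius = _area_pole_and_radius(coords[idx])
            d = np.linalg.norm(coords[idx] - pole, axis=1)
            eligible = idx[d <= spec.sample_radius_frac * radius]
            if eligible.size == 0:
                raise RadiusError(
                    f"area {c}: no pixels within {spec.sample_radius_frac:.2f} of the radius"
                )
            n_tr = min(n_tr, eligible.size)
            train.append(rng.choice(eligible, size=n_tr, replace=False))
        else:
            train.append(rng.choice(idx, size=n_tr, replace=False))
    train_idx = np.sort(np.concatenate(train))
    test_idx = np.setdiff1d(np.arange(labels.size), train_idx)
    train_labels = labels[train_idx].copy()
    if spec.mode == "shuffle_control":
        train_labels = rng.permutation(train_labels)
    return Split(train_idx, test_idx, train_labels)


# ---------------------------------------------------------------------------
# metrics


def accuracy(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Rank-1 accuracy in percent."""
    actual, predicted = np.asarray(actual), np.asarray(predicted)
    if actual.shape != predicted.shape or actual.size == 0:
        raise ValidationError("actual and predicted must be equal-length, nonempty")
    return 100.0 * float(np.mean(actual == predicted))


def confusion(
    actual: np.ndarray,
    predicted: np.ndarray,
    classes: Iterable[int] = AREA_CODES,
    normalize: str = "by_actual",
) -> pd.DataFrame:
    """Confusion matrix in percent; rows are actual classes, columns predicted.

    Each row with a present actual class sums to 100; absent classes yield a
    zero row (logged).
    """
    classes = list(classes)
    actual, predicted = np.asarray(actual), np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ValidationError("length mismatch")
    if not set(np.unique(actual)) <= set(classes) or not set(np.unique(predicted)) <= set(classes):
        raise ValidationError("labels outside the declared class set")
    counts = np.zeros((len(classes), len(classes)))
    pos = {c: i for i, c in enumerate(classes)}
    for a, p in zip(actual, predicted):
        counts[pos[int(a)], pos[int(p)]] += 1
    if normalize != "by_actual":
        raise ValidationError("only by_actual normalization is supported")
    row_sums = counts.sum(axis=1)
    for i, c in enumerate(classes):
        if row_sums[i] == 0:
            logger.warning("confusion: actual class %s absent; zero row emitted", c)
        else:
            counts[i] = 100.0 * counts[i] / row_sums[i]
    return pd.DataFrame(counts, index=classes, columns=classes)


def chance_unbiased(n_classes: int) -> float:
    """Accuracy of an unbiased C-faced die, rounded to 2 decimals (percent)."""
    if n_classes < 2:
        raise ValidationError("need at least 2 classes")
    return round(100.0 / n_classes, 2)


def chance_biased_raw(class_counts: dict[int, int]) -> float:
    """Untruncated size-biased chance: 100 * sum p_i^2 (percent)."""
    counts = np.array(list(class_counts.values()), dtype=float)
    if counts.size < 2 or (counts < 1).any():
        raise ValidationError("need >= 2 classes with counts >= 1")
    p = counts / counts.sum()
    return 100.0 * float(np.sum(p**2))


def chance_biased(class_counts: dict[int, int]) -> float:
    """Size-biased chance level, truncated to 1 decimal (percent).

    This is the accuracy of a die biased by the class proportions (area
    sizes, or unit counts used during training). Truncation -- not rounding
    -- to one decimal is the reporting convention for this quantity.
    """
    return math.floor(chance_biased_raw(class_counts) * 10.0) / 10.0


@dataclass
class CorrelationSummary:
    """Mean pairwise Pearson correlation within vs between areas."""

    intra: float
    inter: float
    ratio: float
    ratio_defined: bool
    n_intra_pairs: int
    n_inter_pairs: int
    n_excluded_units: int = 0


def correlation_analysis(X: np.ndarray, labels: np.ndarray) -> CorrelationSummary:
    """Average Pearson correlation over all unique unit pairs.

    ``intra`` averages same-area pairs, ``inter`` different-area pairs;
    ``ratio = intra / inter`` is flagged undefined (and reported as +inf,
    i.e. maximal intra/inter contrast) when ``inter <= 0``. Constant-trace
    units are excluded and counted.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValidationError("responses and labels must align")
    if X.shape[1] < 3:
        raise ValidationError("need at least 3 timepoints/dimensions")
    keep = X.std(axis=1) > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("correlation_analysis: excluded %d constant units", n_excluded)
    X, labels = X[keep], labels[keep]
    if np.unique(labels).size < 2 or X.shape[0] < 2:
        raise ValidationError("need >= 2 units in >= 2 areas")
    corr = np.corrcoef(X)
    iu = np.triu_indices(X.shape[0], k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = corr[iu]
    intra_vals, inter_vals = vals[same], vals[~same]
    intra = float(intra_vals.mean()) if intra_vals.size else float("nan")
    inter = float(inter_vals.mean()) if inter_vals.size else float("nan")
    defined = np.isfinite(inter) and inter > 0 and np.isfinite(intra)
    ratio = intra / inter if defined else float("inf")
    return CorrelationSummary(
        intra=intra,
        inter=inter,
        ratio=ratio,
        ratio_defined=bool(defined),
        n_intra_pairs=int(intra_vals.size),
        n_inter_pairs=int(inter_vals.size),
        n_excluded_units=n_excluded,
    )


# ---------------------------------------------------------------------------
# supervised protocol


@dataclass
class EvalReport:
    """Accuracy of one classifier under one split protocol."""

    classifier: str
    accuracies: list[float]
    mean: float
    sd: float
    confusion: pd.DataFrame
    chance_unbiased: float
    chance_biased: float
    n_repeats: int
    stimulus: str = "all"
    correlation: CorrelationSummary | None = None

    def to_dict(self) -> dict:
        d = {
            "classifier": self.classifier,
            "stimulus": self.stimulus,
            "accuracies": [float(a) for a in self.accuracies],
            "mean": float(self.mean),
            "sd": float(self.sd),
            "chance_unbiased": self.chance_unbiased,
            "chance_biased": self.chance_biased,
            "n_repeats": self.n_repeats,
        }
        return d

    def summary(self) -> str:
        return (
            f"{self.classifier}: {self.mean:.1f} (+/-{self.sd:.2f}) % over "
            f"{self.n_repeats} repeats; chance {self.chance_unbiased:.2f} "
            f"(unbiased) / {self.chance_biased:.1f} (size-biased) %"
        )


def _evaluate_matrix(
    X: np.ndarray,
    labels: np.ndarray,
    coords: np.ndarray | None,
    classifier: str,
    spec: SplitSpec,
    n_pcs: int | float = 0.95,
    max_pcs: int = 50,
    use_lda: bool = True,
    classifier_kwargs: dict | None = None,
    stimulus: str = "all",
) -> EvalReport:
    classifier_kwargs = dict(classifier_kwargs or {})
    accs: list[float] = []
    all_actual: list[np.ndarray] = []
    all_pred: list[np.ndarray] = []
    train_counts: dict[int, int] = {}
    for r in range(spec.n_repeats):
        rep_seed = int(spec.seed + r) % (2**31 - 1)
        sp = split(labels, coords, spec, seed=rep_seed)
        # LDA and the classifier both see the labels the split provides
        # (the true ones, or the permuted ones in shuffle_control mode).
        fs, _, _ = _refit_with_labels(X, labels, sp, n_pcs, max_pcs, use_lda)
        clf = fit_classifier(
            classifier, fs.features[sp.train_idx], sp.train_labels, seed=rep_seed,
            **classifier_kwargs,
        )
        pred = clf.predict(fs.features[sp.test_idx])
        actual = labels[sp.test_idx]
        accs.append(accuracy(actual, pred))
        all_actual.append(actual)
        all_pred.append(pred)
        for c, n in zip(*np.unique(sp.train_labels, return_counts=True)):
            train_counts[int(c)] = train_counts.get(int(c), 0) + int(n)
    conf = confusion(np.concatenate(all_actual), np.concatenate(all_pred))
    classes = np.unique(labels)
    return EvalReport(
        classifier=classifier,
        accuracies=accs,
        mean=float(np.mean(accs)),
        sd=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        confusion=conf,
        chance_unbiased=chance_unbiased(classes.size),
        chance_biased=chance_biased(train_counts),
        n_repeats=spec.n_repeats,
        stimulus=stimulus,
    )


def _refit_with_labels(X, labels, sp: Split, n_pcs, max_pcs, use_lda: bool = True):
    """Z-score + PCA + LDA, with LDA seeing the training labels of the split."""
    from .features import fit_lda, fit_pca, project_lda, project_pca, zscore_rows

    Z = zscore_rows(X)
    pca = fit_pca(Z[sp.train_idx], n_kept=n_pcs, max_components=max_pcs)
    P = project_pca(pca, Z)
    lda = None
    feats = P
    if use_lda:
        lda = fit_lda(P[sp.train_idx], sp.train_labels)
        feats = project_lda(lda, P)
    return FeatureSet(features=feats, labels=np.asarray(labels)), pca, lda


def _response_matrix(
    rec: Recording,
    stimuli: Iterable[int] | None,
    resting: tuple[float, float, float | None] | None,
    single: bool = False,
) -> tuple[np.ndarray, str]:
    if resting is not None:
        trim0, trim1, dur = resting
        return take_resting(rec, trim0, trim1, dur), "resting"
    if single:
        return single_trial(rec, stimuli), "single_trial"
    return trial_average(rec, stimuli), "trial_averaged"


def run_supervised(
    rec: Recording,
    classifier: str,
    spec: SplitSpec,
    stimuli: Iterable[int] | None = None,
    resting: tuple[float, float, float | None] | None = None,
    n_pcs: int | float = 0.95,
    max_pcs: int = 50,
    classifier_kwargs: dict | None = None,
) -> EvalReport:
    """Run the full supervised protocol on a recording.

    Uses trial-averaged responses of ``stimuli`` (default: all) or, if
    ``resting=(trim_start_s, trim_end_s, duration_s)`` is given, the
    untrialed resting window. Background units (label 0) are excluded. Per
    repeat, the split, the PCA+LDA front end (training units only) and the
    classifier are all refit.
    """
    X, stim_name = _response_matrix(rec, stimuli, resting)
    in_map = rec.unit_labels > 0
    coords = rec.unit_coords[in_map] if rec.unit_coords is not None else None
    return _evaluate_matrix(
        X[in_map],
        rec.unit_labels[in_map],
        coords,
        classifier,
        spec,
        n_pcs=n_pcs,
        max_pcs=max_pcs,
        classifier_kwargs=classifier_kwargs,
        stimulus=stim_name,
    )


def duration_sweep(
    rec: Recording,
    durations_s: Iterable[float],
    conditions: Iterable[str] = ("trial_averaged", "single_trial", "resting"),
    classifier: str = "gmm",
    spec: SplitSpec | None = None,
    resting_trims: tuple[float, float] = (10.0, 10.0),
) -> pd.DataFrame:
    """Accuracy as a function of response duration per condition.

    For ``trial_averaged``/``single_trial`` the concatenated stimulus
    response is truncated to the requested duration; ``resting`` uses an
    untrialed window of that duration. Durations exceeding the available
    data yield a flagged (NaN) row rather than an error.
    """
    spec = spec or SplitSpec()
    in_map = rec.unit_labels > 0
    labels = rec.unit_labels[in_map]
    coords = rec.unit_coords[in_map] if rec.unit_coords is not None else None
    rows = []
    for condition in conditions:
        if condition in ("trial_averaged", "single_trial"):
            X_full, _ = _response_matrix(
                rec, None, None, single=condition == "single_trial"
            )
            X_full = X_full[in_map]
        elif condition != "resting":
            raise ValidationError(f"unknown condition {condition!r}")
        for dur in durations_s:
            n_frames = int(round(dur * rec.frame_rate))
            try:
                if condition == "resting":
                    X = take_resting(rec, resting_trims[0], resting_trims[1], dur)[in_map]
                else:
                    if n_frames > X_full.shape[1]:
                        raise ValidationError("duration exceeds stimulus response")
                    X = X_full[:, :n_frames]
                report = _evaluate_matrix(X, labels, coords, classifier, spec)
                rows.append(
                    {
                        "condition": condition,
                        "duration_s": float(dur),
                        "mean_accuracy": report.mean,
                        "sd_accuracy": report.sd,
                        "n_frames": X.shape[1],
                        "skipped": False,
                    }
                )
            except ValidationError as exc:
                logger.warning("sweep cell (%s, %ss) skipped: %s", condition, dur, exc)
                rows.append(
                    {
                        "condition": condition,
                        "duration_s": float(dur),
                        "mean_accuracy": float("nan"),
                        "sd_accuracy": float("nan"),
                        "n_frames": 0,
                        "skipped": True,
                    }
                )
    return pd.DataFrame(rows)


def resting_duration_trend(table: pd.DataFrame) -> float:
    """Spearman rank correlation of resting accuracy against duration."""
    sub = table[(table["condition"] == "resting") & (~table["skipped"])]
    if len(sub) < 3:
        raise ValidationError("need >= 3 resting durations for a trend")
    if sub["mean_accuracy"].nunique() == 1:
        return 0.0  # flat (e.g. saturated) accuracy: no trend either way
    rho, _ = stats.spearmanr(sub["duration_s"], sub["mean_accuracy"])
    return float(rho)
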