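"""Four supervised area classifiers with a common fit/predict contract.

All four map a reduced feature vector to one of the six area codes:

* ``fit_bayes`` -- unimodal Gaussian per area, maximum-likelihood mean and
  1/n covariance, equal class priors (so the Bayes rule reduces to the
  maximum-likelihood rule);
* ``fit_gmm`` -- a separate Gaussian mixture per area, EM-trained;
* ``fit_svm`` -- one-against-one support-vector machines (15 pairwise
  machines for 6 classes) with majority voting;
* ``fit_ann`` -- a single-hidden-layer network (30 tanh units) with a
  softmax output trained on cross-entropy.

Ties everywhere break to the lowest area code, which makes predictions
reproducible. Train/test protocol is deliberately *not* handled here; see
:mod:`visparc.evaluation`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from ._gmm import GaussianMixture, _floor_full, fit_gaussian_mixture
from .errors import (
    CapacityError,
    ClassSizeError,
    MissingClassError,
    ValidationError,
    VisparcError,
)
from .features import FeatureSet


def _unpack(F, labels):
    if isinstance(F, FeatureSet):
        return np.asarray(F.features, dtype=np.float64), np.asarray(F.labels)
    if labels is None:
        raise ValidationError("labels required when features are a bare matrix")
    return np.asarray(F, dtype=np.float64), np.asarray(labels)


def _check_classes(classes: np.ndarray, expected_classes=None) -> None:
    if classes.size < 2:
        raise ClassSizeError("need at least 2 classes")
    if expected_classes is not None:
        missing = sorted(set(int(c) for c in expected_classes) - set(int(c) for c in classes))
        if missing:
            raise MissingClassError(f"areas absent from training labels: {missing}")


def _argmax_lowest(scores: np.ndarray, classes: np.ndarray) -> np.ndarray:
    # np.argmax returns the first maximum; classes are sorted ascending,
    # so exact ties resolve to the lowest area code.
    return classes[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------


@dataclass
class GaussianClassModel:
    """Per-area Gaussian densities (unimodal Bayes classifier)."""

    classes: np.ndarray
    means: dict[int, np.ndarray]
    covariances: dict[int, np.ndarray]
    _densities: dict[int, GaussianMixture] = field(default_factory=dict, repr=False)

    def score_matrix(self, F: np.ndarray) -> np.ndarray:
        """Per-class log-likelihoods, columns ordered by ascending code."""
        F = np.atleast_2d(np.asarray(F, dtype=np.float64))
        return np.column_stack([self._densities[int(c)].log_density(F) for c in self.classes])

    def predict(self, F: np.ndarray) -> np.ndarray:
        return _argmax_lowest(self.score_matrix(F), self.classes)


def fit_bayes(F, labels=None, expected_classes=None) -> GaussianClassModel:
    """MLE Gaussian per area: sample mean and 1/n covariance (floored to PD)."""
    X, y = _unpack(F, labels)
    classes = np.unique(y)
    _check_classes(classes, expected_classes)
    means, covs, dens = {}, {}, {}
    for c in classes:
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ClassSizeError(f"area {c} has {Xc.shape[0]} training sample(s)")
        mu = Xc.mean(axis=0)
        d = Xc - mu
        cov = _floor_full(d.T @ d / Xc.shape[0])
        means[int(c)], covs[int(c)] = mu, cov
        dens[int(c)] = GaussianMixture(
            weights=np.array([1.0]), means=mu[None, :], covariances=cov[None, :, :]
        )
    return GaussianClassModel(classes=classes, means=means, covariances=covs, _densities=dens)


@dataclass
class GMMModel:
    """Per-area Gaussian mixtures (multimodal Bayes classifier)."""

    classes: np.ndarray
    mixtures: dict[int, GaussianMixture]
    n_components: int

    def score_matrix(self, F: np.ndarray) -> np.ndarray:
        F = np.atleast_2d(np.asarray(F, dtype=np.float64))
        return np.column_stack([self.mixtures[int(c)].log_density(F) for c in self.classes])

    def predict(self, F: np.ndarray) -> np.ndarray:
        return _argmax_lowest(self.score_matrix(F), self.classes)


def fit_gmm(
    F,
    labels=None,
    n_components: int = 4,
    seed: int = 0,
    expected_classes=None,
    capacity_guard: bool = True,
) -> GMMModel:
    """EM-fit one mixture per area from a seeded k-means initialization.

    A full-covariance component in d dimensions needs on the order of 2d
    samples for a stable estimate; with fewer, component variances collapse
    toward the floor and the model rejects its own class's held-out data.
    ``capacity_guard`` therefore caps the per-area component count at
    n_area // (2 d) (never below 1); requesting more components than
    samples is still an error.
    """
    X, y = _unpack(F, labels)
    classes = np.unique(y)
    _check_classes(classes, expected_classes)
    d = X.shape[1]
    mixtures = {}
    for c in classes:
        Xc = X[y == c]
        if Xc.shape[0] < n_components:
            raise CapacityError(
                f"area {c}: {n_components} mixture components exceed "
                f"{Xc.shape[0]} training samples"
            )
        m = n_components
        if capacity_guard:
            m = max(1, min(n_components, Xc.shape[0] // (2 * d)))
        mixtures[int(c)] = fit_gaussian_mixture(Xc, m, seed=seed)
    return GMMModel(classes=classes, mixtures=mixtures, n_components=n_components)


@dataclass
class SVMModel:
    """One-against-one SVMs with majority voting.

    Backed by LIBSVM; prediction recomputes the pairwise votes from the
    decision function so the documented lowest-code tie-break is exact.
    """

    classes: np.ndarray
    svc: SVC
    kernel: str
    C: float

    def score_matrix(self, F: np.ndarray) -> np.ndarray:
        """Pairwise vote counts per class."""
        F = np.atleast_2d(np.asarray(F, dtype=np.float64))
        df = self.svc.decision_function(F)
        if df.ndim == 1:
            df = df[:, None]
        n_classes = self.classes.size
        if n_classes == 2:
            # sklearn collapses ovo to one column; positive favors the 2nd class
            votes = np.zeros((F.shape[0], 2))
            votes[:, 1] = (df[:, 0] > 0).astype(float)
            votes[:, 0] = 1.0 - votes[:, 1]
            return votes
        votes = np.zeros((F.shape[0], n_classes))
        col = 0
        for i in range(n_classes):
            for j in range(i + 1, n_classes):
                wins_i = df[:, col] > 0
                votes[wins_i, i] += 1
                votes[~wins_i, j] += 1
                col += 1
        return votes

    def predict(self, F: np.ndarray) -> np.ndarray:
        return _argmax_lowest(self.score_matrix(F), self.classes)


def fit_svm(
    F,
    labels=None,
    C: float = 1.0,
    kernel: str = "rbf",
    gamma="scale",
    expected_classes=None,
) -> SVMModel:
    """Fit one-against-one SVMs (``gamma='scale'`` is 1 / (N * var(F)))."""
    if C <= 0:
        raise ValidationError("C must be positive")
    if kernel not in ("linear", "rbf"):
        raise ValidationError("kernel must be 'linear' or 'rbf'")
    X, y = _unpack(F, labels)
    classes = np.unique(y)
    _check_classes(classes, expected_classes)
    svc = SVC(C=C, kernel=kernel, gamma=gamma, decision_function_shape="ovo")
    svc.fit(X, y)
    return SVMModel(classes=classes, svc=svc, kernel=kernel, C=C)


@dataclass
class ANNModel:
    """Single-hidden-layer network (30 tanh units, softmax output)."""

    classes: np.ndarray
    mlp: MLPClassifier
    epochs: int
    lr: float
    seed: int

    def score_matrix(self, F: np.ndarray) -> np.ndarray:
        """Softmax class probabilities (rows sum to 1)."""
        F = np.atleast_2d(np.asarray(F, dtype=np.float64))
        return self.mlp.predict_proba(F)

    def predict(self, F: np.ndarray) -> np.ndarray:
        return _argmax_lowest(self.score_matrix(F), self.classes)

    @property
    def loss_curve(self) -> list[float]:
        return list(self.mlp.loss_curve_)


def fit_ann(
    F,
    labels=None,
    epochs: int = 500,
    lr: float = 0.01,
    seed: int = 0,
    hidden_units: int = 30,
    batch_size: int = 32,
    expected_classes=None,
) -> ANNModel:
    """Train the 30-unit network by mini-batch gradient descent on cross-entropy."""
    X, y = _unpack(F, labels)
    classes = np.unique(y)
    _check_classes(classes, expected_classes)
    mlp = MLPClassifier(
        hidden_layer_sizes=(hidden_units,),
        activation="tanh",
        solver="sgd",
        learning_rate_init=lr,
        max_iter=epochs,
        batch_size=min(batch_size, X.shape[0]),
        random_state=seed,
        momentum=0.9,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        mlp.fit(X, y)
    if not np.isfinite(mlp.loss_):
        raise VisparcError(
            "ANN training diverged (non-finite loss); try a smaller learning rate"
        )
    return ANNModel(classes=classes, mlp=mlp, epochs=epochs, lr=lr, seed=seed)


# ---------------------------------------------------------------------------

Classifier = GaussianClassModel | GMMModel | SVMModel | ANNModel

_FITTERS = {"bayes": fit_bayes, "gmm": fit_gmm, "svm": fit_svm, "ann": fit_ann}


def fit_classifier(name: str, F, labels=None, seed: int = 0, **kwargs) -> Classifier:
    """Fit one of the four classifiers by name (``bayes``/``gmm``/``svm``/``ann``)."""
    if name not in _FITTERS:
        raise ValidationError(f"unknown classifier {name!r}; choose from {sorted(_FITTERS)}")
    if name in ("gmm", "ann"):
        kwargs["seed"] = seed
    return _FITTERS[name](F, labels, **kwargs)


def predict(model: Classifier, F: np.ndarray, return_scores: bool = False):
    """Predict area codes (optionally with the per-class score matrix)."""
    codes = model.predict(F)
    if return_scores:
        return codes, model.score_matrix(F)
    return codes
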