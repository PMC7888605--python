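"""Gaussian mixture engine: EM fitting, density evaluation, covariance flooring.

A single implementation backs both the per-area multimodal Bayes classifier
(full covariances, few components) and the universal background model used
for semi-supervised parcellation (diagonal covariances, many components).
EM starts from a seeded k-means partition, guarantees a non-decreasing
training log-likelihood, and floors covariance eigenvalues so degenerate
(e.g. noise-free) inputs stay positive-definite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .errors import CapacityError, ValidationError

_REL_FLOOR = 1e-6
_ABS_FLOOR = 1e-10
_LOG2PI = float(np.log(2.0 * np.pi))


def _floor_full(cov: np.ndarray) -> np.ndarray:
    """Clip covariance eigenvalues from below; keeps the matrix PD."""
    cov = 0.5 * (cov + cov.T)
    evals, evecs = np.linalg.eigh(cov)
    floor = max(_REL_FLOOR * max(evals.mean(), 0.0), _ABS_FLOOR)
    evals = np.clip(evals, floor, None)
    return (evecs * evals) @ evecs.T


def _floor_diag(var: np.ndarray) -> np.ndarray:
    floor = max(_REL_FLOOR * max(var.mean(), 0.0), _ABS_FLOOR)
    return np.clip(var, floor, None)


@dataclass
class GaussianMixture:
    """A fitted mixture: weights ``w_k``, means, covariances.

    ``covariances`` is (M, K, K) for ``cov_type='full'`` or (M, K) of
    variances for ``'diag'``. ``log_likelihood_trace`` records the total
    training log-likelihood per EM iteration.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    cov_type: str = "full"
    log_likelihood_trace: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def component_log_density(self, X: np.ndarray) -> np.ndarray:
        """log N(x | mu_k, Sigma_k) for every point and component -> (n, M)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValidationError(
                f"expected {self.n_features}-dim features, got {X.shape[1]}"
            )
        n, K = X.shape
        out = np.empty((n, self.n_components))
        if self.cov_type == "diag":
            for k in range(self.n_components):
                var = self.covariances[k]
                diff2 = (X - self.means[k]) ** 2 / var
                out[:, k] = -0.5 * (K * _LOG2PI + np.log(var).sum() + diff2.sum(axis=1))
        else:
            for k in range(self.n_components):
                L = np.linalg.cholesky(self.covariances[k])
                sol = np.linalg.solve(L, (X - self.means[k]).T)
                maha = np.sum(sol**2, axis=0)
                logdet = 2.0 * np.log(np.diag(L)).sum()
                out[:, k] = -0.5 * (K * _LOG2PI + logdet + maha)
        return out

    def log_density(self, X: np.ndarray) -> np.ndarray:
        """Mixture log-density log p(x | lambda) per point."""
        comp = self.component_log_density(X) + np.log(self.weights)
        return logsumexp(comp, axis=1)

    def responsibilities(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior component probabilities and the per-point log-density."""
        comp = self.component_log_density(X) + np.log(self.weights)
        total = logsumexp(comp, axis=1)
        return np.exp(comp - total[:, None]), total


def _init_from_kmeans(
    X: np.ndarray, M: int, seed: int, cov_type: str
) -> GaussianMixture:
    n, K = X.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        warnings.filterwarnings("ignore", message=".*distinct clusters.*")
        km = KMeans(n_clusters=M, n_init=1, random_state=seed).fit(X)
    assign = km.labels_
    weights, means, covs = [], [], []
    global_cov = np.cov(X, rowvar=False, bias=True).reshape(K, K)
    for k in range(M):
        sel = assign == k
        nk = int(sel.sum())
        if nk == 0:
            continue  # empty k-means cell: drop the component
        weights.append(nk / n)
        means.append(X[sel].mean(axis=0))
        if nk == 1:
            ck = global_cov
        else:
            d = X[sel] - X[sel].mean(axis=0)
            ck = d.T @ d / nk
        covs.append(_floor_full(ck))
    weights = np.asarray(weights)
    weights /= weights.sum()
    means = np.asarray(means)
    covs = np.asarray(covs)
    if cov_type == "diag":
        covs = np.stack([_floor_diag(np.diag(c)) for c in covs])
    return GaussianMixture(weights, means, covs, cov_type=cov_type)


def fit_gaussian_mixture(
    X: np.ndarray,
    n_components: int,
    seed: int = 0,
    cov_type: str = "full",
    tol: float = 1e-6,
    max_iter: int = 200,
) -> GaussianMixture:
    """EM-fit a Gaussian mixture from a seeded k-means initialization.

    Stops when the relative change in total log-likelihood falls below
    ``tol`` or after ``max_iter`` iterations; the recorded trace is
    non-decreasing up to floating-point noise. Components that lose all
    responsibility mass are dropped, so the fitted mixture may have fewer
    than ``n_components`` components on degenerate data.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = X.shape[0]
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    if n < n_components:
        raise CapacityError(f"{n_components} components exceed {n} samples")
    if cov_type not in ("full", "diag"):
        raise ValidationError("cov_type must be 'full' or 'diag'")

    gmm = _init_from_kmeans(X, n_components, seed, cov_type)
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        resp, logdens = gmm.responsibilities(X)
        ll = float(logdens.sum())
        trace.append(ll)
        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(ll):
            break
        prev = ll

        nk = resp.sum(axis=0)
        alive = nk > 1e-10
        if not alive.all():
            resp = resp[:, alive]
            nk = nk[alive]
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        if cov_type == "diag":
            ex2 = (resp.T @ (X**2)) / nk[:, None]
            covs = np.stack([_floor_diag(v) for v in (ex2 - means**2)])
        else:
            covs = []
            for k in range(means.shape[0]):
                d = X - means[k]
                ck = (resp[:, k][:, None] * d).T @ d / nk[k]
                covs.append(_floor_full(ck))
            covs = np.asarray(covs)
        gmm = GaussianMixture(weights, means, covs, cov_type=cov_type)
    gmm.log_likelihood_trace = trace
    return gmm
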