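"""Visual vocabulary: a K-component Gaussian mixture over HOG descriptors.

The vocabulary is fitted by expectation–maximization on the pooled
descriptors of the *training* images only.  Components use diagonal
covariances by default — with 144-dimensional descriptors and cohorts of
tens of images there are far too few keypoints to estimate full
covariances — with a variance floor to keep every component proper.

Per-descriptor scoring follows the mixture posterior: the weighted density
π_k·N(v | u_k, Σ_k) is evaluated in log space and normalized over
components with log-sum-exp, so responsibilities form a valid probability
simplex even for far outliers whose densities underflow in naive
arithmetic.  Normalization can be disabled to obtain the raw weighted
densities instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

__all__ = [
    "Vocabulary",
    "fit_gmm",
    "component_density",
    "responsibilities",
    "save_vocabulary",
    "load_vocabulary",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class Vocabulary:
    """Fitted mixture: weights π_k, means u_k, diagonal covariances Σ_k."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d) diagonal variances
    loglik_trace: np.ndarray  # total data log-likelihood per EM iteration
    seed: int

    def __post_init__(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("component weights must sum to 1")
        if np.any(self.covariances <= 0):
            raise ValueError("covariance diagonals must be positive")

    @property
    def K(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def log_weighted_densities(self, V: np.ndarray) -> np.ndarray:
        """log[π_k N(v | u_k, Σ_k)] for each row of V; shape (N, K)."""
        V = np.atleast_2d(np.asarray(V, dtype=np.float64))
        log_det = np.sum(np.log(self.covariances), axis=1)  # (K,)
        diff = V[:, None, :] - self.means[None, :, :]  # (N, K, d)
        maha = np.sum(diff * diff / self.covariances[None, :, :], axis=2)
        log_norm = -0.5 * (self.dim * _LOG_2PI + log_det)
        return np.log(self.weights)[None, :] + log_norm[None, :] - 0.5 * maha


def fit_gmm(
    descriptors: np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-3,
    variance_floor: float = 1e-6,
) -> Vocabulary:
    """Fit the K-component diagonal GMM by EM from a k-means++ start.

    EM runs one iteration at a time so the total data log-likelihood can be
    recorded after every step; it stops when the gain drops below ``tol``
    (absolute log-likelihood units) or after ``max_iter`` iterations.
    Deterministic for a given seed.
    """
    X = np.asarray(descriptors, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("descriptors must be a 2-D matrix")
    n = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < K:
        raise ValueError(
            f"{n} descriptors cannot support K={K} components; use a smaller K"
        )
    gm = GaussianMixture(
        n_components=K,
        covariance_type="diag",
        reg_covar=variance_floor,
        init_params="k-means++",
        random_state=int(seed) % (2**31),
        warm_start=True,
        max_iter=1,
        tol=0.0,
    )
    trace: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-step fits never "converge"
        for _ in range(max_iter):
            gm.fit(X)
            trace.append(float(gm.score(X) * n))
            if len(trace) > 1 and trace[-1] - trace[-2] < tol:
                break
    return Vocabulary(
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=np.maximum(gm.covariances_.copy(), variance_floor),
        loglik_trace=np.asarray(trace),
        seed=int(seed),
    )


def component_density(vocab: Vocabulary, v: np.ndarray, k: int) -> float:
    """Weighted component density π_k·N(v | u_k, Σ_k), log-space internally."""
    if not 0 <= k < vocab.K:
        raise IndexError(f"component index {k} out of range [0, {vocab.K})")
    return float(np.exp(vocab.log_weighted_densities(v)[0, k]))


def responsibilities(
    vocab: Vocabulary, v: np.ndarray, normalize: bool = True
) -> np.ndarray:
    """Posterior component probabilities for one descriptor or a matrix.

    With ``normalize=True`` (default) each row is the simplex vector
    p_k = π_k N(v) / Σ_k' π_k' N(v), computed with log-sum-exp; with
    ``normalize=False`` the raw weighted densities are returned.
    Accepts a single d-vector (returns shape (K,)) or an (N, d) matrix.
    """
    v = np.asarray(v, dtype=np.float64)
    single = v.ndim == 1
    log_wd = vocab.log_weighted_densities(v)
    if normalize:
        out = np.exp(log_wd - logsumexp(log_wd, axis=1, keepdims=True))
    else:
        out = np.exp(log_wd)
    return out[0] if single else out


def save_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    """Serialize to a single .npz container; round-trips bit-exactly."""
    np.savez(
        Path(path),
        weights=vocab.weights,
        means=vocab.means,
        covariances=vocab.covariances,
        loglik_trace=vocab.loglik_trace,
        seed=np.asarray(vocab.seed),
    )


def load_vocabulary(path: str | Path) -> Vocabulary:
    with np.load(Path(path)) as data:
        return Vocabulary(
            weights=data["weights"],
            means=data["means"],
            covariances=data["covariances"],
            loglik_trace=data["loglik_trace"],
            seed=int(data["seed"]),
        )
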