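"""Broad learning system, margin classifier, and their λ ensemble.

The broad learning system (BLS) is a wide, shallow network: the input code
U is expanded by ``n_map`` random affine feature-mapping groups
Z_zi = Φ(U·W_zi + β_zi), the concatenated mapping nodes feed a non-linear
enhancement layer H = ξ([Z_1..Z_n]·W_h + β_h), and the output weights on
A = [Z | H] are the ridge-regression minimizer of

    argmin_W ‖A·W − Y‖² + ε‖W‖²,   W = (AᵀA + εI)⁻¹ Aᵀ Y,

solved in closed form — no gradient training.  Random weights are drawn
once from a seeded generator, so the model is fully reproducible.

The margin classifier is an RBF-kernel SVM exposing the signed distance of
a sample to the separating hyperplane (positive toward the FGR class).
The ensemble blends the two probability readings per class j:

    Y_j = λ·softmax(Y_BLS)_j + (1−λ)·sigmoid(dist_j),

with dist_1 the signed distance and dist_0 its negation.  λ = 1 reduces to
the BLS alone and λ = 0 to the SVM alone; λ is either fixed (0.3 by
default) or selected on a validation split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, softmax
from sklearn.svm import SVC

__all__ = [
    "BlsModel",
    "MarginClassifier",
    "EnsembleModel",
    "fit_bls",
    "bls_scores",
    "svm_distance_to_prob",
    "ensemble_probability",
    "fit_ensemble",
    "DEFAULT_LAMBDA",
]

DEFAULT_LAMBDA = 0.3


@dataclass(frozen=True)
class BlsModel:
    """Fitted broad learning system (mapping, enhancement, output weights)."""

    map_weights: list[np.ndarray]  # n_map arrays (d, map_dim)
    map_offsets: list[np.ndarray]  # n_map arrays (map_dim,)
    enh_weights: np.ndarray  # (n_map*map_dim, m_enh)
    enh_offsets: np.ndarray  # (m_enh,)
    output_weights: np.ndarray  # (n_map*map_dim + m_enh, n_classes)
    eps: float
    seed: int

    @property
    def n_features_in(self) -> int:
        return self.map_weights[0].shape[0]


def _expand(model: BlsModel, X: np.ndarray) -> np.ndarray:
    """Forward pass through mapping and enhancement layers: A = [Z | H]."""
    Z = np.hstack([X @ W + b for W, b in zip(model.map_weights, model.map_offsets)])
    H = np.tanh(Z @ model.enh_weights + model.enh_offsets)
    return np.hstack([Z, H])


def fit_bls(
    X: np.ndarray,
    Y: np.ndarray,
    n_map: int = 10,
    map_dim: int = 10,
    m_enh: int = 100,
    eps: float = 1e-3,
    seed: int = 0,
) -> BlsModel:
    """Fit the BLS output weights in closed form.

    ``Y`` is a one-hot label matrix (or a label vector, which is one-hot
    encoded).  Mapping groups use an affine (identity-activation) expansion
    and the enhancement layer uses tanh; weights are drawn uniformly from
    [−1, 1] scaled by the fan-in, from a generator seeded with ``seed``.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y)
    if Y.ndim == 1:
        classes = np.unique(Y)
        if classes.size < 2:
            raise ValueError("training labels contain a single class")
        onehot = np.zeros((Y.shape[0], 2))
        onehot[np.arange(Y.shape[0]), Y.astype(int)] = 1.0
        Y = onehot
    elif np.unique(np.argmax(Y, axis=1)).size < 2:
        raise ValueError("training labels contain a single class")
    if eps <= 0:
        raise ValueError("ridge parameter eps must be > 0")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    rng = np.random.default_rng(seed)
    d = X.shape[1]
    map_weights = [rng.uniform(-1, 1, size=(d, map_dim)) / np.sqrt(d) for _ in range(n_map)]
    map_offsets = [rng.uniform(-1, 1, size=map_dim) for _ in range(n_map)]
    z_dim = n_map * map_dim
    enh_weights = rng.uniform(-1, 1, size=(z_dim, m_enh)) / np.sqrt(z_dim)
    enh_offsets = rng.uniform(-1, 1, size=m_enh)
    model = BlsModel(
        map_weights=map_weights,
        map_offsets=map_offsets,
        enh_weights=enh_weights,
        enh_offsets=enh_offsets,
        output_weights=np.zeros((z_dim + m_enh, Y.shape[1])),
        eps=eps,
        seed=int(seed),
    )
    A = _expand(model, X)
    # ridge minimizer (AᵀA + εI)⁻¹AᵀY, computed via the equivalent augmented
    # least-squares system [A; √ε·I]·W = [Y; 0] for numerical stability
    aug = np.vstack([A, np.sqrt(eps) * np.eye(A.shape[1])])
    rhs = np.vstack([Y, np.zeros((A.shape[1], Y.shape[1]))])
    W_out, *_ = np.linalg.lstsq(aug, rhs, rcond=None)
    return BlsModel(
        map_weights=map_weights,
        map_offsets=map_offsets,
        enh_weights=enh_weights,
        enh_offsets=enh_offsets,
        output_weights=W_out,
        eps=eps,
        seed=int(seed),
    )


def bls_scores(model: BlsModel, X: np.ndarray) -> np.ndarray:
    """Raw per-class scores Y_BLS = [Z | H]·W for each row of X."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features_in:
        raise ValueError(
            f"X must have {model.n_features_in} columns, got shape {X.shape}"
        )
    return _expand(model, X) @ model.output_weights


class MarginClassifier:
    """RBF-kernel SVM exposing the signed distance to the hyperplane.

    Positive distance means the FGR class (label 1).  The kernel width
    defaults to 1/n_features (the reciprocal of the code length K).
    """

    def __init__(self, C: float = 1.0, gamma: float | str = "auto", seed: int = 0):
        self._svc = SVC(C=C, gamma=gamma, kernel="rbf", random_state=int(seed))
        self.fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MarginClassifier":
        self._svc.fit(np.asarray(X, dtype=np.float64), np.asarray(y, dtype=int))
        self.fitted = True
        return self

    def distance(self, X: np.ndarray) -> np.ndarray:
        """Signed distance of each sample to the separating hyperplane."""
        if not self.fitted:
            raise RuntimeError("classifier is not fitted")
        return self._svc.decision_function(np.asarray(X, dtype=np.float64))


def svm_distance_to_prob(d: np.ndarray | float) -> np.ndarray | float:
    """Sigmoid map of a signed hyperplane distance to a probability."""
    return expit(d)


def ensemble_probability(
    y_bls_row: np.ndarray, dists: np.ndarray, lam: float
) -> np.ndarray:
    """Blend BLS softmax and SVM sigmoid probabilities for one sample.

    ``dists`` holds the per-class signed distances (class 0, class 1); the
    result has one entry per class in [0, 1] (the two entries need not sum
    to 1).  Predicted label is the argmax, ties going to class 0.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    return lam * softmax(np.asarray(y_bls_row, dtype=np.float64)) + (
        1.0 - lam
    ) * expit(np.asarray(dists, dtype=np.float64))


@dataclass
class EnsembleModel:
    """BLS + margin classifier blended with mixing weight λ."""

    bls: BlsModel
    svm: MarginClassifier
    lam: float
    lam_trace: dict = field(default_factory=dict)  # λ -> validation accuracy

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-class blended probabilities, shape (n_samples, 2)."""
        X = np.asarray(X, dtype=np.float64)
        scores = bls_scores(self.bls, X)
        d = self.svm.distance(X)
        dists = np.column_stack([-d, d])
        return self.lam * softmax(scores, axis=1) + (1.0 - self.lam) * expit(dists)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def score_class1(self, X: np.ndarray) -> np.ndarray:
        """Class-1 (FGR) blended probability, the ROC ranking score."""
        return self.predict_proba(X)[:, 1]


def fit_ensemble(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    lam_grid: np.ndarray | None = None,
    bls_params: dict | None = None,
    svm_params: dict | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Fit both models on the training split and pick λ on validation.

    λ is chosen from ``lam_grid`` (default 0.0, 0.1, …, 1.0) by validation
    accuracy, ties resolved toward the smaller λ.  An empty validation set
    falls back to λ = 0.3 with a warning.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=int)
    bls = fit_bls(X_train, y_train, seed=seed, **(bls_params or {}))
    svm = MarginClassifier(seed=seed, **(svm_params or {})).fit(X_train, y_train)
    if lam_grid is None:
        lam_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    X_val = np.asarray(X_val, dtype=np.float64)
    if X_val.shape[0] == 0:
        warnings.warn(
            "empty validation set: falling back to lambda = "
            f"{DEFAULT_LAMBDA}",
            stacklevel=2,
        )
        return EnsembleModel(bls=bls, svm=svm, lam=DEFAULT_LAMBDA)
    y_val = np.asarray(y_val, dtype=int)
    scores = bls_scores(bls, X_val)
    d = svm.distance(X_val)
    dists = np.column_stack([-d, d])
    best_lam, best_acc = None, -1.0
    trace = {}
    for lam in lam_grid:
        proba = lam * softmax(scores, axis=1) + (1.0 - lam) * expit(dists)
        acc = float(np.mean(np.argmax(proba, axis=1) == y_val))
        trace[float(lam)] = acc
        if acc > best_acc:
            best_lam, best_acc = float(lam), acc
    return EnsembleModel(bls=bls, svm=svm, lam=best_lam, lam_trace=trace)
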