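"""Weight-scaled bag-of-visual-words image encoding.

Each keypoint descriptor V_{i,j} yields a soft assignment P_{i,j} (the
mixture posterior over the K visual words) and a hard assignment Q_{i,j}
(one-hot at the most probable word, ties broken toward the lowest index).
The image code blends the two and averages over the J_i keypoints:

    U_i = (1/J_i) · Σ_j [ α·P_{i,j} + (1−α)·Q_{i,j} ],   α ∈ [0, 1].

At α = 1 this is the mean posterior (a probability-weighted average); at
α = 0 it is the normalized hard-assignment histogram of classical BOVW.
Intermediate α pulls boundary keypoints — descriptors with similar
posterior mass in several words, common in noisy low-resolution ultrasound
— toward their best-matching word while retaining some soft information.
Because P and Q are simplex vectors, U_i sums to 1 for every α, and U_i is
affine in α: U_i(α) = α·U_i(1) + (1−α)·U_i(0).

Images with zero usable keypoints encode to the uniform vector 1/K and are
flagged as degenerate rather than aborting an evaluation run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vocabulary import Vocabulary, responsibilities

__all__ = ["EncodedVector", "hard_assign", "encode_image", "encode_corpus"]

DEFAULT_ALPHA = 0.15


@dataclass(frozen=True)
class EncodedVector:
    """K-dimensional image code with its blend weight and keypoint count."""

    u: np.ndarray
    alpha: float
    n_keypoints: int
    degenerate: bool = False


def hard_assign(p: np.ndarray) -> np.ndarray:
    """One-hot vector at the argmax of a responsibility vector.

    Ties are broken toward the lowest component index, so the result is
    deterministic.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.zeros_like(p)
    q[np.argmax(p)] = 1.0
    return q


def encode_image(
    vocab: Vocabulary,
    V: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    normalize_responsibilities: bool = True,
) -> EncodedVector:
    """Encode one image's descriptor matrix into its K-vector code.

    ``V`` has one 144-dimensional row per keypoint and may be empty, in
    which case the uniform code 1/K is returned with ``degenerate=True``.
    ``normalize_responsibilities=False`` blends raw weighted densities
    instead of posteriors (the code then no longer sums to 1).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    V = np.asarray(V, dtype=np.float64)
    if V.ndim != 2:
        raise ValueError("descriptor matrix must be 2-D")
    if V.shape[0] == 0:
        return EncodedVector(
            u=np.full(vocab.K, 1.0 / vocab.K),
            alpha=alpha,
            n_keypoints=0,
            degenerate=True,
        )
    P = responsibilities(vocab, V, normalize=normalize_responsibilities)
    Q = np.zeros_like(P)
    Q[np.arange(P.shape[0]), np.argmax(P, axis=1)] = 1.0
    u = np.mean(alpha * P + (1.0 - alpha) * Q, axis=0)
    return EncodedVector(u=u, alpha=alpha, n_keypoints=V.shape[0])


def encode_corpus(
    vocab: Vocabulary,
    mats: list[np.ndarray],
    alpha: float = DEFAULT_ALPHA,
    normalize_responsibilities: bool = True,
) -> tuple[np.ndarray, list[int]]:
    """Encode a list of descriptor matrices into a (n_images, K) matrix.

    Image order is preserved.  Returns the code matrix and the indices of
    degenerate (zero-keypoint) images so callers can report them.
    """
    codes = np.zeros((len(mats), vocab.K))
    degenerate: list[int] = []
    for i, V in enumerate(mats):
        enc = encode_image(vocab, V, alpha, normalize_responsibilities)
        codes[i] = enc.u
        if enc.degenerate:
            degenerate.append(i)
    return codes, degenerate
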