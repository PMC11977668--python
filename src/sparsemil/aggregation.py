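"""Permutation-invariant MIL pooling operators and sparse probability transforms.

The attention variants of the MIL models turn a vector of per-instance
logits into a probability distribution over instances, either with the
softmax (strictly positive weights) or with the sparsemax (the Euclidean
projection onto the probability simplex, which yields exact zeros and
thereby discards instances entirely).  Two penalties push the attention
distribution toward sparsity: an L0 count penalty and an entropy-based
penalty on ``sum p_i log p_i``.

Everything in this module is a pure deterministic function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "SparsemaxResult",
    "RegularizerWeights",
    "softmax_transform",
    "sparsemax_transform",
    "sparsemax_jacobian_vector",
    "simplex_projection_oracle",
    "l0_penalty",
    "l0_smooth_penalty",
    "mer_penalty",
    "max_pool_embeddings",
    "max_pool_predictions",
    "attention_aggregate_embeddings",
    "attention_aggregate_predictions",
]


@dataclass(frozen=True)
class SparsemaxResult:
    """Sparsemax output: probabilities, the threshold tau, and support size.

    Every nonzero probability equals ``v_i - threshold``; the support size
    is the number of strictly positive entries.
    """

    probabilities: np.ndarray
    threshold: float
    support_size: int


@dataclass(frozen=True)
class RegularizerWeights:
    """Weights of the two sparsity penalties applied to attention weights.

    ``mer_sign`` selects the sign convention of the entropy penalty:
    +1 adds ``lambda_mer * sum p log p`` (<= 0 on the simplex) exactly as
    written, -1 negates it so that minimizing the loss minimizes entropy.
    ``l0_smooth`` switches the L0 term to a differentiable surrogate
    ``lambda * sum(1 - exp(-p^2 / sigma^2))``.
    """

    lambda_l0: float = 0.0
    lambda_mer: float = 0.0
    mer_sign: int = +1
    l0_smooth: bool = False
    l0_sigma: float = 0.01

    def __post_init__(self):
        if self.lambda_l0 < 0:
            raise ValueError(f"lambda_l0 must be nonnegative, got {self.lambda_l0}")
        if self.mer_sign not in (+1, -1):
            raise ValueError(f"mer_sign must be +1 or -1, got {self.mer_sign}")


def _as_vector(v, name: str = "v") -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 1 or v.size == 0:
        raise ValueError(f"{name} must be a nonempty 1-D vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite")
    return v


def softmax_transform(v) -> np.ndarray:
    """Softmax probability transform, computed with max-subtraction.

    Output entries are strictly positive and sum to one; the transform is
    invariant under adding a constant to every logit.
    """
    v = _as_vector(v)
    e = np.exp(v - v.max())
    return e / e.sum()


def sparsemax_transform(v) -> SparsemaxResult:
    """Euclidean projection of ``v`` onto the probability simplex.

    Returns ``max(v_i - tau, 0)`` where the threshold ``tau`` is
    ``(sum of the support's logits - 1) / support_size`` with the support
    determined from the sorted coordinates.  Unlike the softmax, entries
    below the threshold are exactly zero.
    """
    v = _as_vector(v)
    z = np.sort(v)[::-1]  # stable descending; ties are threshold-safe
    cumsum = np.cumsum(z)
    ks = np.arange(1, v.size + 1)
    support = 1.0 + ks * z > cumsum
    k = int(ks[support][-1])
    tau = (cumsum[k - 1] - 1.0) / k
    p = np.maximum(v - tau, 0.0)
    return SparsemaxResult(probabilities=p, threshold=float(tau), support_size=k)


def sparsemax_jacobian_vector(result: SparsemaxResult, grad) -> np.ndarray:
    """Backpropagate a gradient through a sparsemax output.

    On the support the Jacobian is ``I - 11^T / k``; off the support it is
    zero.
    """
    grad = np.asarray(grad, dtype=np.float64)
    s = result.probabilities > 0
    out = np.zeros_like(grad)
    out[s] = grad[s] - grad[s].mean()
    return out


def simplex_projection_oracle(v) -> np.ndarray:
    """Brute-force Euclidean projection onto the simplex (test oracle).

    Enumerates every candidate support set, solves the equality-constrained
    projection on each, keeps feasible candidates and returns the one with
    the smallest squared distance to ``v``.  Exponential in ``len(v)``;
    intended for small vectors only.
    """
    v = _as_vector(v)
    n = v.size
    if n > 20:
        raise ValueError("oracle is exponential; use length <= 20")
    best, best_d = None, np.inf
    idx = np.arange(n)
    for k in range(1, n + 1):
        for support in combinations(idx, k):
            s = list(support)
            tau = (v[s].sum() - 1.0) / k
            cand = np.zeros(n)
            cand[s] = v[s] - tau
            if np.any(cand[s] < 0):
                continue
            d = float(np.sum((cand - v) ** 2))
            if d < best_d - 1e-15:
                best, best_d = cand, d
    return best


def l0_penalty(p, lambda_l0: float, zero_tol: float = 0.0) -> float:
    """L0 count penalty: ``lambda_l0 *`` number of entries with |p_i| > zero_tol.

    With the default ``zero_tol = 0`` only exact zeros (as produced by the
    sparsemax) escape the count.  Constant almost everywhere, hence carries
    no gradient; see :func:`l0_smooth_penalty` for the surrogate.
    """
    if lambda_l0 < 0:
        raise ValueError(f"lambda_l0 must be nonnegative, got {lambda_l0}")
    p = _as_vector(p, "p")
    return float(lambda_l0 * np.count_nonzero(np.abs(p) > zero_tol))


def l0_smooth_penalty(p, lambda_l0: float, sigma: float = 0.01):
    """Differentiable L0 surrogate ``lambda * sum(1 - exp(-p^2/sigma^2))``.

    Returns ``(value, gradient)``.  Approaches the exact count as
    ``sigma -> 0``.
    """
    if lambda_l0 < 0:
        raise ValueError(f"lambda_l0 must be nonnegative, got {lambda_l0}")
    p = _as_vector(p, "p")
    e = np.exp(-(p**2) / sigma**2)
    value = float(lambda_l0 * np.sum(1.0 - e))
    grad = lambda_l0 * 2.0 * p / sigma**2 * e
    return value, grad


def mer_penalty(p, lambda_mer: float, mer_sign: int = +1) -> float:
    """Entropy penalty ``mer_sign * lambda_mer * sum p_i log p_i`` (natural log).

    ``0 log 0`` is taken as 0 so sparse probability vectors are handled
    exactly.  ``p`` must lie on the simplex (checked to 1e-6).
    """
    p = _as_vector(p, "p")
    if mer_sign not in (+1, -1):
        raise ValueError(f"mer_sign must be +1 or -1, got {mer_sign}")
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("p must lie on the probability simplex")
    pos = p > 0
    return float(mer_sign * lambda_mer * np.sum(p[pos] * np.log(p[pos])))


def mer_penalty_gradient(p, lambda_mer: float, mer_sign: int = +1) -> np.ndarray:
    """Gradient of :func:`mer_penalty` w.r.t. p; zero on exact-zero entries."""
    p = np.asarray(p, dtype=np.float64)
    g = np.zeros_like(p)
    pos = p > 0
    g[pos] = mer_sign * lambda_mer * (np.log(p[pos]) + 1.0)
    return g


def max_pool_embeddings(H) -> np.ndarray:
    """Coordinate-wise maximum over instance embeddings (rows of ``H``)."""
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ValueError(f"H must be a nonempty L x D matrix, got shape {H.shape}")
    return H.max(axis=0)


def max_pool_predictions(p) -> float:
    """Maximum over instance scores."""
    p = _as_vector(p, "p")
    return float(p.max())


def attention_aggregate_embeddings(H, a) -> np.ndarray:
    """Attention-weighted sum of instance embeddings: ``sum_i a_i H_i``."""
    H = np.asarray(H, dtype=np.float64)
    a = _as_vector(a, "a")
    if H.ndim != 2 or H.shape[0] != a.size:
        raise ValueError(f"H rows ({H.shape}) must match attention length {a.size}")
    return a @ H


def attention_aggregate_predictions(p, a) -> float:
    """Attention-weighted mean of instance scores: ``sum_i a_i p_i``."""
    p = _as_vector(p, "p")
    a = _as_vector(a, "a")
    if p.size != a.size:
        raise ValueError(f"score length {p.size} != attention length {a.size}")
    return float(a @ p)
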