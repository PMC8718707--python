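"""Attention-based memory addressing over a learned latent dictionary.

The memory module replaces an encoder output ``z`` with a sparse convex
combination of ``N`` learned prototype vectors (the *memory items*).  The
addressing weights are a softmax over cosine similarities between the query
and each item; weights at or below a shrinkage threshold ``alpha`` are zeroed
by a continuous hard-shrinkage operator and the survivors are re-normalized
to sum to one.  Retrieval is the weighted sum of items, so the decoder only
ever sees combinations of prototypes recorded during training — the property
that makes reconstruction error a usable class-membership score.

All operations are pure NumPy and exposed both as scalar-query functions
(the reference semantics) and as batched forward/backward routines used by
the trainer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MemoryBank",
    "AddressWeights",
    "cosine_similarity",
    "address_weights",
    "hard_shrink",
    "normalize_weights",
    "retrieve",
    "retrieve_map",
    "init_memory_bank",
    "retrieve_batch_forward",
    "retrieve_batch_backward",
]

DEFAULT_EPSILON = 1e-12


@dataclass
class MemoryBank:
    """Dictionary of ``N`` latent prototype vectors with shrinkage parameters.

    Parameters
    ----------
    items : ndarray of shape (N, C_f)
        One row per memory item. Updated by gradient descent during training.
    alpha : float
        Hard-shrinkage threshold; must lie in ``[1/N, 3/N]``.
    epsilon : float
        Small positive guard used in the cosine denominator and the
        shrinkage denominator.
    """

    items: np.ndarray
    alpha: float
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=np.float64)
        if self.items.ndim != 2 or self.items.shape[0] < 1 or self.items.shape[1] < 1:
            raise ValueError("memory items must be a non-empty (N, C_f) matrix")
        if not np.all(np.isfinite(self.items)):
            raise ValueError("memory items must be finite")
        n = self.items.shape[0]
        if not (1.0 / n - 1e-12 <= self.alpha <= 3.0 / n + 1e-12):
            raise ValueError(
                f"alpha={self.alpha} outside [1/N, 3/N] = [{1 / n}, {3 / n}]"
            )
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")

    @property
    def capacity(self) -> int:
        return self.items.shape[0]

    @property
    def item_dim(self) -> int:
        return self.items.shape[1]


@dataclass
class AddressWeights:
    """Raw softmax weights and their sparsified, re-normalized counterpart."""

    raw: np.ndarray
    sparse: np.ndarray
    fallback: bool = field(default=False)


def init_memory_bank(
    capacity: int,
    item_dim: int,
    alpha: float | None = None,
    epsilon: float = DEFAULT_EPSILON,
    rng: np.random.Generator | None = None,
) -> MemoryBank:
    """Create a bank with items drawn uniformly from ``(-1/sqrt(C_f), 1/sqrt(C_f))``.

    ``alpha`` defaults to ``2/N``, the midpoint of the admissible interval.
    """
    if capacity < 1 or item_dim < 1:
        raise ValueError("capacity and item_dim must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    bound = 1.0 / np.sqrt(item_dim)
    items = rng.uniform(-bound, bound, size=(capacity, item_dim))
    if alpha is None:
        alpha = 2.0 / capacity
    return MemoryBank(items=items, alpha=alpha, epsilon=epsilon)


def cosine_similarity(
    z: np.ndarray, m: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> float:
    """Cosine of the angle between a query and one memory item.

    The denominator is guarded by ``max(|z||m|, epsilon)`` so a zero vector
    yields similarity 0 instead of a division error.
    """
    z = np.asarray(z, dtype=np.float64).ravel()
    m = np.asarray(m, dtype=np.float64).ravel()
    if z.shape != m.shape:
        raise ValueError(f"dimension mismatch: {z.shape} vs {m.shape}")
    denom = max(np.linalg.norm(z) * np.linalg.norm(m), epsilon)
    return float(z @ m / denom)


def _similarity_matrix(queries: np.ndarray, bank: MemoryBank) -> np.ndarray:
    """Guarded cosine similarities, shape (Q, N)."""
    qn = np.linalg.norm(queries, axis=1)
    mn = np.linalg.norm(bank.items, axis=1)
    denom = np.maximum(np.outer(qn, mn), bank.epsilon)
    return (queries @ bank.items.T) / denom


def address_weights(z: np.ndarray, bank: MemoryBank) -> np.ndarray:
    """Softmax attention weights ``k_i = exp(d(z, m_i)) / sum_j exp(d(z, m_j))``."""
    z = np.asarray(z, dtype=np.float64).ravel()
    if z.shape[0] != bank.item_dim:
        raise ValueError(
            f"query dim {z.shape[0]} != memory item dim {bank.item_dim}"
        )
    sims = _similarity_matrix(z[None, :], bank)[0]
    if not np.all(np.isfinite(sims)):
        raise FloatingPointError("non-finite similarity encountered")
    return _softmax(sims)


def _softmax(s: np.ndarray) -> np.ndarray:
    e = np.exp(s - np.max(s, axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def hard_shrink(
    k: np.ndarray, alpha: float, epsilon: float = DEFAULT_EPSILON
) -> np.ndarray:
    """Continuous hard shrinkage ``max(k-a,0) * k / (|k-a| + eps)``.

    Entries at or below ``alpha`` map to exactly zero; entries above pass
    through almost unchanged (relative error bounded by ``eps/(k-alpha)``).
    """
    k = np.asarray(k, dtype=np.float64)
    if np.any(k < 0):
        raise ValueError("hard_shrink requires non-negative weights")
    if alpha <= 0 or epsilon <= 0:
        raise ValueError("alpha and epsilon must be positive")
    return np.maximum(k - alpha, 0.0) * k / (np.abs(k - alpha) + epsilon)


def normalize_weights(shrunk: np.ndarray, raw: np.ndarray) -> AddressWeights:
    """L1-normalize shrunk weights; fall back to raw softmax if all were zeroed."""
    shrunk = np.asarray(shrunk, dtype=np.float64)
    raw = np.asarray(raw, dtype=np.float64)
    if np.any(shrunk < 0):
        raise ValueError("shrunk weights must be non-negative")
    total = shrunk.sum()
    if total > 0:
        return AddressWeights(raw=raw, sparse=shrunk / total, fallback=False)
    return AddressWeights(raw=raw, sparse=raw.copy(), fallback=True)


def retrieve(z: np.ndarray, bank: MemoryBank) -> np.ndarray:
    """Full addressing chain for one query: softmax -> shrink -> normalize -> mix."""
    raw = address_weights(z, bank)
    shrunk = hard_shrink(raw, bank.alpha, bank.epsilon)
    w = normalize_weights(shrunk, raw)
    return w.sparse @ bank.items


def retrieve_map(feature_map: np.ndarray, bank: MemoryBank) -> np.ndarray:
    """Apply :func:`retrieve` independently at every time position.

    ``feature_map`` has shape ``(C_f, T')``; each column is one query, so the
    memory size is independent of the input length.
    """
    feature_map = np.asarray(feature_map, dtype=np.float64)
    if feature_map.ndim != 2:
        raise ValueError("feature map must be 2-D (C_f, T')")
    if feature_map.shape[0] != bank.item_dim:
        raise ValueError(
            f"feature map channels {feature_map.shape[0]} != item dim {bank.item_dim}"
        )
    zhat, _ = retrieve_batch_forward(feature_map.T, bank)
    return zhat.T


# ---------------------------------------------------------------------------
# Batched forward/backward used by the trainer. Queries are stacked as rows
# of a (Q, C_f) matrix; Q is batch*positions.
# ---------------------------------------------------------------------------


def retrieve_batch_forward(queries: np.ndarray, bank: MemoryBank):
    """Vectorized retrieval for a stack of queries.

    Returns ``(zhat, cache)`` where ``zhat`` is (Q, C_f) and ``cache`` holds
    every intermediate needed by :func:`retrieve_batch_backward`.
    """
    Z = np.asarray(queries, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[1] != bank.item_dim:
        raise ValueError("queries must be (Q, C_f) matching the bank item dim")
    M = bank.items
    qn = np.linalg.norm(Z, axis=1)
    mn = np.linalg.norm(M, axis=1)
    outer = np.outer(qn, mn)
    denom = np.maximum(outer, bank.epsilon)
    sims = (Z @ M.T) / denom
    if not np.all(np.isfinite(sims)):
        raise FloatingPointError("non-finite similarity encountered")
    K = _softmax(sims)

    diff = K - bank.alpha
    shrunk = np.maximum(diff, 0.0) * K / (np.abs(diff) + bank.epsilon)
    totals = shrunk.sum(axis=1)
    fallback = totals <= 0.0
    W = np.where(fallback[:, None], K, shrunk / np.where(fallback, 1.0, totals)[:, None])
    zhat = W @ M
    cache = {
        "Z": Z, "qn": qn, "mn": mn, "denom": denom, "outer": outer,
        "sims": sims, "K": K, "shrunk": shrunk, "totals": totals,
        "fallback": fallback, "W": W,
    }
    return zhat, cache


def retrieve_batch_backward(d_zhat: np.ndarray, cache: dict, bank: MemoryBank):
    """Gradients of the retrieval output w.r.t. queries and memory items.

    Returns ``(d_queries, d_items)``. The guarded cosine denominator is
    treated as constant wherever the guard is active (zero-norm query), which
    matches the subgradient convention used for ReLU elsewhere.
    """
    Z, M = cache["Z"], bank.items
    K, W = cache["K"], cache["W"]
    shrunk, totals, fallback = cache["shrunk"], cache["totals"], cache["fallback"]

    d_items = W.T @ d_zhat              # mixing: zhat = W @ M
    dW = d_zhat @ M.T                    # (Q, N)

    # normalization: W = shrunk / total (rows without fallback)
    safe_tot = np.where(fallback, 1.0, totals)
    wdw = (W * dW).sum(axis=1, keepdims=True)
    d_shrunk = (dW - wdw) / safe_tot[:, None]

    # shrinkage: h = (k - a) k / (k - a + eps) for k > a, else 0
    diff = K - bank.alpha
    pos = diff > 0
    denom_s = diff + bank.epsilon  # positive where pos
    with np.errstate(divide="ignore", invalid="ignore"):
        dh_dk = np.where(
            pos,
            ((2.0 * K - bank.alpha) * denom_s - diff * K) / (denom_s ** 2),
            0.0,
        )
    dK = np.where(fallback[:, None], dW, d_shrunk * dh_dk)

    # softmax backward
    s_dot = (dK * K).sum(axis=1, keepdims=True)
    dS = K * (dK - s_dot)

    # cosine backward: s_qi = z_q . m_i / max(|z_q||m_i|, eps)
    denom, sims = cache["denom"], cache["sims"]
    guarded = cache["outer"] < bank.epsilon
    dS_eff = np.where(guarded, 0.0, dS)
    ds_over_denom = dS_eff / denom
    qn2 = np.maximum(cache["qn"] ** 2, bank.epsilon)
    mn2 = np.maximum(cache["mn"] ** 2, bank.epsilon)
    d_queries = ds_over_denom @ M - ((dS_eff * sims).sum(axis=1) / qn2)[:, None] * Z
    d_items += ds_over_denom.T @ Z - ((dS_eff * sims).sum(axis=0) / mn2)[:, None] * M
    return d_queries, d_items
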