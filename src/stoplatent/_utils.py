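"""Shared helpers: RNG handling, label alignment, simple validation."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment


def check_rng(seed_or_rng) -> np.random.Generator:
    """Return a Generator; accepts an int seed, None, or an existing Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def align_labels(true_labels: np.ndarray, est_labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Best-permutation relabeling of ``est_labels`` onto ``true_labels``.

    Mixture-model class indices are arbitrary (label switching); all recovery
    comparisons go through the Hungarian assignment maximising agreement.
    Returns the permuted estimated labels.
    """
    cost = np.zeros((n_classes, n_classes))
    for k in range(n_classes):
        for j in range(n_classes):
            cost[k, j] = -np.sum((true_labels == k) & (est_labels == j))
    _, col = linear_sum_assignment(cost)
    mapping = np.empty(n_classes, dtype=int)
    for k in range(n_classes):
        mapping[col[k]] = k
    return mapping[est_labels]


def align_permutation(reference: np.ndarray, estimate: np.ndarray) -> np.ndarray:
    """Permutation of estimate's rows best matching reference's rows (L1 distance).

    Both arguments are (K, J) parameter matrices (e.g. endorsement probabilities).
    Returns indices ``perm`` such that ``estimate[perm]`` aligns with ``reference``.
    """
    K = reference.shape[0]
    cost = np.zeros((K, K))
    for k in range(K):
        for j in range(K):
            cost[k, j] = np.abs(reference[k] - estimate[j]).sum()
    _, col = linear_sum_assignment(cost)
    return col


def as_binary_matrix(X) -> np.ndarray:
    """Validate a symptom-item matrix: entries must be 0, 1 or NaN (missing)."""
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("item matrix must be 2-dimensional")
    finite = arr[np.isfinite(arr)]
    if not np.isin(finite, (0.0, 1.0)).all():
        bad = finite[~np.isin(finite, (0.0, 1.0))]
        raise ValueError(f"non-binary item values found: {np.unique(bad)[:5]}")
    return arr
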