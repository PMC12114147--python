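"""Synthetic minority oversampling (SMOTE) for class equalization.

Implements the standard k-nearest-neighbour interpolation scheme: each
synthetic sample is drawn on the segment between a random minority point
and one of its k nearest minority-class neighbours (Euclidean metric),
with a uniform interpolation factor.  Classes are equalized to the size
of the largest class.  The algorithm operates in whatever feature space
it is given; in this package it is applied after z-score normalization
so distances are scale-free.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import DegenerateDataError

logger = logging.getLogger(__name__)


def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every minority class up to the majority class size.

    Returns (X_balanced, y_balanced): the original samples (order
    preserved) followed by the synthetic ones.  ``k_neighbors`` is
    reduced with a warning when a minority class is too small to supply
    k distinct neighbours; a singleton class cannot be interpolated and
    raises.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    new_X = [X]
    new_y = [y]
    for cls, count in zip(classes, counts):
        need = int(target - count)
        if need == 0:
            continue
        if count < 2:
            raise DegenerateDataError(
                f"class {cls!r} has a single member; SMOTE cannot interpolate"
            )
        k = min(k_neighbors, count - 1)
        if k < k_neighbors:
            logger.warning(
                "class %r: reducing SMOTE neighbours from %d to %d", cls, k_neighbors, k
            )
        pool = X[y == cls]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pool)
        neighbours = nn.kneighbors(pool, return_distance=False)[:, 1:]
        base = rng.integers(0, count, size=need)
        pick = neighbours[base, rng.integers(0, k, size=need)]
        gamma = rng.random((need, 1))
        synthetic = pool[base] + gamma * (pool[pick] - pool[base])
        new_X.append(synthetic)
        new_y.append(np.full(need, cls, dtype=y.dtype))
    return np.vstack(new_X), np.concatenate(new_y)
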