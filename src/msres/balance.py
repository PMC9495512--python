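"""Minority oversampling for the imbalanced AF segment population.

From-scratch implementations of the three SMOTE-family oversamplers,
operating on flattened (2,700-dimensional) segment vectors under Euclidean
distance:

* **SMOTE** — each synthetic point is ``x + u * (x_nn - x)`` with
  ``u ~ Uniform(0, 1)`` and ``x_nn`` one of the ``k`` nearest minority
  neighbors of a minority seed ``x``;
* **Borderline-SMOTE** — interpolation seeds are restricted to the DANGER
  set: minority points whose k-neighborhood in the full data contains at
  least k/2 but fewer than k majority points;
* **ADASYN** — per-seed synthetic allocation proportional to the majority
  fraction of its neighborhood, plus small Gaussian jitter so the points
  scatter off the interpolation segments.

k-NN distance ties are broken by ascending sample index, making every
sampler fully deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import CannotBalanceError

__all__ = [
    "BalanceConfig",
    "smote",
    "borderline_smote",
    "adasyn",
    "balance_training_set",
    "knn_indices",
]


@dataclass(frozen=True)
class BalanceConfig:
    """Oversampling configuration.

    ``sampling_strategy`` is the minority/majority count ratio after
    balancing; 1.0 equalizes the classes.
    """

    method: str = "smote"  # smote | borderline_smote | adasyn | none
    k_neighbors: int = 5
    sampling_strategy: float = 1.0
    jitter_sd: float | None = None  # ADASYN only; None = 0.01 x minority feature std
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("smote", "borderline_smote", "adasyn", "none"):
            raise ValueError(f"unknown balancing method {self.method!r}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0 < self.sampling_strategy <= 1:
            raise ValueError("sampling_strategy must lie in (0, 1]")


def knn_indices(queries: np.ndarray, pool: np.ndarray, k: int,
                exclude_first: bool = False) -> np.ndarray:
    """Indices into ``pool`` of the k nearest neighbors of each query row.

    Euclidean distance; ties broken by ascending pool index (stable sort).
    ``exclude_first=True`` drops the single nearest neighbor, used when the
    queries themselves are members of the pool (self-neighbor removal).
    """
    queries = np.asarray(queries, dtype=np.float32)
    pool = np.asarray(pool, dtype=np.float32)
    take = k + (1 if exclude_first else 0)
    if take > len(pool):
        raise ValueError(f"k = {k} too large for a pool of {len(pool)} points")
    pool_sq = np.einsum("ij,ij->i", pool, pool)
    out = np.empty((len(queries), k), dtype=np.int64)
    chunk = max(1, int(2**25 // max(len(pool), 1)))
    for lo in range(0, len(queries), chunk):
        q = queries[lo : lo + chunk]
        d2 = pool_sq[None, :] - 2.0 * (q @ pool.T)  # + |q|^2, constant per row
        order = np.argsort(d2, axis=1, kind="stable")[:, :take]
        out[lo : lo + len(q)] = order[:, 1:] if exclude_first else order[:, :k]
    return out


def _interpolate(seeds_x, neighbors_x, rng):
    u = rng.random(len(seeds_x)).astype(seeds_x.dtype)[:, None]
    return seeds_x + u * (neighbors_x - seeds_x)


def smote(
    minority: np.ndarray,
    n_synthetic: int,
    k_neighbors: int = 5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Plain SMOTE: interpolate between minority points and their k-NN."""
    minority = np.atleast_2d(np.asarray(minority))
    rng = rng if rng is not None else np.random.default_rng(0)
    if len(minority) < 2:
        raise CannotBalanceError("SMOTE needs at least 2 minority points")
    if not 1 <= k_neighbors < len(minority):
        raise ValueError("k_neighbors must satisfy 1 <= k < n_minority")
    if n_synthetic < 0:
        raise ValueError("n_synthetic must be >= 0")
    if n_synthetic == 0:
        return np.empty((0, minority.shape[1]), dtype=minority.dtype)
    nn = knn_indices(minority, minority, k_neighbors, exclude_first=True)
    seed_idx = rng.integers(0, len(minority), n_synthetic)
    nbr_pick = rng.integers(0, k_neighbors, n_synthetic)
    return _interpolate(minority[seed_idx], minority[nn[seed_idx, nbr_pick]], rng)


def danger_set(
    minority: np.ndarray, majority: np.ndarray, k_neighbors: int = 5
) -> np.ndarray:
    """Boolean mask of minority points on the class borderline.

    A minority point is DANGER when, among its k nearest neighbors in the
    pooled data (itself excluded), the majority count m satisfies
    ``k/2 <= m < k`` — majority-crowded but not fully engulfed.
    """
    full = np.vstack([minority, majority])
    nn = knn_indices(minority, full, k_neighbors, exclude_first=True)
    m = np.sum(nn >= len(minority), axis=1)
    return (m >= k_neighbors / 2.0) & (m < k_neighbors)


def borderline_smote(
    minority: np.ndarray,
    majority: np.ndarray,
    n_synthetic: int,
    k_neighbors: int = 5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Borderline-SMOTE: SMOTE interpolation seeded only from the DANGER set.

    Falls back to plain SMOTE with a warning when no minority point is on
    the borderline (nothing to refine).
    """
    minority = np.atleast_2d(np.asarray(minority))
    majority = np.atleast_2d(np.asarray(majority))
    rng = rng if rng is not None else np.random.default_rng(0)
    if len(minority) < 2 or len(majority) == 0:
        raise CannotBalanceError("borderline-SMOTE needs >= 2 minority and >= 1 majority points")
    if n_synthetic == 0:
        return np.empty((0, minority.shape[1]), dtype=minority.dtype)
    danger = danger_set(minority, majority, k_neighbors)
    if not danger.any():
        warnings.warn(
            "borderline-SMOTE: DANGER set is empty; falling back to plain SMOTE",
            stacklevel=2,
        )
        return smote(minority, n_synthetic, k_neighbors, rng)
    nn = knn_indices(minority, minority, min(k_neighbors, len(minority) - 1),
                     exclude_first=True)
    danger_idx = np.flatnonzero(danger)
    seed_idx = danger_idx[rng.integers(0, len(danger_idx), n_synthetic)]
    nbr_pick = rng.integers(0, nn.shape[1], n_synthetic)
    return _interpolate(minority[seed_idx], minority[nn[seed_idx, nbr_pick]], rng)


def adasyn(
    minority: np.ndarray,
    majority: np.ndarray,
    n_synthetic: int,
    k_neighbors: int = 5,
    jitter_sd: float | np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """ADASYN: density-adaptive SMOTE with post-hoc Gaussian jitter.

    Each minority point receives a synthetic allocation proportional to the
    majority fraction among its k nearest neighbors in the pooled data
    (uniform when every neighborhood is pure minority); allocations sum to
    exactly ``n_synthetic`` by largest-remainder rounding.  ``jitter_sd``
    defaults to 0.01 x the per-feature minority standard deviation.
    """
    minority = np.atleast_2d(np.asarray(minority))
    majority = np.atleast_2d(np.asarray(majority))
    rng = rng if rng is not None else np.random.default_rng(0)
    if len(minority) < 2 or len(majority) == 0:
        raise CannotBalanceError("ADASYN needs >= 2 minority and >= 1 majority points")
    if n_synthetic == 0:
        return np.empty((0, minority.shape[1]), dtype=minority.dtype)
    full = np.vstack([minority, majority])
    nn_full = knn_indices(minority, full, k_neighbors, exclude_first=True)
    density = np.sum(nn_full >= len(minority), axis=1).astype(float) / k_neighbors
    if density.sum() == 0:
        weights = np.full(len(minority), 1.0 / len(minority))
    else:
        weights = density / density.sum()
    ideal = weights * n_synthetic
    alloc = np.floor(ideal).astype(int)
    short = n_synthetic - alloc.sum()
    if short > 0:
        order = np.argsort(-(ideal - alloc), kind="stable")
        alloc[order[:short]] += 1
    nn_min = knn_indices(minority, minority, min(k_neighbors, len(minority) - 1),
                         exclude_first=True)
    seed_idx = np.repeat(np.arange(len(minority)), alloc)
    nbr_pick = rng.integers(0, nn_min.shape[1], len(seed_idx))
    synth = _interpolate(minority[seed_idx], minority[nn_min[seed_idx, nbr_pick]], rng)
    if jitter_sd is None:
        jitter_sd = 0.01 * minority.std(axis=0)
    jitter_sd = np.asarray(jitter_sd, dtype=synth.dtype)
    if np.any(jitter_sd > 0):
        synth = synth + rng.standard_normal(synth.shape).astype(synth.dtype) * jitter_sd
    return synth


def balance_training_set(
    X: np.ndarray, y: np.ndarray, config: BalanceConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class of a training set.

    Returns ``(X', y')`` with the original samples unchanged and first in
    order, followed by the synthetic minority vectors.  With
    ``sampling_strategy = 1`` the class counts are equal afterwards.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if config.method == "none":
        return X, y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise CannotBalanceError("training set contains a single class; cannot balance")
    minority_label = classes[np.argmin(counts)]
    n_min = counts.min()
    n_maj = counts.max()
    n_target = int(np.floor(config.sampling_strategy * n_maj))
    n_synthetic = max(0, n_target - n_min)
    if n_synthetic == 0:
        return X, y
    rng = np.random.default_rng(config.seed)
    minority = X[y == minority_label]
    majority = X[y != minority_label]
    k = min(config.k_neighbors, len(minority) - 1)
    if k < 1:
        raise CannotBalanceError("need at least 2 minority samples to oversample")
    if config.method == "smote":
        synth = smote(minority, n_synthetic, k, rng)
    elif config.method == "borderline_smote":
        synth = borderline_smote(minority, majority, n_synthetic, k, rng)
    else:
        synth = adasyn(minority, majority, n_synthetic, k, config.jitter_sd, rng)
    X_out = np.vstack([X, synth.astype(X.dtype)])
    y_out = np.concatenate([y, np.full(n_synthetic, minority_label, dtype=y.dtype)])
    return X_out, y_out
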