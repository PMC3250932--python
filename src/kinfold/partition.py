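"""Training/validation fold construction.

Three schemes are supported:

* ``kmeans_folds`` — Hartigan-Wong K-means on the rows of the pedigree
  dissimilarity matrix, so animals end up grouped with their relatives and
  folds are weakly related to each other;
* ``random_folds`` — uniformly random near-equal groups (replicated);
* ``age_split`` — a single old-train / young-validate split at the smallest
  birth-year threshold putting at least the requested fraction in validation.

``cv_plan`` turns any scheme into leave-one-group-out folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "PartitionScheme",
    "kmeans_folds",
    "random_folds",
    "age_split",
    "cv_plan",
]


class PartitionError(ValueError):
    pass


@dataclass
class PartitionScheme:
    """Assignment of animals to mutually exclusive, exhaustive groups."""

    method: str  # "kmeans" | "random" | "age"
    ids: np.ndarray
    groups: np.ndarray  # int labels, 0..K-1
    seed: int | None = None
    replicate: int | None = None
    threshold_year: int | None = None
    objective: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return int(self.groups.max()) + 1

    def assignment(self) -> dict:
        return dict(zip(self.ids, self.groups))


@njit(cache=True)
def _hartigan_wong(X, labels, K, max_sweeps):
    """In-place Hartigan-Wong refinement: move points between clusters while the
    within-cluster sum of squares decreases.  Returns the final objective."""
    n, p = X.shape
    centers = np.zeros((K, p))
    counts = np.zeros(K, dtype=np.int64)
    for i in range(n):
        c = labels[i]
        counts[c] += 1
        for j in range(p):
            centers[c, j] += X[i, j]
    for c in range(K):
        if counts[c] > 0:
            for j in range(p):
                centers[c, j] /= counts[c]
    for _ in range(max_sweeps):
        moved = 0
        for i in range(n):
            c1 = labels[i]
            n1 = counts[c1]
            if n1 <= 1:
                continue
            d1 = 0.0
            for j in range(p):
                diff = X[i, j] - centers[c1, j]
                d1 += diff * diff
            removal_gain = n1 / (n1 - 1.0) * d1
            best_c = -1
            best_cost = removal_gain
            for c2 in range(K):
                if c2 == c1:
                    continue
                n2 = counts[c2]
                d2 = 0.0
                for j in range(p):
                    diff = X[i, j] - centers[c2, j]
                    d2 += diff * diff
                cost = n2 / (n2 + 1.0) * d2
                if cost < best_cost - 1e-12:
                    best_cost = cost
                    best_c = c2
            if best_c >= 0:
                n2 = counts[best_c]
                for j in range(p):
                    centers[c1, j] = (centers[c1, j] * n1 - X[i, j]) / (n1 - 1)
                    centers[best_c, j] = (centers[best_c, j] * n2 + X[i, j]) / (n2 + 1)
                counts[c1] -= 1
                counts[best_c] += 1
                labels[i] = best_c
                moved += 1
        if moved == 0:
            break
    obj = 0.0
    for i in range(n):
        c = labels[i]
        for j in range(p):
            diff = X[i, j] - centers[c, j]
            obj += diff * diff
    return obj


def _kmeans_once(X: np.ndarray, K: int, rng: np.random.Generator, max_sweeps=100):
    n = X.shape[0]
    # k-means++-style seeding on the rows, then Hartigan-Wong refinement
    centers_idx = [int(rng.integers(n))]
    d2 = np.sum((X - X[centers_idx[0]]) ** 2, axis=1)
    for _ in range(1, K):
        total = d2.sum()
        if total <= 0:
            centers_idx.append(int(rng.integers(n)))
        else:
            centers_idx.append(int(rng.choice(n, p=d2 / total)))
        d2 = np.minimum(d2, np.sum((X - X[centers_idx[-1]]) ** 2, axis=1))
    centers = X[centers_idx]
    labels = np.argmin(
        ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    ).astype(np.int64)
    # guarantee K non-empty clusters before refinement
    for c in range(K):
        if not (labels == c).any():
            labels[int(rng.integers(n))] = c
    obj = _hartigan_wong(X, labels, K, max_sweeps)
    return labels, float(obj)


def kmeans_folds(dis, K: int = 5, n_start: int = 25, seed: int = 0) -> PartitionScheme:
    """Cluster animals by Hartigan-Wong K-means on rows of the dissimilarity matrix.

    Each animal's feature vector is its row of D (its pedigree-distance profile
    to every other animal).  The best of ``n_start`` seeded restarts by
    within-cluster sum of squares is kept.  Empty clusters trigger a logged
    restart with a fresh stream.
    """
    D = np.asarray(dis.D, dtype=np.float64)
    ids = np.asarray(dis.ids)
    n = D.shape[0]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T) or np.abs(np.diag(D)).max() > 1e-9:
        raise PartitionError("dissimilarity matrix must be square symmetric with zero diagonal")
    if K < 2 and n > 1:
        raise PartitionError("K must be >= 2")
    if K >= n:
        return PartitionScheme("kmeans", ids, np.arange(n, dtype=np.int64), seed, objective=0.0)
    rng = np.random.default_rng(seed)
    best_labels, best_obj = None, np.inf
    attempts = 0
    starts_done = 0
    while starts_done < n_start and attempts < 4 * n_start:
        attempts += 1
        labels, obj = _kmeans_once(D, K, rng)
        if len(np.unique(labels)) < K:
            continue  # empty cluster: retry with the advanced stream
        starts_done += 1
        if obj < best_obj:
            best_obj, best_labels = obj, labels
    if best_labels is None:
        raise PartitionError("k-means failed to produce K non-empty clusters")
    # relabel clusters by first appearance for determinism across restarts
    order = {}
    for lab in best_labels:
        if lab not in order:
            order[lab] = len(order)
    relabeled = np.array([order[lab] for lab in best_labels], dtype=np.int64)
    return PartitionScheme("kmeans", ids, relabeled, seed, objective=best_obj)


def random_folds(ids, K: int = 5, replicate: int = 0, seed: int = 0) -> PartitionScheme:
    """Uniformly random split into K groups whose sizes differ by at most one."""
    ids = np.asarray(ids)
    n = len(ids)
    rng = np.random.default_rng([seed, replicate])
    perm = rng.permutation(n)
    groups = np.empty(n, dtype=np.int64)
    groups[perm] = np.arange(n) % K
    return PartitionScheme("random", ids, groups, seed, replicate=replicate)


def age_split(ids, birth_years, valid_fraction: float = 0.20) -> PartitionScheme:
    """Old-train / young-validate split on birth year.

    Picks the smallest threshold year such that animals born after it make up
    at least ``valid_fraction`` of those with records; ties at the threshold go
    to training.  Group 0 = training (born <= threshold), group 1 = validation.
    """
    ids = np.asarray(ids)
    years = np.asarray(birth_years, dtype=float)
    uniq = np.unique(years[np.isfinite(years)])
    if len(uniq) < 2:
        raise PartitionError("degenerate birth-year distribution: no split possible")
    n = len(ids)
    threshold = None
    for y in uniq[::-1][1:]:  # candidate thresholds, youngest first
        frac = (years > y).sum() / n
        if frac >= valid_fraction:
            threshold = int(y)
            break
    if threshold is None:
        threshold = int(uniq[0])
    groups = (years > threshold).astype(np.int64)
    return PartitionScheme("age", ids, groups, threshold_year=threshold)


def cv_plan(parts: PartitionScheme) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-group-out folds: (training ids, validation ids) per group.

    An age split yields the single (old, young) fold; every animal is
    validated exactly once, never appearing in its own training set.
    """
    if parts.method == "age":
        train = parts.ids[parts.groups == 0]
        valid = parts.ids[parts.groups == 1]
        folds = [(train, valid)]
    else:
        folds = []
        for g in range(parts.k):
            valid = parts.ids[parts.groups == g]
            train = parts.ids[parts.groups != g]
            folds.append((train, valid))
    for train, valid in folds:
        if set(train) & set(valid):
            raise PartitionError("animal present in both training and validation")
    return folds
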