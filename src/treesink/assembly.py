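"""Community assembly from trait matrices.

Communities are binary presence/absence vectors over tips, in tip order.
Three assembly processes are provided:

* environmental filtering, deterministic: the *k* species nearest a trait
  optimum (Euclidean distance) are present;
* environmental filtering, probabilistic: *k* species sampled without
  replacement with weight exp(-lam * distance);
* limiting similarity: species most similar to the rest of the pool are
  removed one at a time until *k* remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .traitsim import TraitMatrix

__all__ = [
    "Optimum",
    "choose_optimum",
    "filter_deterministic",
    "filter_probabilistic",
    "limiting_similarity",
]


@dataclass(frozen=True)
class Optimum:
    """A point in trait space toward which communities are filtered."""

    point: np.ndarray
    mode: str  # "random_species" or "trait_means"


def _values(traits) -> np.ndarray:
    if isinstance(traits, TraitMatrix):
        return traits.values
    return np.asarray(traits, dtype=float)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def choose_optimum(traits, mode: str = "random_species", seed=None) -> Optimum:
    """Pick a trait-space optimum.

    ``random_species``: the trait row of a uniformly drawn species (an
    arbitrary founder).  ``trait_means``: the column means across all
    species.
    """
    X = _values(traits)
    if X.shape[0] == 0:
        raise ValueError("empty trait matrix")
    if mode == "random_species":
        rng = _as_rng(seed)
        i = int(rng.integers(X.shape[0]))
        return Optimum(X[i].copy(), mode)
    if mode == "trait_means":
        return Optimum(X.mean(axis=0), mode)
    raise ValueError(f"unknown optimum mode {mode!r}")


def _distances(X: np.ndarray, optimum) -> np.ndarray:
    point = optimum.point if isinstance(optimum, Optimum) else np.asarray(optimum, float)
    if point.shape[0] != X.shape[1]:
        raise ValueError("optimum length does not match trait count")
    return cdist(X, point[None, :]).ravel()


def filter_deterministic(traits, optimum, k: int) -> np.ndarray:
    """Presence for the *k* species nearest the optimum; ties by tip order."""
    X = _values(traits)
    n = X.shape[0]
    if not 0 < k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    d = _distances(X, optimum)
    chosen = np.argsort(d, kind="stable")[:k]
    out = np.zeros(n, dtype=np.uint8)
    out[chosen] = 1
    return out


def filter_probabilistic(traits, optimum, k: int, lam: float, seed=None) -> np.ndarray:
    """Sample *k* species without replacement with weight exp(-lam * distance).

    Sequential weighted sampling without replacement (draw, remove,
    renormalize), realized via the exponential-race equivalence: take the k
    smallest values of Exp(1)/weight, compared in log space
    (log E_i + lam * d_i) so the weights themselves never underflow.
    lam = 0 is a uniform draw; as lam -> inf the community converges to the
    deterministic filter.

    If lam * distance overflows (non-finite trait values or an absurdly
    tippy effective tree) the selection probabilities are no longer
    representable and an error asks for truncation of the generating
    parameters.
    """
    X = _values(traits)
    n = X.shape[0]
    if not 0 < k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    rng = _as_rng(seed)
    d = _distances(X, optimum)
    logit = lam * (d - d.min())
    if not np.isfinite(logit).all():
        raise FloatingPointError(
            "selection weights exp(-lam*distance) are not representable; "
            "truncate the generating parameters (smaller |a| or lam) to "
            "avoid vanishing probabilities"
        )
    keys = np.log(rng.exponential(size=n)) + logit
    chosen = np.argpartition(keys, k - 1)[:k]
    out = np.zeros(n, dtype=np.uint8)
    out[chosen] = 1
    return out


def limiting_similarity(traits, k: int, criterion: str = "sum") -> np.ndarray:
    """Iteratively drop the species most similar to the others until k remain.

    ``criterion="sum"`` (default) removes the species with the smallest sum
    of Euclidean trait distances to all remaining species; ``"nearest"``
    removes the one with the smallest nearest-neighbour distance.  The
    criterion is recomputed after every removal; ties break toward the
    earliest tip.  The surviving set is trait-overdispersed.
    """
    X = _values(traits)
    n = X.shape[0]
    if not 0 < k < n:
        raise ValueError(f"k={k} must be in 1..{n - 1}")
    if criterion not in ("sum", "nearest"):
        raise ValueError(f"unknown criterion {criterion!r}")
    D = squareform(pdist(X))
    alive = np.ones(n, dtype=bool)
    rowsum = D.sum(axis=1)
    for _ in range(n - k):
        if criterion == "sum":
            score = np.where(alive, rowsum, np.inf)
        else:
            Dm = np.where(alive[None, :] & alive[:, None], D, np.inf)
            np.fill_diagonal(Dm, np.inf)
            score = np.where(alive, Dm.min(axis=1), np.inf)
        drop = int(np.argmin(score))
        alive[drop] = False
        rowsum -= D[drop]
    return alive.astype(np.uint8)
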