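"""Standardized MPD, MPD curves over a transformation gradient, and the
linear-model estimator mapping curves to evolutionary parameters.

The mean pairwise distance (MPD) of a community is the mean patristic
distance over all unordered pairs of present tips.  Its standardized effect
size (SES) compares the observation with a null of equally sized random
draws from the species pool: (obs - null mean) / null sd; negative values
mean phylogenetic clustering.

An *MPD curve* evaluates SES-MPD on a gradient of effective trees from
stemmy to tippy.  Where on the gradient the community is maximally
clustered carries information about the transformation under which the
community-structuring traits evolved, and a linear model on the whole curve
turns that into a parameter estimate.

Null moments can be obtained by Monte-Carlo permutation or analytically:
for a uniform draw of k tips the mean of MPD is the grand mean of pairwise
distances, and its variance has a closed form in the pair-product sums of
the distance matrix (finite-population moments of a U-statistic), which
makes 81-point curves cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .phylo import (
    Phylogeny,
    TransformParameter,
    cophenetic_distances,
)

__all__ = [
    "TransformGrid",
    "MPDCurve",
    "MPDModel",
    "mpd",
    "ses_mpd",
    "null_moments",
    "mpd_curve",
    "mpd_curves_batch",
    "grid_distance_tensor",
    "fit_mpd_model",
    "predict_mpd_model",
    "curve_minimum",
]


def _default_eb_values() -> np.ndarray:
    """-3..3 stepped by 0.1, refined to 0.05 inside [-1, 1]: 81 points."""
    coarse_lo = np.arange(-3.0, -1.0, 0.1)
    fine = np.arange(-1.0, 1.0, 0.05)
    coarse_hi = np.arange(1.0, 3.0 + 1e-9, 0.1)
    return np.round(np.concatenate([coarse_lo, fine, coarse_hi]), 10)


@dataclass(frozen=True)
class TransformGrid:
    """Ordered gradient of transformation parameters (model EB or delta)."""

    model: str = "EB"
    values: np.ndarray = field(default_factory=_default_eb_values)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.model not in ("EB", "delta"):
            raise ValueError(f"unknown transform model {self.model!r}")
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("grid values must be a nonempty 1-D array")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("grid values must be strictly increasing")
        if self.model == "delta" and np.any(self.values <= 0):
            raise ValueError("delta grid values must be positive")

    def __len__(self) -> int:
        return self.values.size

    @classmethod
    def default_eb(cls) -> "TransformGrid":
        return cls("EB", _default_eb_values())

    @classmethod
    def default_delta(cls) -> "TransformGrid":
        """exp of the EB grid: same stemmy-to-tippy sweep for delta."""
        return cls("delta", np.exp(_default_eb_values()))


@dataclass
class MPDCurve:
    """SES-MPD per grid point for one community."""

    grid: TransformGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid),):
            raise ValueError("curve length must match grid length")


@dataclass
class MPDModel:
    """Linear map from an MPD curve to the evolutionary parameter."""

    grid: TransformGrid
    coef: np.ndarray
    intercept: float


def _community_indices(community, n_pool: int) -> np.ndarray:
    """Binary mask (length n_pool, values 0/1) or explicit tip indices."""
    c = np.asarray(community)
    if c.dtype == bool:
        return np.flatnonzero(c)
    if c.size == n_pool and np.isin(c, (0, 1)).all():
        return np.flatnonzero(c)
    return c.astype(np.int64)


def _mpd_idx(dist: np.ndarray, idx: np.ndarray) -> float:
    k = idx.size
    sub = dist[np.ix_(idx, idx)]
    return float(sub.sum() / (k * (k - 1)))


def mpd(dist: np.ndarray, community) -> float:
    """Mean patristic distance over all unordered present pairs."""
    idx = _community_indices(community, dist.shape[0])
    if idx.size < 2:
        raise ValueError("community must contain at least 2 species")
    return _mpd_idx(dist, idx)


def null_moments(dist: np.ndarray, k: int) -> tuple[float, float]:
    """Exact mean and sd of MPD for a uniform k-subset of the pool.

    With pair sums S1 = sum d_p, S2 = sum d_p^2 over unordered pairs p and
    row sums r_i, the second moment splits over pairs-of-pairs sharing 2, 1,
    or 0 indices, with inclusion probabilities k(k-1)/(n(n-1)) etc.
    """
    n = dist.shape[0]
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    iu = np.triu_indices(n, 1)
    dp = dist[iu]
    S1 = float(dp.sum())
    S2 = float((dp * dp).sum())
    r = dist.sum(axis=1)
    share1 = float((r * r).sum()) - 2.0 * S2        # ordered pairs sharing one index
    disjoint = S1 * S1 - S2 - share1
    p2 = k * (k - 1) / (n * (n - 1))
    p3 = p2 * (k - 2) / (n - 2)
    p4 = p3 * (k - 3) / (n - 3) if k >= 2 and n >= 4 else 0.0
    npairs = k * (k - 1) / 2
    mean = S1 / (n * (n - 1) / 2)
    second = (p2 * S2 + p3 * share1 + p4 * disjoint) / npairs**2
    var = max(second - mean * mean, 0.0)
    return mean, float(np.sqrt(var))


def _null_draws(n_pool: int, k: int, n_null: int, rng: np.random.Generator) -> np.ndarray:
    draws = np.empty((n_null, k), dtype=np.int64)
    for i in range(n_null):
        draws[i] = rng.choice(n_pool, size=k, replace=False)
    return draws


def ses_mpd(
    dist: np.ndarray,
    community,
    n_null: int = 499,
    seed=None,
    method: str = "permutation",
) -> float:
    """Standardized MPD against random same-size draws from the pool.

    ``method="permutation"`` uses ``n_null`` Monte-Carlo draws;
    ``"analytic"`` uses the exact moments of :func:`null_moments`.  A null
    standard deviation of zero (e.g. a star tree, where every community has
    the same MPD) yields 0 with a warning.
    """
    idx = _community_indices(community, dist.shape[0])
    k = idx.size
    if k < 2:
        raise ValueError("community must contain at least 2 species")
    obs = _mpd_idx(dist, idx)
    if method == "analytic":
        mu, sd = null_moments(dist, k)
    elif method == "permutation":
        if n_null < 1:
            raise ValueError("n_null must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        draws = _null_draws(dist.shape[0], k, n_null, rng)
        vals = np.array([_mpd_idx(dist, d) for d in draws])
        mu, sd = float(vals.mean()), float(vals.std(ddof=1)) if n_null > 1 else 0.0
    else:
        raise ValueError(f"unknown method {method!r}")
    # relative floor: float summation noise must not masquerade as a null sd
    if sd <= max(abs(mu), 1.0) * 1e-10 or not np.isfinite(sd):
        warnings.warn("null MPD standard deviation is zero; SES set to 0")
        return 0.0
    return (obs - mu) / sd


def grid_distance_tensor(tree: Phylogeny, grid: TransformGrid) -> np.ndarray:
    """(n_grid, n_tips, n_tips) patristic distances of each transformed tree."""
    out = np.empty((len(grid), tree.n_tips, tree.n_tips))
    for g, v in enumerate(grid.values):
        out[g] = cophenetic_distances(TransformParameter(grid.model, float(v)).apply(tree))
    return out


def mpd_curve(
    tree: Phylogeny,
    community,
    grid: TransformGrid | None = None,
    n_null: int = 499,
    seed=None,
    method: str = "analytic",
) -> MPDCurve:
    """SES-MPD across the transformation gradient.

    In permutation mode the same null draws (tip index sets) are reused at
    every grid point so the curve's shape reflects the transformation, not
    resampling noise.
    """
    if grid is None:
        grid = TransformGrid.default_eb()
    idx = _community_indices(community, tree.n_tips)
    k = idx.size
    if k < 2:
        raise ValueError("community must contain at least 2 species")
    D3 = grid_distance_tensor(tree, grid)
    values = np.empty(len(grid))
    if method == "analytic":
        for g in range(len(grid)):
            mu, sd = null_moments(D3[g], k)
            obs = _mpd_idx(D3[g], idx)
            values[g] = 0.0 if sd <= max(abs(mu), 1.0) * 1e-10 else (obs - mu) / sd
    elif method == "permutation":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        draws = _null_draws(tree.n_tips, k, n_null, rng)
        for g in range(len(grid)):
            obs = _mpd_idx(D3[g], idx)
            nulls = np.array([_mpd_idx(D3[g], d) for d in draws])
            sd = nulls.std(ddof=1)
            mu = nulls.mean()
            values[g] = 0.0 if sd <= max(abs(mu), 1.0) * 1e-10 else (obs - mu) / sd
    else:
        raise ValueError(f"unknown method {method!r}")
    return MPDCurve(grid, values)


def mpd_curves_batch(
    tree: Phylogeny,
    communities: np.ndarray,
    grid: TransformGrid | None = None,
    method: str = "analytic",
    D3: np.ndarray | None = None,
    chunk: int = 256,
) -> np.ndarray:
    """SES-MPD curves for many same-size communities on one tree.

    ``communities`` is an (n_sims, n_tips) binary matrix with constant row
    sum k.  Null moments (analytic mode) are computed once per grid point
    and shared across communities, which is what makes curve training sets
    affordable.  Returns an (n_sims, n_grid) matrix.
    """
    if grid is None:
        grid = TransformGrid.default_eb()
    if method != "analytic":
        raise ValueError("batch mode supports the analytic null only")
    C = np.asarray(communities)
    ks = C.sum(axis=1)
    if not np.all(ks == ks[0]):
        raise ValueError("batch mode requires equal community sizes")
    k = int(ks[0])
    if D3 is None:
        D3 = grid_distance_tensor(tree, grid)
    G = len(grid)
    mus = np.empty(G)
    sds = np.empty(G)
    for g in range(G):
        mus[g], sds[g] = null_moments(D3[g], k)
    sds = np.where(sds > np.maximum(np.abs(mus), 1.0) * 1e-10, sds, np.inf)
    idx = np.argsort(~C.astype(bool), axis=1, kind="stable")[:, :k]  # present indices per sim
    n = C.shape[0]
    out = np.empty((n, G))
    denom = k * (k - 1)
    for lo in range(0, n, chunk):
        sl = idx[lo : lo + chunk]                      # (c, k)
        sub = D3[:, sl[:, :, None], sl[:, None, :]]    # (G, c, k, k)
        obs = sub.sum(axis=(2, 3)) / denom             # (G, c)
        out[lo : lo + chunk] = ((obs - mus[:, None]) / sds[:, None]).T
    return out


def fit_mpd_model(curves, a_true) -> MPDModel:
    """OLS of the parameter on curve values; ridge fallback if ill-posed.

    ``curves`` is a list of :class:`MPDCurve` or an (n, n_grid) matrix plus
    a grid taken from the first curve.  With fewer training curves than
    grid points (+2) the normal equations are rank deficient and a lightly
    penalized ridge fit is used instead, with a warning.
    """
    if isinstance(curves, (list, tuple)):
        grid = curves[0].grid
        X = np.stack([c.values for c in curves])
    else:
        raise TypeError("pass a list of MPDCurve; use fit_mpd_model_matrix for arrays")
    return _fit_mpd(X, np.asarray(a_true, float), grid)


def fit_mpd_model_matrix(X: np.ndarray, a_true, grid: TransformGrid) -> MPDModel:
    return _fit_mpd(np.asarray(X, float), np.asarray(a_true, float), grid)


def _fit_mpd(X: np.ndarray, y: np.ndarray, grid: TransformGrid) -> MPDModel:
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    needs_ridge = n < p + 2
    if not needs_ridge:
        coef, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
        needs_ridge = rank < p + 1
    if needs_ridge:
        warnings.warn(
            "MPD-curve design is rank deficient (need > grid length + 1 "
            "training curves for OLS); falling back to ridge"
        )
        from sklearn.linear_model import Ridge

        r = Ridge(alpha=1e-2).fit(X, y)
        return MPDModel(grid, r.coef_.copy(), float(r.intercept_))
    return MPDModel(grid, coef[1:], float(coef[0]))


def predict_mpd_model(model: MPDModel, curve) -> float | np.ndarray:
    """Apply the linear functional to one curve or a stack of curves."""
    if isinstance(curve, MPDCurve):
        v = curve.values
    else:
        v = np.asarray(curve, dtype=float)
    return v @ model.coef + model.intercept


def curve_minimum(curve) -> float:
    """Grid value at which the community is maximally clustered (min SES).

    Ties resolve to the smallest grid value.
    """
    if isinstance(curve, MPDCurve):
        grid, v = curve.grid, curve.values
    else:
        raise TypeError("curve_minimum expects an MPDCurve")
    if v.size == 0:
        raise ValueError("empty curve")
    return float(grid.values[int(np.argmin(v))])
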