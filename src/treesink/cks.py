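"""Convolutional Kitchen Sinks: random convolutional features + ridge.

A kitchen sink turns each observation (a vector of length l, e.g. species
presence/absence in tip order) into f random features: every sliding window
of width w is projected by a fixed w-by-f standard-normal matrix, rectified
(negatives to zero), and the result averaged over windows.  A ridge
regression on those features then maps observations to a target such as an
evolutionary parameter.  This is the one-layer, untrained analogue of a
convolutional network: features are random, only the linear readout is fit.

The normal matrix is frozen by its seed, so a trained model can be
re-applied to new data (and serialized) without storing the matrix itself.
Predictions are clamped to the range of the training targets, since a
linear readout can extrapolate into parameter regions the simulations never
covered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .evaluation import evaluate

__all__ = [
    "CKSConfig",
    "NormalMatrix",
    "CKSModel",
    "SweepResult",
    "BootstrapEstimate",
    "make_norms",
    "gather_windows",
    "clamp",
    "kitchen_sink",
    "fit_cks",
    "kitchen_predict",
    "kitchen_sweep",
    "bootstrap_estimate",
]

#: default ridge-penalty grid for generalized cross-validation
DEFAULT_ALPHAS = np.logspace(-4, 4, 17)

#: cap on elements materialized at once inside kitchen_sink
_CHUNK_ELEMS = 2 ** 24


@dataclass(frozen=True)
class CKSConfig:
    """Hyperparameters of one kitchen sink: window size and feature count."""

    w: int
    f: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w < 1 or self.f < 1:
            raise ValueError("window size and feature count must be >= 1")


@dataclass
class NormalMatrix:
    """Frozen w-by-f standard-normal projection, regenerable from its seed."""

    w: int
    f: int
    seed: object
    matrix: np.ndarray = field(repr=False)


def make_norms(w: int, f: int, seed=0) -> NormalMatrix:
    """Draw the w-by-f i.i.d. N(0, 1) projection matrix."""
    if w < 1 or f < 1:
        raise ValueError("w and f must be >= 1")
    rng = np.random.default_rng(seed)
    return NormalMatrix(w, f, seed, rng.standard_normal((w, f)))


def gather_windows(x: np.ndarray, w: int) -> np.ndarray:
    """All length-w sliding windows of a vector, one per row (no padding)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    if not 1 <= w <= x.size:
        raise ValueError(f"window size {w} outside 1..{x.size}")
    return sliding_window_view(x, w).copy()


def clamp(M: np.ndarray) -> np.ndarray:
    """Rectifier: elementwise max(0, .)."""
    return np.maximum(np.asarray(M, dtype=float), 0.0)


def kitchen_sink(X: np.ndarray, norms: NormalMatrix) -> np.ndarray:
    """Random convolutional features for each row of X.

    Per observation: gather windows, project by the normal matrix, rectify,
    average over windows.  Every row uses the same matrix.  Returns an
    (n, f) feature matrix.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, l = X.shape
    w, f = norms.w, norms.f
    if not 1 <= w <= l:
        raise ValueError(f"window size {w} exceeds observation length {l}")
    n_win = l - w + 1
    out = np.empty((n, f))
    step = max(1, _CHUNK_ELEMS // max(n_win * max(w, f), 1))
    windows = sliding_window_view(X, w, axis=1)  # (n, n_win, w) view
    for lo in range(0, n, step):
        proj = windows[lo : lo + step] @ norms.matrix   # (c, n_win, f)
        np.maximum(proj, 0.0, out=proj)
        out[lo : lo + step] = proj.mean(axis=1)
    return out


@dataclass
class CKSModel:
    """A fitted kitchen-sink regression.

    Holds the frozen projection, the ridge readout, and the training-target
    range used to clamp out-of-range predictions.
    """

    norms: NormalMatrix
    coef: np.ndarray
    intercept: float
    penalty: float
    y_min: float
    y_max: float

    @property
    def config(self) -> CKSConfig:
        seed = self.norms.seed
        return CKSConfig(self.norms.w, self.norms.f, seed if isinstance(seed, int) else 0)


def _ridge_fit(F: np.ndarray, y: np.ndarray, penalty):
    from sklearn.linear_model import Ridge, RidgeCV

    if penalty is None:
        model = RidgeCV(alphas=DEFAULT_ALPHAS)  # efficient LOO/GCV
        model.fit(F, y)
        return model.coef_.copy(), float(model.intercept_), float(model.alpha_)
    model = Ridge(alpha=float(penalty))
    model.fit(F, y)
    return model.coef_.copy(), float(model.intercept_), float(penalty)


def fit_cks(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: CKSConfig | None = None,
    penalty: float | None = None,
    norms: NormalMatrix | None = None,
    features: np.ndarray | None = None,
) -> CKSModel:
    """Fit ridge regression of y on kitchen-sink features of X.

    ``penalty=None`` selects the ridge penalty by generalized (leave-one-
    out) cross-validation over a logarithmic grid; pass a number for exact
    reproducibility of a fixed penalty.  Features are centered through the
    unpenalized intercept.  Precomputed ``features`` (matching ``norms``)
    may be passed to avoid recomputation during sweeps and bootstraps.
    """
    y = np.asarray(y_train, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 training observations")
    if norms is None:
        if config is None:
            raise ValueError("pass a CKSConfig or a NormalMatrix")
        norms = make_norms(config.w, config.f, config.seed)
    F = kitchen_sink(X_train, norms) if features is None else np.asarray(features, float)
    if np.ptp(y) == 0:
        coef, intercept, pen = np.zeros(norms.f), float(y[0]), np.inf
    else:
        coef, intercept, pen = _ridge_fit(F, y, penalty)
    return CKSModel(norms, coef, intercept, pen, float(y.min()), float(y.max()))


def kitchen_predict(model: CKSModel, X_new: np.ndarray, clip: bool = True) -> np.ndarray:
    """Predict targets for new observations.

    New data pass through the same frozen projection; raw linear
    predictions are clamped to [y_min, y_max] of the training targets
    unless ``clip=False``.
    """
    F = kitchen_sink(X_new, model.norms)
    pred = F @ model.coef + model.intercept
    if clip:
        pred = np.clip(pred, model.y_min, model.y_max)
    return pred


@dataclass
class SweepResult:
    """Hyperparameter-sweep table and the winning cell."""

    table: "object"  # pandas DataFrame with columns w, f, adj_r2, r2, slope, penalty
    best_w: int
    best_f: int
    best_adj_r2: float
    best_model: CKSModel


def kitchen_sweep(
    X_train,
    y_train,
    X_val,
    y_val,
    w_grid,
    f_grid,
    base_seed: int = 0,
    penalty: float | None = None,
) -> SweepResult:
    """Grid-search window size and feature count.

    For each (w, f): fit on the training split, predict the validation
    split, regress true on predicted, and score by adjusted R^2.  Each cell
    gets its own normal matrix derived deterministically from ``base_seed``
    and the cell index.  Cells whose fit fails are recorded with NaN and
    skipped.
    """
    import pandas as pd

    X_train = np.atleast_2d(np.asarray(X_train, float))
    X_val = np.atleast_2d(np.asarray(X_val, float))
    l = X_train.shape[1]
    w_grid = [int(w) for w in w_grid]
    f_grid = [int(f) for f in f_grid]
    if not w_grid or not f_grid:
        raise ValueError("hyperparameter grids must be nonempty")
    if max(w_grid) > l:
        raise ValueError(f"window size {max(w_grid)} exceeds observation length {l}")
    rows = []
    best = None
    cell = 0
    for w in w_grid:
        for f in f_grid:
            seed = np.random.SeedSequence([int(base_seed), cell])
            cell += 1
            try:
                norms = NormalMatrix(w, f, (int(base_seed), cell - 1), np.random.default_rng(seed).standard_normal((w, f)))
                model = fit_cks(X_train, y_train, norms=norms, penalty=penalty)
                pred = kitchen_predict(model, X_val)
                rep = evaluate(y_val, pred)
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"sweep cell (w={w}, f={f}) failed: {exc}")
                rows.append(dict(w=w, f=f, adj_r2=np.nan, r2=np.nan, slope=np.nan, penalty=np.nan))
                continue
            rows.append(dict(w=w, f=f, adj_r2=rep.adj_r2, r2=rep.r2, slope=rep.slope, penalty=model.penalty))
            if best is None or rep.adj_r2 > best[0]:
                best = (rep.adj_r2, w, f, model)
    table = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError("every sweep cell failed")
    return SweepResult(table, best[1], best[2], best[0], best[3])


@dataclass
class BootstrapEstimate:
    """Bootstrap point estimate and percentile confidence interval."""

    point: float
    lo: float
    hi: float
    draws: np.ndarray


def bootstrap_estimate(
    X_train,
    y_train,
    x_observed,
    config: CKSConfig | None = None,
    B: int = 100,
    seed=None,
    penalty: float | None = None,
    norms: NormalMatrix | None = None,
    level: float = 0.95,
) -> BootstrapEstimate:
    """Bootstrap a kitchen-sink prediction for one observed vector.

    The training rows are resampled with replacement B times; the model is
    refit each time with the *same* normal matrix and applied to the
    observation.  The point estimate is the mean of the B predictions and
    the interval their 2.5/97.5 percentiles (for the default level).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    y = np.asarray(y_train, dtype=float)
    if norms is None:
        if config is None:
            raise ValueError("pass a CKSConfig or a NormalMatrix")
        norms = make_norms(config.w, config.f, config.seed)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    F = kitchen_sink(X_train, norms)
    f_obs = kitchen_sink(np.atleast_2d(x_observed), norms)
    n = F.shape[0]
    draws = np.empty(B)
    for b in range(B):
        take = rng.integers(n, size=n)
        model = fit_cks(None, y[take], norms=norms, penalty=penalty, features=F[take])
        pred = f_obs @ model.coef + model.intercept
        draws[b] = float(np.clip(pred, model.y_min, model.y_max)[0])
    tail = (1.0 - level) / 2.0 * 100.0
    lo, hi = np.percentile(draws, [tail, 100.0 - tail])
    return BootstrapEstimate(float(draws.mean()), float(lo), float(hi), draws)
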