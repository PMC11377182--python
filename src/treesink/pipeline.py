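"""End-to-end experiment drivers.

These reproduce the simulation studies the estimators are validated on:
draw an evolutionary parameter, rescale the tree, evolve traits, assemble a
community, and repeat; then train the kitchen-sink and MPD-curve estimators
on one split and score them on the other.  The empirical workflow does the
same on a supplied tree and applies the trained model to an observed
presence/absence vector with a bootstrap confidence interval.

All randomness flows from a single master seed through spawned
``numpy.random.SeedSequence`` streams, so a config plus a seed reproduces a
dataset bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import assembly as asm
from . import cks as cks_mod
from . import mpdcurve as mpd_mod
from . import traitsim
from .evaluation import EvaluationReport, evaluate
from .phylo import Phylogeny, eb_rescale, read_newick, simulate_birth_death, tree_depth

__all__ = [
    "ExperimentConfig",
    "SimulatedDataset",
    "ComparisonReport",
    "EmpiricalEstimate",
    "simulate_dataset",
    "run_comparison",
    "run_sensitivity",
    "estimate_empirical",
    "evaluate",
    "EvaluationReport",
]

SENSITIVITY_VARIANTS = (
    "probabilistic",
    "covariance",
    "multi_a_mean",
    "multi_a_max",
    "limiting_similarity",
)


@dataclass
class ExperimentConfig:
    """Everything needed to simulate a training/validation dataset.

    ``a_sd=None`` applies the depth rule sd = 5 / tree depth, which keeps
    the parameter draw inside the phylogenetically informative range as
    trees get deeper.  ``a_bounds`` truncates the normal draw; with
    ``truncation="reject"`` draws outside the bounds are redrawn (an exact
    truncated normal), with ``"clip"`` they are clamped to the bounds.
    """

    # tree source: simulate unless a Newick path/text is given
    n_tips: int = 128
    birth: float = 0.8
    death: float = 0.2
    tree_seed: int = 1
    newick: str | None = None

    # simulation design
    n_sims: int = 2000
    n_train: int = 1200

    # parameter distribution
    a_mean: float = 0.0
    a_sd: float | None = None  # None -> 5 / tree depth
    a_bounds: tuple[float, float] | None = None
    truncation: str = "reject"  # or "clip"

    # trait evolution
    n_traits: int = 10
    sigma2: float = 1.0
    covarying: bool = False
    n_a: int = 1              # >1: traits split over n_a effective trees
    target: str = "a"         # "a", "mean", or "max" (multi-a scenarios)

    # community assembly
    process: str = "deterministic"  # deterministic | probabilistic | limiting_similarity
    k: int = 30
    lam: float = 1.0                 # probabilistic filter rate
    optimum: str = "random_species"  # or "trait_means"

    # estimator settings
    w_grid: Sequence[int] = (4, 16, 64)
    f_grid: Sequence[int] = (64, 256)
    penalty: float | None = None
    mpd_grid: mpd_mod.TransformGrid | None = None

    def __post_init__(self) -> None:
        if self.n_train >= self.n_sims:
            raise ValueError("n_train must be smaller than n_sims")
        if self.process not in ("deterministic", "probabilistic", "limiting_similarity"):
            raise ValueError(f"unknown assembly process {self.process!r}")
        if self.truncation not in ("reject", "clip"):
            raise ValueError(f"unknown truncation mode {self.truncation!r}")
        if self.target not in ("a", "mean", "max"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.n_a > 1 and self.target == "a":
            raise ValueError("multi-a configs must target 'mean' or 'max'")


@dataclass
class SimulatedDataset:
    """Communities (rows, tip order) with the parameters that produced them."""

    tree: Phylogeny
    X: np.ndarray        # (n_sims, n_tips) uint8
    y: np.ndarray        # (n_sims,) regression target
    a_draws: np.ndarray  # (n_sims, n_a) raw parameter draws
    config: ExperimentConfig

    def split(self):
        n_train = self.config.n_train
        return (
            self.X[:n_train],
            self.y[:n_train],
            self.X[n_train:],
            self.y[n_train:],
        )


def resolve_tree(config: ExperimentConfig) -> Phylogeny:
    if config.newick is not None:
        text = config.newick
        if "(" not in text:  # treat as a path
            with open(text) as fh:
                text = fh.read()
        return read_newick(text)
    return simulate_birth_death(config.n_tips, config.birth, config.death, config.tree_seed)


def _draw_a(rng: np.random.Generator, mean: float, sd: float, bounds, mode: str, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    if bounds is None:
        return out
    lo, hi = bounds
    if mode == "clip":
        return np.clip(out, lo, hi)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_dataset(config: ExperimentConfig, seed: int = 0, tree: Phylogeny | None = None) -> SimulatedDataset:
    """Simulate the full community/parameter dataset for one experiment.

    Per simulation: draw the evolutionary parameter(s), build the effective
    tree(s), evolve traits, choose the optimum, and assemble the community.
    The optimum species (random_species mode) is redrawn per simulation.
    """
    if tree is None:
        tree = resolve_tree(config)
    sd = config.a_sd if config.a_sd is not None else 5.0 / tree_depth(tree)
    master = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in master.spawn(config.n_sims)]
    n = tree.n_tips
    X = np.zeros((config.n_sims, n), dtype=np.uint8)
    a_draws = np.empty((config.n_sims, config.n_a))
    y = np.empty(config.n_sims)
    for i, rng in enumerate(streams):
        a = _draw_a(rng, config.a_mean, sd, config.a_bounds, config.truncation, config.n_a)
        a_draws[i] = a
        if config.n_a == 1:
            eff = eb_rescale(tree, float(a[0]))
            if config.covarying:
                traits = traitsim.simulate_covarying(eff, config.n_traits, config.sigma2, seed=rng)
            else:
                traits = traitsim.simulate_bm(eff, config.n_traits, config.sigma2, seed=rng)
            y[i] = a[0]
        else:
            if config.n_traits % config.n_a:
                raise ValueError("n_traits must divide evenly over n_a effective trees")
            traits, _ = traitsim.simulate_multi_a(
                tree, a, config.n_traits // config.n_a, config.sigma2, seed=rng
            )
            y[i] = a.mean() if config.target == "mean" else a.max()
        if config.process == "limiting_similarity":
            X[i] = asm.limiting_similarity(traits, config.k)
            continue
        optimum = asm.choose_optimum(traits, config.optimum, seed=rng)
        if config.process == "deterministic":
            X[i] = asm.filter_deterministic(traits, optimum, config.k)
        else:
            X[i] = asm.filter_probabilistic(traits, optimum, config.k, config.lam, seed=rng)
    return SimulatedDataset(tree, X, y, a_draws, config)


def _usable_w_grid(config: ExperimentConfig, length: int) -> list[int]:
    """Drop sweep windows wider than the observation (tips) length."""
    grid = [int(w) for w in config.w_grid if int(w) <= length]
    if not grid:
        raise ValueError(
            f"no window size in {tuple(config.w_grid)} fits observations of length {length}"
        )
    return grid


@dataclass
class ComparisonReport:
    """Side-by-side validation performance of the two estimators."""

    cks: EvaluationReport
    mpd: EvaluationReport
    sweep: cks_mod.SweepResult
    mpd_model: mpd_mod.MPDModel
    predictions: "object"  # DataFrame: y_true, cks_pred, mpd_pred

    def summary(self) -> str:
        return (
            f"CKS  (w={self.sweep.best_w}, f={self.sweep.best_f}): {self.cks}\n"
            f"MPD curve: {self.mpd}"
        )


def _fit_mpd_estimator(dataset: SimulatedDataset, grid=None):
    config = dataset.config
    grid = grid or config.mpd_grid or mpd_mod.TransformGrid.default_eb()
    curves = mpd_mod.mpd_curves_batch(dataset.tree, dataset.X, grid)
    n_train = config.n_train
    model = mpd_mod.fit_mpd_model_matrix(curves[:n_train], dataset.y[:n_train], grid)
    pred = mpd_mod.predict_mpd_model(model, curves[n_train:])
    return model, pred


def run_comparison(config: ExperimentConfig, seed: int = 0, dataset: SimulatedDataset | None = None) -> ComparisonReport:
    """Train and validate both estimators on one simulated dataset."""
    import pandas as pd

    if dataset is None:
        dataset = simulate_dataset(config, seed)
    X_tr, y_tr, X_val, y_val = dataset.split()
    sweep = cks_mod.kitchen_sweep(
        X_tr, y_tr, X_val, y_val, _usable_w_grid(config, X_tr.shape[1]),
        config.f_grid, base_seed=seed, penalty=config.penalty,
    )
    cks_pred = cks_mod.kitchen_predict(sweep.best_model, X_val)
    mpd_model, mpd_pred = _fit_mpd_estimator(dataset)
    report = ComparisonReport(
        cks=evaluate(y_val, cks_pred),
        mpd=evaluate(y_val, mpd_pred),
        sweep=sweep,
        mpd_model=mpd_model,
        predictions=pd.DataFrame(
            {"y_true": y_val, "cks_pred": cks_pred, "mpd_pred": mpd_pred}
        ),
    )
    return report


def _cks_only(config: ExperimentConfig, seed: int, dataset=None, tree=None) -> tuple[EvaluationReport, cks_mod.SweepResult]:
    if dataset is None:
        dataset = simulate_dataset(config, seed, tree=tree)
    X_tr, y_tr, X_val, y_val = dataset.split()
    sweep = cks_mod.kitchen_sweep(
        X_tr, y_tr, X_val, y_val, _usable_w_grid(config, X_tr.shape[1]),
        config.f_grid, base_seed=seed, penalty=config.penalty,
    )
    pred = cks_mod.kitchen_predict(sweep.best_model, X_val)
    return evaluate(y_val, pred), sweep


def _lambda_truncation(lam: float, depth: float = 7.0, n_traits: int = 10) -> tuple[float, float]:
    """Positive truncation of the parameter draw for probabilistic filters.

    Large positive draws make effective trees tippy and trait distances
    huge; selection probabilities exp(-lam * distance) then fall below the
    smallest representable double and weighted sampling is impossible.  The
    admissible upper bound solves lam * scale(a) ~ 600, where
    scale(a) = sqrt(2 * n_traits * (e^{a T} - 1) / a) is the typical trait-
    distance scale on a depth-T tree, clamped to [1, 3].  Negative draws
    only shrink distances, so the lower bound stays at the grid edge -3.
    """
    from scipy.optimize import brentq

    if lam <= 0:
        return (-3.0, 3.0)
    f = lambda a: lam * np.sqrt(2 * n_traits * (np.exp(a * depth) - 1) / a) - 600.0
    try:
        hi = brentq(f, 0.01, 5.0)
    except ValueError:
        hi = 3.0
    return (-3.0, float(np.clip(hi, 1.0, 3.0)))


def run_sensitivity(variant: str, config: ExperimentConfig | None = None, seed: int = 0, lambdas: Sequence[float] | None = None):
    """Run one of the alternative-assembly sensitivity experiments.

    ``probabilistic``: CKS performance across an exponential-rate (lambda)
    grid from near-random to near-deterministic assembly (k=32; 3000/1000
    split at full scale); returns a list of (lambda, EvaluationReport).

    ``covariance``: independent vs perfectly covarying traits (k=64,
    lambda=0.5); returns {"independent": report, "covarying": report}.

    ``multi_a_mean`` / ``multi_a_max``: recover the mean or max of 2 and 5
    independent parameters (k=32, lambda=3); returns {n_a: report}.

    ``limiting_similarity``: both estimators on limiting-similarity
    communities (k=32, a ~ N(0, 0.5), 1350/650 split); returns a
    ComparisonReport.
    """
    if variant not in SENSITIVITY_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; one of {SENSITIVITY_VARIANTS}")
    base = config or ExperimentConfig(
        n_tips=128, n_sims=4000, n_train=3000, a_sd=1.0, k=32, process="probabilistic"
    )
    tree = resolve_tree(base)
    depth = tree_depth(tree)
    if variant == "probabilistic":
        if lambdas is None:
            lambdas = (0.05, 0.125, 0.25, 0.5, 1.0, 2.0, 5.0)
        out = []
        for j, lam in enumerate(lambdas):
            cfg = replace(base, process="probabilistic", lam=float(lam),
                          a_bounds=_lambda_truncation(float(lam), depth, base.n_traits))
            rep, _ = _cks_only(cfg, seed + j, tree=tree)
            out.append((float(lam), rep))
        return out
    if variant == "covariance":
        cfg = replace(base, process="probabilistic", lam=0.5, k=64, optimum="trait_means",
                      a_bounds=_lambda_truncation(0.5, depth, base.n_traits))
        out = {}
        for label, cov in (("independent", False), ("covarying", True)):
            rep, _ = _cks_only(replace(cfg, covarying=cov), seed, tree=tree)
            out[label] = rep
        return out
    if variant in ("multi_a_mean", "multi_a_max"):
        target = "mean" if variant.endswith("mean") else "max"
        cfg = replace(base, process="probabilistic", lam=3.0, k=32,
                      optimum="trait_means", a_bounds=_lambda_truncation(3.0, depth, base.n_traits))
        out = {}
        for n_a in (2, 5):
            rep, _ = _cks_only(replace(cfg, n_a=n_a, target=target), seed, tree=tree)
            out[n_a] = rep
        return out
    # limiting similarity
    cfg = config or ExperimentConfig(
        n_tips=128, n_sims=2000, n_train=1350, a_sd=0.5, k=32,
        process="limiting_similarity",
    )
    return run_comparison(cfg, seed)


@dataclass
class EmpiricalEstimate:
    """Estimate of the evolutionary parameter behind an observed community."""

    cks_point: float
    cks_lo: float
    cks_hi: float
    mpd_point: float
    sweep: cks_mod.SweepResult
    validation: EvaluationReport
    bootstrap: cks_mod.BootstrapEstimate
    k: int


def estimate_empirical(
    tree: Phylogeny | str,
    membership,
    config: ExperimentConfig | None = None,
    seed: int = 0,
    B: int = 100,
) -> EmpiricalEstimate:
    """Estimate the evolutionary model of an observed community.

    ``membership`` is a binary vector in tip order or a mapping from tip
    label to state, where 1 marks community members.  Training communities
    are simulated on the supplied tree with k equal to the observed
    community size, the kitchen-sink hyperparameters are swept, the best
    model is bootstrapped (B refits on resampled training rows) on the
    observed vector, and the MPD-curve model is applied for comparison.
    """
    if isinstance(tree, str):
        with open(tree) as fh:
            tree = read_newick(fh.read())
    vec = _membership_vector(tree, membership)
    k = int(vec.sum())
    if k == 0 or k == tree.n_tips:
        raise ValueError("degenerate community: membership is all-ones or all-zeros")
    if k < 2:
        raise ValueError("community must contain at least 2 members")
    if config is None:
        config = ExperimentConfig(n_sims=2000, n_train=1200)
    config = replace(config, k=k, n_tips=tree.n_tips)
    dataset = simulate_dataset(config, seed, tree=tree)
    X_tr, y_tr, X_val, y_val = dataset.split()
    sweep = cks_mod.kitchen_sweep(
        X_tr, y_tr, X_val, y_val, _usable_w_grid(config, X_tr.shape[1]),
        config.f_grid, base_seed=seed, penalty=config.penalty,
    )
    validation = evaluate(y_val, cks_mod.kitchen_predict(sweep.best_model, X_val))
    boot = cks_mod.bootstrap_estimate(
        X_tr, y_tr, vec.astype(float), B=B,
        seed=np.random.default_rng(np.random.SeedSequence([seed, 2**20])),
        penalty=sweep.best_model.penalty, norms=sweep.best_model.norms,
    )
    grid = config.mpd_grid or mpd_mod.TransformGrid.default_eb()
    curves = mpd_mod.mpd_curves_batch(tree, dataset.X[: config.n_train], grid)
    mpd_model = mpd_mod.fit_mpd_model_matrix(curves, y_tr, grid)
    obs_curve = mpd_mod.mpd_curve(tree, vec, grid)
    mpd_point = float(mpd_mod.predict_mpd_model(mpd_model, obs_curve))
    return EmpiricalEstimate(
        cks_point=boot.point, cks_lo=boot.lo, cks_hi=boot.hi,
        mpd_point=mpd_point, sweep=sweep, validation=validation,
        bootstrap=boot, k=k,
    )


def _membership_vector(tree: Phylogeny, membership) -> np.ndarray:
    if hasattr(membership, "items"):
        labels = set(tree.tip_labels)
        extra = sorted(set(membership) - labels)
        if extra:
            raise ValueError(f"membership labels not on the tree: {extra[:10]}")
        vec = np.array([int(membership.get(lbl, 0)) for lbl in tree.tip_labels], dtype=np.uint8)
    else:
        vec = np.asarray(membership).astype(np.uint8)
        if vec.shape != (tree.n_tips,):
            raise ValueError("membership vector length must equal the number of tips")
    if not np.isin(vec, (0, 1)).all():
        raise ValueError("membership states must be 0/1")
    return vec
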