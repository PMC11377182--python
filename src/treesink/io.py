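"""Delimited-text I/O for communities, traits, curves, and models."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mpdcurve import MPDCurve, MPDModel, TransformGrid
from .phylo import Phylogeny
from .traitsim import TraitMatrix

__all__ = [
    "write_community",
    "read_community",
    "write_community_matrix",
    "read_community_matrix",
    "write_traits",
    "read_traits",
    "write_curve",
    "read_curve",
    "write_mpd_model",
    "read_mpd_model",
]


def write_community(path, tree: Phylogeny, membership) -> None:
    """Two-column table: tip label, 0/1 presence."""
    vec = np.asarray(membership).astype(int)
    pd.DataFrame({"tip": tree.tip_labels, "present": vec}).to_csv(path, sep="\t", index=False)


def read_community(path, tree: Phylogeny) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    states = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)))
    missing = [t for t in tree.tip_labels if t not in states]
    if missing:
        raise ValueError(f"tips missing from community table: {missing[:10]}")
    return np.array([states[t] for t in tree.tip_labels], dtype=np.uint8)


def write_community_matrix(path, tree: Phylogeny, X, y=None) -> None:
    """Batch simulation output: one community per row, tips as columns.

    If targets ``y`` are given they are stored in a leading ``a_true``
    column.
    """
    df = pd.DataFrame(np.asarray(X, dtype=int), columns=tree.tip_labels)
    if y is not None:
        df.insert(0, "a_true", np.asarray(y, dtype=float))
    df.to_csv(path, sep="\t", index=False)


def read_community_matrix(path):
    df = pd.read_csv(path, sep="\t")
    y = None
    if df.columns[0] == "a_true":
        y = df.pop("a_true").to_numpy()
    return df.to_numpy(dtype=np.uint8), y, list(df.columns)


def write_traits(path, traits: TraitMatrix) -> None:
    traits.to_frame().to_csv(path, sep="\t", index_label="tip")


def read_traits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_curve(path, curve: MPDCurve) -> None:
    pd.DataFrame({"grid": curve.grid.values, "ses_mpd": curve.values}).to_csv(
        path, sep="\t", index=False
    )


def read_curve(path, model: str = "EB") -> MPDCurve:
    df = pd.read_csv(path, sep="\t")
    return MPDCurve(TransformGrid(model, df["grid"].to_numpy()), df["ses_mpd"].to_numpy())


def write_mpd_model(path, model: MPDModel) -> None:
    df = pd.DataFrame({"grid": model.grid.values, "coef": model.coef})
    df.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"# model={model.grid.model} intercept={model.intercept!r}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_mpd_model(path) -> MPDModel:
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, sep="\t")
    fields = dict(tok.split("=") for tok in header.lstrip("# ").split())
    grid = TransformGrid(fields["model"], df["grid"].to_numpy())
    return MPDModel(grid, df["coef"].to_numpy(), float(fields["intercept"]))
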