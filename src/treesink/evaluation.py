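"""Validation regression of true parameters on predictions."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["EvaluationReport", "evaluate"]


@dataclass
class EvaluationReport:
    """Fit of true values regressed on predicted values (one predictor)."""

    r2: float
    adj_r2: float
    slope: float
    intercept: float
    n: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"R2={self.r2:.3f} adjR2={self.adj_r2:.3f} "
            f"slope={self.slope:.3f} (n={self.n})"
        )


def evaluate(true, predicted) -> EvaluationReport:
    """Regress true on predicted; report R2, adjusted R2 (p=1), and slope.

    A perfect estimator gives R2 = 1 and slope = 1.  If the predictions have
    zero variance the regression is undefined and R2 = slope = 0 is
    returned with a warning.
    """
    y = np.asarray(true, dtype=float)
    x = np.asarray(predicted, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("true and predicted must be equal-length 1-D arrays")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 points")
    vx = x.var()
    if vx <= 0 or not np.isfinite(vx):
        warnings.warn("predictions have zero variance; R2 set to 0")
        return EvaluationReport(0.0, 0.0, 0.0, float(y.mean()), n)
    slope = float(np.cov(x, y, ddof=1)[0, 1] / x.var(ddof=1))
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return EvaluationReport(r2, adj, slope, intercept, n)
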