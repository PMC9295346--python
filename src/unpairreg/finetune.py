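"""Covariance-preserving refinement of predicted expression.

The regression stage predicts E_hat = O beta for the ATAC cells. Fine-tuning
searches for a nonnegative matrix X near that prediction whose gene-gene
inner products match R1 = (n1/n2) E'E and whose cell-cell inner products
match R2 = (mu2/mu1) OO' (scaling factors bridge the cell-count and
data-type gaps), by minimizing

    ||R1 - X'X||_F^2 + lambda1 ||R2 - XX'||_F^2

with the multiplicative fixed-point update X <- X * B / C,
B = X R1 + lambda1 R2 X, C = (1 + lambda1) X X' X. Multiplicative updates
preserve nonnegativity; zeros stay zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .types import CellMatrix

__all__ = [
    "ScaledTargets",
    "build_scaled_targets",
    "finetune_objective",
    "finetune_expression",
    "CovarianceFineTuner",
]

_EPS = 1e-12


@dataclass
class ScaledTargets:
    """Scaled covariance targets for fine-tuning."""

    R1: np.ndarray  # p2 x p2, (n1/n2) E'E
    R2: np.ndarray  # n1 x n1, (mu2/mu1) OO'
    mu1: float  # mean of OO'
    mu2: float  # mean of EE'


def build_scaled_targets(E: CellMatrix, O: CellMatrix) -> ScaledTargets:
    """Gene-gene and cell-cell targets with cell-count / data-type scaling."""
    OOt = O.values @ O.values.T
    EEt = E.values @ E.values.T
    mu1 = float(OOt.mean())
    mu2 = float(EEt.mean())
    if mu1 <= 0 or mu2 <= 0:
        raise ValueError("zero covariance scale; inputs must be nonzero")
    R1 = (O.n_cells / E.n_cells) * (E.values.T @ E.values)
    R2 = (mu2 / mu1) * OOt
    return ScaledTargets(R1=R1, R2=R2, mu1=mu1, mu2=mu2)


def finetune_objective(X: np.ndarray, targets: ScaledTargets, lambda1: float = 0.5) -> float:
    """||R1 - X'X||_F^2 + lambda1 ||R2 - XX'||_F^2."""
    g = targets.R1 - X.T @ X
    c = targets.R2 - X @ X.T
    return float(np.sum(g * g) + lambda1 * np.sum(c * c))


def finetune_expression(
    X0: np.ndarray,
    targets: ScaledTargets,
    lambda1: float = 0.5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Iterate the multiplicative update from X0 until the objective stalls.

    Negative entries of X0 (the regression coefficients are unconstrained)
    are clipped to zero first. Returns the refined nonnegative matrix and an
    objective trace (iteration, objective).
    """
    X = np.asarray(X0, dtype=np.float64)
    if X.size and X.min() < 0:
        warnings.warn(
            "negative entries in fine-tuning start point clipped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        X = np.clip(X, 0.0, None)
    else:
        X = X.copy()
    # scale-matched start: multiplicative updates overshoot badly when
    # X0'X0 and R1 live on different scales; the optimal global rescaling
    # s minimizing ||R1 - s^2 X'X||_F has a closed form
    gram = X.T @ X
    denom = float(np.sum(gram * gram))
    if denom > 0:
        s2 = float(np.sum(targets.R1 * gram)) / denom
        if s2 > 0:
            X *= np.sqrt(s2)
    trace = [(0, finetune_objective(X, targets, lambda1))]
    for it in range(1, max_iter + 1):
        B = X @ targets.R1 + lambda1 * (targets.R2 @ X)
        C = (1.0 + lambda1) * (X @ (X.T @ X))
        X *= B / (C + _EPS)
        obj = finetune_objective(X, targets, lambda1)
        prev = trace[-1][1]
        trace.append((it, obj))
        if prev > 0 and abs(prev - obj) / prev < tol:
            break
    return X, pd.DataFrame(trace, columns=["iteration", "objective"])


class CovarianceFineTuner(BaseEstimator, TransformerMixin):
    """Transformer form of the fine-tuning step.

    ``fit(E, O)`` computes the scaled covariance targets;
    ``transform(X0)`` refines a predicted expression matrix for the O cells.

    Attributes
    ----------
    targets_ : ScaledTargets
    objective_trace_ : pandas.DataFrame (from the last transform)
    """

    def __init__(self, lambda1: float = 0.5, max_iter: int = 200, tol: float = 1e-6):
        self.lambda1 = lambda1
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, E: CellMatrix, O: CellMatrix) -> "CovarianceFineTuner":
        self.targets_ = build_scaled_targets(E, O)
        return self

    def transform(self, X0: np.ndarray) -> np.ndarray:
        if not hasattr(self, "targets_"):
            raise RuntimeError("fine-tuner is not fitted")
        X, trace = finetune_expression(
            X0, self.targets_, lambda1=self.lambda1, max_iter=self.max_iter, tol=self.tol
        )
        self.objective_trace_ = trace
        return X
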