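"""Soft-margin RBF support-vector classifier over the fused features.

Thin wrapper around sklearn's SVC solving the usual dual of
min 1/2 ||w||^2 + C sum xi_i with the Gaussian kernel
K(x, x') = exp(-gamma ||x - x'||^2). The positive class is label 1, so the
signed decision score is > 0 for predicted responders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

KKT_TOL = 1e-6


@dataclass
class SVMModel:
    """Fitted classifier plus the resolved hyperparameters."""

    svc: SVC
    C: float
    gamma: float

    @property
    def dual_coef(self) -> np.ndarray:
        """alpha_i * y_i for the support vectors."""
        return self.svc.dual_coef_.ravel()

    @property
    def support_vectors(self) -> np.ndarray:
        return self.svc.support_vectors_

    @property
    def bias(self) -> float:
        return float(self.svc.intercept_[0])

    def kkt_box_satisfied(self, tol: float = KKT_TOL) -> bool:
        """Dual box constraint 0 <= alpha_i <= C at tolerance."""
        return bool(np.all(np.abs(self.dual_coef) <= self.C + tol))


def resolve_gamma(X, gamma) -> float:
    """Numeric kernel width; ``"scale"`` means 1 / (d * var(X))."""
    if gamma == "scale":
        X = np.asarray(X, dtype=float)
        var = X.var()
        if var == 0.0:
            raise ValueError("cannot resolve gamma='scale' on zero-variance input")
        return 1.0 / (X.shape[1] * var)
    g = float(gamma)
    if g <= 0:
        raise ValueError("gamma must be > 0")
    return g


def fit_svm(X, y, C: float = 1.0, gamma="scale") -> SVMModel:
    """Fit the soft-margin RBF SVM on the fused training matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, d) with one label per row")
    if len(np.unique(y)) < 2:
        raise ValueError("single-class input: SVM needs both classes")
    if C <= 0:
        raise ValueError("C must be > 0")
    g = resolve_gamma(X, gamma)
    svc = SVC(C=C, kernel="rbf", gamma=g)
    svc.fit(X, y)
    model = SVMModel(svc=svc, C=C, gamma=g)
    if not model.kkt_box_satisfied():  # pragma: no cover - solver guarantee
        raise RuntimeError("dual coefficients violate the box constraint")
    return model


def decision_score(model: SVMModel, X) -> np.ndarray | float:
    """Signed margin of row(s) X; positive predicts the positive class."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    scores = model.svc.decision_function(np.atleast_2d(X))
    return float(scores[0]) if single else scores
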