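"""Kernel logistic regression on source + transported target samples.

After transport, the classifier sees AD and NC subjects together with the
transported L-MCI / E-MCI training subjects, coded by the class pairing
(+1 = AD / L-MCI side, -1 = NC / E-MCI side).  The classifier is a
ridge-penalized kernel logistic regression

    min_{alpha, b}  sum_i log(1 + exp(-y_i f_i)) + (ridge/2) alpha' K alpha,
    f = K alpha + b,

with linear or polynomial kernel, fitted by L-BFGS with analytic
gradients.  Linear SVM and plain logistic regression (scikit-learn) serve
as the no-transport baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .io import BinaryTask

logger = logging.getLogger(__name__)

__all__ = [
    "KernelSpec",
    "TrainedClassifier",
    "KernelLogistic",
    "kernel_matrix",
    "build_training_set",
    "fit_kernel_logistic",
    "predict_proba",
    "fit_baseline",
]

_RIDGE_FLOOR = 1e-8


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and regularization for the source-domain classifier."""

    kind: str = "linear"  # linear | polynomial
    degree: int = 2
    coef0: float = 1.0
    scale: float = 1.0
    ridge: float = 1.0

    def __post_init__(self):
        if self.kind not in ("linear", "polynomial"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "polynomial" and self.degree < 2:
            raise ValueError("polynomial degree must be >= 2")
        if self.ridge < 0:
            raise ValueError("ridge must be nonnegative")


def kernel_matrix(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Gram matrix K[i, j] = k(A_i, B_j); PSD on any sample set."""
    A, B = np.atleast_2d(A), np.atleast_2d(B)
    inner = A @ B.T
    if spec.kind == "linear":
        return spec.scale * inner
    return (spec.scale * inner + spec.coef0) ** spec.degree


@dataclass
class TrainedClassifier:
    """Fitted kernel logistic model (dual form).

    ``label_semantics``: +1 is the AD / L-MCI side, -1 the NC / E-MCI side.
    """

    kernel: KernelSpec
    support_features: np.ndarray
    dual_weights: np.ndarray
    intercept: float
    converged: bool = True
    provenance: dict = None

    def decision_function(self, samples: np.ndarray) -> np.ndarray:
        samples = np.atleast_2d(samples)
        if samples.shape[1] != self.support_features.shape[1]:
            raise ValueError("feature dimension mismatch")
        K = kernel_matrix(self.kernel, samples, self.support_features)
        return K @ self.dual_weights + self.intercept

    def predict_proba(self, samples: np.ndarray) -> np.ndarray:
        """P(y = +1); sigmoid of the kernel decision value."""
        return expit(self.decision_function(samples))

    def predict(self, samples: np.ndarray) -> np.ndarray:
        """+1 iff the probability is >= 0.5."""
        return np.where(self.predict_proba(samples) >= 0.5, 1, -1)

    def summary(self) -> str:
        n, d = self.support_features.shape
        prov = self.provenance or {}
        return "\n".join(
            [
                "Kernel logistic classifier",
                "=" * 40,
                f"kernel: {self.kernel.kind} "
                + (
                    f"(degree={self.kernel.degree}, coef0={self.kernel.coef0:g}) "
                    if self.kernel.kind == "polynomial"
                    else ""
                )
                + f"ridge={self.kernel.ridge:g}",
                f"training samples: {n} (features: {d})"
                + (f", provenance: {prov}" if prov else ""),
                f"intercept: {self.intercept:.4g}  converged: {self.converged}",
            ]
        )


def build_training_set(source: BinaryTask, transported: np.ndarray, labels: np.ndarray):
    """Stack source samples with transported target-train samples.

    AD and L-MCI code +1, NC and E-MCI code -1 (the transport pairing),
    so the two sample provenances share one label semantics.  Returns
    (X, y, provenance) where provenance counts rows per origin.
    """
    labels = np.asarray(labels, int)
    transported = np.atleast_2d(np.asarray(transported, float))
    if transported.size and transported.shape[1] != source.X.shape[1]:
        raise ValueError("transported samples do not match the source feature space")
    if transported.size and not np.all(np.isin(labels, (-1, 1))):
        raise ValueError("transported labels must be +/-1")
    if transported.size == 0:
        X, y = source.X, source.y
        prov = {"source": len(source.y), "transported": 0}
    else:
        X = np.vstack([source.X, transported])
        y = np.concatenate([source.y, labels])
        prov = {"source": len(source.y), "transported": len(labels)}
    return X, y, prov


def fit_kernel_logistic(
    X: np.ndarray,
    y: np.ndarray,
    kernel: KernelSpec = KernelSpec(),
    provenance: dict = None,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> TrainedClassifier:
    """Fit the ridge-penalized kernel logistic model by L-BFGS."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("training labels must contain both classes, coded +/-1")
    ridge = kernel.ridge
    if ridge < _RIDGE_FLOOR:
        logger.info("ridge %.2g below floor; using %.2g", ridge, _RIDGE_FLOOR)
        ridge = _RIDGE_FLOOR
    K = kernel_matrix(kernel, X, X)

    n = len(y)

    def objective(theta):
        alpha, b = theta[:n], theta[n]
        Ka = K @ alpha
        f = Ka + b
        margins = y * f
        # log(1 + exp(-m)) computed stably
        loss = np.sum(np.logaddexp(0.0, -margins))
        value = loss + 0.5 * ridge * float(alpha @ Ka)
        dLdf = -y * expit(-margins)
        grad_alpha = K @ dLdf + ridge * Ka
        grad_b = dLdf.sum()
        return value, np.concatenate([grad_alpha, [grad_b]])

    res = minimize(
        objective,
        np.zeros(n + 1),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
    )
    return TrainedClassifier(
        kernel=KernelSpec(
            kind=kernel.kind,
            degree=kernel.degree,
            coef0=kernel.coef0,
            scale=kernel.scale,
            ridge=ridge,
        ),
        support_features=X,
        dual_weights=res.x[:n],
        intercept=float(res.x[n]),
        converged=bool(res.success),
        provenance=provenance,
    )


class KernelLogistic:
    """Model wrapper: ``KernelLogistic(X, y, kernel).fit()`` -> classifier."""

    def __init__(self, X, y, kernel: KernelSpec = KernelSpec()):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y)
        self.kernel = kernel

    def fit(self, **kwargs) -> TrainedClassifier:
        return fit_kernel_logistic(self.X, self.y, self.kernel, **kwargs)


def predict_proba(model, samples: np.ndarray) -> np.ndarray:
    """P(y = +1) for a :class:`TrainedClassifier` or sklearn estimator."""
    if isinstance(model, TrainedClassifier):
        return model.predict_proba(samples)
    if hasattr(model, "predict_proba"):
        return model.predict_proba(samples)[:, list(model.classes_).index(1)]
    return expit(model.decision_function(samples))


def fit_baseline(train: BinaryTask, model: str = "logistic", C: float = 1.0):
    """No-transport baselines on the raw (selected) target features."""
    if len(np.unique(train.y)) < 2:
        raise ValueError("baseline fit requires both classes")
    if model == "SVM":
        clf = SVC(kernel="linear", C=C)
    elif model == "logistic":
        clf = LogisticRegression(C=C, max_iter=2000)
    else:
        raise ValueError(f"unknown baseline {model!r}")
    clf.fit(train.X, train.y)
    return clf
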