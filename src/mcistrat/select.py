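"""Feature selection: one-way ANOVA filter and the rMLTFL multi-task model.

Two routes select ROI features for the E-MCI/L-MCI stratification task:

* :func:`anova_select` — per-feature one-way ANOVA between the two target
  groups; a feature is kept when its p-value falls below ``alpha``.  With
  two groups the F statistic is the square of the pooled-variance t
  statistic.

* rMLTFL (robust multi-label transfer feature learning) — a multi-task
  sparse regression.  Three auxiliary classifiers (AD vs NC, AD vs MCI,
  MCI vs NC) each predict a label for every target subject; the true
  target label plus the three predictions form the multi-bit label matrix
  ``Y`` (n x 4).  A weight matrix ``W = P + Q`` (d x 4) is then fitted by

      min ||Y - XW||_F^2 + l1 ||P||_{2,1} + l2 ||Q^T||_{2,1}
          + l3 sum_i ||(X w_t - X w_i) - (y_t - y_p_i)||^2

  where the row-wise group penalty on ``P`` selects features shared across
  tasks and the column-wise penalty on ``Q`` discards unhelpful auxiliary
  domains.  The coupling term keeps the gap between the target prediction
  and each auxiliary prediction close to the gap between the corresponding
  labels.  The problem is solved with an accelerated proximal-gradient
  (FISTA) scheme with backtracking and a monotone restart, the group
  penalties entering through their exact proximal operator
  (:func:`prox_group_l21`).  Domains whose ``Q`` column vanishes are
  pruned and the model refitted without them; features are the nonzero
  rows of ``P`` in the refit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io import BinaryTask, FeatureTable, Modality, TaskName, make_binary_task

logger = logging.getLogger(__name__)

__all__ = [
    "MultiBitLabelMatrix",
    "WeightDecomposition",
    "SelectionResult",
    "anova_select",
    "fit_auxiliary_models",
    "build_multibit_labels",
    "prox_group_l21",
    "rmltfl_objective",
    "rmltfl_fit",
    "MultiTaskFeatureSelector",
    "filter_and_refit",
    "grid_search_rmltfl",
    "default_lambda_grid",
]

#: Auxiliary task order used for the multi-bit label columns 1..3.
AUX_TASK_ORDER = (TaskName.AD_vs_NC, TaskName.AD_vs_MCI, TaskName.MCI_vs_NC)

#: A group (row/column) counts as zero when its norm falls below this
#: fraction of the largest group norm in the matrix.
ZERO_GROUP_RTOL = 1e-6


@dataclass(frozen=True)
class MultiBitLabelMatrix:
    """Per-subject true target label plus three auxiliary predictions."""

    Y: np.ndarray
    column_tasks: tuple

    def __post_init__(self):
        Y = np.asarray(self.Y, float)
        if not np.all(np.isin(Y, (-1.0, 1.0))):
            raise ValueError("multi-bit labels must be +/-1")
        object.__setattr__(self, "Y", Y)

    @property
    def n_tasks(self) -> int:
        return self.Y.shape[1]


@dataclass
class WeightDecomposition:
    """Fitted W = P + Q with its hyperparameters and derived masks."""

    P: np.ndarray
    Q: np.ndarray
    lambda1: float
    lambda2: float
    lambda3: float
    objective: float = np.nan
    objective_trace: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    @property
    def W(self) -> np.ndarray:
        return self.P + self.Q

    @property
    def selected_features(self) -> np.ndarray:
        """True where a row of P has nonzero norm (relative tolerance)."""
        norms = np.linalg.norm(self.P, axis=1)
        return norms > ZERO_GROUP_RTOL * max(norms.max(), np.finfo(float).tiny)

    @property
    def retained_domains(self) -> np.ndarray:
        """Per *auxiliary* column of Q: False where the column vanishes."""
        norms = np.linalg.norm(self.Q, axis=0)
        keep = norms > ZERO_GROUP_RTOL * max(norms.max(), np.finfo(float).tiny)
        return keep[1:]  # column 0 is the target task, never pruned


@dataclass
class SelectionResult:
    """Outcome of a feature-selection run."""

    method: str  # "ANOVA" or "rMLTFL"
    modality: Modality
    feature_indices: list
    per_fold_indices: Optional[list] = None
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        self.feature_indices = sorted(int(i) for i in self.feature_indices)
        if self.per_fold_indices is not None:
            union = sorted({int(i) for fold in self.per_fold_indices for i in fold})
            if union != self.feature_indices:
                raise ValueError("feature_indices must be the union of per-fold sets")

    @property
    def n_selected(self) -> int:
        return len(self.feature_indices)


# ---------------------------------------------------------------------------
# ANOVA filter
# ---------------------------------------------------------------------------

def anova_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature one-way ANOVA p-values between the groups of ``y``.

    Features with zero between-group variance (e.g. constant columns) get
    p = 1 rather than NaN.
    """
    groups = [X[y == g] for g in np.unique(y)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 subjects for ANOVA")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.f_oneway(*groups, axis=0)
    return np.where(np.isnan(p), 1.0, p)


def anova_select(task: BinaryTask | FeatureTable, alpha: float = 0.05) -> SelectionResult:
    """Keep features whose one-way ANOVA p-value is below ``alpha``."""
    if isinstance(task, FeatureTable):
        task = make_binary_task(task, TaskName.LMCI_vs_EMCI)
    p = anova_pvalues(task.X, task.y)
    idx = np.flatnonzero(p < alpha)
    return SelectionResult(
        method="ANOVA",
        modality=task.table.modality,
        feature_indices=idx.tolist(),
        hyperparameters={"alpha": alpha},
    )


# ---------------------------------------------------------------------------
# Multi-bit labels
# ---------------------------------------------------------------------------

def fit_auxiliary_models(aux_tasks: Sequence[BinaryTask], C: float = 1.0):
    """Fit one linear logistic model per auxiliary task (deterministic)."""
    models = []
    for task in aux_tasks:
        if len(np.unique(task.y)) < 2:
            raise ValueError(f"auxiliary task {task.name} has a single class")
        m = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
        m.fit(task.X, task.y)
        models.append(m)
    return models


def build_multibit_labels(target: BinaryTask, aux_models) -> MultiBitLabelMatrix:
    """Concatenate the true target label with three hard aux predictions.

    Predictions are thresholded at probability 0.5, giving +/-1 labels;
    column 0 is the true target label bit-for-bit.
    """
    cols = [np.asarray(target.y, float)]
    for m in aux_models:
        if m.coef_.shape[1] != target.X.shape[1]:
            raise ValueError(
                f"auxiliary model expects {m.coef_.shape[1]} features, "
                f"target has {target.X.shape[1]}"
            )
        proba = m.predict_proba(target.X)[:, list(m.classes_).index(1)]
        cols.append(np.where(proba >= 0.5, 1.0, -1.0))
    return MultiBitLabelMatrix(
        Y=np.column_stack(cols),
        column_tasks=(target.name,) + tuple(AUX_TASK_ORDER[: len(aux_models)]),
    )


# ---------------------------------------------------------------------------
# rMLTFL optimization
# ---------------------------------------------------------------------------

def prox_group_l21(M: np.ndarray, threshold: float, axis: str = "rows") -> np.ndarray:
    """Proximal operator of ``threshold * sum_g ||g||_2`` over rows/columns.

    Each group g maps to ``max(0, 1 - threshold/||g||) * g``; zero groups
    stay zero.  This is the exact minimizer of
    ``(1/2)||Z - M||_F^2 + threshold * sum_g ||Z_g||``.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    M = np.asarray(M, float)
    ax = 1 if axis == "rows" else 0
    norms = np.linalg.norm(M, axis=ax, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.maximum(0.0, 1.0 - threshold / norms)
    scale = np.where(norms > 0, scale, 0.0)
    return M * scale


def _smooth_parts(X, Y, W, lambda3):
    """Value and gradient (wrt W) of the smooth objective terms."""
    E = X @ W
    R = Y - E
    value = float(np.sum(R * R))
    G = -2.0 * (X.T @ R)
    if lambda3 > 0 and W.shape[1] > 1:
        # coupling: for each aux column i, D_i = (Xw_t - Xw_i) - (y_t - y_i)
        D = (E[:, [0]] - E[:, 1:]) - (Y[:, [0]] - Y[:, 1:])
        value += lambda3 * float(np.sum(D * D))
        XtD = X.T @ D
        G[:, 0] += 2.0 * lambda3 * XtD.sum(axis=1)
        G[:, 1:] -= 2.0 * lambda3 * XtD
    return value, G


def rmltfl_objective(
    X: np.ndarray,
    Y: MultiBitLabelMatrix | np.ndarray,
    dec: WeightDecomposition,
) -> float:
    """Value of the four-term rMLTFL objective at ``dec`` (W = P + Q)."""
    Ym = Y.Y if isinstance(Y, MultiBitLabelMatrix) else np.asarray(Y, float)
    smooth, _ = _smooth_parts(X, Ym, dec.W, dec.lambda3)
    pen = dec.lambda1 * np.linalg.norm(dec.P, axis=1).sum()
    pen += dec.lambda2 * np.linalg.norm(dec.Q, axis=0).sum()
    return smooth + float(pen)


def rmltfl_fit(
    X: np.ndarray,
    Y: MultiBitLabelMatrix | np.ndarray,
    lambdas: Sequence[float],
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> WeightDecomposition:
    """Fit W = P + Q by accelerated proximal gradient (FISTA).

    The smooth part (data fit + coupling) is handled by gradient steps
    with backtracking from a Lipschitz-bound initial step; the two group
    penalties by :func:`prox_group_l21` on rows of P and columns of Q.
    A monotone restart keeps the best-iterate objective non-increasing.
    Non-convergence at ``max_iter`` is reported via ``converged=False``,
    never an exception.
    """
    lambda1, lambda2, lambda3 = (float(v) for v in lambdas)
    if min(lambda1, lambda2, lambda3) < 0:
        raise ValueError("penalty weights must be nonnegative")
    Ym = Y.Y if isinstance(Y, MultiBitLabelMatrix) else np.asarray(Y, float)
    X = np.asarray(X, float)
    n, d = X.shape
    T = Ym.shape[1]

    P = np.zeros((d, T))
    Q = np.zeros((d, T))
    # Lipschitz bound for grad wrt W: 2||X||^2 (1 + 2 lambda3 (T-1));
    # the (P, Q) joint variable doubles it.  Backtracking refines.
    sigma2 = np.linalg.norm(X, 2) ** 2
    L = 4.0 * sigma2 * (1.0 + 2.0 * lambda3 * max(T - 1, 1)) + 1e-12
    step = 1.0 / L

    def penalty(Pm, Qm):
        return lambda1 * np.linalg.norm(Pm, axis=1).sum() + lambda2 * np.linalg.norm(
            Qm, axis=0
        ).sum()

    f0, _ = _smooth_parts(X, Ym, P + Q, lambda3)
    best_obj = f0 + penalty(P, Q)
    best = (P.copy(), Q.copy())
    trace = [best_obj]

    Py, Qy = P.copy(), Q.copy()
    t_momentum = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        fy, G = _smooth_parts(X, Ym, Py + Qy, lambda3)
        while True:
            P_new = prox_group_l21(Py - step * G, step * lambda1, axis="rows")
            Q_new = prox_group_l21(Qy - step * G, step * lambda2, axis="columns")
            f_new, _ = _smooth_parts(X, Ym, P_new + Q_new, lambda3)
            dP, dQ = P_new - Py, Q_new - Qy
            quad = fy + np.sum(G * dP) + np.sum(G * dQ) + (
                np.sum(dP * dP) + np.sum(dQ * dQ)
            ) / (2 * step)
            if f_new <= quad + 1e-12 * max(1.0, abs(quad)):
                break
            step *= 0.5

        obj_new = f_new + penalty(P_new, Q_new)
        if obj_new > best_obj:  # monotone restart: drop momentum
            Py, Qy = best[0].copy(), best[1].copy()
            t_momentum = 1.0
            P, Q = best[0].copy(), best[1].copy()
            trace.append(best_obj)
            continue

        rel_change = abs(best_obj - obj_new) / max(1.0, abs(best_obj))
        best_obj = obj_new
        best = (P_new.copy(), Q_new.copy())
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_momentum**2)) / 2.0
        beta = (t_momentum - 1.0) / t_next
        Py = P_new + beta * (P_new - P)
        Qy = Q_new + beta * (Q_new - Q)
        P, Q, t_momentum = P_new, Q_new, t_next
        trace.append(best_obj)
        if rel_change < tol:
            converged = True
            break
    else:
        logger.debug("rmltfl_fit hit max_iter=%d without convergence", max_iter)

    return WeightDecomposition(
        P=best[0],
        Q=best[1],
        lambda1=lambda1,
        lambda2=lambda2,
        lambda3=lambda3,
        objective=best_obj,
        objective_trace=trace,
        converged=converged,
        n_iter=it,
    )


class MultiTaskFeatureSelector:
    """rMLTFL model: multi-task sparse regression on multi-bit labels.

    Parameters
    ----------
    X : ndarray (n_subjects, n_features)
        Target-domain feature matrix, column-scaled to [0, 1].
    Y : MultiBitLabelMatrix or ndarray (n_subjects, 4)
    lambdas : (lambda1, lambda2, lambda3)
        Feature-sparsity, domain-sparsity and coupling weights.

    ``fit()`` returns a :class:`MultiTaskFeatureSelectorResults` carrying
    the W = P + Q decomposition, the selected-feature / retained-domain
    masks after domain pruning, and convergence diagnostics.
    """

    def __init__(self, X, Y, lambdas=(1.0, 1.0, 1.0)):
        self.X = np.asarray(X, float)
        if not isinstance(Y, MultiBitLabelMatrix):
            Y = np.asarray(Y, float)
            names = ("target",) + tuple(f"aux{i}" for i in range(1, Y.shape[1]))
            Y = MultiBitLabelMatrix(Y=Y, column_tasks=names)
        self.Y = Y
        self.lambdas = tuple(float(v) for v in lambdas)
        if self.X.shape[0] != self.Y.Y.shape[0]:
            raise ValueError("X and Y row counts differ")

    def fit(self, max_iter: int = 1000, tol: float = 1e-8, prune_domains: bool = True):
        first = rmltfl_fit(self.X, self.Y, self.lambdas, max_iter, tol)
        if not prune_domains or self.Y.n_tasks == 1:
            return MultiTaskFeatureSelectorResults(self, first, first, None)
        retained = first.retained_domains
        if retained.all():
            return MultiTaskFeatureSelectorResults(self, first, first, retained)
        keep_cols = np.concatenate(([True], retained))
        if not retained.any():
            logger.warning("all auxiliary domains pruned; refitting on target only")
        Y2 = MultiBitLabelMatrix(
            Y=self.Y.Y[:, keep_cols],
            column_tasks=tuple(np.array(self.Y.column_tasks, object)[keep_cols]),
        )
        second = rmltfl_fit(self.X, Y2, self.lambdas, max_iter, tol)
        return MultiTaskFeatureSelectorResults(self, first, second, retained)


class MultiTaskFeatureSelectorResults:
    """Results of the two-stage (fit, prune, refit) rMLTFL procedure."""

    def __init__(self, model, first_fit, final_fit, retained_domains):
        self.model = model
        self.first_fit: WeightDecomposition = first_fit
        self.final_fit: WeightDecomposition = final_fit
        n_aux = model.Y.n_tasks - 1
        self.retained_domains = (
            np.ones(n_aux, bool) if retained_domains is None else retained_domains
        )
        self.all_domains_pruned = n_aux > 0 and not self.retained_domains.any()

    @property
    def selected_features(self) -> np.ndarray:
        return self.final_fit.selected_features

    @property
    def feature_indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected_features)

    @property
    def converged(self) -> bool:
        return self.first_fit.converged and self.final_fit.converged

    def summary(self) -> str:
        l1, l2, l3 = self.model.lambdas
        lines = [
            "Multi-task feature selection (rMLTFL)",
            "=" * 42,
            f"subjects: {self.model.X.shape[0]}   features: {self.model.X.shape[1]}",
            f"lambda1={l1:g}  lambda2={l2:g}  lambda3={l3:g}",
            f"selected features: {int(self.selected_features.sum())}",
            f"retained auxiliary domains: {self.retained_domains.astype(int).tolist()}",
            f"objective: {self.final_fit.objective:.6g}  "
            f"(iters: {self.final_fit.n_iter}, converged: {self.converged})",
        ]
        return "\n".join(lines)


def filter_and_refit(
    X: np.ndarray,
    Y: MultiBitLabelMatrix,
    lambdas: Sequence[float],
    modality: Modality = Modality.FDG,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> SelectionResult:
    """Full rMLTFL selection: fit, prune zero-Q domains, refit, read P rows."""
    res = MultiTaskFeatureSelector(X, Y, lambdas).fit(max_iter=max_iter, tol=tol)
    return SelectionResult(
        method="rMLTFL",
        modality=modality,
        feature_indices=res.feature_indices.tolist(),
        hyperparameters={
            "lambda1": lambdas[0],
            "lambda2": lambdas[1],
            "lambda3": lambdas[2],
            "retained_domains": res.retained_domains.astype(int).tolist(),
            "all_domains_pruned": bool(res.all_domains_pruned),
        },
    )


def default_lambda_grid(n: int = 10, low: float = 1e-3, high: float = 1e2):
    """Log-spaced grid per hyperparameter (n=10 gives 1000 combinations)."""
    axis = np.logspace(np.log10(low), np.log10(high), n)
    return [(a, b, c) for a in axis for b in axis for c in axis]


def grid_search_rmltfl(
    X: np.ndarray,
    Y: MultiBitLabelMatrix,
    lambda_grid: Optional[Sequence] = None,
    k_folds: int = 5,
    seed: int = 0,
    modality: Modality = Modality.FDG,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> SelectionResult:
    """Choose (lambda1, lambda2, lambda3) by stratified k-fold CV.

    For every grid point, features are selected on each training fold and
    a linear logistic model on the selected features is scored on the
    held-out fold; the grid point with the highest mean accuracy wins.
    The final feature set is the union of the per-fold selections at the
    winning hyperparameters.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    if len(lambda_grid) == 0:
        raise ValueError("empty lambda grid")
    y_target = Y.Y[:, 0]
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y_target))

    def fold_accuracy(lams, train_idx, test_idx):
        sel = filter_and_refit(
            X[train_idx],
            MultiBitLabelMatrix(Y=Y.Y[train_idx], column_tasks=Y.column_tasks),
            lams,
            modality=modality,
            max_iter=max_iter,
            tol=tol,
        )
        if not sel.feature_indices:
            maj = 1.0 if (y_target[train_idx] == 1).mean() >= 0.5 else -1.0
            return float((y_target[test_idx] == maj).mean()), sel
        clf = LogisticRegression(max_iter=2000)
        clf.fit(X[np.ix_(train_idx, sel.feature_indices)], y_target[train_idx])
        acc = clf.score(X[np.ix_(test_idx, sel.feature_indices)], y_target[test_idx])
        return float(acc), sel

    best_lams, best_acc = None, -np.inf
    for lams in lambda_grid:
        accs = [fold_accuracy(lams, tr, te)[0] for tr, te in folds]
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc:
            best_acc, best_lams = mean_acc, tuple(lams)

    per_fold = []
    for tr, te in folds:
        _, sel = fold_accuracy(best_lams, tr, te)
        if not sel.feature_indices:
            logger.warning("empty feature selection in one fold at best lambdas")
        per_fold.append(sel.feature_indices)
    union = sorted({i for fold in per_fold for i in fold})
    return SelectionResult(
        method="rMLTFL",
        modality=modality,
        feature_indices=union,
        per_fold_indices=per_fold,
        hyperparameters={
            "lambda1": best_lams[0],
            "lambda2": best_lams[1],
            "lambda3": best_lams[2],
            "cv_accuracy": best_acc,
            "k_folds": k_folds,
            "seed": seed,
        },
    )
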