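"""Entropic and group-regularized optimal transport, target -> source.

The stratification framework reverses the usual domain-adaptation
direction: the labelled E-MCI/L-MCI *target* training samples are
transported onto the AD/NC *source* domain, where the decision boundary
is clearly defined.  Three couplings are supported:

``SD``
    Entropy-regularized optimal transport (Sinkhorn distance):
    ``min <gamma, C> + eps * sum gamma (log gamma - 1)`` over couplings
    with prescribed marginals, solved by log-domain Sinkhorn scaling.

``SD_Lpl1``
    SD plus an Lp-l1 group penalty ``eta * sum_j sum_cls
    ||gamma(I_cls, j)||_p^p`` (0 < p <= 1), solved by
    majorization-minimization: each outer step re-runs Sinkhorn with a
    per-entry cost adjustment derived from the current group masses.

``SD_L1l2``
    SD plus an l1-l2 group penalty ``eta * sum_j sum_cls
    ||gamma(I_cls, j)||_2``, solved by generalized conditional gradient
    with Sinkhorn as the linearized subproblem and an Armijo line search.

Both group penalties softly discourage a source sample from receiving
mass from more than one target class, which realises the class pairing
L-MCI -> AD, E-MCI -> NC.  Fitted training samples are mapped by the
barycentric projection; unseen test samples use a k-nearest-neighbour
displacement extension (the transport map is only defined on the
training support).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .io import BinaryTask

logger = logging.getLogger(__name__)

__all__ = [
    "TransportConfig",
    "TransportModel",
    "ClassPairedTransport",
    "cost_matrix",
    "sinkhorn",
    "sinkhorn_group",
    "fit_transport",
    "transform",
]

#: Class pairing enforced (softly) by the group regularizer.
CLASS_PAIRING = {"L-MCI": "AD", "E-MCI": "NC"}


@dataclass(frozen=True)
class TransportConfig:
    """Solver settings for the target->source coupling.

    Defaults (epsilon = eta = 0.1, squared Euclidean cost) assume
    [0, 1]-scaled features.
    """

    regularizer: str = "SD"  # SD | SD_L1l2 | SD_Lpl1
    epsilon: float = 0.1
    eta: float = 0.1
    p_exponent: float = 0.5
    cost_metric: str = "sqeuclidean"
    max_iter: int = 1000
    tol: float = 1e-9
    n_outer: int = 10  # outer loops for the group-regularized solvers

    def __post_init__(self):
        if self.regularizer not in ("SD", "SD_L1l2", "SD_Lpl1"):
            raise ValueError(f"unknown regularizer {self.regularizer!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")
        if not 0 < self.p_exponent <= 1:
            raise ValueError("p_exponent must lie in (0, 1]")


def cost_matrix(A: np.ndarray, B: np.ndarray, metric: str = "sqeuclidean") -> np.ndarray:
    """Pairwise ground costs between the rows of A and B."""
    A, B = np.atleast_2d(np.asarray(A, float)), np.atleast_2d(np.asarray(B, float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"feature dimensions differ: {A.shape[1]} vs {B.shape[1]}")
    return cdist(A, B, metric=metric)


def _check_weights(a, b, C):
    a, b = np.asarray(a, float), np.asarray(b, float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("weights must be nonnegative")
    if not (np.isclose(a.sum(), 1.0) and np.isclose(b.sum(), 1.0)):
        raise ValueError("weights must each sum to 1")
    if C.shape != (a.size, b.size):
        raise ValueError("cost matrix shape does not match weights")
    return a, b


def sinkhorn(
    a: np.ndarray,
    b: np.ndarray,
    C: np.ndarray,
    epsilon: float,
    max_iter: int = 1000,
    tol: float = 1e-9,
    return_trace: bool = False,
):
    """Entropic optimal transport by log-domain Sinkhorn scaling.

    Alternates exact dual-block maximizations of the potentials (f, g)
    until the worst marginal violation drops below ``tol``; log-domain
    updates make small ``epsilon`` safe (no silent NaN/underflow).

    Returns the coupling ``gamma`` (strictly positive), and when
    ``return_trace`` also the dual-objective trace, which is
    non-decreasing under the exact block updates.
    """
    C = np.asarray(C, float)
    a, b = _check_weights(a, b, C)
    loga, logb = np.log(a), np.log(b)
    f = np.zeros_like(a)
    g = np.zeros_like(b)
    trace = []

    def log_gamma():
        return (f[:, None] + g[None, :] - C) / epsilon

    def dual_value():
        # <f,a> + <g,b> - eps * sum exp((f+g-C)/eps)
        return float(f @ a + g @ b - epsilon * np.exp(logsumexp(log_gamma())))

    for _ in range(max_iter):
        f = epsilon * (loga - logsumexp((g[None, :] - C) / epsilon, axis=1))
        g = epsilon * (logb - logsumexp((f[:, None] - C) / epsilon, axis=0))
        if return_trace:
            trace.append(dual_value())
        gamma = np.exp(log_gamma())
        err = max(
            np.abs(gamma.sum(axis=1) - a).max(), np.abs(gamma.sum(axis=0) - b).max()
        )
        if err < tol:
            break
    else:
        logger.debug("sinkhorn reached max_iter with marginal error %.3g", err)
    gamma = np.exp(log_gamma())
    return (gamma, trace) if return_trace else gamma


def _group_rows(target_labels: np.ndarray):
    labels = np.asarray(target_labels)
    return [np.flatnonzero(labels == c) for c in np.unique(labels)]


def _entropic_objective(gamma, C, epsilon):
    g = np.where(gamma > 0, gamma, 1.0)
    return float(np.sum(gamma * C) + epsilon * np.sum(gamma * (np.log(g) - 1.0)))


def _l1l2_penalty(gamma, groups):
    return float(sum(np.linalg.norm(gamma[idx], axis=0).sum() for idx in groups))


def sinkhorn_group(
    a: np.ndarray,
    b: np.ndarray,
    C: np.ndarray,
    target_labels: np.ndarray,
    config: TransportConfig,
):
    """Group-regularized entropic transport (rows grouped by target class).

    ``SD_Lpl1`` runs majorization-minimization: at each outer step the
    concave per-group ``||.||_p^p`` term is majorized by its tangent,
    which adds ``eta * p * mass^(p-1)`` to the cost of every entry in the
    group, and plain Sinkhorn solves the majorized problem.  ``SD_L1l2``
    runs generalized conditional gradient: Sinkhorn solves the problem
    linearized in the group term and an Armijo backtracking line search
    mixes the new coupling in.  With ``eta = 0`` both reduce exactly to
    plain Sinkhorn.
    """
    C = np.asarray(C, float)
    a, b = _check_weights(a, b, C)
    if len(target_labels) != len(a):
        raise ValueError("one label per target row required")
    if config.regularizer == "SD" or config.eta == 0:
        return sinkhorn(a, b, C, config.epsilon, config.max_iter, config.tol)
    groups = _group_rows(target_labels)
    if config.regularizer == "SD_Lpl1":
        return _sinkhorn_lpl1_mm(a, b, C, groups, config)
    return _sinkhorn_l1l2_gcg(a, b, C, groups, config)


def _sinkhorn_lpl1_mm(a, b, C, groups, cfg: TransportConfig):
    p = cfg.p_exponent
    tiny = 1e-12
    adjustment = np.zeros_like(C)
    gamma = None
    for _ in range(cfg.n_outer):
        gamma = sinkhorn(a, b, C + cfg.eta * adjustment, cfg.epsilon, cfg.max_iter, cfg.tol)
        for idx in groups:
            mass = gamma[idx].sum(axis=0)  # per-source-column group mass
            adjustment[idx] = p * (mass + tiny) ** (p - 1.0)
    return gamma


def _sinkhorn_l1l2_gcg(a, b, C, groups, cfg: TransportConfig):
    def penalty(G):
        return _l1l2_penalty(G, groups)

    def penalty_grad(G):
        D = np.zeros_like(G)
        for idx in groups:
            norms = np.linalg.norm(G[idx], axis=0)
            D[idx] = G[idx] / np.maximum(norms, 1e-300)
        return D

    def total(G):
        return _entropic_objective(G, C, cfg.epsilon) + cfg.eta * penalty(G)

    gamma = sinkhorn(a, b, C, cfg.epsilon, cfg.max_iter, cfg.tol)
    obj = total(gamma)
    for _ in range(cfg.n_outer):
        grad_cost = C + cfg.eta * penalty_grad(gamma)
        candidate = sinkhorn(a, b, grad_cost, cfg.epsilon, cfg.max_iter, cfg.tol)
        direction = candidate - gamma
        # Armijo backtracking on the full objective along the segment
        slope = float(
            np.sum((grad_cost + cfg.epsilon * np.log(np.maximum(gamma, 1e-300))) * direction)
        )
        alpha, accepted = 1.0, False
        for _ls in range(30):
            new = gamma + alpha * direction
            if total(new) <= obj + 1e-4 * alpha * min(slope, 0.0):
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            logger.debug("GCG line search failed to improve; stopping")
            break
        new_obj = total(gamma + alpha * direction)
        gamma = gamma + alpha * direction
        if obj - new_obj < cfg.tol * max(1.0, abs(obj)):
            obj = new_obj
            break
        obj = new_obj
    return gamma


@dataclass
class TransportModel:
    """Fitted target->source coupling plus everything needed to map samples."""

    coupling: np.ndarray
    source_features: np.ndarray
    target_train_features: np.ndarray
    target_train_labels: np.ndarray
    config: TransportConfig
    class_pairing: dict = field(default_factory=lambda: dict(CLASS_PAIRING))

    @property
    def n_target_train(self) -> int:
        return self.coupling.shape[0]

    def marginal_errors(self):
        n, m = self.coupling.shape
        a, b = np.full(n, 1.0 / n), np.full(m, 1.0 / m)
        return (
            float(np.abs(self.coupling.sum(axis=1) - a).max()),
            float(np.abs(self.coupling.sum(axis=0) - b).max()),
        )

    def transform(self, samples: np.ndarray, fitted: bool = False) -> np.ndarray:
        return transform(self, samples, fitted=fitted)

    def summary(self) -> str:
        row_err, col_err = self.marginal_errors()
        return "\n".join(
            [
                "Class-paired optimal transport (target -> source)",
                "=" * 50,
                f"regularizer: {self.config.regularizer}  "
                f"epsilon={self.config.epsilon:g}  eta={self.config.eta:g}",
                f"coupling: {self.coupling.shape[0]} target-train x "
                f"{self.coupling.shape[1]} source samples",
                f"marginal errors (row, col): {row_err:.2e}, {col_err:.2e}",
                f"class pairing: {self.class_pairing}",
            ]
        )


class ClassPairedTransport:
    """Model object: transport E-MCI/L-MCI training samples onto AD/NC.

    ``fit()`` returns a :class:`TransportModel`; sample weights are
    uniform and the target training labels define the regularizer groups.
    """

    def __init__(
        self,
        source: BinaryTask,
        target_train: BinaryTask,
        config: TransportConfig = TransportConfig(),
    ):
        if source.X.shape[1] != target_train.X.shape[1]:
            raise ValueError(
                f"feature spaces differ: source {source.X.shape[1]}, "
                f"target {target_train.X.shape[1]}"
            )
        self.source = source
        self.target_train = target_train
        self.config = config

    def fit(self) -> TransportModel:
        Xs, Xt = self.source.X, self.target_train.X
        n, m = Xt.shape[0], Xs.shape[0]
        a, b = np.full(n, 1.0 / n), np.full(m, 1.0 / m)
        C = cost_matrix(Xt, Xs, self.config.cost_metric)
        gamma = sinkhorn_group(a, b, C, self.target_train.y, self.config)
        return TransportModel(
            coupling=gamma,
            source_features=Xs,
            target_train_features=Xt,
            target_train_labels=np.asarray(self.target_train.y),
            config=self.config,
        )


def fit_transport(
    source: BinaryTask, target_train: BinaryTask, config: TransportConfig = TransportConfig()
) -> TransportModel:
    """Functional wrapper over :class:`ClassPairedTransport`."""
    return ClassPairedTransport(source, target_train, config).fit()


def _barycentric_images(model: TransportModel) -> np.ndarray:
    gamma = model.coupling
    row_mass = gamma.sum(axis=1, keepdims=True)
    images = np.empty_like(model.target_train_features)
    ok = row_mass[:, 0] > 1e-300
    images[ok] = (gamma[ok] / row_mass[ok]) @ model.source_features
    if not ok.all():
        logger.warning(
            "%d coupling rows carry no mass; using nearest fitted image", (~ok).sum()
        )
        # fall back to the image of the nearest row that has mass
        D = cost_matrix(model.target_train_features[~ok], model.target_train_features[ok])
        images[~ok] = images[ok][np.argmin(D, axis=1)]
    return images


def transform(
    model: TransportModel,
    samples: np.ndarray,
    fitted: bool = False,
    k_neighbors: int = 5,
) -> np.ndarray:
    """Map samples from target space into source space.

    Fitted training rows use the barycentric projection (coupling-weighted
    average of source samples).  New samples use a label-free
    out-of-sample extension: the displacement vectors of the
    ``k_neighbors`` nearest fitted training samples, inverse-distance
    weighted, are applied to the sample.
    """
    samples = np.atleast_2d(np.asarray(samples, float))
    if samples.shape[1] != model.target_train_features.shape[1]:
        raise ValueError("sample feature dimension does not match the model")
    images = _barycentric_images(model)
    if fitted:
        if samples.shape[0] != model.n_target_train:
            raise ValueError("fitted=True requires exactly the training rows")
        return images
    displacement = images - model.target_train_features
    D = cost_matrix(samples, model.target_train_features, "euclidean")
    k = min(k_neighbors, model.n_target_train)
    nn = np.argpartition(D, k - 1, axis=1)[:, :k]
    d = np.take_along_axis(D, nn, axis=1)
    w = 1.0 / np.maximum(d, 1e-12)
    w /= w.sum(axis=1, keepdims=True)
    shift = np.einsum("ik,ikd->id", w, displacement[nn])
    return samples + shift
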