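"""Evaluation protocols: ten-fold CV, 80/20 holdout and 80/10/10 splits.

All protocols operate on a four-class :class:`~mcistrat.io.FeatureTable`
and a :class:`PipelineConfig`.  Inside every fold/split, scaling and
feature selection are fitted on the training portion only (source
subjects plus target-train subjects), transport is fitted on the target
training samples, and the held-out target samples are transported with
the out-of-sample map before scoring.  Accuracy is reported in percent,
AUC on [0, 1] from predicted probabilities (mean probability for the
bagged ensemble).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .classify import KernelSpec, fit_baseline, predict_proba
from .ensemble import fit_ensemble, fit_submodel, predict_ensemble
from .io import BinaryTask, FeatureTable, TaskName, make_binary_task
from .select import (
    AUX_TASK_ORDER,
    MultiBitLabelMatrix,
    anova_select,
    build_multibit_labels,
    fit_auxiliary_models,
    filter_and_refit,
    grid_search_rmltfl,
)
from .transport import TransportConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "EvalResult", "score", "cross_validate", "holdout_eval"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline evaluation needs, serializable.

    ``classifier``: ``"ot_klr"`` is the transfer pipeline (transport +
    kernel logistic); ``"svm"``/``"logistic"`` are the no-transport
    baselines on the raw selected target features.
    """

    selection: str = "anova"  # anova | rmltfl | none
    alpha: float = 0.05
    lambdas: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    lambda_grid: Optional[tuple] = None  # rMLTFL grid search when given
    transport: TransportConfig = TransportConfig()
    kernel: KernelSpec = KernelSpec()
    classifier: str = "ot_klr"
    n_bags: int = 5
    bag_scheme: str = "fold"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class EvalResult:
    """Per-fold metrics plus their summary statistics.

    ``per_fold_auc`` entries are None where the fold's test portion held
    a single class (AUC undefined); those folds are excluded from the
    AUC mean and counted in ``n_missing_auc``.
    """

    protocol: str
    per_fold_accuracy: List[float]
    per_fold_auc: List[Optional[float]]
    config: dict = field(default_factory=dict)
    seed: int = 0
    portions: Optional[List[str]] = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.per_fold_accuracy))

    @property
    def _auc_values(self) -> List[float]:
        return [a for a in self.per_fold_auc if a is not None]

    @property
    def mean_auc(self) -> float:
        vals = self._auc_values
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def sd_auc(self) -> float:
        vals = self._auc_values
        return float(np.std(vals)) if vals else float("nan")

    @property
    def n_missing_auc(self) -> int:
        return sum(a is None for a in self.per_fold_auc)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "per_fold_accuracy": self.per_fold_accuracy,
            "per_fold_auc": self.per_fold_auc,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "n_missing_auc": self.n_missing_auc,
            "seed": self.seed,
            "portions": self.portions,
            "config": self.config,
        }

    def summary(self) -> str:
        lines = [
            f"Protocol: {self.protocol} (seed {self.seed})",
            "=" * 40,
            f"accuracy: {self.mean_accuracy:.2f} +/- {self.sd_accuracy:.2f} %",
            f"AUC:      {self.mean_auc:.3f} +/- {self.sd_auc:.3f}"
            + (f"  ({self.n_missing_auc} fold(s) undefined)" if self.n_missing_auc else ""),
        ]
        if self.portions:
            for name, acc, auc in zip(self.portions, self.per_fold_accuracy, self.per_fold_auc):
                auc_s = f"{auc:.3f}" if auc is not None else "n/a"
                lines.append(f"  {name}: accuracy {acc:.2f} %, AUC {auc_s}")
        return "\n".join(lines)


def score(labels: np.ndarray, predictions: np.ndarray, probabilities: np.ndarray):
    """(accuracy in percent, AUC) of +/-1 predictions and probabilities.

    AUC is the rank statistic (ties count half); with a single-class
    truth it is undefined and returned as None.
    """
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if not (len(labels) == len(predictions) == len(probabilities)):
        raise ValueError("labels, predictions and probabilities differ in length")
    acc = float((labels == predictions).mean() * 100.0)
    if len(np.unique(labels)) < 2:
        logger.warning("single-class truth: AUC undefined for this fold")
        return acc, None
    return acc, float(roc_auc_score(labels, probabilities))


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------


def _fit_minmax(X_ref: np.ndarray):
    lo, hi = X_ref.min(axis=0), X_ref.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return lo, span, (hi == lo)


def _apply_minmax(X, lo, span, const_mask):
    scaled = np.clip((X - lo) / span, 0.0, 1.0)
    scaled[:, const_mask] = 0.0
    return scaled


def _select_features(
    config: PipelineConfig,
    train_table: FeatureTable,
    target_train: BinaryTask,
    seed: int,
) -> Sequence[int]:
    """Fit the configured selection route on the training portion only."""
    if config.selection == "none":
        return list(range(target_train.X.shape[1]))
    if config.selection == "anova":
        return anova_select(target_train, alpha=config.alpha).feature_indices
    if config.selection != "rmltfl":
        raise ValueError(f"unknown selection method {config.selection!r}")
    aux_tasks = [make_binary_task(train_table, t) for t in AUX_TASK_ORDER]
    models = fit_auxiliary_models(aux_tasks)
    Y = build_multibit_labels(target_train, models)
    if config.lambda_grid is not None:
        res = grid_search_rmltfl(
            target_train.X, Y, list(config.lambda_grid), seed=seed,
            modality=train_table.modality,
        )
    else:
        res = filter_and_refit(
            target_train.X, Y, config.lambdas, modality=train_table.modality
        )
    if not res.feature_indices:
        logger.warning("empty rMLTFL selection; falling back to all features")
        return list(range(target_train.X.shape[1]))
    return res.feature_indices


def _restrict_task(task: BinaryTask, indices) -> BinaryTask:
    return BinaryTask(
        name=task.name,
        table=task.table.select_features(indices),
        y=task.y,
        positive_codes=task.positive_codes,
        negative_codes=task.negative_codes,
    )


def _scaled_tasks(table: FeatureTable, target_train_ids, target_test_ids):
    """Scale on training subjects, carve out source/target-train/test."""
    is_test = np.isin(table.subject_ids, target_test_ids)
    train_table = table.subset(~is_test)
    lo, span, const = _fit_minmax(train_table.features)

    def scaled(t: FeatureTable) -> FeatureTable:
        from dataclasses import replace

        return replace(t, features=_apply_minmax(t.features, lo, span, const))

    train_scaled = scaled(train_table)
    source = make_binary_task(train_scaled, TaskName.AD_vs_NC)
    target_full = make_binary_task(train_scaled, TaskName.LMCI_vs_EMCI)
    keep = np.isin(target_full.table.subject_ids, target_train_ids)
    target_train = BinaryTask(
        name=target_full.name,
        table=target_full.table.subset(keep),
        y=target_full.y[keep],
        positive_codes=target_full.positive_codes,
        negative_codes=target_full.negative_codes,
    )
    test_table = scaled(table.subset(is_test))
    test_task = make_binary_task(test_table, TaskName.LMCI_vs_EMCI)
    return train_scaled, source, target_train, test_task


def _predict_single(config, source, target_train, test_X, seed):
    if config.classifier == "ot_klr":
        tp, clf = fit_submodel(
            source, target_train.X, target_train.y, config.transport, config.kernel
        )
        mapped = tp.transform(test_X, fitted=False)
        proba = clf.predict_proba(mapped)
    elif config.classifier in ("svm", "logistic"):
        name = "SVM" if config.classifier == "svm" else "logistic"
        clf = fit_baseline(target_train, name)
        proba = predict_proba(clf, test_X)
    else:
        raise ValueError(f"unknown classifier {config.classifier!r}")
    return np.where(proba >= 0.5, 1, -1), proba


def cross_validate(
    table: FeatureTable,
    config: PipelineConfig = PipelineConfig(),
    k: int = 10,
    seed: int = 0,
) -> EvalResult:
    """Stratified k-fold cross-validation over the target (MCI) subjects.

    Source (AD/NC) subjects participate in every training portion; folds
    partition only the target subjects.  Scaling and feature selection
    are refitted inside each fold on the training portion.
    """
    target = make_binary_task(table, TaskName.LMCI_vs_EMCI)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs, aucs = [], []
    for train_idx, test_idx in skf.split(target.X, target.y):
        train_ids = target.table.subject_ids[train_idx]
        test_ids = target.table.subject_ids[test_idx]
        train_scaled, source, target_train, test_task = _scaled_tasks(
            table, train_ids, test_ids
        )
        feats = _select_features(config, train_scaled, target_train, seed)
        source_s = _restrict_task(source, feats)
        target_s = _restrict_task(target_train, feats)
        test_s = _restrict_task(test_task, feats)
        pred, proba = _predict_single(config, source_s, target_s, test_s.X, seed)
        acc, auc = score(test_s.y, pred, proba)
        accs.append(acc)
        aucs.append(auc)
    return EvalResult(
        protocol=f"cv{k}",
        per_fold_accuracy=accs,
        per_fold_auc=aucs,
        config=config.to_dict(),
        seed=seed,
    )


def holdout_eval(
    table: FeatureTable,
    config: PipelineConfig = PipelineConfig(),
    splits: Sequence[float] = (0.8, 0.2),
    seed: int = 0,
) -> EvalResult:
    """Bagged-ensemble evaluation on stratified holdout splits.

    ``splits`` is (train, test) or (train, validation, test) and must sum
    to 1 with every portion nonempty.  The ensemble (``config.n_bags``
    sub-models, each refitting transport) is trained on the training
    portion only; metrics are reported per held-out portion.
    """
    splits = tuple(float(s) for s in splits)
    if not np.isclose(sum(splits), 1.0):
        raise ValueError("split fractions must sum to 1")
    if len(splits) not in (2, 3) or min(splits) <= 0:
        raise ValueError("need (train, test) or (train, val, test), all positive")
    target = make_binary_task(table, TaskName.LMCI_vs_EMCI)
    idx = np.arange(target.n_subjects)
    train_idx, rest_idx = train_test_split(
        idx, train_size=splits[0], stratify=target.y, random_state=seed
    )
    if len(splits) == 2:
        portions = {"test": rest_idx}
    else:
        val_frac = splits[1] / (splits[1] + splits[2])
        val_idx, test_idx = train_test_split(
            rest_idx, train_size=val_frac, stratify=target.y[rest_idx],
            random_state=seed,
        )
        portions = {"validation": val_idx, "test": test_idx}

    held_ids = target.table.subject_ids[np.concatenate(list(portions.values()))]
    train_ids = target.table.subject_ids[train_idx]
    train_scaled, source, target_train, held_task = _scaled_tasks(
        table, train_ids, held_ids
    )
    feats = _select_features(config, train_scaled, target_train, seed)
    source_s = _restrict_task(source, feats)
    target_s = _restrict_task(target_train, feats)

    if config.classifier == "ot_klr":
        ens = fit_ensemble(
            source_s,
            target_s,
            transport_config=config.transport,
            kernel=config.kernel,
            n_bags=config.n_bags,
            seed=seed,
            scheme=config.bag_scheme,
        )
        predict = lambda X: predict_ensemble(ens, X)  # noqa: E731
    else:
        predict = _bagged_baseline_predictor(config, target_s, seed)

    accs, aucs, names = [], [], []
    for name, p_idx in portions.items():
        ids = target.table.subject_ids[p_idx]
        mask = np.isin(held_task.table.subject_ids, ids)
        sub = held_task.table.subset(mask).select_features(feats)
        y = held_task.y[mask]
        pred, proba = predict(sub.features)
        acc, auc = score(y, pred, proba)
        accs.append(acc)
        aucs.append(auc)
        names.append(name)
    return EvalResult(
        protocol="split_" + "_".join(f"{int(round(s * 100))}" for s in splits),
        per_fold_accuracy=accs,
        per_fold_auc=aucs,
        config=config.to_dict(),
        seed=seed,
        portions=names,
    )


def _bagged_baseline_predictor(config: PipelineConfig, target_s: BinaryTask, seed: int):
    """Bag the no-transport baselines the same leave-one-fold-out way."""
    from .ensemble import make_bags

    name = "SVM" if config.classifier == "svm" else "logistic"
    bags = make_bags(target_s, n_bags=config.n_bags, seed=seed, scheme=config.bag_scheme)
    models = []
    for bag in bags:
        sub = BinaryTask(
            name=target_s.name,
            table=target_s.table.subset(bag),
            y=target_s.y[bag],
            positive_codes=target_s.positive_codes,
            negative_codes=target_s.negative_codes,
        )
        models.append(fit_baseline(sub, name))

    def predict(X):
        probas = np.array([predict_proba(m, X) for m in models])
        votes = np.where(probas >= 0.5, 1, -1)
        labels = np.where(votes.sum(axis=0) > 0, 1, -1)
        return labels, probas.mean(axis=0)

    return predict
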