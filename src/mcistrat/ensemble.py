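"""Bootstrap aggregation of (transport + classifier) sub-models.

Five bags are built by leave-one-fold-out subsampling: the training set
is split into five stratified folds and bag *i* is the union of all
folds except fold *i*, so every subject appears in exactly
``n_bags - 1`` bags.  (This is the variant used throughout the package;
classical with-replacement resampling is available via
``scheme="classic"`` for comparison.)  Each bag refits its own transport
map and classifier.  Test samples are transported by each bag's own
out-of-sample map; the ensemble label is the majority vote and the
ensemble probability the mean of sub-model probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .classify import (
    KernelSpec,
    TrainedClassifier,
    build_training_set,
    fit_kernel_logistic,
    predict_proba,
)
from .io import BinaryTask
from .select import SelectionResult
from .transport import ClassPairedTransport, TransportConfig, TransportModel

logger = logging.getLogger(__name__)

__all__ = [
    "BaggedEnsemble",
    "make_bags",
    "fit_submodel",
    "fit_ensemble",
    "predict_ensemble",
]


def make_bags(
    train: BinaryTask, n_bags: int = 5, seed: int = 0, scheme: str = "fold"
) -> List[np.ndarray]:
    """Build bag index sets over the training subjects.

    ``scheme="fold"``: stratified split into ``n_bags`` folds; bag i is
    everything except fold i.  ``scheme="classic"``: with-replacement
    resampling of the full training size.  If a bag ends up with a single
    class the draw is repeated with a bumped seed (logged).
    """
    n = train.n_subjects
    if n < n_bags:
        raise ValueError(f"training set of {n} smaller than n_bags={n_bags}")
    if n_bags == 1 and scheme == "fold":
        return [np.arange(n)]  # degenerate bagging: one model on everything
    for attempt in range(20):
        rng = np.random.default_rng(seed + attempt)
        if scheme == "classic":
            bags = [rng.integers(0, n, size=n) for _ in range(n_bags)]
        elif scheme == "fold":
            # stratified fold assignment: spread each class over the folds
            fold_of = np.empty(n, int)
            for cls in (-1, 1):
                idx = rng.permutation(np.flatnonzero(train.y == cls))
                fold_of[idx] = np.arange(len(idx)) % n_bags
            bags = [np.flatnonzero(fold_of != i) for i in range(n_bags)]
        else:
            raise ValueError(f"unknown bagging scheme {scheme!r}")
        if all(len(np.unique(train.y[bag])) == 2 for bag in bags):
            if attempt:
                logger.info("bag draw repeated %d time(s) for class coverage", attempt)
            return bags
    raise ValueError("could not draw bags containing both classes")


def fit_submodel(
    source: BinaryTask,
    target_train_X: np.ndarray,
    target_train_y: np.ndarray,
    transport_config: Optional[TransportConfig],
    kernel: KernelSpec,
) -> Tuple[Optional[TransportModel], TrainedClassifier]:
    """One pipeline fit: transport the target-train bag, train the classifier.

    With ``transport_config=None`` no transport is applied and the
    classifier is trained on source + raw target samples (used by the
    ensemble reduction tests; the proper baselines live in ``classify``).
    """
    sub_task = BinaryTask(
        name=source.name,  # placeholder name; only X/y are used downstream
        table=source.table,
        y=source.y,
        positive_codes=source.positive_codes,
        negative_codes=source.negative_codes,
    )
    if transport_config is not None:
        tp = ClassPairedTransport(
            source,
            _as_target_task(target_train_X, target_train_y, source),
            transport_config,
        ).fit()
        mapped = tp.transform(target_train_X, fitted=True)
    else:
        tp, mapped = None, target_train_X
    X, y, prov = build_training_set(sub_task, mapped, target_train_y)
    clf = fit_kernel_logistic(X, y, kernel, provenance=prov)
    return tp, clf


def _as_target_task(X, y, like: BinaryTask) -> BinaryTask:
    from .io import FeatureTable, TaskName, LABEL_EMCI, LABEL_LMCI

    y = np.asarray(y, int)
    table = FeatureTable(
        subject_ids=np.array([f"T{i:04d}" for i in range(len(y))]),
        features=np.asarray(X, float),
        labels=np.where(y > 0, LABEL_LMCI, LABEL_EMCI),
        modality=like.table.modality,
    )
    return BinaryTask(
        name=TaskName.LMCI_vs_EMCI,
        table=table,
        y=y,
        positive_codes=frozenset({LABEL_LMCI}),
        negative_codes=frozenset({LABEL_EMCI}),
    )


@dataclass
class BaggedEnsemble:
    """Bag of (transport, classifier) sub-models with majority-vote output."""

    sub_models: List[Tuple[Optional[TransportModel], TrainedClassifier]]
    bag_assignments: List[np.ndarray]
    seed: int
    aggregation: str = "majority_vote"
    selection: Optional[SelectionResult] = None
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.sub_models) % 2 == 0:
            raise ValueError("n_bags must be odd so majority votes cannot tie")

    @property
    def n_bags(self) -> int:
        return len(self.sub_models)

    def predict(self, test: np.ndarray):
        return predict_ensemble(self, test)

    def summary(self) -> str:
        kinds = {
            "with transport" if tp is not None else "no transport"
            for tp, _ in self.sub_models
        }
        return "\n".join(
            [
                "Bagged transfer ensemble",
                "=" * 40,
                f"bags: {self.n_bags} ({', '.join(sorted(kinds))}), seed: {self.seed}",
                f"aggregation: {self.aggregation} (probability = mean over bags)",
                f"bag sizes: {[len(b) for b in self.bag_assignments]}",
            ]
        )


def fit_ensemble(
    source: BinaryTask,
    target_train: BinaryTask,
    transport_config: Optional[TransportConfig] = TransportConfig(),
    kernel: KernelSpec = KernelSpec(),
    n_bags: int = 5,
    seed: int = 0,
    selection: Optional[SelectionResult] = None,
    scheme: str = "fold",
) -> BaggedEnsemble:
    """Fit ``n_bags`` sub-models, each with its own transport map.

    ``selection`` (optional) restricts both domains to the selected
    feature columns before anything is fitted, keeping source and target
    in one feature space.  Any sub-model failure aborts the ensemble with
    the bag index named.
    """
    if selection is not None:
        source = _restrict(source, selection.feature_indices)
        target_train = _restrict(target_train, selection.feature_indices)
    bags = make_bags(target_train, n_bags=n_bags, seed=seed, scheme=scheme)
    subs = []
    for i, bag in enumerate(bags):
        try:
            subs.append(
                fit_submodel(
                    source,
                    target_train.X[bag],
                    target_train.y[bag],
                    transport_config,
                    kernel,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"sub-model for bag {i} failed: {exc}") from exc
    return BaggedEnsemble(
        sub_models=subs,
        bag_assignments=bags,
        seed=seed,
        selection=selection,
        config={
            "transport": None if transport_config is None else vars(transport_config),
            "kernel": vars(kernel),
            "scheme": scheme,
        },
    )


def _restrict(task: BinaryTask, indices) -> BinaryTask:
    return BinaryTask(
        name=task.name,
        table=task.table.select_features(indices),
        y=task.y,
        positive_codes=task.positive_codes,
        negative_codes=task.negative_codes,
    )


def predict_ensemble(ens: BaggedEnsemble, test: np.ndarray):
    """Aggregate sub-model predictions on raw target-space test samples.

    Each sub-model transports the test samples with its own out-of-sample
    map and votes; the returned label is the majority vote and the
    probability the mean sub-model probability.  Vote and mean probability
    can disagree; both are reported.
    """
    test = np.atleast_2d(np.asarray(test, float))
    votes, probas = [], []
    for tp, clf in ens.sub_models:
        mapped = tp.transform(test, fitted=False) if tp is not None else test
        p = predict_proba(clf, mapped)
        probas.append(p)
        votes.append(np.where(p >= 0.5, 1, -1))
    votes = np.asarray(votes)
    labels = np.where(votes.sum(axis=0) > 0, 1, -1)
    return labels, np.mean(probas, axis=0)
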