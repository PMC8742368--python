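"""Feature-table I/O and task assembly.

The pipeline's universal currency is a :class:`FeatureTable`: one row per
subject, 116 region-of-interest (ROI) measurements per imaging modality
(FDG-PET metabolism or VBM-MRI morphometry), and an integer diagnostic
label per subject using the cohort coding

    1 = NC (normal control), 3 = E-MCI, 4 = L-MCI, 5 = AD.

Tables are read from/written to plain CSV with one header row, a label
column (auto-detected by name, or configured) and numeric feature columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LABEL_NC",
    "LABEL_EMCI",
    "LABEL_LMCI",
    "LABEL_AD",
    "VALID_LABELS",
    "Modality",
    "TaskName",
    "FeatureTable",
    "BinaryTask",
    "load_feature_table",
    "save_feature_table",
    "scale_unit_interval",
    "make_binary_task",
    "concat_modalities",
]

LABEL_NC = 1
LABEL_EMCI = 3
LABEL_LMCI = 4
LABEL_AD = 5
VALID_LABELS = frozenset({LABEL_NC, LABEL_EMCI, LABEL_LMCI, LABEL_AD})

LABEL_NAMES = {LABEL_NC: "NC", LABEL_EMCI: "E-MCI", LABEL_LMCI: "L-MCI", LABEL_AD: "AD"}

#: Candidate names for the label column, matched case-insensitively.
_LABEL_COLUMN_CANDIDATES = ("label", "labels", "dx", "diagnosis", "class")


class Modality(str, Enum):
    FDG = "FDG"
    VBM = "VBM"
    FDG_VBM = "FDG+VBM"


class TaskName(str, Enum):
    LMCI_vs_EMCI = "LMCI_vs_EMCI"
    AD_vs_NC = "AD_vs_NC"
    AD_vs_MCI = "AD_vs_MCI"
    MCI_vs_NC = "MCI_vs_NC"


class SchemaError(ValueError):
    """The CSV does not conform to the feature-table dialect."""


@dataclass(frozen=True)
class FeatureTable:
    """Subjects x ROI-features matrix with diagnostic labels.

    Attributes
    ----------
    subject_ids : ndarray of str
        Opaque subject identifiers (row order is meaningful).
    features : ndarray, shape (n_subjects, n_features)
        Real-valued ROI measurements; never contains NaN.
    labels : ndarray of int, shape (n_subjects,)
        Diagnostic codes; for real data drawn from {1, 3, 4, 5}.
    modality : Modality
    feature_names : tuple of str
    """

    subject_ids: np.ndarray
    features: np.ndarray
    labels: np.ndarray
    modality: Modality
    feature_names: tuple = field(default=())

    def __post_init__(self):
        feats = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if feats.ndim != 2:
            raise SchemaError("features must be a 2-D matrix")
        if feats.shape[0] != labels.shape[0]:
            raise SchemaError(
                f"row count {feats.shape[0]} != label count {labels.shape[0]}"
            )
        if np.isnan(feats).any():
            bad = int(np.argwhere(np.isnan(feats))[0, 0])
            raise SchemaError(f"missing value in row {bad}")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "subject_ids", np.asarray(self.subject_ids))
        if not self.feature_names:
            object.__setattr__(
                self,
                "feature_names",
                tuple(f"f{i}" for i in range(feats.shape[1])),
            )

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict:
        """Subject count per diagnostic code, keyed by code."""
        codes, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            subject_ids=self.subject_ids[mask],
            features=self.features[mask],
            labels=self.labels[mask],
            modality=self.modality,
            feature_names=self.feature_names,
        )

    def select_features(self, indices: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            subject_ids=self.subject_ids,
            features=self.features[:, idx],
            labels=self.labels,
            modality=self.modality,
            feature_names=tuple(self.feature_names[i] for i in idx),
        )


@dataclass(frozen=True)
class BinaryTask:
    """A FeatureTable restricted to two diagnostic groups coded +/-1.

    ``y`` carries the +/-1 coding; ``positive_codes``/``negative_codes``
    record which diagnostic codes map to each side.  For the target task
    L-MCI codes +1 and E-MCI codes -1, matching the class pairing used by
    the transport stage (L-MCI -> AD, E-MCI -> NC).
    """

    name: TaskName
    table: FeatureTable
    y: np.ndarray
    positive_codes: frozenset
    negative_codes: frozenset

    def __post_init__(self):
        y = np.asarray(self.y, dtype=int)
        if not np.all(np.isin(y, (-1, 1))):
            raise ValueError("task labels must be +/-1")
        if y.shape[0] != self.table.n_subjects:
            raise ValueError("label/table length mismatch")
        object.__setattr__(self, "y", y)

    @property
    def X(self) -> np.ndarray:
        return self.table.features

    @property
    def n_subjects(self) -> int:
        return self.table.n_subjects


# task -> (positive diagnostic codes, negative diagnostic codes)
TASK_CODING = {
    TaskName.LMCI_vs_EMCI: ({LABEL_LMCI}, {LABEL_EMCI}),
    TaskName.AD_vs_NC: ({LABEL_AD}, {LABEL_NC}),
    TaskName.AD_vs_MCI: ({LABEL_AD}, {LABEL_EMCI, LABEL_LMCI}),
    TaskName.MCI_vs_NC: ({LABEL_EMCI, LABEL_LMCI}, {LABEL_NC}),
}


def _find_label_column(columns, label_column: Optional[str]) -> str:
    if label_column is not None:
        if label_column not in columns:
            raise SchemaError(f"configured label column {label_column!r} not in CSV")
        return label_column
    lowered = {c.lower(): c for c in columns}
    for cand in _LABEL_COLUMN_CANDIDATES:
        if cand in lowered:
            return lowered[cand]
    raise SchemaError(
        f"no label column found; looked for {_LABEL_COLUMN_CANDIDATES} in header"
    )


def load_feature_table(
    path,
    modality: Modality | str,
    label_column: Optional[str] = None,
    id_column: Optional[str] = None,
    allowed_labels: frozenset = VALID_LABELS,
) -> FeatureTable:
    """Load a feature-table CSV.

    Parameters
    ----------
    path : path-like
        CSV with one header row, one integer label column and numeric
        feature columns.
    modality : Modality or str
    label_column, id_column : str, optional
        Override column auto-detection. When ``id_column`` is None an
        ``id``-like column is used if present, else row numbers.
    allowed_labels : frozenset
        Diagnostic codes accepted; any other code raises ``SchemaError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise SchemaError(f"malformed CSV {path}: {exc}") from exc

    label_col = _find_label_column(df.columns, label_column)
    if id_column is None:
        id_like = [c for c in df.columns if c.lower() in ("id", "subject", "subject_id", "rid")]
        id_column = id_like[0] if id_like else None
    elif id_column not in df.columns:
        raise SchemaError(f"configured id column {id_column!r} not in CSV")

    labels_raw = df[label_col]
    if labels_raw.isna().any():
        row = int(labels_raw.index[labels_raw.isna()][0])
        raise SchemaError(f"missing label in row {row}")
    labels = labels_raw.to_numpy()
    if not np.all(labels == labels.astype(int)):
        raise SchemaError("non-integer label codes")
    labels = labels.astype(int)
    unknown = set(np.unique(labels)) - set(allowed_labels)
    if unknown:
        raise SchemaError(
            f"unknown diagnostic label code(s) {sorted(unknown)}; "
            f"expected codes {sorted(allowed_labels)}"
        )

    drop = [label_col] + ([id_column] if id_column else [])
    feat_df = df.drop(columns=drop)
    non_numeric = [c for c in feat_df.columns if not np.issubdtype(feat_df[c].dtype, np.number)]
    if non_numeric:
        raise SchemaError(f"non-numeric feature column(s): {non_numeric}")
    if feat_df.isna().any().any():
        row = int(np.argwhere(feat_df.isna().to_numpy())[0, 0])
        raise SchemaError(f"missing feature value in row {row}")

    ids = (
        df[id_column].astype(str).to_numpy()
        if id_column
        else np.array([f"S{i:04d}" for i in range(len(df))])
    )
    return FeatureTable(
        subject_ids=ids,
        features=feat_df.to_numpy(dtype=float),
        labels=labels,
        modality=Modality(modality),
        feature_names=tuple(feat_df.columns),
    )


def save_feature_table(table: FeatureTable, path) -> None:
    """Write a table in the same CSV dialect that ``load_feature_table`` reads."""
    df = pd.DataFrame(table.features, columns=list(table.feature_names))
    df.insert(0, "Label", table.labels)
    df.insert(0, "ID", table.subject_ids)
    df.to_csv(path, index=False)


def scale_unit_interval(
    table: FeatureTable, reference: Optional[FeatureTable] = None
) -> FeatureTable:
    """Min-max scale every feature column to [0, 1].

    When ``reference`` is given its per-column min/max are used (fit on
    training subjects, apply to held-out subjects) and out-of-range values
    are clipped to [0, 1].  Constant columns map to 0.
    """
    ref = reference if reference is not None else table
    if ref.n_features < table.n_features:
        raise ValueError(
            f"reference has {ref.n_features} columns but table has {table.n_features}"
        )
    lo = ref.features.min(axis=0)[: table.n_features]
    hi = ref.features.max(axis=0)[: table.n_features]
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    scaled = (table.features - lo) / safe
    scaled[:, span == 0] = 0.0
    scaled = np.clip(scaled, 0.0, 1.0)
    return replace(table, features=scaled)


def make_binary_task(table: FeatureTable, name: TaskName | str) -> BinaryTask:
    """Restrict a table to one diagnostic contrast and code labels +/-1.

    AD_vs_MCI pools E-MCI and L-MCI into the negative class; MCI_vs_NC pools
    them into the positive class.  The target task LMCI_vs_EMCI keeps only
    codes {3, 4} with L-MCI = +1.
    """
    name = TaskName(name)
    pos, neg = TASK_CODING[name]
    mask = np.isin(table.labels, list(pos | neg))
    sub = table.subset(mask)
    y = np.where(np.isin(sub.labels, list(pos)), 1, -1)
    if (y == 1).sum() == 0 or (y == -1).sum() == 0:
        raise ValueError(
            f"task {name.value}: empty class after restriction "
            f"(+{int((y == 1).sum())}/-{int((y == -1).sum())} subjects)"
        )
    return BinaryTask(
        name=name,
        table=sub,
        y=y,
        positive_codes=frozenset(pos),
        negative_codes=frozenset(neg),
    )


def concat_modalities(fdg: FeatureTable, vbm: FeatureTable) -> FeatureTable:
    """Column-concatenate FDG and VBM tables (the FDG+VBM modality).

    Subject alignment is by row order; identifiers and labels are verified
    to agree rather than assumed (the two files carry no stated join key).
    """
    if fdg.n_subjects != vbm.n_subjects:
        raise ValueError("modalities have different subject counts")
    if not np.array_equal(fdg.labels, vbm.labels):
        raise ValueError("modalities disagree on diagnostic labels; cannot align by row")
    ids_informative = not (
        np.all(np.char.startswith(fdg.subject_ids.astype(str), "S0"))
        and np.all(np.char.startswith(vbm.subject_ids.astype(str), "S0"))
    )
    if ids_informative and not np.array_equal(fdg.subject_ids, vbm.subject_ids):
        raise ValueError("modalities disagree on subject identifiers")
    names = tuple(f"FDG_{n}" for n in fdg.feature_names) + tuple(
        f"VBM_{n}" for n in vbm.feature_names
    )
    return FeatureTable(
        subject_ids=fdg.subject_ids,
        features=np.hstack([fdg.features, vbm.features]),
        labels=fdg.labels,
        modality=Modality.FDG_VBM,
        feature_names=names,
    )
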