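"""Multi-label dataset container, descriptive statistics and on-disk formats.

A multi-label dataset (MLD) pairs an ``m x d`` real feature matrix with an
``m x q`` binary label matrix: each instance carries a *subset* of the ``q``
labels.  This module defines the in-memory container used by every other
module, the classic descriptive statistics (label cardinality, density,
distinct label combinations), the active-label filter, and readers/writers
for MEKA-style multi-label ARFF and plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._arff import ArffParseError, meka_label_count, parse_arff, write_arff

__all__ = [
    "MultiLabelDataset",
    "LabelStats",
    "label_stats",
    "filter_active",
    "load_arff",
    "save_arff",
    "load_csv",
    "save_csv",
    "ArffParseError",
]


@dataclass(frozen=True)
class MultiLabelDataset:
    """An immutable multi-label dataset.

    Parameters
    ----------
    features
        ``(m, d)`` float matrix of instance feature vectors.
    labels
        ``(m, q)`` matrix with entries in ``{0, 1}``; column ``j`` is the
        indicator of label ``label_names[j]``.
    label_names, feature_names
        Unique column names for labels and features.
    provenance
        Free-text origin tag (file path or generator description).
    is_synthetic
        Per-instance flag marking rows created by oversampling; original
        data loaded from disk has all entries ``False``.
    """

    features: np.ndarray
    labels: np.ndarray
    label_names: tuple[str, ...]
    feature_names: tuple[str, ...]
    provenance: str = ""
    is_synthetic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels)
        if features.ndim != 2 or labels.ndim != 2:
            raise ValueError("features and labels must be 2-D matrices")
        if features.shape[0] != labels.shape[0]:
            raise ValueError(
                f"row mismatch: {features.shape[0]} feature rows vs "
                f"{labels.shape[0]} label rows"
            )
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("label matrix entries must be exactly 0 or 1")
        labels = labels.astype(np.int8)
        if not np.isfinite(features).all():
            raise ValueError("features must be finite (missing values rejected)")
        names = tuple(str(n) for n in self.label_names)
        if len(set(names)) != len(names):
            raise ValueError("label_names must be unique")
        if labels.shape[1] != len(names):
            raise ValueError("label_names length must match label columns")
        fnames = tuple(str(n) for n in self.feature_names)
        if len(set(fnames)) != len(fnames):
            raise ValueError("feature_names must be unique")
        if features.shape[1] != len(fnames):
            raise ValueError("feature_names length must match feature columns")
        synth = self.is_synthetic
        if synth is None:
            synth = np.zeros(features.shape[0], dtype=bool)
        synth = np.asarray(synth, dtype=bool)
        if synth.shape != (features.shape[0],):
            raise ValueError("is_synthetic must be a length-m boolean vector")
        features.setflags(write=False)
        labels.setflags(write=False)
        synth.setflags(write=False)
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "label_names", names)
        object.__setattr__(self, "feature_names", fnames)
        object.__setattr__(self, "is_synthetic", synth)

    # -- shape accessors ---------------------------------------------------
    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def n_labels(self) -> int:
        return self.labels.shape[1]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def label_counts(self) -> np.ndarray:
        """Number of positive instances per label (length ``q``)."""
        return np.asarray(self.labels.sum(axis=0), dtype=int)

    def subset(self, index: np.ndarray, provenance: str | None = None
               ) -> "MultiLabelDataset":
        """Row-subset (order follows ``index``), preserving metadata."""
        return replace(
            self,
            features=self.features[index],
            labels=self.labels[index],
            is_synthetic=self.is_synthetic[index],
            provenance=self.provenance if provenance is None else provenance,
        )

    def equals(self, other: "MultiLabelDataset") -> bool:
        return (
            np.array_equal(self.features, other.features)
            and np.array_equal(self.labels, other.labels)
            and self.label_names == other.label_names
            and self.feature_names == other.feature_names
        )


@dataclass(frozen=True)
class LabelStats:
    """Descriptive label statistics of an MLD.

    ``cardinality`` (Card) is the mean number of active labels per instance,
    ``density`` (Dens) is Card / q, ``distinct_combinations`` (DC) counts the
    unique label vectors, and ``per_label_counts`` the positives per label.
    """

    cardinality: float
    density: float
    distinct_combinations: int
    per_label_counts: tuple[int, ...]


def label_stats(mld: MultiLabelDataset) -> LabelStats:
    """Compute Card, Dens, DC and per-label positive counts.

    Raises
    ------
    ValueError
        If the dataset is empty (the statistics are means over instances).
    """
    m, q = mld.labels.shape
    if m == 0:
        raise ValueError("label_stats is undefined on an empty dataset")
    card = float(mld.labels.sum()) / m
    dens = card / q if q > 0 else 0.0
    dc = int(np.unique(mld.labels, axis=0).shape[0])
    return LabelStats(card, dens, dc, tuple(int(c) for c in mld.label_counts()))


def filter_active(mld: MultiLabelDataset) -> MultiLabelDataset:
    """Drop instances with no active label, preserving instance order.

    Idempotent; may return an empty dataset.
    """
    keep = np.flatnonzero(mld.labels.sum(axis=1) >= 1)
    if keep.size == mld.n_instances:
        return mld
    return mld.subset(keep)


# ---------------------------------------------------------------------------
# ARFF (MEKA dialect: labels first, count in the relation's "-C q" token)
# ---------------------------------------------------------------------------

def load_arff(path: str | Path, label_count: int | str = "auto"
              ) -> MultiLabelDataset:
    """Read a MEKA-style multi-label ARFF file.

    The first ``label_count`` attributes are taken as labels (MEKA
    convention).  With ``label_count="auto"`` the count is parsed from the
    ``-C <q>`` token in the relation name.  Nominal ``{0,1}`` label
    attributes are mapped to binary.
    """
    path = Path(path)
    relation, attributes, data = parse_arff(path.read_text(encoding="utf-8"))
    if label_count == "auto":
        q = meka_label_count(relation)
        if q is None:
            raise ValueError(
                f"{path}: relation {relation!r} carries no '-C <q>' token; "
                "pass label_count explicitly"
            )
    else:
        q = int(label_count)
    if not 0 < q <= len(attributes):
        raise ValueError(
            f"{path}: label_count {q} out of range for "
            f"{len(attributes)} attributes"
        )
    label_values = np.empty((data.shape[0], q))
    for j, attr in enumerate(attributes[:q]):
        col = data[:, j]
        if attr.kind == "nominal":
            # column holds indices into the nominal domain; map to the
            # declared tokens, which must be 0/1
            domain = attr.values
            if set(domain) - {"0", "1"}:
                raise ValueError(
                    f"{path}: label attribute {attr.name!r} has non-binary "
                    f"domain {domain}"
                )
            mapped = np.array([float(domain[int(v)]) for v in col])
            label_values[:, j] = mapped
        else:
            label_values[:, j] = col
        if not np.isin(label_values[:, j], (0.0, 1.0)).all():
            raise ValueError(
                f"{path}: label attribute {attr.name!r} has non-binary values"
            )
    features = data[:, q:]
    return MultiLabelDataset(
        features=features,
        labels=label_values.astype(np.int8),
        label_names=tuple(a.name for a in attributes[:q]),
        feature_names=tuple(a.name for a in attributes[q:]),
        provenance=str(path),
    )


def save_arff(mld: MultiLabelDataset, path: str | Path,
              relation: str | None = None) -> None:
    """Write a MEKA-style ARFF (labels first, nominal ``{0,1}``, UTF-8)."""
    path = Path(path)
    if relation is None:
        relation = f"mltlsmote: -C {mld.n_labels}"
    text = write_arff(
        relation,
        list(mld.label_names),
        list(mld.feature_names),
        mld.labels,
        mld.features,
    )
    path.write_text(text, encoding="utf-8")


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def load_csv(path: str | Path, label_columns: list[str]) -> MultiLabelDataset:
    """Read a CSV with designated binary label columns.

    Label matrix column order follows ``label_columns``; every other numeric
    column becomes a feature.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in label_columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing label column(s) {missing}")
    for col in label_columns:
        bad = ~frame[col].isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-binary value in label column {col!r} at row {row}"
            )
    feature_cols = [c for c in frame.columns if c not in set(label_columns)]
    features = frame[feature_cols].to_numpy(dtype=float)
    if features.size and not np.isfinite(features).all():
        raise ValueError(f"{path}: missing or non-finite feature values")
    return MultiLabelDataset(
        features=features,
        labels=frame[label_columns].to_numpy(dtype=np.int8),
        label_names=tuple(label_columns),
        feature_names=tuple(feature_cols),
        provenance=str(path),
    )


def save_csv(mld: MultiLabelDataset, path: str | Path) -> None:
    """Write labels + features as one CSV (labels first, UTF-8)."""
    columns: dict[str, object] = {
        name: mld.labels[:, j].astype(int)
        for j, name in enumerate(mld.label_names)
    }
    for j, name in enumerate(mld.feature_names):
        # repr round-trips float64 exactly; pandas' default truncates
        columns[name] = [repr(float(v)) for v in mld.features[:, j]]
    pd.DataFrame(columns).to_csv(Path(path), index=False)
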