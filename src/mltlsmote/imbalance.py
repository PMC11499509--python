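"""Multi-label imbalance measures and the minority/majority partition.

The imbalance ratio per label, ``IRLbl(lam) = max_count / count(lam)``, is 1
for the most frequent label and grows for rarer ones.  ``MeanIR`` and
``MaxIR`` are the mean and maximum over labels, ``IRLbl_sigma`` the sample
standard deviation (q-1 denominator) and ``CVIR = IRLbl_sigma / MeanIR``
its coefficient of variation.  An MLD with ``MeanIR > 1.5`` and
``CVIR > 0.2`` is flagged imbalanced.  Labels with IRLbl strictly above
MeanIR form the minority set, the rest (including ties) the majority set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import MultiLabelDataset

__all__ = ["ImbalanceProfile", "irlbl", "imbalance_profile",
           "MEAN_IR_THRESHOLD", "CVIR_THRESHOLD"]

#: Joint thresholds above which a dataset is considered imbalanced.
MEAN_IR_THRESHOLD = 1.5
CVIR_THRESHOLD = 0.2


@dataclass(frozen=True)
class ImbalanceProfile:
    """Per-label imbalance ratios and the derived summary measures."""

    irlbl: tuple[float, ...]
    mean_ir: float
    max_ir: float
    irlbl_sigma: float
    cvir: float
    minority_labels: tuple[int, ...]
    majority_labels: tuple[int, ...]
    is_imbalanced: bool

    @property
    def n_labels(self) -> int:
        return len(self.irlbl)


def _counts(mld: MultiLabelDataset) -> np.ndarray:
    counts = mld.label_counts()
    zero = np.flatnonzero(counts == 0)
    if zero.size:
        names = [mld.label_names[i] for i in zero]
        raise ValueError(
            f"IRLbl is undefined for label(s) with zero positives: {names}"
        )
    return counts


def irlbl(mld: MultiLabelDataset, label: int) -> float:
    """Imbalance ratio of one label: max label count / this label's count."""
    counts = _counts(mld)
    if not 0 <= label < counts.size:
        raise IndexError(f"label index {label} out of range")
    return float(counts.max() / counts[label])


def imbalance_profile(mld: MultiLabelDataset) -> ImbalanceProfile:
    """Compute IRLbl for every label plus MeanIR, MaxIR, IRLbl-sigma, CVIR.

    Requires every label to have at least one positive instance; zero-count
    labels would make the ratio infinite and are rejected explicitly.
    """
    counts = _counts(mld)
    ratios = counts.max() / counts.astype(float)
    mean_ir = float(ratios.mean())
    max_ir = float(ratios.max())
    q = ratios.size
    if q > 1:
        sigma = float(np.sqrt(((ratios - mean_ir) ** 2).sum() / (q - 1)))
    else:
        sigma = 0.0
    cvir = sigma / mean_ir
    minority = tuple(int(i) for i in np.flatnonzero(ratios > mean_ir))
    majority = tuple(int(i) for i in np.flatnonzero(ratios <= mean_ir))
    return ImbalanceProfile(
        irlbl=tuple(float(r) for r in ratios),
        mean_ir=mean_ir,
        max_ir=max_ir,
        irlbl_sigma=sigma,
        cvir=cvir,
        minority_labels=minority,
        majority_labels=majority,
        is_imbalanced=(mean_ir > MEAN_IR_THRESHOLD and cvir > CVIR_THRESHOLD),
    )
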