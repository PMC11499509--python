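"""Synthetic multi-label data with controllable imbalance structure.

Each instance draws a *labelset* (a full binary label vector) from a finite
distribution, and its features are the sum of one Gaussian prototype per
active label plus isotropic Gaussian noise.  The labelset distribution fixes
the label marginals (hence every imbalance ratio analytically), the pairwise
co-occurrence structure, and the supply of pure single-label instances that
per-label SMOTE seed pools need.

The frailty-like preset emulates the statistical shape of a cohort of older
adults with six binary adverse outcomes — mortality, urgent hospitalization,
disability, preventable hospitalization, emergency admission, fracture — in
descending frequency: marginals proportional to the reciprocals of the
per-label imbalance ratios (1.00, 1.07, 1.33, 2.19, 5.58, 5.90), MeanIR of
about 2.85 and CVIR of about 0.80, with each of the two minority outcomes
co-occurring with the most frequent outcome in about 70% of its occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import MultiLabelDataset

__all__ = [
    "SyntheticSpec",
    "generate_mld",
    "frailty_like_preset",
    "FRAILTY_IRLBL",
    "FRAILTY_LABELS",
]

#: Per-label imbalance ratios the preset's marginals are built from,
#: in descending label frequency.
FRAILTY_IRLBL = (1.000000, 1.074644, 1.330798, 2.192901, 5.584591, 5.904701)

FRAILTY_LABELS = (
    "mortality",
    "urgent_hospitalization",
    "disability",
    "preventable_hospitalization",
    "emergency_admission",
    "fracture",
)

#: Marginal frequency of the most frequent preset label.  0.4 puts the
#: preset's label cardinality near 1.4 active labels per instance.
_TOP_MARGINAL = 0.4

#: Probability mass of each pure single-minority-label set, so the strict
#: SMOTE seed pools are non-empty.
_PURE_MINORITY_MASS = 0.02


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters that determine an MLD's imbalance structure.

    ``labelset_distribution`` maps full binary label vectors to
    probabilities (summing to 1); ``feature_prototypes`` is a ``(q, d)``
    matrix of per-label mean shifts; ``noise_sd`` the within-labelset
    feature standard deviation.
    """

    n_instances: int
    n_features: int
    labelset_distribution: tuple[tuple[tuple[int, ...], float], ...]
    feature_prototypes: np.ndarray
    noise_sd: float
    seed: int
    label_names: tuple[str, ...] = ()

    def validate(self) -> None:
        problems = []
        if self.n_instances < 1:
            problems.append("n_instances must be positive")
        if self.n_features < 1:
            problems.append("n_features must be positive")
        if self.noise_sd <= 0:
            problems.append("noise_sd must be positive")
        if not self.labelset_distribution:
            problems.append("labelset_distribution is empty")
        else:
            probs = np.array([p for _, p in self.labelset_distribution])
            sets = np.array([s for s, _ in self.labelset_distribution])
            if (probs < 0).any():
                problems.append("labelset probabilities must be >= 0")
            if abs(probs.sum() - 1.0) > 1e-9:
                problems.append(
                    f"labelset probabilities sum to {probs.sum()!r}, not 1")
            if sets.ndim != 2 or not np.isin(sets, (0, 1)).all():
                problems.append("labelsets must be equal-length binary vectors")
            else:
                covered = (sets * (probs > 0)[:, None]).any(axis=0)
                if not covered.all():
                    missing = np.flatnonzero(~covered).tolist()
                    problems.append(
                        f"label(s) {missing} appear in no positive-probability "
                        "labelset")
                proto = np.asarray(self.feature_prototypes, dtype=float)
                if proto.shape != (sets.shape[1], self.n_features):
                    problems.append(
                        "feature_prototypes must have shape (q, n_features)")
        if problems:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(problems))

    @property
    def n_labels(self) -> int:
        return len(self.labelset_distribution[0][0])

    def analytic_marginals(self) -> np.ndarray:
        """Exact per-label marginal probabilities implied by the labelsets."""
        sets = np.array([s for s, _ in self.labelset_distribution], dtype=float)
        probs = np.array([p for _, p in self.labelset_distribution])
        return probs @ sets

    def analytic_irlbl(self) -> np.ndarray:
        """Per-label imbalance ratios implied by the analytic marginals."""
        marg = self.analytic_marginals()
        return marg.max() / marg


def generate_mld(spec: SyntheticSpec) -> MultiLabelDataset:
    """Draw a multi-label dataset from a generator spec (pure in the seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sets = np.array([s for s, _ in spec.labelset_distribution], dtype=np.int8)
    probs = np.array([p for _, p in spec.labelset_distribution], dtype=float)
    probs = probs / probs.sum()  # exact renormalization within tolerance
    choice = rng.choice(len(probs), size=spec.n_instances, p=probs)
    labels = sets[choice]
    prototypes = np.asarray(spec.feature_prototypes, dtype=float)
    means = labels.astype(float) @ prototypes
    features = means + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_instances, spec.n_features))
    q = sets.shape[1]
    names = spec.label_names or tuple(f"label_{j + 1}" for j in range(q))
    return MultiLabelDataset(
        features=features,
        labels=labels,
        label_names=names,
        feature_names=tuple(f"x{j + 1}" for j in range(spec.n_features)),
        provenance=f"synthetic(seed={spec.seed}, n={spec.n_instances})",
    )


def frailty_like_preset(n_instances: int, seed: int,
                        n_features: int = 20) -> SyntheticSpec:
    """Generator spec emulating the frailty cohort's imbalance structure.

    Six labels in descending frequency with marginals ``0.4 / IRLbl`` from
    :data:`FRAILTY_IRLBL`, built from singleton and pairwise labelsets so
    that each minority outcome co-occurs with the most frequent outcome in
    about 70% of its occurrences, while every label also appears as a pure
    singleton set (2% mass for each of the three least frequent labels), so
    strict SMOTE seed pools are never empty.  Features
    are 20 weak Gaussian prototypes (entry scale 0.3) under unit noise —
    deliberately overlapping classes, as in administrative health data.
    """
    if n_instances < 100:
        raise ValueError("the preset is calibrated for n_instances >= 100")
    marg = _TOP_MARGINAL / np.asarray(FRAILTY_IRLBL)
    m0, m1, m2, m3, m4, m5 = marg

    def vec(*active: int) -> tuple[int, ...]:
        v = [0] * 6
        for a in active:
            v[a] = 1
        return tuple(v)

    e3 = e4 = e5 = _PURE_MINORITY_MASS     # pure low-frequency singletons
    f4 = m4 - e4                           # minority with the top label
    f5 = m5 - e5
    g = 0.10                               # {top, preventable-hosp}
    u = m3 - e3 - g                        # {disability, preventable-hosp}
    h = 0.08                               # {urgent-hosp, disability}
    pair_mass = float(marg.sum()) - 1.0    # total mass of 2-label sets
    w = pair_mass - (f4 + f5 + g + u + h)  # {top, urgent-hosp}
    a = m0 - (f4 + f5 + g + w)             # singletons absorb the rest
    b = m1 - (h + w)
    c = m2 - (h + u)
    dist = (
        (vec(0), a),
        (vec(1), b),
        (vec(2), c),
        (vec(3), e3),
        (vec(4), e4),
        (vec(5), e5),
        (vec(0, 4), f4),
        (vec(0, 5), f5),
        (vec(0, 3), g),
        (vec(2, 3), u),
        (vec(1, 2), h),
        (vec(0, 1), w),
    )
    root = np.random.SeedSequence(seed)
    proto_ss, draw_ss = root.spawn(2)
    prototypes = np.random.default_rng(proto_ss).normal(
        0.0, 0.3, size=(6, n_features))
    draw_seed = int(draw_ss.generate_state(1)[0] % (2 ** 31))
    return SyntheticSpec(
        n_instances=n_instances,
        n_features=n_features,
        labelset_distribution=dist,
        feature_prototypes=prototypes,
        noise_sd=1.0,
        seed=draw_seed,
        label_names=FRAILTY_LABELS,
    )
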