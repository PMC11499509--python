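"""Hybrid multi-label resampling: per-label SMOTE plus Tomek-link cleaning.

The hybrid pipeline attacks between-label imbalance in two sequential moves:

1. **Per-minority-label SMOTE.**  For each minority label (imbalance ratio
   above MeanIR), synthetic instances are interpolated between seed
   instances that carry that label — and, under the strict seed-pool rule,
   no other label — until the label's imbalance ratio falls to the input
   MeanIR or a safety cap is reached.  Synthetic rows copy their seed's full
   label vector, so majority-label counts never grow.
2. **Per-majority-label Tomek cleaning.**  For each majority label, the
   dataset is viewed as a binary problem (label present / absent) and every
   Tomek link — a cross-class pair of mutual nearest neighbours under
   Euclidean distance — has both members removed, unless removal would
   orphan a label (leave it with no positive instance).

Both moves work on raw feature geometry; callers standardize first if their
feature scales are incommensurate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .dataset import MultiLabelDataset
from .imbalance import ImbalanceProfile, imbalance_profile

__all__ = [
    "TomekPair",
    "ResamplingReport",
    "smote_interpolate",
    "ml_smote",
    "tomek_links",
    "ml_tomek_clean",
    "ml_tlsmote",
]

logger = logging.getLogger(__name__)

#: Per-label safety cap: at most this many synthetic instances per seed-pool
#: member, preventing runaway generation from tiny pools.
MAX_SYNTHETIC_PER_POOL_MEMBER = 5

_CHUNK = 2048  # rows per distance-matrix block


@dataclass(frozen=True)
class TomekPair:
    """A cross-class pair of mutual nearest neighbours (``i < j``)."""

    i: int
    j: int
    distance: float

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("a Tomek pair joins two distinct instances")
        if self.i > self.j:
            object.__setattr__(self, "i", self.j)
            object.__setattr__(self, "j", self.i)


@dataclass(frozen=True)
class ResamplingReport:
    """Before/after imbalance profiles and per-label resampling counts."""

    before: ImbalanceProfile
    after: ImbalanceProfile
    synthetic_added: tuple[int, ...]
    removed_by_tomek: tuple[int, ...]
    seed: int | None

    @property
    def total_added(self) -> int:
        return sum(self.synthetic_added)

    @property
    def total_removed(self) -> int:
        return sum(self.removed_by_tomek)

    def to_dict(self) -> dict:
        def profile(p: ImbalanceProfile) -> dict:
            return {
                "irlbl": list(p.irlbl),
                "mean_ir": p.mean_ir,
                "max_ir": p.max_ir,
                "cvir": p.cvir,
                "minority_labels": list(p.minority_labels),
                "majority_labels": list(p.majority_labels),
                "is_imbalanced": p.is_imbalanced,
            }

        return {
            "before": profile(self.before),
            "after": profile(self.after),
            "synthetic_added": list(self.synthetic_added),
            "removed_by_tomek": list(self.removed_by_tomek),
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# SMOTE primitives
# ---------------------------------------------------------------------------

def smote_interpolate(seed_vector: np.ndarray, neighbor_vector: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """One SMOTE draw: a uniform point on the segment seed -> neighbour.

    Returns ``seed + u * (neighbor - seed)`` with ``u ~ U[0, 1)``, so the
    result lies on the closed segment between the two inputs.
    """
    seed_vector = np.asarray(seed_vector, dtype=float)
    neighbor_vector = np.asarray(neighbor_vector, dtype=float)
    if seed_vector.shape != neighbor_vector.shape:
        raise ValueError("seed and neighbour vectors must share a dimension")
    u = rng.random()
    return seed_vector + u * (neighbor_vector - seed_vector)


def _pool_neighbors(pool_features: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbours inside a pool; ties broken by lowest index.

    Returns an ``(n_pool, k)`` array of pool-local neighbour indices.
    """
    n = pool_features.shape[0]
    dist = cdist(pool_features, pool_features)
    np.fill_diagonal(dist, np.inf)
    # stable argsort on distance gives lowest-index tie-breaking
    order = np.argsort(dist, axis=1, kind="stable")
    return order[:, :k]


def ml_smote(
    mld: MultiLabelDataset,
    profile: ImbalanceProfile,
    k: int = 5,
    rng: np.random.Generator | int | None = None,
    seed_pool: str = "strict",
) -> tuple[MultiLabelDataset, tuple[int, ...]]:
    """Oversample each minority label by SMOTE over its seed pool.

    Minority labels are processed in descending imbalance-ratio order
    (rarest first).  The seed pool for a label is, under ``"strict"``, the
    instances carrying that label and *no other*; under ``"no-majority"``,
    those carrying the label and no majority label.  Synthetic instances are
    generated until the label's imbalance ratio — with the numerator frozen
    at the input profile's maximum label count — drops to the input MeanIR,
    or the safety cap (5x pool size) is hit.  Each synthetic row copies its
    seed's full label vector; original rows are never modified.

    Returns the augmented dataset and per-label synthetic counts.
    """
    if seed_pool not in {"strict", "no-majority"}:
        raise ValueError("seed_pool must be 'strict' or 'no-majority'")
    if k < 1:
        raise ValueError("k must be >= 1")
    if profile.n_labels != mld.n_labels:
        raise ValueError("profile does not match the dataset's label space")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    q = mld.n_labels
    added = [0] * q
    if not profile.minority_labels:
        return mld, tuple(added)

    max_count_frozen = int(mld.label_counts().max())
    target_count = max_count_frozen / profile.mean_ir  # IRLbl <= MeanIR

    labels = mld.labels
    majority_mask = np.zeros(q, dtype=bool)
    majority_mask[list(profile.majority_labels)] = True

    order = sorted(profile.minority_labels,
                   key=lambda j: (-profile.irlbl[j], j))
    new_features: list[np.ndarray] = []
    new_labels: list[np.ndarray] = []
    counts = mld.label_counts().astype(int)

    for lam in order:
        has_lam = labels[:, lam] == 1
        if seed_pool == "strict":
            others = labels.sum(axis=1) - labels[:, lam]
            eligible = has_lam & (others == 0)
        else:
            eligible = has_lam & (labels[:, majority_mask].sum(axis=1) == 0)
        pool = np.flatnonzero(eligible)
        if pool.size < 2:
            logger.warning(
                "ml_smote: label %r has a seed pool of size %d; skipped "
                "(interpolation needs at least 2 seeds)",
                mld.label_names[lam], pool.size)
            continue
        current = counts[lam] + added[lam]
        needed = math.ceil(target_count) - current
        if needed <= 0:
            continue
        cap = MAX_SYNTHETIC_PER_POOL_MEMBER * pool.size
        if needed > cap:
            logger.warning(
                "ml_smote: label %r needs %d synthetic instances but the "
                "safety cap allows %d", mld.label_names[lam], needed, cap)
        n_new = min(needed, cap)
        k_eff = min(k, pool.size - 1)
        if k_eff < k:
            logger.warning(
                "ml_smote: label %r pool size %d clamps k from %d to %d",
                mld.label_names[lam], pool.size, k, k_eff)
        pool_x = mld.features[pool]
        neighbors = _pool_neighbors(pool_x, k_eff)
        for t in range(n_new):
            s = t % pool.size  # cycle seeds round-robin through the pool
            nb = neighbors[s, rng.integers(k_eff)]
            new_features.append(smote_interpolate(pool_x[s], pool_x[nb], rng))
            new_labels.append(labels[pool[s]].copy())
        # synthetic rows raise the counts of every label they carry
        batch = np.asarray(new_labels[-n_new:])
        for j in range(q):
            added[j] += int(batch[:, j].sum())

    if not new_features:
        return mld, tuple(added)
    features = np.vstack([mld.features, np.asarray(new_features)])
    out_labels = np.vstack([labels, np.asarray(new_labels, dtype=np.int8)])
    synth = np.concatenate(
        [mld.is_synthetic, np.ones(len(new_features), dtype=bool)])
    out = MultiLabelDataset(
        features=features,
        labels=out_labels,
        label_names=mld.label_names,
        feature_names=mld.feature_names,
        provenance=mld.provenance + " +ml_smote",
        is_synthetic=synth,
    )
    return out, tuple(added)


# ---------------------------------------------------------------------------
# Tomek links
# ---------------------------------------------------------------------------

def _nearest_sets(features: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Each instance's minimum distance to any other, and all attaining it.

    Ties are kept (every argmin is returned), so downstream link detection
    matches the strict "no third instance strictly closer" definition.
    """
    n = features.shape[0]
    dmin = np.empty(n)
    argmins: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        block = cdist(features[start:stop], features)
        for r in range(stop - start):
            block[r, start + r] = np.inf
        block_min = block.min(axis=1)
        dmin[start:stop] = block_min
        for r in range(stop - start):
            argmins[start + r] = np.flatnonzero(block[r] == block_min[r])
    return dmin, argmins


def tomek_links(features: np.ndarray, binary_target: np.ndarray
                ) -> set[TomekPair]:
    """All cross-class mutual-nearest-neighbour pairs under Euclidean distance.

    A pair ``(i, j)`` with different targets is a link when no third
    instance is strictly closer to either member.  Returns the empty set
    when fewer than two instances or only one class is present.
    """
    features = np.asarray(features, dtype=float)
    binary_target = np.asarray(binary_target)
    if features.ndim != 2 or binary_target.shape != (features.shape[0],):
        raise ValueError("features must be (n, d) and binary_target length n")
    n = features.shape[0]
    if n < 2 or np.unique(binary_target).size < 2:
        return set()
    dmin, argmins = _nearest_sets(features)
    links: set[TomekPair] = set()
    for i in range(n):
        for j in argmins[i]:
            j = int(j)
            if j <= i or binary_target[i] == binary_target[j]:
                continue
            if i in argmins[j]:
                links.add(TomekPair(i, j, float(dmin[i])))
    return links


def ml_tomek_clean(
    mld: MultiLabelDataset, profile: ImbalanceProfile
) -> tuple[MultiLabelDataset, tuple[int, ...]]:
    """Remove Tomek-link members under each majority label's binary view.

    Majority labels are processed in ascending imbalance-ratio order (most
    frequent first).  For each, links are recomputed on the currently
    surviving instances and both members of every link are removed — except
    that an instance is never removed if it is the last surviving positive
    for any label.  Removal counts are attributed to the majority label
    whose pass removed the instance.
    """
    if profile.n_labels != mld.n_labels:
        raise ValueError("profile does not match the dataset's label space")
    q = mld.n_labels
    removed = [0] * q
    alive = np.ones(mld.n_instances, dtype=bool)
    live_counts = mld.label_counts().astype(int)

    order = sorted(profile.majority_labels,
                   key=lambda j: (profile.irlbl[j], j))
    for lam in order:
        idx = np.flatnonzero(alive)
        if idx.size < 2:
            break
        target = mld.labels[idx, lam]
        if np.unique(target).size < 2:
            continue
        links = tomek_links(mld.features[idx], target)
        for pair in sorted(links, key=lambda p: (p.i, p.j)):
            for local in (pair.i, pair.j):
                g = idx[local]
                if not alive[g]:
                    continue
                carried = np.flatnonzero(mld.labels[g] == 1)
                if any(live_counts[c] <= 1 for c in carried):
                    continue  # never orphan a label
                alive[g] = False
                live_counts -= mld.labels[g]
                removed[lam] += 1
    if alive.all():
        return mld, tuple(removed)
    out = mld.subset(np.flatnonzero(alive),
                     provenance=mld.provenance + " +ml_tomek_clean")
    return out, tuple(removed)


# ---------------------------------------------------------------------------
# The hybrid pipeline
# ---------------------------------------------------------------------------

#: Hard ceiling on oversampling rounds inside the hybrid pipeline.
MAX_SMOTE_ROUNDS = 20


def ml_tlsmote(
    mld: MultiLabelDataset,
    k: int = 5,
    seed: int | None = None,
    seed_pool: str = "strict",
) -> tuple[MultiLabelDataset, ResamplingReport]:
    """Hybrid resampling: minority-label SMOTE, then majority-label Tomek.

    The oversampling phase runs :func:`ml_smote` in rounds, recomputing the
    imbalance profile after each round (so its minority set, MeanIR target
    and seed pools track the current data), until both balance indicators
    clear their thresholds (MeanIR <= 1.5 and CVIR <= 0.2) or a round makes
    no progress.  Tomek cleaning then runs once against the profile of the
    augmented data, and the final profile is recomputed.

    Expects a dataset that has passed the active-label filter and has at
    least one positive per label.  Datasets whose input profile is already
    balanced are returned unchanged.  With a fixed ``seed`` the output is
    bit-reproducible.
    """
    before = imbalance_profile(mld)  # also rejects zero-count labels
    q = mld.n_labels
    if not before.is_imbalanced:
        report = ResamplingReport(before, before, (0,) * q, (0,) * q, seed)
        return mld, report
    rng = np.random.default_rng(seed)
    current = mld
    profile = before
    added_total = np.zeros(q, dtype=int)
    for _ in range(MAX_SMOTE_ROUNDS):
        if profile.mean_ir <= 1.5 and profile.cvir <= 0.2:
            break
        current, added = ml_smote(current, profile, k=k, rng=rng,
                                  seed_pool=seed_pool)
        if sum(added) == 0:
            logger.warning(
                "ml_tlsmote: oversampling stalled at MeanIR %.3f / CVIR %.3f "
                "(empty or capped seed pools)", profile.mean_ir, profile.cvir)
            break
        added_total += np.asarray(added)
        profile = imbalance_profile(current)
    cleaned, removed = ml_tomek_clean(current, profile)
    after = imbalance_profile(cleaned)
    report = ResamplingReport(
        before, after, tuple(int(v) for v in added_total), removed, seed)
    return cleaned, report
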