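"""Multi-label classification strategies over a pluggable base learner.

Six strategies are provided, all producing an ``(m, q)`` score matrix and a
binary decision matrix:

* **BR** (binary relevance): one independent binary model per label.
* **CC** (classifier chains): binary models in a chain, each consuming the
  features plus the binary predictions of the earlier chain members.
* **LP** (label powerset): one multi-class model over the observed label
  combinations.
* **RAkEL**: an ensemble of LP models on random k-label subsets, combined by
  thresholded voting.
* **CLR** (calibrated label ranking): pairwise label models plus one
  calibration model per label against a virtual boundary label.
* **MLkNN**: k-nearest-neighbour with Bayesian posteriors over the number
  of neighbours carrying each label.

Base learners are consumed through a small contract (fit on a feature
matrix and a 1-D target, return per-class confidence), realized by
scikit-learn estimators for the five supported families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.naive_bayes import GaussianNB
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataset import MultiLabelDataset
from .metrics import METRIC_NAMES, PredictionResult, evaluate_predictions

__all__ = [
    "BaseLearnerSpec",
    "BASE_LEARNER_PRESETS",
    "fit_br",
    "fit_cc",
    "fit_lp",
    "fit_rakel",
    "fit_clr",
    "fit_mlknn",
    "fit_strategy",
    "run_experiment",
    "average_rank",
    "STRATEGY_NAMES",
]

logger = logging.getLogger(__name__)

STRATEGY_NAMES = ("br", "cc", "lp", "rakel", "clr", "mlknn")

#: Strategy -> base-learner family pairings that performed best in practice:
#: randomized trees for BR/CC/CLR, the polynomial SVM for LP/RAkEL, and
#: Gaussian naive Bayes for MLkNN (which ignores the base learner anyway).
BASE_LEARNER_PRESETS = {
    "br": "random_tree",
    "cc": "random_tree",
    "clr": "random_tree",
    "lp": "svm",
    "rakel": "svm",
    "mlknn": "naive_bayes",
}


@dataclass(frozen=True)
class BaseLearnerSpec:
    """A base-learner family plus overriding parameters.

    Families: ``random_forest``, ``random_tree`` (a single
    randomized-feature tree), ``decision_tree``, ``svm`` (polynomial kernel,
    degree 1, C=0.1, gamma=0.001) and ``naive_bayes``.
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown base-learner family {self.family!r}; "
                f"choose from {sorted(_FAMILIES)}")


def _make_estimator(spec: BaseLearnerSpec, random_state: int | None):
    params = dict(spec.params)
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=params.pop("n_estimators", 100),
            random_state=random_state, **params)
    if spec.family == "random_tree":
        return DecisionTreeClassifier(
            max_features=params.pop("max_features", "sqrt"),
            random_state=random_state, **params)
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(random_state=random_state, **params)
    if spec.family == "svm":
        return SVC(
            kernel=params.pop("kernel", "poly"),
            degree=params.pop("degree", 1),
            C=params.pop("C", 0.1),
            gamma=params.pop("gamma", 0.001),
            random_state=random_state, **params)
    if spec.family == "naive_bayes":
        return GaussianNB(**params)
    raise AssertionError(spec.family)


_FAMILIES = {"random_forest", "random_tree", "decision_tree", "svm",
             "naive_bayes"}


class _ConstantModel:
    """Stands in for a base learner when training saw a single class."""

    def __init__(self, value: float):
        self.value = float(value)

    def confidence(self, X: np.ndarray) -> np.ndarray:
        return np.full(X.shape[0], self.value)


class _BinaryModel:
    """A fitted binary base learner exposing positive-class confidence."""

    def __init__(self, estimator):
        self.estimator = estimator

    @classmethod
    def fit(cls, spec: BaseLearnerSpec, X: np.ndarray, y: np.ndarray,
            random_state: int | None):
        classes = np.unique(y)
        if classes.size < 2:
            logger.warning(
                "degenerate binary target (all %s); using a constant scorer",
                classes[0] if classes.size else "empty")
            return _ConstantModel(float(classes[0]) if classes.size else 0.0)
        est = _make_estimator(spec, random_state)
        est.fit(X, y)
        return cls(est)

    def confidence(self, X: np.ndarray) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X)
            pos = int(np.flatnonzero(est.classes_ == 1)[0])
            return proba[:, pos]
        margin = est.decision_function(X)
        return 1.0 / (1.0 + np.exp(-margin))  # squash margins to (0, 1)


class _MulticlassModel:
    """A fitted multi-class base learner exposing per-class confidences."""

    def __init__(self, estimator, classes: np.ndarray):
        self.estimator = estimator
        self.classes = classes

    @classmethod
    def fit(cls, spec: BaseLearnerSpec, X: np.ndarray, y: np.ndarray,
            random_state: int | None):
        classes = np.unique(y)
        est = _make_estimator(spec, random_state)
        if classes.size < 2:
            return cls(None, classes)
        est.fit(X, y)
        return cls(est, est.classes_)

    def confidences(self, X: np.ndarray) -> np.ndarray:
        """(n, n_classes) confidences summing to 1 per row."""
        if self.estimator is None:
            return np.ones((X.shape[0], 1))
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)
        margin = est.decision_function(X)
        if margin.ndim == 1:  # binary decision_function -> two columns
            margin = np.column_stack([-margin, margin])
        margin = margin - margin.max(axis=1, keepdims=True)
        expm = np.exp(margin)
        return expm / expm.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Strategy models
# ---------------------------------------------------------------------------

@dataclass
class MLCModel:
    """A fitted multi-label strategy; subclasses fill in the scoring rule."""

    strategy: str
    label_names: tuple[str, ...]
    config: dict

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_scores(X) >= 0.5).astype(np.int8)

    def predict_result(self, X: np.ndarray) -> PredictionResult:
        scores = self.predict_scores(X)
        return PredictionResult(scores, self.predict(X), 0.5)


@dataclass
class _BRModel(MLCModel):
    models: list

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([m.confidence(X) for m in self.models])


def fit_br(mld: MultiLabelDataset, base: BaseLearnerSpec,
           random_state: int | None = None) -> MLCModel:
    """Binary relevance: one independent binary model per label."""
    models = [
        _BinaryModel.fit(base, mld.features, mld.labels[:, j], random_state)
        for j in range(mld.n_labels)
    ]
    return _BRModel("br", mld.label_names, {"base": base.family}, models)


@dataclass
class _CCModel(MLCModel):
    models: list
    chain_order: tuple[int, ...]

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        q = len(self.label_names)
        scores = np.zeros((X.shape[0], q))
        augmented = X
        for model, j in zip(self.models, self.chain_order):
            conf = model.confidence(augmented)
            scores[:, j] = conf
            augmented = np.column_stack(
                [augmented, (conf >= 0.5).astype(float)])
        return scores


def fit_cc(mld: MultiLabelDataset, base: BaseLearnerSpec,
           chain_order: tuple[int, ...] | None = None,
           random_state: int | None = None) -> MLCModel:
    """Classifier chain: each model sees earlier models' label predictions.

    At inference the chain propagates its *own* binary predictions.  The
    default chain order is ascending label index.
    """
    q = mld.n_labels
    if chain_order is None:
        chain_order = tuple(range(q))
    if sorted(chain_order) != list(range(q)):
        raise ValueError("chain_order must be a permutation of the labels")
    models = []
    augmented = mld.features
    for j in chain_order:
        models.append(
            _BinaryModel.fit(base, augmented, mld.labels[:, j], random_state))
        augmented = np.column_stack(
            [augmented, mld.labels[:, j].astype(float)])
    return _CCModel("cc", mld.label_names,
                    {"base": base.family, "chain_order": list(chain_order)},
                    models, tuple(chain_order))


@dataclass
class _LPModel(MLCModel):
    model: _MulticlassModel
    labelsets: np.ndarray  # (n_classes, q) binary rows, in class order

    def class_confidences(self, X: np.ndarray) -> np.ndarray:
        return self.model.confidences(X)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        conf = self.class_confidences(X)
        return conf @ self.labelsets.astype(float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        conf = self.class_confidences(X)
        best = conf.argmax(axis=1)
        return self.labelsets[best].astype(np.int8)


def fit_lp(mld: MultiLabelDataset, base: BaseLearnerSpec,
           random_state: int | None = None) -> MLCModel:
    """Label powerset: observed label combinations become classes.

    The per-label score is the summed confidence of the classes whose
    labelset contains the label; the decision is the argmax class's
    labelset, so only combinations seen in training can be predicted.
    """
    combos, y = np.unique(mld.labels, axis=0, return_inverse=True)
    model = _MulticlassModel.fit(base, mld.features, y, random_state)
    order = model.classes  # class ids index into combos
    labelsets = combos[np.asarray(order, dtype=int)]
    return _LPModel("lp", mld.label_names, {"base": base.family},
                    model, labelsets)


@dataclass
class _RakelModel(MLCModel):
    members: list  # (label_subset, _LPModel) pairs
    coverage: np.ndarray
    prior: np.ndarray
    vote_threshold: float

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        q = len(self.label_names)
        votes = np.zeros((X.shape[0], q))
        for subset, model in self.members:
            votes[:, subset] += model.predict(X)
        scores = np.where(
            self.coverage > 0, votes / np.maximum(self.coverage, 1),
            self.prior[None, :])
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_scores(X) >= self.vote_threshold).astype(np.int8)


def fit_rakel(mld: MultiLabelDataset, base: BaseLearnerSpec,
              labelset_size: int = 3, n_models: int = 12,
              vote_threshold: float = 0.5,
              random_state: int | None = None) -> MLCModel:
    """RAkEL: LP models on random k-label subsets, thresholded voting.

    Each member model is an LP over a uniformly drawn k-subset of labels
    (subsets may repeat across members).  A label's score is the fraction of
    covering members voting it positive; labels covered by no member fall
    back to their training prior frequency (logged).
    """
    q = mld.n_labels
    if labelset_size > q:
        raise ValueError(f"labelset_size {labelset_size} exceeds q={q}")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng(random_state)
    coverage = np.zeros(q)
    members = []
    for t in range(n_models):
        subset = np.sort(rng.choice(q, size=labelset_size, replace=False))
        sub = MultiLabelDataset(
            features=mld.features,
            labels=mld.labels[:, subset],
            label_names=tuple(mld.label_names[j] for j in subset),
            feature_names=mld.feature_names,
            provenance=mld.provenance,
        )
        member_seed = None if random_state is None else int(
            np.random.SeedSequence([random_state, t]).generate_state(1)[0]
            % (2 ** 31))
        members.append((subset, fit_lp(sub, base, member_seed)))
        coverage[subset] += 1
    uncovered = np.flatnonzero(coverage == 0)
    if uncovered.size:
        logger.warning(
            "fit_rakel: label(s) %s covered by no subset; falling back to "
            "prior frequency", [mld.label_names[j] for j in uncovered])
    prior = mld.labels.mean(axis=0)
    return _RakelModel(
        "rakel", mld.label_names,
        {"base": base.family, "k": labelset_size, "n_models": n_models,
         "vote_threshold": vote_threshold},
        members, coverage, prior, vote_threshold)


@dataclass
class _CLRModel(MLCModel):
    pairwise: list   # ((a, b), model-or-None) in combination order
    calibration: list

    def _votes(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = X.shape[0]
        q = len(self.label_names)
        votes = np.zeros((n, q))
        n_voting = np.zeros(q)
        for (a, b), model in self.pairwise:
            if model is None:
                continue  # abstaining pair
            conf = model.confidence(X)  # confidence that a beats b
            win_a = conf >= 0.5
            votes[:, a] += win_a
            votes[:, b] += ~win_a
            n_voting[a] += 1
            n_voting[b] += 1
        virtual = np.zeros(n)
        for j, model in enumerate(self.calibration):
            conf = model.confidence(X)
            pos = conf >= 0.5
            votes[:, j] += pos
            virtual += ~pos
            n_voting[j] += 1
        return votes / np.maximum(n_voting, 1)[None, :], virtual / q

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return self._votes(X)[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        share, virtual_share = self._votes(X)
        return (share > virtual_share[:, None]).astype(np.int8)


def fit_clr(mld: MultiLabelDataset, base: BaseLearnerSpec,
            random_state: int | None = None) -> MLCModel:
    """Calibrated label ranking: pairwise models plus a virtual label.

    ``q(q-1)/2`` pairwise models are each trained on the instances carrying
    exactly one label of their pair; ``q`` calibration models (one per
    label, against the virtual boundary label) are ordinary binary
    relevance models.  A label's score is its vote share; the predicted set
    contains the labels whose share beats the virtual label's.
    """
    q = mld.n_labels
    if q < 2:
        raise ValueError("CLR needs at least two labels")
    pairwise = []
    for a, b in combinations(range(q), 2):
        mask = mld.labels[:, a] != mld.labels[:, b]
        if not mask.any():
            logger.warning(
                "fit_clr: no training instance separates labels %r and %r; "
                "the pairwise model abstains",
                mld.label_names[a], mld.label_names[b])
            pairwise.append(((a, b), None))
            continue
        target = mld.labels[mask, a]  # 1 when a (not b) is present
        model = _BinaryModel.fit(base, mld.features[mask], target,
                                 random_state)
        pairwise.append(((a, b), model))
    calibration = [
        _BinaryModel.fit(base, mld.features, mld.labels[:, j], random_state)
        for j in range(q)
    ]
    return _CLRModel("clr", mld.label_names, {"base": base.family},
                     pairwise, calibration)


@dataclass
class _MLkNNModel(MLCModel):
    train_features: np.ndarray
    k: int
    prior_pos: np.ndarray        # (q,)
    lik_pos: np.ndarray          # (q, k+1): P(count | label present)
    lik_neg: np.ndarray

    def _neighbor_counts(self, X: np.ndarray, labels: np.ndarray
                         ) -> np.ndarray:
        dist = cdist(X, self.train_features)
        order = np.argsort(dist, axis=1, kind="stable")[:, :self.k]
        return labels[order].sum(axis=1)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        counts = self._neighbor_counts(X, self._train_labels)
        m, q = counts.shape[0], self.prior_pos.size
        scores = np.empty((m, q))
        for j in range(q):
            c = counts[:, j]
            num = self.prior_pos[j] * self.lik_pos[j, c]
            den = num + (1 - self.prior_pos[j]) * self.lik_neg[j, c]
            scores[:, j] = num / den
        return scores


def fit_mlknn(mld: MultiLabelDataset, k_neighbors: int = 10,
              smoothing: float = 1.0) -> MLCModel:
    """MLkNN: Bayesian posteriors over k-nearest-neighbour label counts.

    Smoothed priors are ``(s + positives) / (2s + m)``; likelihoods of
    observing ``c`` positive neighbours given label presence/absence are
    estimated from leave-one-out neighbour statistics on the training set.
    A label is predicted when its posterior exceeds 1/2.
    """
    m = mld.n_instances
    if k_neighbors >= m:
        raise ValueError(f"k_neighbors={k_neighbors} must be < m={m}")
    s = float(smoothing)
    q = mld.n_labels
    y = mld.labels.astype(int)
    prior = (s + y.sum(axis=0)) / (2 * s + m)

    dist = cdist(mld.features, mld.features)
    np.fill_diagonal(dist, np.inf)  # leave-one-out
    order = np.argsort(dist, axis=1, kind="stable")[:, :k_neighbors]
    counts = y[order].sum(axis=1)  # (m, q) positive neighbours per label

    lik_pos = np.empty((q, k_neighbors + 1))
    lik_neg = np.empty((q, k_neighbors + 1))
    for j in range(q):
        c_pos = np.bincount(counts[y[:, j] == 1, j],
                            minlength=k_neighbors + 1)
        c_neg = np.bincount(counts[y[:, j] == 0, j],
                            minlength=k_neighbors + 1)
        lik_pos[j] = (s + c_pos) / (s * (k_neighbors + 1) + c_pos.sum())
        lik_neg[j] = (s + c_neg) / (s * (k_neighbors + 1) + c_neg.sum())

    model = _MLkNNModel(
        "mlknn", mld.label_names,
        {"k_neighbors": k_neighbors, "smoothing": s},
        mld.features, k_neighbors, prior, lik_pos, lik_neg)
    model._train_labels = y
    return model


def fit_strategy(strategy: str, mld: MultiLabelDataset,
                 base: BaseLearnerSpec | None = None,
                 random_state: int | None = None, **kwargs) -> MLCModel:
    """Fit a strategy by name, defaulting the base learner to its preset."""
    strategy = strategy.lower()
    if strategy not in STRATEGY_NAMES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy == "mlknn":
        return fit_mlknn(mld, **kwargs)
    if base is None:
        base = BaseLearnerSpec(BASE_LEARNER_PRESETS[strategy])
    fitters = {"br": fit_br, "cc": fit_cc, "lp": fit_lp, "rakel": fit_rakel,
               "clr": fit_clr}
    return fitters[strategy](mld, base, random_state=random_state, **kwargs)


# ---------------------------------------------------------------------------
# Experiment protocol and rank aggregation
# ---------------------------------------------------------------------------

def _resample(mld: MultiLabelDataset, method: str, k: int, seed: int
              ) -> MultiLabelDataset:
    from .imbalance import imbalance_profile
    from .resample import ml_smote, ml_tlsmote, ml_tomek_clean

    if method == "none":
        return mld
    if method == "tlsmote":
        return ml_tlsmote(mld, k=k, seed=seed)[0]
    profile = imbalance_profile(mld)
    if method == "smote":
        return ml_smote(mld, profile, k=k,
                        rng=np.random.default_rng(seed))[0]
    if method == "tomek":
        return ml_tomek_clean(mld, profile)[0]
    raise ValueError(f"unknown resampler {method!r}")


def run_experiment(
    mld: MultiLabelDataset,
    resampler: str = "tlsmote",
    strategies: tuple[str, ...] = STRATEGY_NAMES,
    base: BaseLearnerSpec | None = None,
    folds: int = 10,
    seed: int = 0,
    test: MultiLabelDataset | None = None,
    test_fraction: float = 0.3,
    smote_k: int = 5,
) -> dict:
    """The resampled-train / untouched-test evaluation protocol.

    The data is split into a training and a test part (or an explicit test
    set is supplied); resampling is applied **only** to the training part.
    Each strategy is scored by k-fold cross-validation on the resampled
    training data and then refit on all of it and evaluated on the
    untouched test data.  Returns a report dict with per-strategy metric
    tables and the across-strategy standard deviation per metric.
    """
    if not strategies:
        raise ValueError("strategies must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    from sklearn.model_selection import KFold, train_test_split

    rng_seed = int(np.random.SeedSequence(seed).generate_state(1)[0]
                   % (2 ** 31))
    if test is None:
        idx = np.arange(mld.n_instances)
        train_idx, test_idx = train_test_split(
            idx, test_size=test_fraction, random_state=rng_seed)
        train, test = mld.subset(np.sort(train_idx)), mld.subset(
            np.sort(test_idx))
    else:
        train = mld
    resampled = _resample(train, resampler, smote_k, rng_seed)

    report: dict = {
        "config": {
            "resampler": resampler,
            "strategies": list(strategies),
            "base": None if base is None else base.family,
            "folds": folds,
            "seed": seed,
            "smote_k": smote_k,
            "n_train": train.n_instances,
            "n_train_resampled": resampled.n_instances,
            "n_test": test.n_instances,
        },
        "cv": {},
        "test": {},
    }
    splitter = KFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    for strategy in strategies:
        fold_rows = []
        for fold_train, fold_val in splitter.split(resampled.features):
            model = fit_strategy(strategy, resampled.subset(fold_train),
                                 base, random_state=rng_seed)
            val = resampled.subset(fold_val)
            try:
                row = evaluate_predictions(
                    val.labels, model.predict_result(val.features))
            except ValueError:  # a fold without evaluable instances/labels
                continue
            fold_rows.append(row)
        if fold_rows:
            report["cv"][strategy] = {
                name: float(np.mean([r[name] for r in fold_rows]))
                for name in METRIC_NAMES}
        model = fit_strategy(strategy, resampled, base,
                             random_state=rng_seed)
        report["test"][strategy] = evaluate_predictions(
            test.labels, model.predict_result(test.features))
    for split in ("cv", "test"):
        table = report[split]
        if table:
            report[f"{split}_std"] = {
                name: float(np.std([row[name] for row in table.values()],
                                   ddof=0))
                for name in METRIC_NAMES}
    return report


def average_rank(scores_by_dataset: pd.DataFrame,
                 higher_is_better: bool = True) -> pd.Series:
    """Mean rank of each model across datasets (ties share average rank).

    ``scores_by_dataset`` is a models x datasets table of one metric; within
    each dataset column models are ranked (rank 1 = best) and each model's
    ranks are averaged across columns.
    """
    frame = pd.DataFrame(scores_by_dataset)
    if frame.empty:
        raise ValueError("average_rank needs a non-empty table")
    if frame.isna().any().any():
        raise ValueError("average_rank requires a complete table")
    values = frame.to_numpy(dtype=float)
    if higher_is_better:
        values = -values
    ranks = np.column_stack(
        [rankdata(values[:, j]) for j in range(values.shape[1])])
    return pd.Series(ranks.mean(axis=1), index=frame.index,
                     name="average_rank")
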