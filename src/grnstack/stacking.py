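"""The stacking core: TF-disjoint splitting, kurtosis-based input filtering,
feature assembly, the level-2 model zoo, the average-rank community
baseline, and hyper-parameter tuning.

The level-2 step treats GRN inference as binary edge classification: each
candidate (TF, target) edge is one row, each retained level-1 method one
feature, and gold-standard presence/absence the label.  Train and test
rows never share a transcription factor, mirroring how wet-lab validation
accrues TF by TF.  Gaussian Naive Bayes is the default level-2 model; its
inputs are restricted to level-1 methods whose score distribution has
positive excess kurtosis, since the Gaussian class-conditional assumption
fits heavy-tailed confidence outputs far better than flat ones.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .exceptions import (
    ConfigError,
    ContractError,
    DegenerateTrainingError,
    GrnValidationError,
    SplitError,
    TuningError,
)
from .grn_data import CandidateEdgeUniverse
from .level1 import EdgeScoreTable

logger = logging.getLogger(__name__)

LEVEL2_KINDS = (
    "voting",
    "logistic",
    "logistic_sgd",
    "naive_bayes",
    "svm",
    "knn",
    "random_forest",
    "adaboost",
    "gradient_boost",
)


@dataclass(frozen=True)
class SplitSpec:
    """A TF-disjoint train/test partition of the gold-standard regulators."""

    train_tfs: frozenset[str]
    test_tfs: frozenset[str]
    seed: int
    ratio: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.train_tfs & self.test_tfs:
            raise SplitError("train and test TFs overlap")
        if not self.train_tfs or not self.test_tfs:
            raise SplitError("both split sides must be non-empty")


def tf_disjoint_split(
    regulators: Iterable[str], ratio: float = 2.0 / 3.0, seed: int = 0
) -> SplitSpec:
    """Uniformly random TF partition with ``round(ratio * n)`` training TFs.

    Train share defaults to 2/3 (twice as many regulators in training as in
    testing).  Deterministic given ``seed``.
    """
    regs = sorted(set(regulators))
    if len(regs) < 2:
        raise SplitError("need at least 2 regulators to split")
    if not 0 < ratio < 1:
        raise ConfigError("ratio must lie strictly between 0 and 1")
    n_train = int(round(ratio * len(regs)))
    n_train = min(max(n_train, 1), len(regs) - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(regs))
    train = frozenset(regs[i] for i in perm[:n_train])
    test = frozenset(regs[i] for i in perm[n_train:])
    return SplitSpec(train_tfs=train, test_tfs=test, seed=seed, ratio=ratio)


def kurtosis_filter(
    table: EdgeScoreTable,
) -> tuple[list[str], dict[str, float]]:
    """Retain methods whose score distribution has positive excess kurtosis.

    Sample excess kurtosis uses the population-moment form
    ``g2 = m4 / m2^2 - 3`` (Fisher convention: exactly Gaussian gives 0)
    computed over the full score column.  Zero-variance columns are dropped
    with a warning (kurtosis undefined); if no method survives, all
    finite-kurtosis methods are retained with a warning so the ensemble
    still has inputs.
    """
    if table.scores.shape[0] < 4:
        raise GrnValidationError("kurtosis needs >= 4 score values per column")
    kurt: dict[str, float] = {}
    retained: list[str] = []
    usable: list[str] = []
    for name in table.method_names:
        col = table.column(name)
        if np.ptp(col) == 0:
            logger.warning("dropping %r: zero variance, kurtosis undefined", name)
            kurt[name] = float("nan")
            continue
        g2 = float(stats.kurtosis(col, fisher=True, bias=True))
        kurt[name] = g2
        usable.append(name)
        if g2 > 0:
            retained.append(name)
    if not retained:
        logger.warning("no method has positive kurtosis; retaining all usable")
        retained = list(usable)
    return retained, kurt


def rank_normalize(col: np.ndarray) -> np.ndarray:
    """Map scores to average-rank / n, i.e. values in (0, 1]."""
    return stats.rankdata(col, method="average") / len(col)


@dataclass
class FeatureTable:
    """Rank-normalised level-1 scores for the edges of one split side."""

    edges: tuple[tuple[str, str], ...]
    X: np.ndarray  # (n_edges_on_side, n_retained_methods), values in (0, 1]
    method_names: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.edges), len(self.method_names)):
            raise ValueError("feature matrix shape mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)

    @property
    def n_rows(self) -> int:
        return len(self.edges)


def assemble_features(
    table: EdgeScoreTable,
    retained: Sequence[str],
    universe: CandidateEdgeUniverse,
    split: SplitSpec,
    side: str,
) -> FeatureTable:
    """Build the level-2 feature table for one side of a TF-disjoint split.

    Scores are rank-normalised over the *full* candidate universe (average
    ranks for ties, divided by edge count) before the side's rows are
    selected, so train and test features live on a common scale.  Labels are
    attached on the train side.
    """
    if side not in ("train", "test"):
        raise ValueError("side must be 'train' or 'test'")
    missing = [m for m in retained if m not in table.method_names]
    if missing:
        raise ContractError(f"retained methods not in table: {missing}")
    tfs = split.train_tfs if side == "train" else split.test_tfs
    mask = np.fromiter(
        ((r in tfs) for r, _ in universe.edges), dtype=bool, count=universe.n_edges
    )
    if not mask.any():
        raise GrnValidationError(f"no candidate edges on the {side} side")
    normalized = np.column_stack(
        [rank_normalize(table.column(m)) for m in retained]
    )
    edges = tuple(e for e, keep in zip(universe.edges, mask) if keep)
    labels = None
    if side == "train":
        if universe.labels is None:
            raise GrnValidationError("universe has no labels for training")
        labels = universe.labels[mask]
    return FeatureTable(
        edges=edges, X=normalized[mask], method_names=list(retained), labels=labels
    )


class GaussianNaiveBayes:
    """Gaussian Naive Bayes edge classifier.

    Class priors are the empirical label frequencies; each retained level-1
    method contributes an independent Gaussian class-conditional likelihood
    p(x | e) per class e in {absent, present}.  Per-class per-feature
    variances are floored at ``1e-9 * max feature variance`` to keep the
    log-likelihood finite on (near-)constant features.
    """

    def __init__(self) -> None:
        self.classes_: np.ndarray | None = None
        self.priors_: np.ndarray | None = None
        self.means_: np.ndarray | None = None
        self.variances_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianNaiveBayes":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise DegenerateTrainingError("training labels contain one class")
        floor = 1e-9 * max(float(np.max(X.var(axis=0))), np.finfo(float).tiny)
        priors, means, variances = [], [], []
        for c in self.classes_:
            sub = X[y == c]
            priors.append(len(sub) / len(X))
            means.append(sub.mean(axis=0))
            variances.append(np.maximum(sub.var(axis=0), floor))
        self.priors_ = np.array(priors)
        self.means_ = np.array(means)
        self.variances_ = np.array(variances)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        log_post = np.log(self.priors_)[None, :] + np.stack(
            [
                -0.5
                * np.sum(
                    np.log(2 * math.pi * self.variances_[k])
                    + (X - self.means_[k]) ** 2 / self.variances_[k],
                    axis=1,
                )
                for k in range(len(self.classes_))
            ],
            axis=1,
        )
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        return post / post.sum(axis=1, keepdims=True)


@dataclass
class Level2Model:
    """A fitted level-2 ensemble model bound to its retained feature columns."""

    kind: str
    retained_methods: list[str]
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    estimator: Any = None


def _gaussianize(X: np.ndarray) -> np.ndarray:
    """Probit transform of rank-normalised features onto the real line.

    Gaussian Naive Bayes assumes Gaussian class-conditionals, but
    rank-normalised scores are bounded and near-uniform, which makes the
    fitted positive-class Gaussians artificially narrow and the posterior
    overconfident.  Mapping ranks through the standard normal quantile
    function is strictly monotone (so no ranking information changes) and
    gives the model inputs on which its distributional assumption is far
    closer to true.
    """
    return stats.norm.ppf(np.clip(X, 1e-6, 1 - 1e-6))


def _make_estimator(kind: str, hp: Mapping[str, Any], seed: int):
    hp = dict(hp)
    if kind == "logistic":
        return LogisticRegression(max_iter=1000, **hp)
    if kind == "logistic_sgd":
        hp.setdefault("loss", "log_loss")
        return SGDClassifier(random_state=seed, **hp)
    if kind == "naive_bayes":
        return GaussianNaiveBayes()
    if kind == "svm":
        return SVC(random_state=seed, **hp)
    if kind == "knn":
        return KNeighborsClassifier(**hp)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if kind == "adaboost":
        return AdaBoostClassifier(random_state=seed, **hp)
    if kind == "gradient_boost":
        return GradientBoostingClassifier(random_state=seed, **hp)
    raise ConfigError(f"unknown level-2 kind {kind!r}")


def fit_level2(
    kind: str,
    train: FeatureTable,
    hyperparameters: Mapping[str, Any] | None = None,
    seed: int = 0,
) -> Level2Model:
    """Fit a level-2 classifier on the training feature table.

    ``voting`` needs no fitting; every other kind requires both classes in
    the training labels.
    """
    hp = dict(hyperparameters or {})
    if kind not in LEVEL2_KINDS:
        raise ConfigError(f"unknown level-2 kind {kind!r}")
    if kind == "voting":
        return Level2Model(kind=kind, retained_methods=list(train.method_names),
                           hyperparameters=hp)
    if train.labels is None:
        raise DegenerateTrainingError("training table has no labels")
    if len(np.unique(train.labels)) < 2:
        raise DegenerateTrainingError("training labels contain one class")
    gaussianize = hp.pop("gaussianize", kind == "naive_bayes")
    hp_model = dict(hp)
    hp["gaussianize"] = gaussianize
    est = _make_estimator(kind, hp_model, seed)
    X = _gaussianize(train.X) if gaussianize else train.X
    est.fit(X, np.asarray(train.labels, dtype=int))
    return Level2Model(
        kind=kind,
        retained_methods=list(train.method_names),
        hyperparameters=hp,
        estimator=est,
    )


def predict_level2(model: Level2Model, test: FeatureTable) -> np.ndarray:
    """Score the test edges: one confidence in [0, 1] per edge.

    Probabilistic kinds emit the class-1 posterior; the SVM maps its
    decision value through a logistic sigmoid; voting emits the fraction of
    methods ranking the edge in their top decile (feature value > 0.9).
    """
    if list(test.method_names) != list(model.retained_methods):
        missing = [m for m in model.retained_methods if m not in test.method_names]
        extra = [m for m in test.method_names if m not in model.retained_methods]
        raise ContractError(
            f"feature columns mismatch; missing={missing} extra={extra}"
        )
    if model.kind == "voting":
        threshold = model.hyperparameters.get("vote_quantile", 0.9)
        return np.mean(test.X > threshold, axis=1)
    est = model.estimator
    X = _gaussianize(test.X) if model.hyperparameters.get("gaussianize") else test.X
    if model.kind == "svm":
        z = est.decision_function(X)
        return 1.0 / (1.0 + np.exp(-z))
    proba = est.predict_proba(X)
    classes = list(getattr(est, "classes_"))
    return np.clip(proba[:, classes.index(1)], 0.0, 1.0)


def average_rank_baseline(
    table: EdgeScoreTable, retained: Sequence[str]
) -> np.ndarray:
    """Community baseline: mean normalised rank of each edge over the methods.

    Best (highest score) edges get rank near 1; output lies in (0, 1] and is
    returned for every edge of the table's universe.
    """
    if not retained:
        raise ConfigError("average_rank_baseline needs >= 1 retained method")
    cols = [rank_normalize(table.column(m)) for m in retained]
    return np.mean(np.column_stack(cols), axis=1)


def _tf_folds(
    regulators: Sequence[str], k_folds: int, seed: int
) -> list[frozenset[str]]:
    regs = sorted(set(regulators))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(regs))
    folds: list[set[str]] = [set() for _ in range(k_folds)]
    for i, p in enumerate(perm):
        folds[i % k_folds].add(regs[p])
    return [frozenset(f) for f in folds if f]


def tune_hyperparameters(
    kind: str,
    tuning_table: FeatureTable,
    grid: Mapping[str, Sequence[Any]],
    k_folds: int = 3,
    seed: int = 0,
) -> dict[str, Any]:
    """Exhaustive grid search with TF-disjoint cross-validation folds.

    Fold assignment is by regulator, mirroring deployment (no TF appears in
    both a fit and a validation side).  The selection metric is mean
    validation AUPRC; ties break toward the earliest grid combination.
    Infeasible combinations (estimator refuses to fit/predict) are skipped
    with a warning.  An empty grid returns ``{}`` immediately.
    """
    from .evaluation import auprc  # local import to avoid a cycle

    if not grid:
        return {}
    if tuning_table.labels is None or len(np.unique(tuning_table.labels)) < 2:
        raise DegenerateTrainingError("tuning table needs both classes")
    keys = list(grid.keys())
    combos = [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]
    regulators = sorted({r for r, _ in tuning_table.edges})
    folds = _tf_folds(regulators, k_folds, seed)
    edge_regs = np.array([r for r, _ in tuning_table.edges])

    best_hp: dict[str, Any] | None = None
    best_score = -np.inf
    for combo in combos:
        fold_scores = []
        feasible = True
        for fold in folds:
            val_mask = np.isin(edge_regs, list(fold))
            tr_mask = ~val_mask
            y_tr = tuning_table.labels[tr_mask]
            y_val = tuning_table.labels[val_mask]
            if len(np.unique(y_tr)) < 2 or len(np.unique(y_val)) < 2:
                logger.warning("skipping single-class fold during tuning")
                continue
            sub_train = FeatureTable(
                edges=tuple(e for e, m in zip(tuning_table.edges, tr_mask) if m),
                X=tuning_table.X[tr_mask],
                method_names=tuning_table.method_names,
                labels=y_tr,
            )
            sub_val = FeatureTable(
                edges=tuple(e for e, m in zip(tuning_table.edges, val_mask) if m),
                X=tuning_table.X[val_mask],
                method_names=tuning_table.method_names,
            )
            try:
                model = fit_level2(kind, sub_train, combo, seed=seed)
                scores = predict_level2(model, sub_val)
            except (ValueError, DegenerateTrainingError) as exc:
                logger.warning("skipping infeasible combo %s: %s", combo, exc)
                feasible = False
                break
            fold_scores.append(auprc(scores, y_val))
        if not feasible or not fold_scores:
            continue
        mean_score = float(np.mean(fold_scores))
        if mean_score > best_score:
            best_score = mean_score
            best_hp = combo
    if best_hp is None:
        raise TuningError("no feasible hyper-parameter combination had a usable fold")
    return best_hp
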