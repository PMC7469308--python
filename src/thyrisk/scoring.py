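"""Classifier backends, repetition-averaged risk scores and their metrics.

A nodule's risk score is its malignancy class probability averaged over many
classifiers, each trained on the training part of a fresh stratified
60/20/20 split restricted to the selected characteristics.  The random
forest emits the fraction of trees voting malignant; other backends emit
their native class probability.  Backends plug in through a small contract
(build from hyperparameters + seed, ``fit(X, y)``, ``predict_malignant(X)``)
so further classifiers can be adapted without touching the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .cohort import Cohort, encode_design, stratified_split
from .diagnostics import rank_auc

__all__ = [
    "ClassifierSpec",
    "RiskScoreTable",
    "MetricSet",
    "MetricSummary",
    "register_classifier",
    "train_and_score",
    "ensemble_risk_scores",
    "optimal_probability_cutoff",
    "classifier_metrics",
    "summarize_over_repetitions",
]

METRIC_NAMES = ("auc", "sen", "f1", "spe", "ppv", "npv")


@dataclass(frozen=True)
class ClassifierSpec:
    """Backend identifier plus hyperparameters; defaults follow the study's
    tuned values (random forest: ntree=500, mtry=2)."""

    name: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0


class ClassifierBackend(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> None: ...

    def predict_malignant(self, X: np.ndarray) -> np.ndarray: ...


_REGISTRY: dict[str, Callable[[dict, int], ClassifierBackend]] = {}


def register_classifier(name: str):
    """Register a backend builder ``(hyperparameters, seed) -> backend``."""

    def deco(builder):
        _REGISTRY[name] = builder
        return builder

    return deco


class _SklearnProba:
    def __init__(self, est):
        self.est = est

    def fit(self, X, y):
        self.est.fit(X, y)

    def predict_malignant(self, X):
        idx = list(self.est.classes_).index(1)
        return self.est.predict_proba(X)[:, idx]


@register_classifier("random_forest")
def _build_rf(hp: dict, seed: int):
    ntree = int(hp.get("ntree", 500))
    mtry = hp.get("mtry", 2)

    class _RFVotes:
        """Class probability = percentage of trees voting malignant."""

        def __init__(self):
            self.rf = RandomForestClassifier(
                n_estimators=ntree, max_features=mtry, random_state=seed
            )

        def fit(self, X, y):
            self.rf.fit(X, y)

        def predict_malignant(self, X):
            votes = np.stack([tree.predict(X) for tree in self.rf.estimators_])
            return (votes == 1).mean(axis=0)

        @property
        def feature_importances_(self):
            return self.rf.feature_importances_

    return _RFVotes()


@register_classifier("logistic")
def _build_logistic(hp: dict, seed: int):
    # C=inf turns the default ridge penalty off: plain maximum likelihood
    return _SklearnProba(LogisticRegression(C=np.inf, max_iter=2000))


# Optional adapters mirroring the study's comparison classifiers.
@register_classifier("svm")
def _build_svm(hp: dict, seed: int):
    return _SklearnProba(
        SVC(
            C=float(hp.get("C", 0.25)),
            gamma=float(hp.get("sigma", 0.071)),
            probability=True,
            random_state=seed,
        )
    )


@register_classifier("net")
def _build_net(hp: dict, seed: int):
    return _SklearnProba(
        MLPClassifier(
            hidden_layer_sizes=(int(hp.get("size", 1)),),
            alpha=float(hp.get("decay", 0.1)),
            max_iter=2000,
            random_state=seed,
        )
    )


@register_classifier("knn")
def _build_knn(hp: dict, seed: int):
    return _SklearnProba(KNeighborsClassifier(n_neighbors=int(hp.get("k", 9))))


@register_classifier("naive_bayes")
def _build_nb(hp: dict, seed: int):
    return _SklearnProba(GaussianNB())


@register_classifier("adaboost")
def _build_adab(hp: dict, seed: int):
    return _SklearnProba(
        AdaBoostClassifier(n_estimators=int(hp.get("mfinal", 100)), random_state=seed)
    )


@register_classifier("lda")
def _build_lda(hp: dict, seed: int):
    return _SklearnProba(LinearDiscriminantAnalysis())


def _build(spec: ClassifierSpec, seed: int | None = None) -> ClassifierBackend:
    if spec.name not in _REGISTRY:
        raise KeyError(f"unknown classifier backend {spec.name!r}; known: {sorted(_REGISTRY)}")
    return _REGISTRY[spec.name](spec.hyperparameters, spec.seed if seed is None else seed)


def train_and_score(
    cohort: Cohort,
    train_mask: np.ndarray,
    spec: ClassifierSpec,
    features: list[str] | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Fit the backend on the masked training records (restricted to
    *features*) and emit P(malignant) for every nodule in the cohort."""
    design = encode_design(cohort, features)
    train_mask = np.asarray(train_mask, dtype=bool)
    ytr = design.y[train_mask]
    if ytr.min() == ytr.max():
        raise ValueError("training split contains a single outcome class")
    backend = _build(spec, seed)
    backend.fit(design.values[train_mask], ytr)
    probs = np.asarray(backend.predict_malignant(design.values), dtype=float)
    return np.clip(probs, 0.0, 1.0)


@dataclass
class RiskScoreTable:
    """Per-nodule risk scores with the per-repetition detail behind them."""

    nodule_ids: list[str]
    scores: np.ndarray  # repetition-averaged P(malignant)
    n_contributing: np.ndarray
    probabilities: np.ndarray  # (R, n) per-repetition class probabilities
    partitions: np.ndarray  # (R, n) of {"train","validate","test"}
    y: np.ndarray
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nodule_id": self.nodule_ids,
                "score": self.scores,
                "n_repetitions": self.n_contributing,
            }
        )


def ensemble_risk_scores(
    cohort: Cohort,
    spec: ClassifierSpec,
    features: list[str] | None = None,
    R: int = 100,
    seed: int = 0,
    proportions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    mode: str = "all_predictions",
) -> RiskScoreTable:
    """Average class probabilities over *R* repeated stratified splits.

    ``mode="all_predictions"`` averages every repetition's probability for
    every nodule (the study convention); ``"out_of_split"`` averages only
    repetitions in which the nodule was outside the training split.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if mode not in ("all_predictions", "out_of_split"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(R, 2))
    n = len(cohort)
    probs = np.empty((R, n))
    parts = np.empty((R, n), dtype=object)
    for r in range(R):
        labels = stratified_split(cohort, proportions, seed=int(rep_seeds[r, 0]))
        parts[r] = labels
        probs[r] = train_and_score(
            cohort, labels == "train", spec, features, seed=int(rep_seeds[r, 1])
        )
    if mode == "all_predictions":
        scores = probs.mean(axis=0)
        n_contrib = np.full(n, R)
    else:
        held_out = parts != "train"
        n_contrib = held_out.sum(axis=0)
        never = np.flatnonzero(n_contrib == 0)
        if never.size:
            raise ValueError(
                f"nodule {cohort.records[never[0]].nodule_id!r} was never held out in {R} repetitions"
            )
        scores = np.where(held_out, probs, 0.0).sum(axis=0) / n_contrib
    return RiskScoreTable(
        nodule_ids=[rec.nodule_id for rec in cohort.records],
        scores=scores,
        n_contributing=n_contrib,
        probabilities=probs,
        partitions=parts,
        y=cohort.outcomes(),
        mode=mode,
    )


def optimal_probability_cutoff(scores, labels) -> float:
    """Threshold minimizing the ROC distance to the perfect corner (0, 1),
    i.e. sqrt((1-SEN)^2 + (1-SPE)^2), over midpoints of adjacent unique
    scores plus the two infinities; ties resolve to the smaller threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = labels.sum()
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    uniq = np.unique(scores)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    sen = 1.0 - np.searchsorted(pos, candidates, side="right") / n1
    spe = np.searchsorted(neg, candidates, side="right") / n0
    d = np.hypot(1.0 - sen, 1.0 - spe)
    return float(candidates[int(np.argmin(d))])  # first minimum = smallest threshold


@dataclass(frozen=True)
class MetricSet:
    auc: float
    sen: float
    f1: float | None
    spe: float
    ppv: float | None
    npv: float | None


def benign_f1(spe: float, npv: float) -> float:
    """Benign-class F1: harmonic mean of the benign precision (NPV) and
    benign recall (SPE)."""
    if spe + npv == 0:
        return 0.0
    return 2 * npv * spe / (npv + spe)


def classifier_metrics(scores, labels, threshold: float) -> MetricSet:
    """Threshold the scores (malignant iff score > threshold) and compute
    AUC, SEN, benign-class F1, SPE, PPV, NPV.  PPV/NPV (and hence F1) are
    ``None`` when a predicted class is empty."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores > threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("both classes required")
    sen = tp / (tp + fn)
    spe = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp else None
    npv = tn / (tn + fn) if tn + fn else None
    f1 = benign_f1(spe, npv) if npv is not None else None
    return MetricSet(auc=rank_auc(scores, labels), sen=sen, f1=f1, spe=spe, ppv=ppv, npv=npv)


@dataclass
class MetricSummary:
    """Arithmetic mean of each metric over repetitions, with the count of
    repetitions in which it was defined."""

    means: dict[str, float]
    counts: dict[str, int]

    def to_series(self) -> pd.Series:
        return pd.Series(self.means)


def summarize_over_repetitions(metric_sets: list[MetricSet]) -> MetricSummary:
    if not metric_sets:
        raise ValueError("need at least one repetition")
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for name in METRIC_NAMES:
        vals = [getattr(ms, name) for ms in metric_sets if getattr(ms, name) is not None]
        counts[name] = len(vals)
        means[name] = float(np.mean(vals)) if vals else float("nan")
    return MetricSummary(means=means, counts=counts)
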