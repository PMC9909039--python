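"""Classifier training, cross-validation and benchmarking.

The primary model is a random forest over the fused descriptor matrix;
support-vector, gradient-boosting (LightGBM), decision-tree and
logistic-regression baselines are available through the same interface.
Evaluation follows the two protocols usual for peptide benchmarks:
stratified 10-fold cross-validation on the training partition (metrics on
the pooled out-of-fold predictions, per-fold values also retained) and a
held-out independent set. The zero-column filter is always fitted on the
training side of whatever split is being evaluated, so no information
leaks from validation data into the retained-column set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .encoders import ENCODER_ORDER, EncoderConfig, PeptideEncoder
from .fusion import ZeroColumnFilter, fuse
from .metrics import EvaluationReport, compute_metrics
from .peptides import LabeledDataset, stratified_split

__all__ = [
    "CLASSIFIER_FAMILIES",
    "ClassifierSpec",
    "make_classifier",
    "BitterPeptideClassifier",
    "train",
    "evaluate",
    "cross_validate",
    "run_benchmark",
    "save_model",
    "load_model",
]

CLASSIFIER_FAMILIES = (
    "random_forest",
    "svm",
    "gradient_boosting",
    "decision_tree",
    "logistic_regression",
)


def make_classifier(family: str, seed: int = 0, **hyperparameters):
    """Build a scikit-learn-compatible classifier for one model family.

    The random forest defaults to 500 trees, unrestricted depth and √p
    features per split; the baselines use library defaults, with only a
    raised iteration cap for logistic regression on the wide fused matrix.
    """
    if family == "random_forest":
        params = dict(n_estimators=500, max_features="sqrt", n_jobs=1)
        params.update(hyperparameters)
        return RandomForestClassifier(random_state=seed, **params)
    if family == "svm":
        return SVC(probability=True, random_state=seed, **hyperparameters)
    if family == "gradient_boosting":
        from lightgbm import LGBMClassifier

        params = dict(verbose=-1)
        params.update(hyperparameters)
        return LGBMClassifier(random_state=seed, **params)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hyperparameters)
    if family == "logistic_regression":
        params = dict(max_iter=2000)
        params.update(hyperparameters)
        return LogisticRegression(random_state=seed, **params)
    raise ValueError(
        f"unknown classifier family {family!r}; choose from {CLASSIFIER_FAMILIES}"
    )


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus hyperparameters and the seed to train with."""

    family: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def build(self):
        return make_classifier(self.family, self.seed, **self.hyperparameters)


def _check_xy(features: pd.DataFrame, labels=None):
    if labels is None:
        labels = features.attrs.get("labels")
    if labels is None:
        raise ValueError("labels required: pass explicitly or via df.attrs['labels']")
    y = np.asarray(labels, dtype=int)
    if len(y) != len(features):
        raise ValueError("labels and feature rows differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    return features, y


def train(spec: ClassifierSpec, features: pd.DataFrame, labels=None):
    """Fit ``(zero-column filter → classifier)`` on a fused feature matrix.

    Returns a fitted pair as a dict-like handle with ``filter`` and
    ``classifier``; deterministic given (spec, features).
    """
    features, y = _check_xy(features, labels)
    filt = ZeroColumnFilter().fit(features)
    clf = spec.build().fit(filt.transform(features).to_numpy(float), y)
    return {"spec": spec, "filter": filt, "classifier": clf}


def _scores(handle, features: pd.DataFrame) -> np.ndarray:
    x = handle["filter"].transform(features)
    x = x.to_numpy(float) if isinstance(x, pd.DataFrame) else x
    proba = handle["classifier"].predict_proba(x)
    pos = list(handle["classifier"].classes_).index(1)
    return proba[:, pos]


def evaluate(handle, features: pd.DataFrame, labels=None, threshold: float = 0.5):
    """Score a fitted handle on a feature matrix and compute the metrics."""
    features, y = _check_xy(features, labels)
    return compute_metrics(y, _scores(handle, features), threshold)


def cross_validate(
    spec: ClassifierSpec,
    features: pd.DataFrame,
    labels=None,
    k: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of a classifier spec.

    Folds are stratified and shuffled with ``seed``. The aggregate report
    is computed on the pooled out-of-fold scores/calls (primary); per-fold
    reports and per-fold metric means are attached as ``folds`` and
    ``fold_means``. The zero-column filter is refitted inside every
    training fold.
    """
    features, y = _check_xy(features, labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= k={k} members, got {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.empty(len(y), dtype=float)
    folds: list[EvaluationReport] = []
    for tr, te in skf.split(np.zeros(len(y)), y):
        handle = train(spec, features.iloc[tr], y[tr])
        s = _scores(handle, features.iloc[te])
        pooled[te] = s
        folds.append(compute_metrics(y[te], s))
    report = compute_metrics(y, pooled)
    report.folds = folds
    report.fold_means = {
        m: float(np.mean([getattr(f, m) for f in folds]))
        for m in ("sn", "sp", "acc", "mcc", "auroc")
    }
    return report


class BitterPeptideClassifier(ClassifierMixin, BaseEstimator):
    """End-to-end bitter-peptide classifier over raw sequences.

    A scikit-learn estimator that chains the ten-descriptor encoder, the
    zero-column filter (fitted on the training sequences) and a classifier
    (random forest by default). ``X`` is an iterable of peptide sequences
    or :class:`~bitterpep.peptides.Peptide` objects; ``y`` is binary with
    1 = bitter.

    Fitted attributes: ``encoder_``, ``filter_``, ``classifier_``,
    ``classes_``, ``n_features_fused_``, ``n_features_retained_``.
    """

    def __init__(
        self,
        classifier: str = "random_forest",
        lambda_: int = 1,
        omega_tpaac: float = 0.05,
        w_apaac: float = 0.5,
        w_qsorder: float = 0.1,
        nlag: int = 1,
        threshold: float = 0.5,
        random_state: int = 0,
        classifier_params: dict | None = None,
    ):
        self.classifier = classifier
        self.lambda_ = lambda_
        self.omega_tpaac = omega_tpaac
        self.w_apaac = w_apaac
        self.w_qsorder = w_qsorder
        self.nlag = nlag
        self.threshold = threshold
        self.random_state = random_state
        self.classifier_params = classifier_params

    def _encoder(self) -> PeptideEncoder:
        return PeptideEncoder(
            lambda_=self.lambda_,
            omega_tpaac=self.omega_tpaac,
            w_apaac=self.w_apaac,
            w_qsorder=self.w_qsorder,
            nlag=self.nlag,
        )

    def fit(self, X, y) -> "BitterPeptideClassifier":
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.encoder_ = self._encoder().fit()
        fused = pd.DataFrame(
            self.encoder_.transform(X), columns=self.encoder_.feature_names_out_
        )
        self.n_features_fused_ = fused.shape[1]
        self.filter_ = ZeroColumnFilter().fit(fused)
        x = self.filter_.transform(fused).to_numpy(float)
        self.n_features_retained_ = x.shape[1]
        self.classifier_ = make_classifier(
            self.classifier, self.random_state, **(self.classifier_params or {})
        ).fit(x, y)
        self.classes_ = self.classifier_.classes_
        return self

    def _transform(self, X) -> np.ndarray:
        fused = pd.DataFrame(
            self.encoder_.transform(X), columns=self.encoder_.feature_names_out_
        )
        return self.filter_.transform(fused).to_numpy(float)

    def predict_proba(self, X) -> np.ndarray:
        return self.classifier_.predict_proba(self._transform(X))

    def decision_scores(self, X) -> np.ndarray:
        """Probability of the positive (bitter) class."""
        pos = list(self.classes_).index(1)
        return self.predict_proba(X)[:, pos]

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= self.threshold).astype(int)

    def evaluate(self, X, y) -> EvaluationReport:
        return compute_metrics(np.asarray(y, int), self.decision_scores(X), self.threshold)


def save_model(model, path: str | Path) -> None:
    joblib.dump(model, path)


def load_model(path: str | Path):
    return joblib.load(path)


def _encoder_columns(columns: Sequence[str], encoder: str) -> list[str]:
    return [c for c in columns if c.startswith(encoder + ".")]


def run_benchmark(
    dataset: LabeledDataset,
    cfg: EncoderConfig = EncoderConfig(),
    specs: Sequence[ClassifierSpec] | None = None,
    seed: int = 0,
    train_fraction: float = 0.8,
    k: int = 10,
) -> pd.DataFrame:
    """Full evaluation protocol on one labeled dataset.

    Splits the data 8:2 per class (seeded), then reports, for both
    stratified k-fold cross-validation on the training partition and the
    independent set:

    - a random-forest model on each of the ten single descriptor families,
    - a random-forest model on the fused descriptors,
    - every classifier family in ``specs`` (default: all five) on the
      fused descriptors.

    Returns a tidy DataFrame with one row per (evaluation, feature,
    classifier); the dimension column is the retained width after
    zero-column removal on the relevant training matrix. The split seed is
    recorded on every row.
    """
    if specs is None:
        specs = [ClassifierSpec(f, seed=seed) for f in CLASSIFIER_FAMILIES]
    train_set, indep_set = stratified_split(dataset, train_fraction, seed)
    fused_train, fused_indep = fuse(train_set, cfg), fuse(indep_set, cfg)

    rows = []

    def add(section, feature, spec, cols):
        ftr = fused_train.loc[:, cols]
        ftr.attrs = dict(fused_train.attrs)
        fin = fused_indep.loc[:, cols]
        fin.attrs = dict(fused_indep.attrs)
        cv = cross_validate(spec, ftr, k=k, seed=seed)
        handle = train(spec, ftr)
        indep = evaluate(handle, fin)
        dim = int(handle["filter"].support_.sum())
        for evaluation, rep in (("cv", cv), ("independent", indep)):
            rows.append(
                {
                    "section": section,
                    "evaluation": evaluation,
                    "feature": feature,
                    "classifier": spec.family,
                    "dimension": dim,
                    "auroc": rep.auroc,
                    "sn": rep.sn,
                    "sp": rep.sp,
                    "acc": rep.acc,
                    "mcc": rep.mcc,
                    "seed": seed,
                }
            )

    rf = ClassifierSpec("random_forest", seed=seed)
    for enc in ENCODER_ORDER:
        add("single_feature", enc, rf, _encoder_columns(fused_train.columns, enc))
    all_cols = list(fused_train.columns)
    add("fusion", "Fusion", rf, all_cols)
    for spec in specs:
        add("classifier_comparison", "Fusion", spec, all_cols)
    return pd.DataFrame(rows)
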