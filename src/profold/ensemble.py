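"""Multi-view ensemble classification with per-view model selection.

The ensemble treats each feature group (DSSP, AAsCPP, PSSM, FunD) as an
independent view. Training proceeds in five steps:

1. for each view, evaluate every classifier in a roster by stratified
   k-fold cross-validation (default k = 5), pooling out-of-fold accuracy;
2. select, per view, the classifier with the highest cross-validated
   accuracy (ties broken by roster order);
3. refit the selected classifier on the full training matrix of its view;
4. at prediction time, obtain each view model's class-probability row
   P_ij for a query;
5. average the probabilities across views, q_j = (1/G) * sum_i P_ij, and
   predict the class with the highest average (ties broken by lowest class
   index).

The default roster approximates a set of ten classical learning algorithms
(logistic model trees, random forests, kernel and linear SVMs, logistic
regression, rotation-forest-style randomized tree ensembles, naive Bayes,
single randomized trees, functional trees, CART) with scikit-learn
estimators. It is an approximation by design: the roster is
configuration-driven and any estimator exposing ``fit``/``predict_proba``
can be slotted in.

Evaluation uses the standard overall accuracy Q = C/N together with
per-class accuracies c_i/n_i, where n_i and c_i are the per-class test and
correct counts.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .formats_io import FeatureGroupMatrix

__all__ = [
    "ClassifierSpec",
    "CvReport",
    "TrainedEnsemble",
    "EvaluationResult",
    "default_roster",
    "fast_roster",
    "roster_from_config",
    "select_classifier",
    "cross_validate_roster",
    "train_ensemble",
    "predict",
    "q_accuracy",
    "save_ensemble",
    "load_ensemble",
]

logger = logging.getLogger(__name__)

_BUNDLE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ClassifierSpec:
    """One roster member: a name plus a factory for fresh estimators.

    ``factory(seed)`` must return an unfitted scikit-learn-compatible
    estimator exposing ``fit`` and ``predict_proba`` (rows summing to 1
    over ``classes_``).
    """

    name: str
    factory: Callable[[int], BaseEstimator]

    def build(self, seed: int) -> BaseEstimator:
        return self.factory(seed)


def _seeded(cls, **params):
    def factory(seed: int) -> BaseEstimator:
        if "random_state" in cls().get_params():
            params.setdefault("random_state", None)
            p = dict(params)
            p["random_state"] = seed
            return cls(**p)
        return cls(**params)

    return factory


#: scikit-learn estimator registry for configuration-driven rosters.
ESTIMATOR_REGISTRY: dict[str, type[BaseEstimator]] = {
    "GradientBoostingClassifier": GradientBoostingClassifier,
    "HistGradientBoostingClassifier": HistGradientBoostingClassifier,
    "RandomForestClassifier": RandomForestClassifier,
    "ExtraTreesClassifier": ExtraTreesClassifier,
    "LogisticRegression": LogisticRegression,
    "SVC": SVC,
    "GaussianNB": GaussianNB,
    "DecisionTreeClassifier": DecisionTreeClassifier,
}


def default_roster() -> list[ClassifierSpec]:
    """Ten-member roster approximating the classical algorithm set.

    Mapping (classical name -> estimator used here):

    * LMT (logistic model tree) -> gradient boosting with log-loss
      (stagewise additive logistic trees)
    * RandomForest -> RandomForestClassifier
    * LibSVM -> RBF-kernel SVC with Platt-calibrated probabilities
    * SimpleLogistic -> LogisticRegression
    * RotationForest -> ExtraTreesClassifier (randomized tree ensemble)
    * SMO -> linear-kernel SVC with Platt-calibrated probabilities
    * NaiveBayes -> GaussianNB
    * RandomTree -> single DecisionTree with random feature subsets
    * FT (functional tree) -> histogram gradient boosting
    * SimpleCart -> DecisionTreeClassifier (CART)
    """
    return [
        ClassifierSpec("LMT", _seeded(GradientBoostingClassifier, n_estimators=50)),
        ClassifierSpec("RandomForest", _seeded(RandomForestClassifier, n_estimators=100)),
        ClassifierSpec("LibSVM", _seeded(SVC, kernel="rbf", probability=True)),
        ClassifierSpec("SimpleLogistic", _seeded(LogisticRegression, max_iter=1000)),
        ClassifierSpec("RotationForest", _seeded(ExtraTreesClassifier, n_estimators=100)),
        ClassifierSpec("SMO", _seeded(SVC, kernel="linear", probability=True)),
        ClassifierSpec("NaiveBayes", _seeded(GaussianNB)),
        ClassifierSpec("RandomTree", _seeded(DecisionTreeClassifier, max_features="sqrt")),
        ClassifierSpec("FT", _seeded(HistGradientBoostingClassifier, max_iter=50)),
        ClassifierSpec("SimpleCart", _seeded(DecisionTreeClassifier)),
    ]


def fast_roster() -> list[ClassifierSpec]:
    """A small, quick roster for smoke runs and examples."""
    return [
        ClassifierSpec("SimpleLogistic", _seeded(LogisticRegression, max_iter=1000)),
        ClassifierSpec("RandomForest", _seeded(RandomForestClassifier, n_estimators=50)),
        ClassifierSpec("NaiveBayes", _seeded(GaussianNB)),
    ]


def roster_from_config(config: Sequence[Mapping]) -> list[ClassifierSpec]:
    """Build a roster from ``[{name, estimator, params}, ...]`` entries."""
    roster: list[ClassifierSpec] = []
    for entry in config:
        est_name = entry["estimator"]
        if est_name not in ESTIMATOR_REGISTRY:
            raise ValueError(
                f"unknown estimator {est_name!r}; known: {sorted(ESTIMATOR_REGISTRY)}"
            )
        cls = ESTIMATOR_REGISTRY[est_name]
        params = dict(entry.get("params", {}))
        roster.append(ClassifierSpec(entry["name"], _seeded(cls, **params)))
    if not roster:
        raise ValueError("roster configuration is empty")
    return roster


# ---------------------------------------------------------------------------
# Cross-validated per-view selection
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Cross-validation accuracies of every roster member on one view."""

    group_name: str
    entries: list[tuple[str, float]]
    selected: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=["classifier", "cv_accuracy"])
        df.insert(0, "feature_group", self.group_name)
        df["selected"] = df["classifier"] == self.selected
        return df


def select_classifier(entries: Sequence[tuple[str, float]]) -> str:
    """Winner of a CV report: highest accuracy, ties to earliest entry."""
    if not entries:
        raise ValueError("cannot select from an empty report")
    best_name, best_acc = entries[0]
    for name, acc in entries[1:]:
        if acc > best_acc:
            best_name, best_acc = name, acc
    return best_name


def _validate_labels(labels: Sequence[str], n: int) -> np.ndarray:
    y = np.asarray(labels, dtype=object)
    if len(y) != n:
        raise ValueError(f"{len(y)} labels for {n} samples")
    if len(np.unique(y)) < 2:
        raise ValueError("at least two classes are required")
    return y


def _effective_folds(y: np.ndarray, k_folds: int, group_name: str) -> int:
    _, counts = np.unique(y, return_counts=True)
    min_class = int(counts.min())
    if min_class < 2:
        raise ValueError(
            f"{group_name}: smallest class has {min_class} member(s); "
            "at least 2 per class are required for cross-validation"
        )
    k = min(k_folds, min_class)
    if k < k_folds:
        warnings.warn(
            f"{group_name}: smallest class has {min_class} members; "
            f"reducing folds from {k_folds} to {k}",
            stacklevel=2,
        )
    return k


def cross_validate_roster(
    features: FeatureGroupMatrix,
    labels: Sequence[str],
    roster: Sequence[ClassifierSpec],
    k_folds: int = 5,
    seed: int = 0,
) -> CvReport:
    """Pooled out-of-fold accuracy of every roster member on one view.

    All members are evaluated on the same stratified, seeded split; the
    reported accuracy is pooled over folds (total correct / total samples).
    The selected member attains the maximum accuracy, ties broken by roster
    order.
    """
    if not roster:
        raise ValueError("roster must be nonempty")
    y = _validate_labels(labels, features.n_samples)
    X = features.values
    k = _effective_folds(y, k_folds, features.group_name)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    entries: list[tuple[str, float]] = []
    for spec in roster:
        correct = 0
        for train_idx, test_idx in splits:
            model = spec.build(seed)
            model.fit(X[train_idx], y[train_idx])
            pred = model.predict(X[test_idx])
            correct += int(np.sum(pred == y[test_idx]))
        entries.append((spec.name, correct / len(y)))
    report = CvReport(
        group_name=features.group_name,
        entries=entries,
        selected=select_classifier(entries),
    )
    logger.info(
        "%s: selected %s (cv accuracy %.3f)",
        report.group_name,
        report.selected,
        dict(entries)[report.selected],
    )
    return report


# ---------------------------------------------------------------------------
# Ensemble training and prediction
# ---------------------------------------------------------------------------

@dataclass
class TrainedEnsemble:
    """Per-view fitted models sharing one class ordering."""

    class_labels: list[str]
    per_group: dict[str, tuple[str, BaseEstimator]]
    cv_reports: dict[str, CvReport] = field(default_factory=dict)
    feature_columns: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    @property
    def groups_used(self) -> list[str]:
        return list(self.per_group)


def _check_aligned(feature_groups: Mapping[str, FeatureGroupMatrix]) -> list[str]:
    groups = list(feature_groups)
    if not groups:
        raise ValueError("at least one feature group is required")
    ref = feature_groups[groups[0]].sample_ids
    for g in groups[1:]:
        if feature_groups[g].sample_ids != ref:
            raise ValueError(f"sample ids of group {g!r} do not match group {groups[0]!r}")
    return groups


def train_ensemble(
    feature_groups: Mapping[str, FeatureGroupMatrix],
    labels: Sequence[str],
    roster: Sequence[ClassifierSpec] | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> TrainedEnsemble:
    """Select (by CV) and fit one classifier per feature group.

    All groups must share identical sample ids in identical order, aligned
    with ``labels``.
    """
    roster = list(roster) if roster is not None else default_roster()
    groups = _check_aligned(feature_groups)
    n = feature_groups[groups[0]].n_samples
    y = _validate_labels(labels, n)
    class_labels = sorted(np.unique(y).tolist())

    per_group: dict[str, tuple[str, BaseEstimator]] = {}
    cv_reports: dict[str, CvReport] = {}
    feature_columns: dict[str, list[str]] = {}
    for g in groups:
        fm = feature_groups[g]
        report = cross_validate_roster(fm, y, roster, k_folds=k_folds, seed=seed)
        spec = next(s for s in roster if s.name == report.selected)
        model = spec.build(seed)
        model.fit(fm.values, y)
        per_group[g] = (spec.name, model)
        cv_reports[g] = report
        feature_columns[g] = list(fm.column_names)
    return TrainedEnsemble(
        class_labels=class_labels,
        per_group=per_group,
        cv_reports=cv_reports,
        feature_columns=feature_columns,
        seed=seed,
    )


def _aligned_proba(
    model: BaseEstimator, X: np.ndarray, class_labels: list[str]
) -> np.ndarray:
    """predict_proba reindexed onto the ensemble class ordering."""
    raw = model.predict_proba(X)
    order = {str(c): j for j, c in enumerate(model.classes_)}
    out = np.zeros((raw.shape[0], len(class_labels)))
    for j, label in enumerate(class_labels):
        if str(label) in order:
            out[:, j] = raw[:, order[str(label)]]
    return out


def predict(
    ensemble: TrainedEnsemble,
    feature_groups: Mapping[str, FeatureGroupMatrix],
    allow_missing_groups: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Average per-view class probabilities and take the argmax.

    Returns ``(predicted_labels, averaged_probabilities)`` where the
    probability matrix is n x k over ``ensemble.class_labels``. By default
    every trained view must be supplied; ``allow_missing_groups=True``
    averages over the subset present (divisor = number of views present).
    """
    present = [g for g in ensemble.groups_used if g in feature_groups]
    missing = [g for g in ensemble.groups_used if g not in feature_groups]
    if missing and not allow_missing_groups:
        raise ValueError(f"missing feature group(s) at prediction: {missing}")
    if not present:
        raise ValueError("no trained feature group present in the input")
    _check_aligned({g: feature_groups[g] for g in present})

    total: np.ndarray | None = None
    for g in present:
        fm = feature_groups[g]
        expected = ensemble.feature_columns.get(g)
        if expected is not None and list(fm.column_names) != expected:
            raise ValueError(
                f"group {g!r}: feature columns differ from training "
                f"({len(fm.column_names)} vs {len(expected)})"
            )
        _, model = ensemble.per_group[g]
        proba = _aligned_proba(model, fm.values, ensemble.class_labels)
        total = proba if total is None else total + proba
    avg = total / len(present)
    # np.argmax returns the first maximum: ties go to the lowest class index.
    idx = np.argmax(avg, axis=1)
    labels = [ensemble.class_labels[i] for i in idx]
    return labels, avg


# ---------------------------------------------------------------------------
# Q accuracy
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Per-class and overall classification accuracy (Q = C/N)."""

    class_labels: list[str]
    n: np.ndarray
    c: np.ndarray
    N: int
    C: int
    Q: float

    @property
    def k(self) -> int:
        return len(self.class_labels)

    @property
    def per_class_accuracy(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n > 0, self.c / np.maximum(self.n, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold_class": self.class_labels,
                "n_test": self.n,
                "n_correct": self.c,
                "accuracy": self.per_class_accuracy,
            }
        )


def q_accuracy(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    class_labels: Sequence[str] | None = None,
) -> EvaluationResult:
    """Overall accuracy Q = C/N with per-class counts n_i, c_i.

    ``class_labels`` fixes the class ordering of the report; it defaults to
    the sorted labels occurring in ``y_true``. Every label in both vectors
    must be a known class.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if not y_true:
        raise ValueError("at least one sample is required")
    if class_labels is None:
        class_labels = sorted(set(y_true))
    class_labels = list(class_labels)
    known = set(class_labels)
    unknown = (set(y_true) | set(y_pred)) - known
    if unknown:
        raise ValueError(f"labels outside class_labels: {sorted(unknown)}")

    index = {c: i for i, c in enumerate(class_labels)}
    n = np.zeros(len(class_labels), dtype=int)
    c = np.zeros(len(class_labels), dtype=int)
    for t, p in zip(y_true, y_pred):
        n[index[t]] += 1
        if t == p:
            c[index[t]] += 1
    N = int(n.sum())
    C = int(c.sum())
    return EvaluationResult(
        class_labels=class_labels, n=n, c=c, N=N, C=C, Q=C / N
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: TrainedEnsemble, directory: str | Path) -> None:
    """Persist a trained ensemble as a manifest + one model file per view."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": _BUNDLE_FORMAT_VERSION,
        "class_labels": ensemble.class_labels,
        "seed": ensemble.seed,
        "probability_normalization": "native predict_proba",
        "groups": [
            {
                "group": g,
                "classifier": name,
                "model_file": f"model_{g}.joblib",
                "n_features": len(ensemble.feature_columns.get(g, [])),
            }
            for g, (name, _) in ensemble.per_group.items()
        ],
        "feature_columns": ensemble.feature_columns,
        "cv_reports": {
            g: {"entries": r.entries, "selected": r.selected}
            for g, r in ensemble.cv_reports.items()
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    for g, (_, model) in ensemble.per_group.items():
        joblib.dump(model, directory / f"model_{g}.joblib")


def load_ensemble(directory: str | Path) -> TrainedEnsemble:
    """Load a bundle written by :func:`save_ensemble`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if manifest.get("format_version") != _BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"bundle format version {manifest.get('format_version')} "
            f"not supported (expected {_BUNDLE_FORMAT_VERSION})"
        )
    per_group: dict[str, tuple[str, BaseEstimator]] = {}
    for entry in manifest["groups"]:
        model_path = directory / entry["model_file"]
        if not model_path.exists():
            raise FileNotFoundError(
                f"model file for group {entry['group']!r} missing: {model_path}"
            )
        per_group[entry["group"]] = (entry["classifier"], joblib.load(model_path))
    cv_reports = {
        g: CvReport(
            group_name=g,
            entries=[(n, a) for n, a in r["entries"]],
            selected=r["selected"],
        )
        for g, r in manifest.get("cv_reports", {}).items()
    }
    return TrainedEnsemble(
        class_labels=list(manifest["class_labels"]),
        per_group=per_group,
        cv_reports=cv_reports,
        feature_columns={
            g: list(cols) for g, cols in manifest.get("feature_columns", {}).items()
        },
        seed=int(manifest.get("seed", 0)),
    )
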