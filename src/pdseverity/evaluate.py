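"""Subject-level leave-one-out evaluation, metrics, baselines, and grids.

Every fold refits the whole symbolic pipeline (standardizer, codebooks,
topic model, optional augmentation, classifier) on the training subjects
only, then predicts the single held-out subject.  Metrics are one-vs-rest
tallies with support-weighted averaging, under which weighted recall equals
accuracy.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, HistGradientBoostingClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from pdseverity.augment import augment_training_set
from pdseverity.bags import BagModel, Standardizer, group_by_subject
from pdseverity.features import WindowFeature, extract_cohort_features
from pdseverity.preprocess import preprocess_recording
from pdseverity.simulate import Cohort

logger = logging.getLogger(__name__)

CLASS_NAMES = {0: "healthy", 1: "mild", 2: "moderate", 3: "severe"}

#: Library-level hyperparameter defaults per algorithm.
CLASSIFIER_DEFAULTS: Dict[str, Dict] = {
    "knn": {"n_neighbors": 5, "weights": "uniform", "metric": "minkowski"},
    "xgb": {"learning_rate": 0.3, "n_estimators": 650, "max_depth": 3},
    "svm": {"kernel": "poly", "C": 1.0},
    "lgbm": {"learning_rate": 0.1, "max_iter": 500, "max_depth": 2},
}


class SingleClassError(ValueError):
    """Raised when a training set contains fewer than two classes."""


@dataclass
class ClassifierConfig:
    """Algorithm choice plus hyperparameters; unknown algorithms rejected.

    The boosted-tree algorithms are realized with scikit-learn's gradient
    boosting machines configured with the stated learning rate, estimator
    count, and depth.
    """

    algorithm: str = "knn"
    seed: int = 0
    params: Dict = field(default_factory=dict)

    def resolved_params(self) -> Dict:
        if self.algorithm not in CLASSIFIER_DEFAULTS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; "
                f"expected one of {sorted(CLASSIFIER_DEFAULTS)}"
            )
        resolved = dict(CLASSIFIER_DEFAULTS[self.algorithm])
        resolved.update(self.params)
        return resolved

    def build(self):
        p = self.resolved_params()
        if self.algorithm == "knn":
            return KNeighborsClassifier(**p)
        if self.algorithm == "svm":
            return SVC(random_state=self.seed, **p)
        if self.algorithm == "xgb":
            return GradientBoostingClassifier(random_state=self.seed, **p)
        if self.algorithm == "lgbm":
            return HistGradientBoostingClassifier(random_state=self.seed, **p)
        raise AssertionError("unreachable")


@dataclass
class AugmentConfig:
    enabled: bool = False
    neighbors_per_subject: int = 1
    policy: str = "balance"
    methods: Tuple[str, ...] = ("mix", "shuffle")
    seed: int = 0


@dataclass
class PipelineConfig:
    """Full configuration of one evaluation run."""

    activities: Tuple[int, ...] = (2, 3, 4, 5)
    k: int = 8
    t: int = 4
    use_lda: bool = True
    counts_norm: str = "raw"
    bag_seed: int = 0
    kmeans_restarts: int = 10
    alpha: Optional[float] = None
    beta: float = 0.01
    filter_low: float = 0.3
    filter_high: float = 20.0
    filter_order: int = 4
    window_samples: int = 300
    overlap: float = 0.5
    correlation_scope: str = "triad"
    min_recording_seconds: float = 0.0
    average: str = "weighted"
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PipelineConfig":
        """Build from a plain mapping (e.g. parsed YAML/JSON config file)."""
        payload = dict(payload)
        if "activities" in payload:
            payload["activities"] = tuple(payload["activities"])
        if "augment" in payload:
            aug = dict(payload["augment"])
            if "methods" in aug:
                aug["methods"] = tuple(aug["methods"])
            payload["augment"] = AugmentConfig(**aug)
        if "classifier" in payload:
            payload["classifier"] = ClassifierConfig(**payload["classifier"])
        return cls(**payload)

    def fingerprint(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class EvaluationReport:
    """Per-fold predictions plus aggregate and per-class metrics."""

    subjects: List[str]
    y_true: List[int]
    y_pred: List[int]
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: Dict[int, Dict[str, float]]
    classes: List[int]
    confusion: List[List[int]]
    config_fingerprint: str = ""
    seeds: Dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["per_class"] = {str(k): v for k, v in payload["per_class"].items()}
        return json.dumps(payload, indent=1)

    def confusion_frame(self) -> pd.DataFrame:
        labels = [CLASS_NAMES.get(c, str(c)) for c in self.classes]
        return pd.DataFrame(self.confusion, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_metrics(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    average: str = "weighted",
) -> Dict:
    """One-vs-rest tallies with support-weighted (or macro) averaging.

    A class that is never predicted gets precision 0 with a warning; with
    weighted averaging the summary recall equals accuracy identically.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if not y_true or len(y_true) != len(y_pred):
        raise ValueError("label sequences must be non-empty and equal length")
    if average not in ("weighted", "macro"):
        raise ValueError(f"average must be 'weighted' or 'macro', got {average!r}")
    classes = sorted(set(y_true) | set(y_pred))
    n = len(y_true)
    accuracy = sum(t == p for t, p in zip(y_true, y_pred)) / n

    per_class: Dict[int, Dict[str, float]] = {}
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        support = tp + fn
        if tp + fp == 0:
            if support > 0:
                warnings.warn(
                    f"class {c} is never predicted; precision set to 0",
                    stacklevel=2,
                )
            precision = 0.0
        else:
            precision = tp / (tp + fp)
        recall = tp / support if support > 0 else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        per_class[c] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support,
        }

    if average == "weighted":
        weights = {c: per_class[c]["support"] / n for c in classes}
    else:
        with_support = [c for c in classes if per_class[c]["support"] > 0]
        weights = {c: (1 / len(with_support) if c in with_support else 0.0)
                   for c in classes}
    summary = {
        metric: sum(weights[c] * per_class[c][metric] for c in classes)
        for metric in ("precision", "recall", "f1")
    }

    index = {c: i for i, c in enumerate(classes)}
    confusion = [[0] * len(classes) for _ in classes]
    for t, p in zip(y_true, y_pred):
        confusion[index[t]][index[p]] += 1

    return {
        "accuracy": accuracy,
        "precision": summary["precision"],
        "recall": summary["recall"],
        "f1": summary["f1"],
        "per_class": per_class,
        "classes": classes,
        "confusion": confusion,
    }


def _report_from_predictions(
    subjects: List[str],
    y_true: List[int],
    y_pred: List[int],
    config: PipelineConfig,
) -> EvaluationReport:
    m = compute_metrics(y_true, y_pred, average=config.average)
    return EvaluationReport(
        subjects=subjects,
        y_true=y_true,
        y_pred=y_pred,
        accuracy=m["accuracy"],
        precision=m["precision"],
        recall=m["recall"],
        f1=m["f1"],
        per_class=m["per_class"],
        classes=m["classes"],
        confusion=m["confusion"],
        config_fingerprint=config.fingerprint(),
        seeds={
            "bag": config.bag_seed,
            "classifier": config.classifier.seed,
            "augment": config.augment.seed,
        },
    )


# ---------------------------------------------------------------------------
# Classifier training
# ---------------------------------------------------------------------------

def train_classifier(config: ClassifierConfig, x: np.ndarray, y: Sequence[int]):
    """Fit the configured classifier; rejects single-class training sets."""
    y = np.asarray(list(y))
    if len(np.unique(y)) < 2:
        raise SingleClassError("training set contains a single class")
    clf = config.build()
    clf.fit(np.asarray(x, dtype=float), y)
    return clf


def predict(model, x: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Cohort -> window features
# ---------------------------------------------------------------------------

def prepare_features(
    cohort: Cohort, config: PipelineConfig
) -> Tuple[List[WindowFeature], Dict[str, int], List[str]]:
    """Preprocess every in-scope recording into window features.

    Returns (features, labels, subjects); subjects with zero windows over
    all in-scope activities are excluded with a warning — mirroring the
    protocol's exclusion of too-short recordings.
    """
    scope = set(config.activities)
    segments = []
    for rec in cohort.recordings:
        if rec.activity_id not in scope:
            continue
        if rec.duration < config.min_recording_seconds:
            logger.warning(
                "skipping %s/%d: %.1f s < minimum %.1f s",
                rec.subject_id, rec.activity_id, rec.duration,
                config.min_recording_seconds,
            )
            continue
        segments.extend(
            preprocess_recording(
                rec,
                low=config.filter_low,
                high=config.filter_high,
                order=config.filter_order,
                window=config.window_samples,
                overlap=config.overlap,
            )
        )
    features = extract_cohort_features(segments, config.correlation_scope)
    labels = cohort.labels
    with_windows = {f.subject_id for f in features}
    subjects = []
    for p in cohort.profiles:
        if p.subject_id in with_windows:
            subjects.append(p.subject_id)
        else:
            warnings.warn(
                f"subject {p.subject_id} has no windows in scope; excluded",
                stacklevel=2,
            )
    return features, labels, subjects


# ---------------------------------------------------------------------------
# Leave-one-out over the full symbolic pipeline
# ---------------------------------------------------------------------------

def fit_fold(
    features: Sequence[WindowFeature],
    labels: Mapping[str, int],
    train_subjects: Sequence[str],
    config: PipelineConfig,
):
    """Fit bag model, optional augmentation, and classifier on one fold.

    Returns (bag_model, classifier, audit_log)."""
    bag_model = BagModel(
        k=config.k,
        t=config.t,
        seed=config.bag_seed,
        use_lda=config.use_lda,
        counts_norm=config.counts_norm,
        alpha=config.alpha,
        beta=config.beta,
        kmeans_restarts=config.kmeans_restarts,
    ).fit(features, labels, train_subjects)

    train_set = set(train_subjects)
    grouped = group_by_subject([f for f in features if f.subject_id in train_set])
    documents = [
        bag_model.document(grouped[s], label=labels[s]) for s in sorted(grouped)
    ]
    audit: List[dict] = []
    if config.augment.enabled:
        documents, audit = augment_training_set(
            documents,
            seed=config.augment.seed,
            policy=config.augment.policy,
            methods=config.augment.methods,
            neighbors_per_subject=config.augment.neighbors_per_subject,
        )
    vectors = [bag_model.vector_from_document(d) for d in documents]
    x = np.stack([v.fused for v in vectors])
    y = [v.label for v in vectors]
    clf = train_classifier(config.classifier, x, y)
    return bag_model, clf, audit


def loocv(
    cohort: Cohort,
    config: Optional[PipelineConfig] = None,
    labels: Optional[Mapping[str, int]] = None,
) -> EvaluationReport:
    """Subject-level leave-one-out CV of the full symbolic pipeline.

    ``labels`` overrides the cohort's subject labels (e.g. for
    permutation-null experiments)."""
    config = config or PipelineConfig()
    features, cohort_labels, subjects = prepare_features(cohort, config)
    labels = dict(labels) if labels is not None else cohort_labels
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects with windows for LOOCV")
    if len({labels[s] for s in subjects}) < 2:
        raise SingleClassError("cohort has a single class; LOOCV is meaningless")
    grouped = group_by_subject(features)

    y_true: List[int] = []
    y_pred: List[int] = []
    for held_out in subjects:
        t0 = time.perf_counter()
        train_subjects = [s for s in subjects if s != held_out]
        bag_model, clf, _ = fit_fold(features, labels, train_subjects, config)
        bag = bag_model.vector_from_document(
            bag_model.document(grouped[held_out], label=labels[held_out])
        )
        pred = int(predict(clf, bag.fused[None])[0])
        y_true.append(labels[held_out])
        y_pred.append(pred)
        logger.debug(
            "fold %s: true=%d pred=%d (%.2f s)",
            held_out, labels[held_out], pred, time.perf_counter() - t0,
        )
    return _report_from_predictions(subjects, y_true, y_pred, config)


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def _loocv_fixed_vectors(
    subjects: List[str],
    vectors: Dict[str, np.ndarray],
    labels: Mapping[str, int],
    config: PipelineConfig,
) -> EvaluationReport:
    """LOOCV over precomputed per-subject vectors (standardized per fold)."""
    y_true: List[int] = []
    y_pred: List[int] = []
    for held_out in subjects:
        train = [s for s in subjects if s != held_out]
        x_train = np.stack([vectors[s] for s in train])
        std = Standardizer.fit(x_train)
        clf = train_classifier(
            config.classifier, std.transform(x_train), [labels[s] for s in train]
        )
        pred = int(predict(clf, std.transform(vectors[held_out][None]))[0])
        y_true.append(labels[held_out])
        y_pred.append(pred)
    return _report_from_predictions(subjects, y_true, y_pred, config)


def majority_vote(window_predictions: Sequence[int]) -> int:
    """Most frequent predicted class; ties go to the lowest class id."""
    votes = np.bincount(np.asarray(window_predictions, dtype=int))
    return int(np.argmax(votes))


def instance_baseline(
    cohort: Cohort, config: Optional[PipelineConfig] = None
) -> EvaluationReport:
    """Propagate the bag label to every window; majority vote per subject.

    Ties in the vote go to the lowest class id."""
    config = config or PipelineConfig()
    features, labels, subjects = prepare_features(cohort, config)
    grouped = group_by_subject(features)

    y_true: List[int] = []
    y_pred: List[int] = []
    for held_out in subjects:
        train = [s for s in subjects if s != held_out]
        x_train = np.stack(
            [f.vector for s in train for f in grouped[s]]
        )
        y_train = [labels[s] for s in train for _ in grouped[s]]
        std = Standardizer.fit(x_train)
        clf = train_classifier(config.classifier, std.transform(x_train), y_train)
        window_preds = predict(
            clf, std.transform(np.stack([f.vector for f in grouped[held_out]]))
        )
        y_true.append(labels[held_out])
        y_pred.append(majority_vote(window_preds))
    return _report_from_predictions(subjects, y_true, y_pred, config)


def simplemi_baseline(
    cohort: Cohort,
    aggregation: str = "mean",
    config: Optional[PipelineConfig] = None,
) -> EvaluationReport:
    """Bag = elementwise mean / median / min||max over window features."""
    config = config or PipelineConfig()
    if aggregation not in ("mean", "median", "minmax"):
        raise ValueError(
            f"aggregation must be 'mean', 'median' or 'minmax', got {aggregation!r}"
        )
    features, labels, subjects = prepare_features(cohort, config)
    grouped = group_by_subject(features)

    vectors: Dict[str, np.ndarray] = {}
    for s in subjects:
        stack = np.stack([f.vector for f in grouped[s]])
        if aggregation == "mean":
            vectors[s] = stack.mean(axis=0)
        elif aggregation == "median":
            vectors[s] = np.median(stack, axis=0)
        else:
            vectors[s] = np.concatenate([stack.min(axis=0), stack.max(axis=0)])
    return _loocv_fixed_vectors(subjects, vectors, labels, config)


# ---------------------------------------------------------------------------
# Hyperparameter grid
# ---------------------------------------------------------------------------

DEFAULT_K_GRID = tuple(range(4, 18))
DEFAULT_T_GRID = tuple(range(4, 11))


def grid_search(
    cohort: Cohort,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    t_grid: Sequence[int] = DEFAULT_T_GRID,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Full Cartesian (k, t) sweep; each cell is a complete LOOCV run.

    Returns a frame with columns k, t, accuracy, f1, sorted by f1
    descending (ties by k then t)."""
    if not k_grid or not t_grid:
        raise ValueError("grids must be non-empty")
    config = config or PipelineConfig()
    rows = []
    for k in k_grid:
        for t in t_grid:
            cell = dataclasses.replace(config, k=k, t=t)
            report = loocv(cohort, cell)
            rows.append(
                {"k": k, "t": t, "accuracy": report.accuracy, "f1": report.f1}
            )
            logger.info(
                "grid cell k=%d t=%d: acc=%.3f f1=%.3f",
                k, t, report.accuracy, report.f1,
            )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["f1", "k", "t"], ascending=[False, True, True]
    ).reset_index(drop=True)
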