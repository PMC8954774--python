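"""Closed-set identification (one-to-many).

Two methodologies:

* classifier — LDA / kNN / decision tree / SVM trained on individual
  session-1 cardiac cycles (600 features each, label = subject); session-2
  cycles are classified one by one and a subject's predicted identity is the
  majority vote over their test cycles.  Configurations 20/20 and 60/60 name
  the per-subject template counts used for train/test.
* distance — Manhattan 1-NN over concatenated (and typically ICA-reduced)
  subject feature rows; Configuration 1/1 decides from one test template,
  Configuration 1/3 requires at least two of three test templates to hit the
  right training row.

Metrics are reported at subject level: accuracy plus support-weighted
one-vs-rest precision, recall and F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .preprocess import CycleTemplateSet
from .synthetic import ConfigurationError
from .templates import SubjectFeatureMatrix

log = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("lda", "knn", "dt", "svm")


@dataclass(frozen=True)
class IdentConfig:
    """Identification run settings.

    ``configuration`` is "20/20" or "60/60" for the classifier methodology
    (k templates per subject in each session) and "1/1" or "1/3" for the
    distance methodology (test templates per subject).
    """

    methodology: str = "classifier"      # classifier | distance | cnn
    classifier: str = "lda"
    configuration: str = "60/60"
    normalized: bool = True
    knn_k: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.methodology in ("classifier", "cnn"):
            if self.configuration not in ("20/20", "60/60"):
                raise ConfigurationError(
                    f"configuration {self.configuration!r} invalid for {self.methodology}"
                )
            if self.methodology == "classifier" and self.classifier not in CLASSIFIER_KINDS:
                raise ConfigurationError(f"unknown classifier {self.classifier!r}")
        elif self.methodology == "distance":
            if self.configuration not in ("1/1", "1/3"):
                raise ConfigurationError(
                    f"configuration {self.configuration!r} invalid for distance"
                )
        else:
            raise ConfigurationError(f"unknown methodology {self.methodology!r}")

    @property
    def k(self) -> int:
        return int(self.configuration.split("/")[0])


@dataclass
class IdentReport:
    """Subject-level identification outcome."""

    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    confusion: np.ndarray
    subject_ids: list[str]
    correct: dict[str, bool]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "subject_ids": self.subject_ids,
            "correct": self.correct,
            "confusion": self.confusion.tolist(),
        }


def compute_ident_metrics(confusion: np.ndarray,
                          subject_ids: list[str] | None = None) -> IdentReport:
    """Accuracy and support-weighted precision/recall/F1 from a confusion
    matrix (rows: true subject, columns: predicted)."""
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ConfigurationError("confusion matrix must be square")
    if np.any(c < 0):
        raise ConfigurationError("confusion matrix must be nonnegative")
    n = c.shape[0]
    if subject_ids is None:
        subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    total = c.sum()
    tp = np.diag(c)
    support = c.sum(axis=1)
    pred_tot = c.sum(axis=0)

    def safe_div(num, den, what):
        out = np.zeros_like(num)
        nz = den > 0
        out[nz] = num[nz] / den[nz]
        if np.any(~nz & (num > 0)) or np.any(~nz):
            log.warning("zero division in %s set to 0", what)
        return out

    precision = safe_div(tp, pred_tot, "precision")
    recall = safe_div(tp, support, "recall")
    f1 = safe_div(2 * precision * recall, precision + recall, "f1")
    w = support / total if total > 0 else np.full(n, 1.0 / n)
    correct = {sid: bool(c[i, i] == support[i] and support[i] > 0)
               for i, sid in enumerate(subject_ids)}
    return IdentReport(
        accuracy=float(tp.sum() / total) if total > 0 else 0.0,
        weighted_precision=float(w @ precision),
        weighted_recall=float(w @ recall),
        weighted_f1=float(w @ f1),
        confusion=c.astype(int),
        subject_ids=list(subject_ids),
        correct=correct,
    )


def _make_classifier(cfg: IdentConfig):
    if cfg.classifier == "lda":
        return LinearDiscriminantAnalysis(solver="svd")
    if cfg.classifier == "knn":
        return KNeighborsClassifier(n_neighbors=cfg.knn_k, metric="euclidean")
    if cfg.classifier == "dt":
        return DecisionTreeClassifier(criterion="gini", random_state=cfg.seed)
    if cfg.classifier == "svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale", decision_function_shape="ovr")
    raise ConfigurationError(f"unknown classifier {cfg.classifier!r}")


def _majority_vote(labels: np.ndarray, scores: np.ndarray | None,
                   classes: np.ndarray) -> str:
    """Subject vote over per-cycle predictions.  Ties break by the higher
    summed confidence, then lexicographically."""
    uniq, counts = np.unique(labels, return_counts=True)
    top = uniq[counts == counts.max()]
    if top.size == 1:
        return str(top[0])
    if scores is not None:
        conf = {}
        for lab in top:
            j = int(np.where(classes == lab)[0][0])
            conf[str(lab)] = float(scores[:, j].sum())
        best = max(conf.values())
        top = np.array(sorted(lab for lab in conf if conf[lab] == best))
    return str(sorted(top)[0])


def identify_with_classifier(
    train_sets: dict[str, CycleTemplateSet],
    test_sets: dict[str, CycleTemplateSet],
    cfg: IdentConfig,
) -> IdentReport:
    """Train on session-1 cycles, classify session-2 cycles, vote per subject.

    The session firewall is structural: only ``train_sets`` (session-1
    objects) reach the fit.
    """
    cfg.validate()
    if set(train_sets) != set(test_sets):
        raise ConfigurationError("train and test subject sets differ")
    subjects = sorted(train_sets)
    k = cfg.k
    for sid in subjects:
        if train_sets[sid].k != k or test_sets[sid].k != k:
            raise ConfigurationError(
                f"configuration {cfg.configuration} expects {k} cycles per subject"
            )

    Xtr = np.concatenate([train_sets[sid].as_matrix() for sid in subjects])
    ytr = np.repeat(subjects, k)
    clf = _make_classifier(cfg)
    clf.fit(Xtr, ytr)

    idx = {sid: i for i, sid in enumerate(subjects)}
    confusion = np.zeros((len(subjects), len(subjects)), dtype=int)
    for sid in subjects:
        Xte = test_sets[sid].as_matrix()
        pred = clf.predict(Xte)
        scores = None
        if hasattr(clf, "predict_proba"):
            try:
                scores = clf.predict_proba(Xte)
            except AttributeError:
                scores = None
        elif hasattr(clf, "decision_function"):
            scores = clf.decision_function(Xte)
        winner = _majority_vote(np.asarray(pred), scores, clf.classes_)
        confusion[idx[sid], idx[winner]] += 1
    return compute_ident_metrics(confusion, subjects)


def manhattan_argmin(train_values: np.ndarray, test_row: np.ndarray) -> int:
    """Index of the training row nearest (L1) to one test row; ties break to
    the earlier row."""
    d = np.abs(train_values - test_row[None, :]).sum(axis=1)
    return int(np.argmin(d))


def identify_with_distance(
    train: SubjectFeatureMatrix,
    test: SubjectFeatureMatrix | list[SubjectFeatureMatrix],
    cfg: IdentConfig,
) -> IdentReport:
    """Manhattan 1-NN identification over subject feature rows."""
    cfg.validate()
    tests = [test] if isinstance(test, SubjectFeatureMatrix) else list(test)
    if cfg.configuration == "1/3" and len(tests) != 3:
        raise ConfigurationError("Configuration 1/3 requires three test matrices")
    if cfg.configuration == "1/1" and len(tests) != 1:
        raise ConfigurationError("Configuration 1/1 requires one test matrix")
    for tm in tests:
        if tm.subject_ids != train.subject_ids:
            raise ConfigurationError("train/test subject order mismatch")
        if tm.n_features != train.n_features:
            raise ConfigurationError("train/test feature length mismatch")

    subjects = train.subject_ids
    n = len(subjects)
    confusion = np.zeros((n, n), dtype=int)
    correct_needed = 2 if cfg.configuration == "1/3" else 1
    for i, sid in enumerate(subjects):
        hits = [manhattan_argmin(train.values, tm.values[i]) for tm in tests]
        n_self = sum(h == i for h in hits)
        if n_self >= correct_needed:
            confusion[i, i] += 1
        else:
            # attribute the miss to the modal wrong identity
            wrong = [h for h in hits if h != i]
            vals, cnts = np.unique(wrong, return_counts=True)
            confusion[i, int(vals[np.argmax(cnts)])] += 1
    return compute_ident_metrics(confusion, subjects)


class CNNBackendUnavailableError(RuntimeError):
    """The optional convolutional classifier needs a deep-learning backend."""


def identify_with_cnn(train_images, test_images, cfg: IdentConfig, backend=None):
    """Optional convolutional-classifier identification.

    The convolutional methodology is a pluggable component: pass ``backend``,
    a callable ``backend(train_images, train_labels, test_images, seed) ->
    predicted labels``, to supply an implementation.  Without one this raises
    a clear availability error rather than silently degrading.
    """
    cfg.validate()
    if backend is None:
        raise CNNBackendUnavailableError(
            "convolutional identification requires a user-supplied backend; "
            "none is configured"
        )
    subjects = sorted(train_images)
    labels = np.repeat(subjects, [len(train_images[s]) for s in subjects])
    flat_train = [img for s in subjects for img in train_images[s]]
    idx = {sid: i for i, sid in enumerate(subjects)}
    confusion = np.zeros((len(subjects), len(subjects)), dtype=int)
    for sid in subjects:
        pred = np.asarray(backend(flat_train, labels, test_images[sid], cfg.seed))
        winner = _majority_vote(pred, None, np.asarray(subjects))
        confusion[idx[sid], idx[winner]] += 1
    return compute_ident_metrics(confusion, subjects)
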