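"""One-to-one authentication with per-subject distance thresholds.

A subject's threshold is T_i = mu_i - sigma_i, where mu_i and sigma_i are
the mean and standard deviation of the Manhattan distances between that
subject's test template(s) and the training templates of the whole cohort.
A claim is accepted when the subject's self-distance does not exceed T_i
(Configuration 1/3: at least two of three self-distances).  Impostor
resistance is evaluated leave-one-out: each subject in turn is held out, its
threshold is recomputed from distances to the remaining cohort, and every
other subject falling under that threshold counts as an impostor.

Tie conventions: genuine authentication uses <= ("does not exceed") while
impostor flagging uses strict < ("below the threshold"), so distance ties
resolve pro-genuine and anti-impostor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic import ConfigurationError
from .templates import SubjectFeatureMatrix

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Manhattan distances, shape (n_train, n_test, multiplicity)."""

    values: np.ndarray
    train_ids: list[str]
    test_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 2:
            v = v[:, :, None]
        if v.shape[0] != len(self.train_ids) or v.shape[1] != len(self.test_ids):
            raise ConfigurationError("distance matrix shape does not match id lists")
        if np.any(v < 0):
            raise ConfigurationError("distances must be nonnegative")
        self.values = v

    @property
    def multiplicity(self) -> int:
        return self.values.shape[2]


@dataclass
class AuthThresholds:
    """Per-subject pool statistics and thresholds T_i = mu_i - sigma_i."""

    subject_ids: list[str]
    mu: np.ndarray
    sigma: np.ndarray

    @property
    def t(self) -> np.ndarray:
        return self.mu - self.sigma


@dataclass
class AuthReport:
    """Authentication outcome: accept/reject per subject plus cohort metrics.

    ``impostor_score`` is the mean over subjects of the impostor count as a
    percentage of the n-1 possible impostors per subject.
    """

    configuration: str
    authenticated: dict[str, bool]
    accuracy: float
    impostor_counts: dict[str, int] = field(default_factory=dict)
    impostors: dict[str, list[str]] = field(default_factory=dict)
    impostor_score: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "configuration": self.configuration,
            "accuracy": self.accuracy,
            "impostor_score": self.impostor_score,
            "authenticated": self.authenticated,
            "impostor_counts": self.impostor_counts,
            "impostors": self.impostors,
        }


def manhattan_distance_matrix(
    train: SubjectFeatureMatrix,
    test: SubjectFeatureMatrix | list[SubjectFeatureMatrix],
) -> DistanceMatrix:
    """All pairwise L1 distances between training rows and test template(s)."""
    tests = [test] if isinstance(test, SubjectFeatureMatrix) else list(test)
    for tm in tests:
        if tm.n_features != train.n_features:
            raise ConfigurationError("train/test feature length mismatch")
        if tm.subject_ids != train.subject_ids:
            raise ConfigurationError("train/test subject universe mismatch")
    stacks = []
    for tm in tests:
        d = np.abs(train.values[:, None, :] - tm.values[None, :, :]).sum(axis=2)
        stacks.append(d)
    return DistanceMatrix(np.stack(stacks, axis=2), list(train.subject_ids),
                          list(train.subject_ids))


def _pool_stats(pool: np.ndarray, population_sd: bool) -> tuple[float, float]:
    mu = float(np.mean(pool))
    sigma = float(np.std(pool, ddof=0 if population_sd else 1))
    return mu, sigma


def compute_thresholds(d: DistanceMatrix, population_sd: bool = True,
                       include_self: bool = True) -> AuthThresholds:
    """T_i from subject i's distance pool: i's test template(s) against all
    training templates (population sd by default; both conventions are
    switchable)."""
    n = len(d.train_ids)
    if n < 2:
        raise ConfigurationError("need at least 2 training subjects for a threshold")
    mu = np.empty(n)
    sigma = np.empty(n)
    for i in range(n):
        pool = d.values[:, i, :]
        if not include_self:
            pool = np.delete(pool, i, axis=0)
        mu[i], sigma[i] = _pool_stats(pool.ravel(), population_sd)
    return AuthThresholds(list(d.test_ids), mu, sigma)


def authenticate_subjects(d: DistanceMatrix, thresholds: AuthThresholds,
                          configuration: str = "1/1") -> AuthReport:
    """Accept subject i iff the self-distance(s) D[i,i] satisfy the rule:
    1/1 — D[i,i] <= T_i; 1/3 — at least 2 of 3 self-distances <= T_i."""
    if configuration not in ("1/1", "1/3"):
        raise ConfigurationError(f"unknown configuration {configuration!r}")
    if configuration == "1/3" and d.multiplicity != 3:
        raise ConfigurationError("Configuration 1/3 needs multiplicity-3 distances")
    if thresholds.subject_ids != d.test_ids:
        raise ConfigurationError("thresholds not aligned with distance matrix")
    need = 2 if configuration == "1/3" else 1
    t = thresholds.t
    decisions = {}
    for i, sid in enumerate(d.test_ids):
        selfd = d.values[i, i, :]
        decisions[sid] = bool(np.sum(selfd <= t[i]) >= need)
    acc = sum(decisions.values()) / len(decisions)
    return AuthReport(configuration=configuration, authenticated=decisions,
                      accuracy=float(acc))


def loo_impostor_evaluation(
    train: SubjectFeatureMatrix,
    test: SubjectFeatureMatrix | list[SubjectFeatureMatrix],
    configuration: str = "1/1",
    population_sd: bool = True,
) -> AuthReport:
    """Leave-one-out impostor count.

    For each held-out subject i: pool = distances from i's test template(s)
    to the n-1 remaining training templates; T_i = mu - sigma of that pool;
    subject j != i is an impostor of i iff d(train_j, test_i) < T_i (1/3: at
    least 2 of 3 strict hits).  The self column is excluded by construction,
    so a subject is never its own impostor.
    """
    d = manhattan_distance_matrix(train, test)
    n = len(d.train_ids)
    if n < 3:
        raise ConfigurationError("leave-one-out impostor evaluation needs n >= 3")
    need = 2 if configuration == "1/3" else 1
    if configuration == "1/3" and d.multiplicity != 3:
        raise ConfigurationError("Configuration 1/3 needs multiplicity-3 distances")

    counts: dict[str, int] = {}
    impostors: dict[str, list[str]] = {}
    for i, sid in enumerate(d.test_ids):
        others = [j for j in range(n) if j != i]
        pool = d.values[others, i, :]
        mu, sigma = _pool_stats(pool.ravel(), population_sd)
        t_i = mu - sigma
        hits = []
        for j in others:
            if int(np.sum(d.values[j, i, :] < t_i)) >= need:
                hits.append(d.train_ids[j])
        counts[sid] = len(hits)
        impostors[sid] = hits
    score = 100.0 * float(np.mean([counts[s] / (n - 1) for s in d.test_ids]))
    return AuthReport(configuration=configuration, authenticated={},
                      accuracy=float("nan"), impostor_counts=counts,
                      impostors=impostors, impostor_score=score)


def authenticate_cohort(
    train: SubjectFeatureMatrix,
    test: SubjectFeatureMatrix | list[SubjectFeatureMatrix],
    configuration: str = "1/1",
    population_sd: bool = True,
    include_self: bool = True,
) -> AuthReport:
    """Full authentication run: accuracy from cohort-pool thresholds plus the
    leave-one-out impostor score, merged into one report."""
    d = manhattan_distance_matrix(train, test)
    thr = compute_thresholds(d, population_sd=population_sd, include_self=include_self)
    acc_report = authenticate_subjects(d, thr, configuration)
    imp_report = loo_impostor_evaluation(train, test, configuration, population_sd)
    return AuthReport(
        configuration=configuration,
        authenticated=acc_report.authenticated,
        accuracy=acc_report.accuracy,
        impostor_counts=imp_report.impostor_counts,
        impostors=imp_report.impostors,
        impostor_score=imp_report.impostor_score,
    )
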