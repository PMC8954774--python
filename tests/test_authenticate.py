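"""Threshold authentication and leave-one-out impostor evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heartprint.authenticate import (
    AuthThresholds,
    DistanceMatrix,
    authenticate_cohort,
    authenticate_subjects,
    compute_thresholds,
    loo_impostor_evaluation,
    manhattan_distance_matrix,
)
from heartprint.synthetic import ConfigurationError
from heartprint.templates import SubjectFeatureMatrix


def _matrix(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"S{i:03d}" for i in range(rows.shape[0])]
    return SubjectFeatureMatrix(rows, ids)


def test_distance_matrix_zero_diagonal_and_hand_values():
    train = _matrix([[0, 0], [1, 1]])
    d_self = manhattan_distance_matrix(train, train)
    assert np.all(np.diag(d_self.values[:, :, 0]) == 0)
    test = _matrix([[0, 1], [0, 1]])
    d = manhattan_distance_matrix(train, test)
    assert d.values[0, 0, 0] == 1 and d.values[1, 0, 0] == 1


def test_distance_matrix_homogeneity():
    rng = np.random.default_rng(0)
    train = _matrix(rng.normal(size=(4, 9)))
    test = _matrix(rng.normal(size=(4, 9)))
    d1 = manhattan_distance_matrix(train, test)
    train3 = _matrix(3.0 * train.values)
    test3 = _matrix(3.0 * test.values)
    d3 = manhattan_distance_matrix(train3, test3)
    np.testing.assert_allclose(d3.values, 3.0 * d1.values)


def test_distance_matrix_feature_mismatch():
    with pytest.raises(ConfigurationError):
        manhattan_distance_matrix(_matrix(np.zeros((2, 3))), _matrix(np.zeros((2, 4))))


def test_threshold_from_pool_1_2_3():
    # subject 0's pool {1,2,3}: mu=2, population sd=0.8165, T=1.1835
    train_ids = ["A", "B", "C"]
    values = np.array([[1.0, 9, 9], [2.0, 9, 9], [3.0, 9, 9]])
    d = DistanceMatrix(values, train_ids, train_ids)
    thr = compute_thresholds(d, population_sd=True)
    assert thr.mu[0] == pytest.approx(2.0)
    assert thr.sigma[0] == pytest.approx(0.816497, abs=1e-6)
    assert thr.t[0] == pytest.approx(1.183503, abs=1e-6)
    # the sample-sd convention is exposed but distinct
    thr_s = compute_thresholds(d, population_sd=False)
    assert thr_s.t[0] == pytest.approx(1.0)


def test_threshold_constant_pool():
    d = DistanceMatrix(np.full((3, 3), 4.0), list("ABC"), list("ABC"))
    thr = compute_thresholds(d)
    np.testing.assert_allclose(thr.t, 4.0)


def test_threshold_matches_independent_oracle():
    rng = np.random.default_rng(3)
    values = rng.random((6, 6))
    d = DistanceMatrix(values, list("ABCDEF"), list("ABCDEF"))
    thr = compute_thresholds(d)
    for i in range(6):
        pool = values[:, i]
        t_oracle = np.mean(pool) - np.sqrt(np.mean((pool - np.mean(pool)) ** 2))
        assert abs(thr.t[i] - t_oracle) <= 1e-12 * max(abs(t_oracle), 1.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(alpha=st.floats(0.001, 1000))
def test_threshold_scales_linearly(alpha):
    values = np.array([[1.0, 5, 2], [2.0, 1, 4], [3.0, 2, 2]])
    d1 = DistanceMatrix(values, list("ABC"), list("ABC"))
    d2 = DistanceMatrix(alpha * values, list("ABC"), list("ABC"))
    t1 = compute_thresholds(d1).t
    t2 = compute_thresholds(d2).t
    np.testing.assert_allclose(t2, alpha * t1, rtol=1e-9)


def test_authentication_rule():
    ids = list("ABC")
    values = np.diag([1.0, 5.0, 2.0]) + 10 * (1 - np.eye(3))
    d = DistanceMatrix(values, ids, ids)
    thr = AuthThresholds(ids, mu=np.array([2.0, 2, 2]), sigma=np.zeros(3))
    rep = authenticate_subjects(d, thr, "1/1")
    assert rep.accuracy == pytest.approx(2 / 3)
    assert rep.authenticated == {"A": True, "B": False, "C": True}
    # boundary: self-distance equal to the threshold authenticates
    thr_eq = AuthThresholds(ids, mu=np.array([1.0, 5, 2]), sigma=np.zeros(3))
    assert all(authenticate_subjects(d, thr_eq, "1/1").authenticated.values())


def test_two_of_three_rule():
    ids = list("AB")
    vals = np.zeros((2, 2, 3))
    vals[0, 0] = [1.0, 1.0, 9.0]   # two of three under threshold
    vals[1, 1] = [9.0, 9.0, 1.0]   # only one under
    vals[0, 1] = vals[1, 0] = [5, 5, 5]
    d = DistanceMatrix(vals, ids, ids)
    thr = AuthThresholds(ids, mu=np.array([2.0, 2.0]), sigma=np.zeros(2))
    rep = authenticate_subjects(d, thr, "1/3")
    assert rep.authenticated == {"A": True, "B": False}


def test_raising_threshold_never_deauthenticates():
    rng = np.random.default_rng(7)
    values = rng.random((8, 8)) * 10
    d = DistanceMatrix(values, [f"S{i}" for i in range(8)], [f"S{i}" for i in range(8)])
    thr = compute_thresholds(d)
    base = authenticate_subjects(d, thr, "1/1").authenticated
    raised = AuthThresholds(thr.subject_ids, thr.mu + 1.0, thr.sigma)
    up = authenticate_subjects(d, raised, "1/1").authenticated
    assert all(up[s] for s in base if base[s])


def test_stricter_threshold_tradeoff():
    # mu - 2 sigma never increases accuracy nor impostor score vs mu - sigma
    for seed in range(3):
        rng = np.random.default_rng(seed)
        train = _matrix(rng.normal(size=(10, 40)))
        test = _matrix(train.values + 0.5 * rng.normal(size=(10, 40)),
                       list(train.subject_ids))
        d = manhattan_distance_matrix(train, test)
        thr = compute_thresholds(d)
        strict = AuthThresholds(thr.subject_ids, thr.mu, 2.0 * thr.sigma)
        acc1 = authenticate_subjects(d, thr, "1/1").accuracy
        acc2 = authenticate_subjects(d, strict, "1/1").accuracy
        assert acc2 <= acc1
        imp1 = _impostor_count(d, sigma_mult=1.0)
        imp2 = _impostor_count(d, sigma_mult=2.0)
        assert imp2 <= imp1


def _impostor_count(d, sigma_mult):
    n = len(d.train_ids)
    total = 0
    for i in range(n):
        others = [j for j in range(n) if j != i]
        pool = d.values[others, i, 0]
        t = pool.mean() - sigma_mult * pool.std()
        total += int(np.sum(pool < t))
    return total


def test_loo_orthogonal_templates_zero_impostors():
    train = _matrix(100.0 * np.eye(6))
    rep = loo_impostor_evaluation(train, train, "1/1")
    assert rep.impostor_score == 0.0
    assert all(c == 0 for c in rep.impostor_counts.values())


def test_loo_near_duplicates_flag_each_other():
    rng = np.random.default_rng(1)
    rows = 50.0 * np.eye(8) + rng.random((8, 8))
    rows[7] = rows[6] + 0.01  # subjects 6 and 7 nearly identical
    train = _matrix(rows)
    rep = loo_impostor_evaluation(train, train, "1/1")
    ids = train.subject_ids
    assert ids[6] in rep.impostors[ids[7]]
    assert ids[7] in rep.impostors[ids[6]]


def test_loo_self_never_impostor():
    rng = np.random.default_rng(2)
    train = _matrix(rng.normal(size=(7, 12)))
    rep = loo_impostor_evaluation(train, train, "1/1")
    for sid, hits in rep.impostors.items():
        assert sid not in hits


def test_loo_requires_three_subjects():
    train = _matrix(np.eye(2))
    with pytest.raises(ConfigurationError):
        loo_impostor_evaluation(train, train, "1/1")


def test_full_report_merges_accuracy_and_impostors():
    rng = np.random.default_rng(4)
    train = _matrix(20 * np.eye(5) + rng.random((5, 5)))
    test = _matrix(train.values + 0.1, list(train.subject_ids))
    rep = authenticate_cohort(train, test, "1/1")
    assert 0.0 <= rep.accuracy <= 1.0
    assert 0.0 <= rep.impostor_score <= 100.0
    assert set(rep.impostor_counts) == set(train.subject_ids)
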