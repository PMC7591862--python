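"""Permutation engines, AUC, FDR: exact examples and calibration."""

import itertools

import numpy as np
import pytest

from canomap.stats import (
    auc_mann_whitney,
    fdr_bh,
    paired_sign_flip_test,
    pearson,
    two_sample_permutation,
)


# -- two-sample permutation ---------------------------------------------------


def test_exhaustive_two_sample_p_one_sixth():
    res = two_sample_permutation([-3, -3], [0, 0], "mean_diff", "less", n_perm=100)
    assert res.exhaustive
    assert res.p_value == pytest.approx(1 / 6)


def test_identical_groups_give_p_one():
    # constant identical groups: every permuted statistic equals the observed
    for side in ("less", "greater", "two-sided"):
        res = two_sample_permutation([1, 1], [1, 1], "mean_diff", side, n_perm=100)
        assert res.p_value == pytest.approx(1.0)
    # identical multisets, two-sided: |stat| >= |0| for all 6 assignments
    res = two_sample_permutation([1, 2], [1, 2], "mean_diff", "two-sided", n_perm=100)
    assert res.p_value == pytest.approx(1.0)
    # one-sided the -1 assignment is strictly smaller: exact 5/6
    res = two_sample_permutation([1, 2], [1, 2], "mean_diff", "greater", n_perm=100)
    assert res.p_value == pytest.approx(5 / 6)


def test_sampled_p_never_zero(rng):
    res = two_sample_permutation(
        np.arange(10) + 100.0, np.arange(10), "mean_diff", "greater",
        n_perm=200, seed=1,
    )
    assert not res.exhaustive
    assert res.p_value == pytest.approx(1 / 201)


def test_exhaustive_matches_independent_enumeration(rng):
    for _ in range(20):
        x = rng.standard_normal(3)
        y = rng.standard_normal(4)
        res = two_sample_permutation(x, y, "mean_diff", "less", n_perm=100)
        pooled = np.concatenate([x, y])
        obs = x.mean() - y.mean()
        stats = []
        for c in itertools.combinations(range(7), 3):
            xs = pooled[list(c)]
            ys = np.delete(pooled, list(c))
            stats.append(xs.mean() - ys.mean())
        expect = np.mean(np.asarray(stats) <= obs + 1e-12)
        assert res.p_value == pytest.approx(expect, abs=1e-12)


def test_sampled_agrees_with_exhaustive_within_mc_error(rng):
    x = rng.standard_normal(5) + 0.8
    y = rng.standard_normal(5)
    exact = two_sample_permutation(x, y, "mean_diff", "greater", n_perm=300).p_value
    sampled = two_sample_permutation(
        x, y, "mean_diff", "greater", n_perm=100, seed=7
    ).p_value
    se = np.sqrt(exact * (1 - exact) / 100)
    assert abs(sampled - exact) <= 3 * se + 0.02


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        two_sample_permutation([], [1.0], n_perm=10)


def test_two_sample_type1_calibration(rng):
    n_reject = 0
    runs = 400
    for _ in range(runs):
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        p = two_sample_permutation(
            x, y, "mean_diff", "two-sided", n_perm=250,
            seed=int(rng.integers(2**31)),
        ).p_value
        n_reject += p <= 0.05
    assert abs(n_reject / runs - 0.05) < 0.03


# -- sign-flip ----------------------------------------------------------------


def test_sign_flip_exhaustive_examples():
    res = paired_sign_flip_test([1, 2, 3], "greater", n_perm=100)
    assert res.exhaustive and res.p_value == pytest.approx(1 / 8)
    res = paired_sign_flip_test([-1, 1], "greater", n_perm=100)
    assert res.p_value == pytest.approx(3 / 4)


def test_sign_flip_rejects_degenerate_input():
    with pytest.raises(ValueError):
        paired_sign_flip_test([0.0, 0.0, 1.0])


def test_sign_flip_type1_calibration(rng):
    n_reject = 0
    runs = 400
    for _ in range(runs):
        d = rng.standard_normal(15)
        p = paired_sign_flip_test(
            d, "two-sided", n_perm=250, seed=int(rng.integers(2**31))
        ).p_value
        n_reject += p <= 0.05
    assert abs(n_reject / runs - 0.05) < 0.03


# -- AUC ----------------------------------------------------------------------


def test_auc_toy_examples():
    assert auc_mann_whitney([0.1, 0.2, 0.9], [0, 0, 1]) == pytest.approx(1.0)
    assert auc_mann_whitney([0.5, 0.5], [0, 1]) == pytest.approx(0.5)
    assert auc_mann_whitney([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)


def test_auc_matches_pair_counting_with_midranks(rng):
    for _ in range(100):
        n = int(rng.integers(4, 30))
        scores = rng.integers(0, 6, n).astype(float)  # many ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        expect = wins / (len(pos) * len(neg))
        assert auc_mann_whitney(scores, labels) == pytest.approx(expect, abs=1e-12)


def test_auc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    for _ in range(20):
        scores = rng.standard_normal(25)
        labels = rng.integers(0, 2, 25)
        if labels.min() == labels.max():
            continue
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


def test_auc_complement_for_tie_free_scores(rng):
    scores = rng.permutation(30).astype(float)
    labels = np.r_[np.ones(10), np.zeros(20)]
    total = auc_mann_whitney(scores, labels) + auc_mann_whitney(-scores, labels)
    assert total == pytest.approx(1.0, abs=1e-12)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        auc_mann_whitney([1.0, 2.0], [1, 1])


# -- FDR ----------------------------------------------------------------------


def test_bh_stepup_example():
    reject, adj = fdr_bh([0.01, 0.02, 0.03, 0.5], q=0.05)
    assert reject.tolist() == [True, True, True, False]
    assert np.all(np.diff(adj[np.argsort([0.01, 0.02, 0.03, 0.5])]) >= -1e-15)


def test_bh_all_ones_rejects_none():
    reject, _ = fdr_bh(np.ones(10), q=0.05)
    assert not reject.any()


def test_bh_rejects_nonfinite():
    with pytest.raises(ValueError):
        fdr_bh([0.1, np.nan])


def test_bh_idempotent_on_rejection_set(rng):
    p = np.concatenate([rng.uniform(0, 1e-4, 20), rng.uniform(size=200)])
    reject, _ = fdr_bh(p, q=0.05)
    if reject.any():
        again, _ = fdr_bh(p[reject], q=0.05)
        assert again.all()


# -- Pearson helper -----------------------------------------------------------


def test_pearson_matches_scipy(rng):
    from scipy import stats as sps

    for _ in range(100):
        n = int(rng.integers(3, 50))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        assert pearson(x, y) == pytest.approx(sps.pearsonr(x, y).statistic, abs=1e-12)


def test_pearson_degenerate_is_nan():
    assert np.isnan(pearson([1, 1, 1], [1, 2, 3]))
    assert np.isnan(pearson([1, 2], [3, 4]))
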