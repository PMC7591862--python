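"""Permutation tests, AUC, correlation helpers and FDR control.

All inference in the pipeline is permutation-based.  Sampled permutation
p-values use the (b + 1) / (n + 1) convention so that p is never zero;
exhaustive enumeration (used automatically when feasible) returns the exact
fraction of arrangements at least as extreme as the observed one, which by
construction includes the observed arrangement itself.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "two_sample_permutation",
    "paired_sign_flip_test",
    "auc_mann_whitney",
    "fdr_bh",
    "pearson",
]

_TOL = 1e-12  # floating-point slack when counting "as extreme" statistics


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    n_perm: int
    exceedances: int
    p_value: float
    sidedness: str
    seed: int | None
    exhaustive: bool

    def as_row(self) -> dict:
        return {
            "observed": self.observed,
            "n_perm": self.n_perm,
            "exceedances": self.exceedances,
            "p_value": self.p_value,
            "sidedness": self.sidedness,
            "seed": self.seed if self.seed is not None else -1,
            "exhaustive": int(self.exhaustive),
        }


def _count(stats_null: np.ndarray, observed: float, sidedness: str) -> int:
    if sidedness == "greater":
        return int(np.sum(stats_null >= observed - _TOL))
    if sidedness == "less":
        return int(np.sum(stats_null <= observed + _TOL))
    if sidedness == "two-sided":
        return int(np.sum(np.abs(stats_null) >= abs(observed) - _TOL))
    raise ValueError(f"unknown sidedness {sidedness!r}")


def _mean_diff(x_sum: np.ndarray, total: float, nx: int, ny: int) -> np.ndarray:
    return x_sum / nx - (total - x_sum) / ny


def two_sample_permutation(
    x,
    y,
    statistic: str = "mean_diff",
    sidedness: str = "two-sided",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Label-shuffling two-sample test.

    ``statistic`` is ``"mean_diff"`` (mean(x) - mean(y)), ``"auc"`` (AUC of
    the pooled values as predictor of membership in ``x``), or a callable
    ``f(x, y) -> float``.  Enumeration is exhaustive when the number of
    distinct label assignments C(nx+ny, nx) does not exceed ``n_perm``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    nx, ny = x.size, y.size
    n = nx + ny

    ranks = sps.rankdata(pooled) if statistic == "auc" else None

    def stat_from_idx(idx: np.ndarray) -> float:
        if statistic == "mean_diff":
            xs = pooled[idx]
            return float(xs.mean() - (pooled.sum() - xs.sum()) / ny)
        if statistic == "auc":
            return float((ranks[idx].sum() - nx * (nx + 1) / 2) / (nx * ny))
        return float(statistic(pooled[idx], np.delete(pooled, idx)))

    observed = stat_from_idx(np.arange(nx))

    exhaustive = comb(n, nx) <= n_perm
    if exhaustive:
        null = np.array(
            [stat_from_idx(np.array(c)) for c in itertools.combinations(range(n), nx)]
        )
        b = _count(null, observed, sidedness)
        total = null.size
        return PermutationResult(
            observed, total, b, b / total, sidedness, seed, True
        )

    rng = np.random.default_rng(seed)
    if statistic in ("mean_diff", "auc"):
        # vectorised: each row of `order` is a permutation of 0..n-1
        order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :nx]
        if statistic == "mean_diff":
            x_sum = pooled[order].sum(axis=1)
            null = _mean_diff(x_sum, pooled.sum(), nx, ny)
        else:
            null = (ranks[order].sum(axis=1) - nx * (nx + 1) / 2) / (nx * ny)
    else:
        null = np.empty(n_perm)
        for i in range(n_perm):
            idx = rng.permutation(n)[:nx]
            null[i] = stat_from_idx(idx)
    b = _count(null, observed, sidedness)
    return PermutationResult(
        observed, n_perm, b, (b + 1) / (n_perm + 1), sidedness, seed, False
    )


def paired_sign_flip_test(
    differences,
    sidedness: str = "two-sided",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Sign-flipping test on the mean of paired differences."""
    d = np.asarray(differences, dtype=float).ravel()
    if np.count_nonzero(d) < 2:
        raise ValueError("need at least 2 nonzero differences")
    n = d.size
    observed = float(d.mean())
    exhaustive = n <= 30 and 2**n <= n_perm
    if exhaustive:
        signs = np.array(
            [[1 if (i >> k) & 1 else -1 for k in range(n)] for i in range(2**n)]
        )
        null = (signs * d).mean(axis=1)
        b = _count(null, observed, sidedness)
        return PermutationResult(observed, 2**n, b, b / 2**n, sidedness, seed, True)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    null = (signs * d).mean(axis=1)
    b = _count(null, observed, sidedness)
    return PermutationResult(
        observed, n_perm, b, (b + 1) / (n_perm + 1), sidedness, seed, False
    )


def auc_mann_whitney(scores, labels) -> float:
    """AUC of ``scores`` predicting ``labels == 1``, midrank tie handling.

    Equals the Mann-Whitney U statistic divided by n1 * n0.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up control of the FDR at level ``q``.

    Returns (reject mask, adjusted p-values).
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if not np.isfinite(p).all() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and within [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def pearson(x, y) -> float:
    """Pearson correlation; NaN for degenerate (constant or too-short) input."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
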