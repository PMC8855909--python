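"""Shared fixtures and independent oracles.

The oracles are deliberately naive (loops, full enumeration, textbook
formulas) and independent of the package's vectorized implementations;
tests compare the two routes.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from brafsig.signature import (
    fit_all_genes,
    label_braf_status,
    log2_transform,
    select_signature,
)
from brafsig.scoring import score_cohort
from brafsig.synthetic import CohortSpec, gen_expression


# ---------------------------------------------------------------- oracles

def oracle_curves(g, w):
    """Loop evaluation of the foreground/background cumulative curves.

    Ranking is assumed done; accumulates |g_k| * w_k and |g_k| * (1-w_k)
    index by index and divides by the full sums.
    """
    n = len(g)
    f_den = sum(abs(g[k]) * w[k] for k in range(n))
    b_den = sum(abs(g[k]) * (1 - w[k]) for k in range(n))
    f, b = [], []
    for i in range(1, n + 1):
        f.append(sum(abs(g[k]) * w[k] for k in range(i)) / f_den)
        b.append(sum(abs(g[k]) * (1 - w[k]) for k in range(i)) / b_den)
    return np.array(f), np.array(b)


def oracle_pre_score(g, w):
    f, b = oracle_curves(g, w)
    d = f - b
    best = 0
    for i in range(len(d)):
        if abs(d[i]) > abs(d[best]):
            best = i
    return d[best]


def oracle_wilcoxon_greater(a, b):
    """Exact one-sided rank-sum p by enumerating all group assignments.

    P(rank-sum of a random |a|-subset >= observed rank-sum of a), over
    all C(n, |a|) assignments of the pooled ranks. Assumes no ties.
    """
    pooled = sorted(list(a) + list(b))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in a)
    n, k = len(pooled), len(a)
    hits = sum(
        1 for idx in combinations(range(1, n + 1), k) if sum(idx) >= observed
    )
    return hits / comb(n, k)


def oracle_fisher_two_sided(table):
    """Two-sided Fisher p: sum of hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed
    the observed table's (with the conventional 1+1e-7 slack)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def oracle_irls_logistic(X, y, tol=1e-10, max_iter=100):
    """Textbook iteratively-reweighted least squares for logistic MLE.

    Returns (beta, covariance). Independent of statsmodels.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        XtWX = X.T @ (X * W[:, None])
        grad = X.T @ (y - mu)
        step = np.linalg.solve(XtWX, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1 - mu)
    cov = np.linalg.inv(X.T @ (X * W[:, None]))
    return beta, cov


def oracle_logrank(times, events, group):
    """Two-sample log-rank chi-square from the observed-minus-expected
    sums over distinct event times (hypergeometric variance)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=int)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


# ---------------------------------------------------------------- fixtures

SMALL_SPEC = CohortSpec(
    n_genes=400, n_samples=40, n_signal_genes=20, effect_size=1.5,
    noise_sd=1.0, seed=101,
)

STUDY_TRAIN_SEED = 11
STUDY_TEST_SEED = 12
STUDY_SCORE_SEED = 5


@pytest.fixture(scope="session")
def small_cohort():
    """400-gene, 40-sample cohort with 20 planted genes (quick tests)."""
    return gen_expression(SMALL_SPEC)


@pytest.fixture(scope="session")
def signature_study():
    """Reference study: train a 200-gene signature on the default cohort
    (5000 genes, 40/40, 100 planted, effect 1.0) and score an
    independent held-out cohort sharing the same planted genes."""
    train = gen_expression(CohortSpec(seed=STUDY_TRAIN_SEED))
    m = log2_transform(train.matrix)
    status = label_braf_status(train.mutations, list(m.sample_ids))
    fits = fit_all_genes(m, status, train.covariates)
    sig = select_signature(fits, 200)

    test = gen_expression(
        CohortSpec(seed=STUDY_TEST_SEED, signal_seed=STUDY_TRAIN_SEED)
    )
    mt = log2_transform(test.matrix)
    results = score_cohort(mt, sig, n_permutations=1000,
                           seed=STUDY_SCORE_SEED)
    scores = pd.Series(
        [r.score for r in results], index=[r.sample_id for r in results]
    )
    return {
        "train": train,
        "signature": sig,
        "test": test,
        "test_matrix_log2": mt,
        "results": results,
        "scores": scores,
        "test_is_mutant": scores.index.isin(set(test.mutant_samples)),
    }
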