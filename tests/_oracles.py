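"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's computational paths: posterior
inclusion probabilities come from exhaustive enumeration of inclusion
configurations with the effect vector integrated analytically; PWM score
tails come from enumerating all 4^w words.
"""

import itertools

import numpy as np
from scipy import stats


def exact_pip(y, X, pi, d0, d1, de):
    """Exact PIPs by summing over all 2^p inclusion configurations.

    For fixed hyperparameters the marginal likelihood of y given a
    configuration g is N(0, de*I + X diag(v_g) X'), v_gj = d1 if g_j else d0.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    log_w, configs = [], []
    for bits in itertools.product((0, 1), repeat=p):
        g = np.array(bits)
        v = np.where(g == 1, d1, d0)
        cov = de * np.eye(n) + (X * v) @ X.T
        ll = stats.multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov)
        lp = float((g * np.log(pi) + (1 - g) * np.log(1 - pi)).sum())
        log_w.append(ll + lp)
        configs.append(g)
    log_w = np.array(log_w)
    w = np.exp(log_w - log_w.max())
    w /= w.sum()
    return (w[:, None] * np.array(configs)).sum(axis=0)


def brute_force_tail(int_scores, background):
    """Exact tail P(total integer score >= t) by enumerating all 4^w words."""
    int_scores = np.asarray(int_scores)
    w = int_scores.shape[1]
    max_total = int(int_scores.max(axis=0).sum())
    pmf = np.zeros(max_total + 1)
    for word in itertools.product(range(4), repeat=w):
        s = int(int_scores[list(word), range(w)].sum())
        pmf[s] += float(np.prod([background[b] for b in word]))
    return np.cumsum(pmf[::-1])[::-1]


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def greedy_cluster_reference(kmers: list[str]):
    """Direct string-based greedy Hamming-1 clustering (priority order input)."""
    reps: list[str] = []
    assign = []
    for km in kmers:
        best = -1
        for ci, rep in enumerate(reps):
            if hamming(km, rep) <= 1:
                best = ci
                break
        if best < 0:
            reps.append(km)
            assign.append(len(reps) - 1)
        else:
            assign.append(best)
    return assign, reps
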