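"""Independent brute-force oracles used by the test suite.

Each function here recomputes a quantity by direct enumeration or naive
looping, deliberately avoiding the code paths (and libraries) used by
the package implementation it checks.
"""

from __future__ import annotations

from math import comb, inf, log, exp

import numpy as np


def pairwise_auc(pos, neg) -> float:
    """AUC by explicit pair enumeration: P(pos > neg) + 0.5 P(equal)."""
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def mann_whitney_u(x, y) -> float:
    """U statistic for x by pair counting (ties count half)."""
    u = 0.0
    for a in x:
        for b in y:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Sums, over all tables with the observed margins, the probabilities
    of tables whose probability does not exceed the observed table's
    (minimum-likelihood rule).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(n, c1)
    probs = {k: comb(r1, k) * comb(r2, c1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    # small relative slack against floating-point ties in the comparison
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-10))


def group_mean_log2fc(values, labels, class_a, class_b):
    """Per-gene difference of group means by an explicit python loop."""
    values = np.asarray(values)
    labels = list(labels)
    out = []
    for row in values:
        sa = [v for v, l in zip(row, labels) if l == class_a]
        sb = [v for v, l in zip(row, labels) if l == class_b]
        out.append(sum(sa) / len(sa) - sum(sb) / len(sb))
    return np.array(out)


def breslow_log_partial_likelihood(beta, time, event, x) -> float:
    """Breslow log partial likelihood for a single covariate."""
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    x = np.asarray(x, float)
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            at_risk = time >= time[i]
            ll += beta * x[i] - log(np.sum(np.exp(beta * x[at_risk])))
    return ll


def maximize_breslow(time, event, x, lo=-8.0, hi=8.0, tol=1e-10) -> float:
    """Golden-section maximizer of the Breslow partial likelihood."""
    gr = (5**0.5 - 1) / 2
    a, b = lo, hi
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc = breslow_log_partial_likelihood(c, time, event, x)
    fd = breslow_log_partial_likelihood(d, time, event, x)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = breslow_log_partial_likelihood(c, time, event, x)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = breslow_log_partial_likelihood(d, time, event, x)
    return (a + b) / 2


def cox_score_statistic(time, event, x) -> float:
    """Cox score test statistic at beta = 0 (binary covariate, no ties).

    U^2 / I with U the sum over events of (x_i - mean of x over the risk
    set) and I the summed risk-set variance of x; equals the two-group
    log-rank chi-square when no event times are tied.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    x = np.asarray(x, float)
    u = v = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            r = x[time >= time[i]]
            u += x[i] - r.mean()
            v += r.mean() - r.mean() ** 2  # binary x: E[x^2] = E[x]
    return u * u / v


def km_by_hand(time, event):
    """Product-limit estimate as {time: survival} over distinct times."""
    order = np.argsort(time, kind="stable")
    time = np.asarray(time, float)[order]
    event = np.asarray(event, float)[order]
    s = 1.0
    out = {}
    for t in sorted(set(time)):
        at_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        if d > 0:
            s *= 1 - d / at_risk
        out[t] = s
    return out
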