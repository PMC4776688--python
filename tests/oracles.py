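"""Independent brute-force oracles used to validate the optimized implementations.

Everything here is written as plainly as possible (explicit loops, direct
formula transcription) and never calls the code under test.
"""

import itertools
import math

import numpy as np


def sampen_naive(v, m, r):
    """Sample entropy by direct double-loop template counting (nats)."""
    v = list(map(float, v))
    N = len(v)
    n_templ = N - m

    def count(length):
        total = 0
        for i in range(n_templ):
            for j in range(i + 1, n_templ):
                if all(abs(v[i + k] - v[j + k]) <= r for k in range(length)):
                    total += 1
        return total

    B = count(m)
    A = count(m + 1)
    if A == 0 or B == 0:
        return float("nan")
    return -math.log(A / B)


def l5_m10_naive(profile, interval):
    """Circular window-sum scan over every start position."""
    p = list(map(float, profile))
    n = len(p)
    w5 = round(300 / interval)
    w10 = round(600 / interval)
    sums5 = [sum(p[(s + k) % n] for k in range(w5)) for s in range(n)]
    sums10 = [sum(p[(s + k) % n] for k in range(w10)) for s in range(n)]
    return min(sums5), max(sums10)


def mi_table(counts):
    """Plug-in mutual information (bits) straight from a contingency table."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    mi = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            nij = counts[i, j]
            if nij > 0:
                mi += (nij / n) * math.log2(nij * n / (counts[i].sum() * counts[:, j].sum()))
    return mi


def mi_labels(a, b):
    labels_a = sorted(set(a))
    labels_b = sorted(set(b))
    counts = [[sum(1 for x, y in zip(a, b) if x == la and y == lb) for lb in labels_b]
              for la in labels_a]
    return mi_table(counts)


def mrmr_naive(disc, labels, names):
    """Greedy MID ordering by exhaustive score evaluation; ties lexicographic."""
    relevance = {nm: mi_labels(disc[nm], labels) for nm in names}
    order = []
    remaining = sorted(names)
    while remaining:
        scored = []
        for nm in remaining:
            red = (sum(mi_labels(disc[nm], disc[s]) for s in order) / len(order)
                   if order else 0.0)
            scored.append((-(relevance[nm] - red), nm))
        scored.sort()
        pick = scored[0][1]
        order.append(pick)
        remaining.remove(pick)
    return order


def ranksum_exact_p(a, b):
    """Two-sided rank-sum p by exhaustive enumeration of rank assignments."""
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"
    n1 = len(a)
    w_obs = sum(sorted(pooled).index(x) + 1 for x in a)
    mean_w = n1 * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n1):
        total += 1
        if abs(sum(combo) - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def auc_concordance(scores, truth):
    """AUC as the rank (concordance) statistic with half-credit for ties."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
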