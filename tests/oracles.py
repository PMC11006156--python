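"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by direct enumeration, deliberately
avoiding the library's vectorised code paths.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2_contingency


def auc_pairwise(pos, neg) -> float:
    """Mann-Whitney AUC by exhaustive pair counting (ties count 1/2)."""
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def _thresholds(values):
    v = sorted(set(values))
    mids = [(a + b) / 2.0 for a, b in zip(v[:-1], v[1:])]
    return [-np.inf] + mids + [np.inf]


def _sens_spec(pos, neg, c):
    sens = sum(1 for p in pos if p > c) / len(pos)
    spec = sum(1 for q in neg if q <= c) / len(neg)
    return sens, spec


def best_youden(pos, neg):
    """(threshold, J) maximizing J; smallest threshold on ties."""
    best_c, best_j = None, -np.inf
    for c in _thresholds(list(pos) + list(neg)):
        sens, spec = _sens_spec(pos, neg, c)
        j = sens + spec - 1.0
        if j > best_j:
            best_c, best_j = c, j
    return best_c, best_j


def best_topleft(pos, neg):
    """(threshold, d) minimizing the squared corner distance."""
    best_c, best_d = None, np.inf
    for c in _thresholds(list(pos) + list(neg)):
        sens, spec = _sens_spec(pos, neg, c)
        d = (1 - sens) ** 2 + (1 - spec) ** 2
        if d < best_d:
            best_c, best_d = c, d
    return best_c, best_d


def chi2_enumeration(pos, neg):
    """[(threshold, chi2)] for every interior midpoint, via scipy's
    contingency-table routine (uncorrected, 1 df)."""
    out = []
    for c in _thresholds(list(pos) + list(neg))[1:-1]:
        tp = sum(1 for p in pos if p > c)
        fn = len(pos) - tp
        fp = sum(1 for q in neg if q > c)
        tn = len(neg) - fp
        table = np.array([[tp, fp], [fn, tn]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            stat = 0.0
        else:
            stat = chi2_contingency(table, correction=False)[0]
        out.append((c, stat))
    return out


def best_chi2(pos, neg, tol=1e-9):
    """(smallest tied argmax threshold, max chi2, tied thresholds).

    Mathematically tied maxima can differ in the last float bits between
    implementations, so the tie set is resolved with a tolerance.
    """
    enum = chi2_enumeration(pos, neg)
    best = max(s for _, s in enum)
    ties = [c for c, s in enum if s >= best - tol]
    return min(ties), best, ties


def delong_variance_bruteforce(pos, neg):
    """DeLong AUC variance from O(m*n) placement loops."""
    pos, neg = list(pos), list(neg)
    m, n = len(pos), len(neg)

    def psi(a, b):
        return 1.0 if a > b else (0.5 if a == b else 0.0)

    v10 = [sum(psi(p, q) for q in neg) / n for p in pos]
    v01 = [sum(psi(p, q) for p in pos) / m for q in neg]
    auc = sum(v10) / m
    s10 = sum((v - auc) ** 2 for v in v10) / (m - 1)
    s01 = sum((v - auc) ** 2 for v in v01) / (n - 1)
    return auc, s10 / m + s01 / n
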