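"""Independent brute-force oracles used across the test suite.

Each oracle is written from the definition, not from the package's code path:
pair counting for AUROC, threshold-set precision/recall for average
precision, the literal BH step-up recursion, and combinatorial enumeration of
the hypergeometric tail.
"""

from __future__ import annotations

from math import comb

import numpy as np


def auroc_bruteforce(scores, labels) -> float:
    """Concordant-pair count over all case-control pairs, ties = 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def auprc_bruteforce(scores, labels) -> float:
    """Step integration of the PR curve over distinct thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    thresholds = sorted(set(scores), reverse=True)
    ap = 0.0
    recall_prev = 0.0
    for t in thresholds:
        called = scores >= t
        tp = int((labels[called] == 1).sum())
        precision = tp / int(called.sum())
        recall = tp / n_pos
        ap += (recall - recall_prev) * precision
        recall_prev = recall
    return ap


def bh_stepup_bruteforce(pvals) -> np.ndarray:
    """q_(i) = min_{j >= i} p_(j) * n / j over the ascending order, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(n)
    running = np.inf
    for i in range(n - 1, -1, -1):
        running = min(running, p[order[i]] * n / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def hypergeom_tail_bruteforce(found: int, universe_size: int, set_size: int,
                              n_hits: int) -> float:
    """P(X >= found) by summing the hypergeometric pmf term by term."""
    denom = comb(universe_size, n_hits)
    total = 0
    for k in range(found, min(set_size, n_hits) + 1):
        if universe_size - set_size >= n_hits - k >= 0:
            total += comb(set_size, k) * comb(universe_size - set_size, n_hits - k)
    return total / denom
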