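"""Exact statistical primitives: two-tailed Fisher test and Kruskal-Wallis.

The Fisher test is implemented with exact integer arithmetic so the
two-sided point-probability convention (sum of all same-margin tables
whose hypergeometric point probability is at most the observed one) is
decided without floating-point tie ambiguity. Point probabilities share
the constant denominator C(N, r1), so the "at most as probable"
comparison reduces to an exact integer comparison of numerators
C(c1, k) * C(c2, r1 - k).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats as sps


def fisher_exact_two_tailed(tp: int, fp: int, fn: int, tn: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[tp, fp], [fn, tn]].

    Rows are clinical presence/absence, columns preclinical
    presence/absence; by symmetry of the hypergeometric the orientation
    does not matter. A zero margin yields p = 1 by convention.
    """
    for v in (tp, fp, fn, tn):
        if v < 0 or v != int(v):
            raise ValueError("cells must be non-negative integers")
    tp, fp, fn, tn = int(tp), int(fp), int(fn), int(tn)
    r1 = tp + fp  # clinical-present margin
    c1 = tp + fn  # preclinical-present margin
    n = tp + fp + fn + tn
    c2 = n - c1
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0

    k_min = max(0, r1 - c2)
    k_max = min(r1, c1)
    # integer numerators of the hypergeometric pmf over the support
    num = math.comb(c1, k_min) * math.comb(c2, r1 - k_min)
    obs_num = None
    total = 0
    tail = 0
    k = k_min
    while True:
        if k == tp:
            obs_num = num
        total += num
        if k == k_max:
            break
        # exact recurrence: ratio of consecutive pmf numerators
        num = num * (c1 - k) * (r1 - k) // ((k + 1) * (c2 - r1 + k + 1))
        k += 1
    assert obs_num is not None
    # second pass: accumulate numerators <= the observed one
    num = math.comb(c1, k_min) * math.comb(c2, r1 - k_min)
    k = k_min
    while True:
        if num <= obs_num:
            tail += num
        if k == k_max:
            break
        num = num * (c1 - k) * (r1 - k) // ((k + 1) * (c2 - r1 + k + 1))
        k += 1
    return tail / total


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with mid-ranked ties and the chi-square p (df = g-1).

    Implemented over ranks directly so +inf values are valid inputs (all
    +inf observations tie at the top). The standard tie correction
    divides H by 1 - sum(t^3 - t)/(N^3 - N).
    """
    sizes = [len(g) for g in groups]
    if any(s == 0 for s in sizes) or len(groups) < 2:
        raise ValueError("kruskal_wallis needs >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = pooled.size
    ranks = sps.rankdata(pooled)  # mid-ranks; inf ranks above all finite
    h = 0.0
    start = 0
    for s in sizes:
        r = ranks[start : start + s]
        h += r.sum() ** 2 / s
        start += s
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n**3 - n)
    if denom <= 0:  # all values identical
        return 0.0, 1.0
    h /= denom
    p = float(sps.chi2.sf(h, df=len(groups) - 1))
    return float(h), p
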