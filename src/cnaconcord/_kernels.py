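"""Numba-compiled inner loops for the two segmentation engines.

Both kernels operate on a single chromosome vector of log2 ratios.
The CBS split statistic is the pooled two-sample t between an arc and
its complement. For a fixed vector, t^2 = B * (n-2) / (T - B) where
T is the total sum of squares (permutation-invariant) and B the
between-group sum of squares of the split, so maximizing |t| over arcs
is equivalent to maximizing B — and B/n = (s - w*mu)^2 / (w*(n-w))
needs only a prefix sum. The exact argmax kernel tracks indices with
lexicographic tie-breaks; the value-only kernel used inside permutation
scans is a branch-light max reduction. ``pcf_dp`` is the exact O(n^2)
dynamic program for the penalized least-squares fit. The test suite
re-implements all of this in plain Python as independent oracles.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["max_arc_full", "max_arc_crit", "pcf_dp"]


@njit(cache=True)
def max_arc_full(x, min_seg):  # pragma: no cover - exercised via segmentation tests
    """Best arc (i, j] of ``x`` under the pooled two-sample t-statistic.

    Scans all arcs with width >= 2 on both the arc and its complement;
    with ``min_seg`` > 1, arcs whose boundaries would leave a flanking
    piece shorter than ``min_seg`` markers are excluded (i must be 0 or
    >= min_seg; j must be n or <= n - min_seg). Returns (i, j, crit, t)
    where crit = B/n is the scale-free split criterion compared across
    permutations. Ties break to smallest i, then smallest j
    (strict-improvement scanning in (i, j) order). A constant window
    scores t = 0; a perfect split (zero within-group variance,
    different means) scores t = +inf.
    """
    n = x.shape[0]
    S = np.empty(n + 1)
    S[0] = 0.0
    T = 0.0
    qtot = 0.0
    for k in range(n):
        S[k + 1] = S[k] + x[k]
        qtot += x[k] * x[k]
    mu = S[n] / n
    for k in range(n):
        d = x[k] - mu
        T += d * d
    best = -1.0
    bi = 0
    bj = 2
    wmax = n - 2  # complement needs >= 2 markers
    for i in range(0, n - 1):
        if i != 0 and i < min_seg:
            continue
        jhi = i + wmax
        if jhi > n:
            jhi = n
        Si = S[i]
        for j in range(i + 2, jhi + 1):
            if j != n and n - j < min_seg:
                continue
            w = j - i
            e = S[j] - Si - w * mu
            crit = e * e / (w * (n - w))
            # tolerance tie-break: complementary arcs score equal up to
            # 1 ulp; prefer the lexicographically first (i, j)
            if crit > best * (1.0 + 1e-12):
                best = crit
                bi = i
                bj = j
    if best < 0.0:
        best = 0.0
    B = n * best
    resid = T - B
    if B <= 0.0 or T <= 1e-20 * max(qtot, 1e-300):
        t = 0.0  # constant vector up to float rounding
    elif resid <= 1e-12 * T:  # perfect split up to float cancellation
        t = np.inf
    else:
        t = np.sqrt(B * (n - 2) / resid)
    return bi, bj, best, t


@njit(cache=True, fastmath=True)
def max_arc_crit(x, min_seg):  # pragma: no cover
    """Max split criterion B/n over the same arc family as
    ``max_arc_full`` (value only, for permutation scans); monotone in
    max |t| for a fixed value multiset."""
    n = x.shape[0]
    S = np.empty(n + 1)
    S[0] = 0.0
    for k in range(n):
        S[k + 1] = S[k] + x[k]
    mu = S[n] / n
    best = 0.0
    for w in range(2, n - 1):
        wm = w * mu
        m = 0.0
        # interior starts: both flanks at least min_seg markers
        ihi = n - w - min_seg
        for i in range(min_seg, ihi + 1):
            e = S[i + w] - S[i] - wm
            sq = e * e
            if sq > m:
                m = sq
        # boundary-touching arcs (i = 0 and j = n)
        if w <= n - min_seg:
            e = S[w] - wm
            if e * e > m:
                m = e * e
            e = S[n] - S[n - w] - wm
            if e * e > m:
                m = e * e
        c = m / (w * (n - w))
        if c > best:
            best = c
    return best


@njit(cache=True)
def pcf_dp(x, gamma, kmin):  # pragma: no cover
    """Exact minimizer of sum-of-within-segment-SS + gamma * n_breakpoints
    over all segmentations with segments of >= kmin markers.

    Suffix dynamic program; ties resolve to fewer segments, then the
    lexicographically smallest breakpoint vector (smallest feasible next
    breakpoint chosen greedily from the left). Returns the sorted array
    of interior breakpoints.
    """
    n = x.shape[0]
    S = np.empty(n + 1)
    Q = np.empty(n + 1)
    S[0] = 0.0
    Q[0] = 0.0
    for k in range(n):
        S[k + 1] = S[k] + x[k]
        Q[k + 1] = Q[k] + x[k] * x[k]
    INF = 1e300
    BIG = np.int64(1) << 60
    suf = np.full(n + 1, INF)
    nseg = np.full(n + 1, BIG)
    suf[n] = 0.0
    nseg[n] = 0
    for i in range(n - kmin, -1, -1):
        best = INF
        bseg = BIG
        Si = S[i]
        Qi = Q[i]
        for j in range(i + kmin, n + 1):
            if j < n and suf[j] >= INF:
                continue
            sse = (Q[j] - Qi) - (S[j] - Si) * (S[j] - Si) / (j - i)
            if j == n:
                c = sse
                ns = np.int64(1)
            else:
                c = sse + gamma + suf[j]
                ns = np.int64(1) + nseg[j]
            if c < best or (c == best and ns < bseg):
                best = c
                bseg = ns
        suf[i] = best
        nseg[i] = bseg
    bps = np.empty(n, np.int64)
    nb = 0
    i = 0
    while i < n:
        advanced = False
        Si = S[i]
        Qi = Q[i]
        for j in range(i + kmin, n + 1):
            if j < n and suf[j] >= INF:
                continue
            sse = (Q[j] - Qi) - (S[j] - Si) * (S[j] - Si) / (j - i)
            if j == n:
                c = sse
                ns = np.int64(1)
            else:
                c = sse + gamma + suf[j]
                ns = np.int64(1) + nseg[j]
            if c == suf[i] and ns == nseg[i]:
                if j < n:
                    bps[nb] = j
                    nb += 1
                i = j
                advanced = True
                break
        if not advanced:  # float-equality safety net: take the argmin
            bestj = -1
            best = INF
            bseg = BIG
            for j in range(i + kmin, n + 1):
                if j < n and suf[j] >= INF:
                    continue
                sse = (Q[j] - Qi) - (S[j] - Si) * (S[j] - Si) / (j - i)
                if j == n:
                    c = sse
                    ns = np.int64(1)
                else:
                    c = sse + gamma + suf[j]
                    ns = np.int64(1) + nseg[j]
                if c < best or (c == best and ns < bseg):
                    best = c
                    bseg = ns
                    bestj = j
            if bestj < n and bestj >= 0:
                bps[nb] = bestj
                nb += 1
            if bestj < 0:
                break
            i = bestj
    return bps[:nb]
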