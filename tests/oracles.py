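"""Independent brute-force oracles used to validate the scanners and statistics.

Everything here is written naively (nested loops, explicit enumeration)
and kept independent of the implementation code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import hypergeom


# ---------------------------------------------------------------------------
# STR oracle
# ---------------------------------------------------------------------------

def str_calls_oracle(seq: str, min_units: int = 6, periods=(2, 3, 4, 5, 6)):
    """All perfect STR calls by exhaustive (start, period) search.

    Returns tuples (start, end, period, units, unit).  Semantics: maximal
    runs anchored leftmost, complete units only, primitive units only,
    left run claims shared bases first, N breaks runs.
    """

    def match(i: int, p: int) -> bool:
        if i < 0 or i + p >= len(seq):
            return False
        a, b = seq[i], seq[i + p]
        return a == b and a != "N" and b != "N"

    def primitive(unit: str) -> bool:
        for d in range(1, len(unit)):
            if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
                return False
        return True

    raw = []
    for start in range(len(seq)):
        for p in periods:
            if match(start - 1, p):
                continue  # not leftmost
            j = start
            while match(j, p):
                j += 1
            if j == start:
                continue
            extent = (j - start) + p
            if extent // p >= min_units:
                raw.append((start, p, start + extent))
    raw.sort(key=lambda t: (t[0], t[1]))

    claimed = [False] * len(seq)
    calls = []
    for start, p, raw_end in raw:
        s = start
        while s < raw_end and claimed[s]:
            s += 1
        units = (raw_end - s) // p
        if units < min_units:
            continue
        unit = seq[s : s + p]
        if not primitive(unit):
            continue
        end = s + units * p
        calls.append((s, end, p, units, unit))
        for i in range(s, end):
            claimed[i] = True
    calls.sort(key=lambda c: (c[0], c[2]))
    return calls


# ---------------------------------------------------------------------------
# PQS candidate oracle
# ---------------------------------------------------------------------------

def pqs_candidates_oracle(seq: str, max_span: int = 30, min_tetrad: int = 4,
                          min_loop: int = 0):
    """Exhaustive search over all four-tract placements on a short sequence.

    Returns a set of (run_starts, run_lengths) tuples.  Only practical
    for sequences up to ~60 nt.
    """
    L = len(seq)

    def all_g(s: int, t: int) -> bool:
        return s >= 0 and s + t <= L and all(c == "G" for c in seq[s : s + t])

    out = set()
    for s1 in range(L):
        for t1 in range(min_tetrad, max_span + 1):
            if not all_g(s1, t1):
                break
            for s2 in range(s1 + t1 + min_loop, L):
                if s2 + min_tetrad > s1 + max_span:
                    break
                for t2 in range(min_tetrad, max_span + 1):
                    if not all_g(s2, t2) or s2 + t2 > s1 + max_span:
                        break
                    for s3 in range(s2 + t2 + min_loop, L):
                        if s3 + min_tetrad > s1 + max_span:
                            break
                        for t3 in range(min_tetrad, max_span + 1):
                            if not all_g(s3, t3) or s3 + t3 > s1 + max_span:
                                break
                            for s4 in range(s3 + t3 + min_loop, L):
                                if s4 + min_tetrad > s1 + max_span:
                                    break
                                for t4 in range(min_tetrad, max_span + 1):
                                    if (not all_g(s4, t4)
                                            or s4 + t4 > s1 + max_span):
                                        break
                                    span_seq = seq[s1 : s4 + t4]
                                    if all(c == "G" for c in span_seq):
                                        continue  # undisrupted poly-G
                                    out.add(((s1, s2, s3, s4),
                                             (t1, t2, t3, t4)))
    return out


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------

def kendall_tau_b_oracle(x, y) -> float:
    """Pairwise concordant/discordant enumeration with the tau-b denominator."""
    n = len(x)
    conc = disc = 0
    tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - _tie_pairs(x)) * (n0 - _tie_pairs(y)))
    if denom == 0:
        return math.nan
    return (conc - disc) / denom


def _tie_pairs(v) -> float:
    from collections import Counter

    return sum(c * (c - 1) / 2 for c in Counter(v).values())


def mann_whitney_u_oracle(a, b) -> float:
    """U for sample a by direct pair counting (ties count half)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mann_whitney_exact_p_oracle(a, b):
    """(p_two_sided, p_one_sided) by enumerating all labelings of the pool."""
    pooled = list(a) + list(b)
    n = len(a)
    mu = n * len(b) / 2.0
    u_obs = mann_whitney_u_oracle(a, b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        ia = set(idx)
        aa = [pooled[i] for i in idx]
        bb = [pooled[i] for i in range(len(pooled)) if i not in ia]
        us.append(mann_whitney_u_oracle(aa, bb))
    us = np.array(us)
    p_two = float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-9))
    p_one = float(
        min(np.mean(us <= u_obs + 1e-9), np.mean(us >= u_obs - 1e-9))
    )
    return p_two, p_one


def fisher_2x2_oracle(table):
    """Two-sided Fisher p by hypergeometric summation over all margin tables."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    probs = {k: hypergeom.pmf(k, n, c1, r1) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))
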