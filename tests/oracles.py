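"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's search strategies: the junction
oracle enumerates every anchor decomposition naively; the hypergeometric
tail is exact integer arithmetic via math.comb; the BH oracle applies the
step-up definition literally.
"""

from __future__ import annotations

from math import comb


def brute_force_call(S: str, R: str, c: int, o: int = 0, k: int = 10):
    """Enumerate all exact-anchor decompositions of read S against reference R.

    Returns None (unalignable) or a tuple
    (status, del_left, del_right, insertion, mh_length) for the
    minimal-total-deletion decomposition, ranked by
    (total deletion, insertion length, del_right, del_left), with the
    deletion register canonicalized to its leftmost placement and
    microhomology measured by boundary extension.
    """
    best_key = None
    best = None
    for dl in range(0, c - o - k + 1):
        jl = c - dl - o
        if jl - k < 0 or jl > len(S):
            continue
        if S[jl - k : jl] != R[c - dl - k : c - dl]:
            continue
        for dr in range(0, len(R) - c - k + 1):
            kmer = R[c + dr : c + dr + k]
            for q in range(0, len(S) - k + 1):
                if S[q : q + k] != kmer:
                    continue
                if q >= jl:
                    key = (dl + dr, q - jl, dr, dl)
                    full = (dl, dr, q, 0, S[jl:q])
                elif jl - q <= k:
                    v = jl - q
                    key = (dl + dr + v, 0, dr, dl)
                    full = (dl, dr, q, v, "")
                else:
                    continue
                if best_key is None or key < best_key:
                    best_key, best = key, full
    if best is None:
        return None
    dl, dr, q, v, ins = best
    d_total = dl + dr + v
    if d_total == 0 and not ins:
        return ("INTACT", 0, 0, "", 0)
    if ins:
        return ("PASS", dl, dr, ins, 0)
    b1, b2 = c - dl - v, c + dr
    while b1 > 0 and R[b1 - 1] == R[b2 - 1]:
        b1 -= 1
        b2 -= 1
    mh = 0
    cap = min(d_total, k)
    while mh < cap and b2 + mh < len(R) and R[b1 + mh] == R[b2 + mh]:
        mh += 1
    return ("PASS", c - b1, b2 - c, "", mh)


def hypergeom_lower_tail(b: int, population: int, successes: int, draws: int) -> float:
    """P(X <= b) for X ~ Hypergeometric(population, successes, draws), exact."""
    denom = comb(population, draws)
    lo = max(0, draws - (population - successes))
    hi = min(b, successes, draws)
    total = 0
    for x in range(lo, hi + 1):
        total += comb(successes, x) * comb(population - successes, draws - x)
    return total / denom


def bh_reject_stepup(p_values, q: float):
    """Literal Benjamini-Hochberg step-up rule; ties at the threshold all rejected."""
    p = list(p_values)
    m = len(p)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: p[i])
    kmax = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= rank * q / m:
            kmax = rank
    if kmax == 0:
        return [False] * m
    threshold = p[order[kmax - 1]]
    return [pi <= threshold for pi in p]
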