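"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions, deliberately avoiding the
code paths under test: direct predicate evaluation for profiles, all-pairs
interval arithmetic for overlap, full-recomputation average linkage, and
exact rational arithmetic for the binomial test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def oriented_count(reads, position: int, flank: int) -> int:
    """Reads within ``flank`` of ``position`` whose orientation points at it."""
    n = 0
    for r in reads:
        if abs(r.pos5 - position) > flank:
            continue
        if r.strand == "+" and r.pos5 <= position:
            n += 1
        elif r.strand == "-" and r.pos5 >= position:
            n += 1
    return n


def brute_profile(reads, chrom_length: int, resolution: int, flank: int) -> np.ndarray:
    """O(reads x grid) profile by direct predicate evaluation."""
    nbins = (chrom_length - 1) // resolution + 1
    return np.array(
        [oriented_count(reads, k * resolution, flank) for k in range(nbins)],
        dtype=np.int64,
    )


def intervals_overlap(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def brute_classify(transcripts, peaks, layout, upstream, downstream):
    """All peaks x all windows, from the window formula written out again."""
    out = {}
    for t in transcripts:
        if t.strand == "+":
            lo, hi = t.tx_start - upstream, t.tx_start + downstream
        else:
            lo, hi = t.tx_end - downstream, t.tx_end + upstream
        lo, hi = max(lo, 0), min(hi, layout[t.chrom])
        n = sum(
            1
            for p in peaks
            if p.interval.chrom == t.chrom
            and intervals_overlap(p.interval.start, p.interval.end, lo, hi)
        )
        out[t.transcript_id] = (n >= 1, n)
    return out


def brute_average_linkage(x: np.ndarray):
    """Agglomerative average linkage recomputed from the full leaf matrix.

    Cluster-cluster distance is the mean of 1 - Pearson r over all cross
    pairs of member leaves; ties broken by lowest (i, j) node pair.
    """
    n = x.shape[0]
    dmat = 1.0 - np.corrcoef(x)
    members = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(members) > 1:
        best = None
        for i in sorted(members):
            for j in sorted(members):
                if j <= i:
                    continue
                d = float(
                    np.mean([dmat[a, b] for a in members[i] for b in members[j]])
                )
                if best is None or (d, i, j) < best:
                    best = (d, i, j)
        d, i, j = best
        merges.append((i, j, d))
        members[next_id] = members.pop(i) + members.pop(j)
        next_id += 1
    return merges


def exact_binom_two_sided(k: int, n: int, p_num: int, p_den: int) -> Fraction:
    """Two-sided exact binomial p (minlike) in exact rational arithmetic."""
    p = Fraction(p_num, p_den)
    q = 1 - p
    pmf = [comb(n, x) * p**x * q ** (n - x) for x in range(n + 1)]
    observed = pmf[k]
    return min(Fraction(1), sum(m for m in pmf if m <= observed))


def poisson_tail(c: int, lam: float) -> float:
    """P(X >= c) for Poisson(lam) by direct series summation."""
    import math

    if c <= 0:
        return 1.0
    lower = sum(math.exp(-lam) * lam**x / math.factorial(x) for x in range(c))
    return 1.0 - lower
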