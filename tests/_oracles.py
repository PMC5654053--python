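"""Independent brute-force / direct-formula oracles used by the tests.

These deliberately re-derive results from first principles (enumeration,
closed forms, rank-then-Pearson) without calling the library code paths
they are used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Direct Benjamini-Hochberg step-up formula:
    q_i = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running_min = np.inf
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        q_sorted[rank_from_top - 1] = min(running_min, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def rank_then_pearson(x, y) -> float:
    """Spearman rho as Pearson correlation of mean ranks (ties averaged),
    computed without scipy."""
    def mean_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(v.size)
        i = 0
        sorted_v = v[order]
        while i < v.size:
            j = i
            while j < v.size and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0  # average of 1-based ranks
            i = j
        return ranks

    rx, ry = mean_ranks(x), mean_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


def hypergeom_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) by exhaustive enumeration of all C(N, n) query draws
    against a fixed K-element term in an N-element universe."""
    universe = range(N)
    term = set(range(K))
    total = 0
    hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(term.intersection(draw)) >= k:
            hits += 1
    return hits / total


def brute_force_bidirectional(peaks, gap, halfwidth, dmax):
    """All-pairs enumeration of the divergent-pairing rule, with the same
    strongest-first overlap resolution, written independently of the
    implementation.  Returns a set of (chrom, start, end, midpoint) tuples.
    """
    cands = []
    for m in peaks:
        if m.strand != "-":
            continue
        for p in peaks:
            if p.strand != "+" or p.interval.chrom != m.interval.chrom:
                continue
            sep = p.summit - m.summit
            if sep <= 0 or sep > gap:
                continue
            mid = (m.summit + p.summit) // 2
            start, end = mid - halfwidth, mid + halfwidth + 1
            if start < 0:
                continue
            P = sum(
                q.total_count
                for q in peaks
                if q.strand == "+" and q.interval.chrom == m.interval.chrom
                and mid <= q.summit < end
            )
            M = sum(
                q.total_count
                for q in peaks
                if q.strand == "-" and q.interval.chrom == m.interval.chrom
                and start <= q.summit < mid
            )
            if P + M == 0:
                continue
            D = (P - M) / (P + M)
            if abs(D) >= dmax:
                continue
            cands.append((m.interval.chrom, start, end, mid, P + M))
    # strongest-first greedy resolution
    cands.sort(key=lambda c: (-c[4], c[0], c[1], c[3]))
    chosen = []
    for c in cands:
        clash = any(
            c[0] == o[0] and c[1] < o[2] and o[1] < c[2] for o in chosen
        )
        if not clash:
            chosen.append(c)
    return {(c[0], c[1], c[2], c[3]) for c in chosen}


def random_peak_set(rng, max_peaks=50, chrom="chrT"):
    """Random CAGE peak configuration for oracle-equivalence checks."""
    from ernalink.genome_model import CagePeak, GenomicInterval

    n = int(rng.integers(2, max_peaks + 1))
    peaks = []
    for i in range(n):
        strand = "-" if rng.random() < 0.5 else "+"
        summit = int(rng.integers(1000, 20000))
        half = int(rng.integers(0, 30))
        start = max(0, summit - half)
        end = summit + half + 1
        counts = rng.integers(0, 50, size=3)
        peaks.append(
            CagePeak(f"p{i}", GenomicInterval(chrom, start, end, strand), summit, counts)
        )
    return peaks
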