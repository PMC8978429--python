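"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (O(n^2) pairwise scans, union-find,
explicit enumeration) and shares no code with the package, so agreement is
evidence of correctness rather than self-consistency.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
from scipy.stats import nbinom, binom


class UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def brute_force_islands(reads, max_gap, min_reads, min_density):
    """Cluster intervals from pairwise union-find over collapsed reads.

    Two reads chain when on the same chromosome with starts within max_gap;
    the island relation is the transitive closure.  ``reads`` must already
    be collapsed to unique (sequence, chrom, start, strand) entries.
    """
    reads = list(reads)
    n = len(reads)
    uf = UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if reads[i].chrom == reads[j].chrom and abs(
                reads[i].start - reads[j].start
            ) <= max_gap:
                uf.union(i, j)
    groups = defaultdict(list)
    for i in range(n):
        groups[uf.find(i)].append(reads[i])
    out = []
    for members in groups.values():
        start = min(r.start for r in members)
        end = max(r.end for r in members)
        density = len(members) / ((end - start) / 1000.0) if end > start else float("inf")
        if len(members) >= min_reads and density >= min_density:
            out.append((members[0].chrom, start, end))
    return sorted(out)


def brute_force_merge(intervals, merge_dist):
    """Transitive-closure merge of (chrom, start, end) intervals via
    pairwise union-find on the gap <= merge_dist relation."""
    intervals = list(intervals)
    n = len(intervals)
    uf = UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = intervals[i]
            cj, sj, ej = intervals[j]
            if ci == cj and max(si, sj) - min(ei, ej) <= merge_dist:
                uf.union(i, j)
    groups = defaultdict(list)
    for i in range(n):
        groups[uf.find(i)].append(intervals[i])
    return sorted(
        (g[0][0], min(s for _, s, _ in g), max(e for _, _, e in g))
        for g in groups.values()
    )


def brute_force_overlap_hist(reads, max_overlap, weighted=True):
    """Ping-pong overlap histogram by full pairwise enumeration."""
    hist = {o: 0.0 for o in range(1, max_overlap + 1)}
    plus = [r for r in reads if r.strand == "+"]
    minus = [r for r in reads if r.strand == "-"]
    for a in plus:
        for b in minus:
            if a.chrom != b.chrom:
                continue
            p = a.start
            q = b.end - 1
            o = q - p + 1
            if 1 <= o <= max_overlap:
                hist[o] += (a.copy_count * b.copy_count) if weighted else 1
    return hist


def brute_force_distance_hist(reads, max_dist):
    """Phasing distance histogram: for each collapsed read, find its nearest
    downstream (in transcription direction) same-strand neighbour by scanning
    all other reads, and record the 3'-to-5' distance."""
    hist = {d: 0 for d in range(1, max_dist + 1)}
    by_group = defaultdict(list)
    for r in reads:
        by_group[(r.chrom, r.strand)].append(r)
    for (chrom, strand), group in by_group.items():
        five = [(r.start if strand == "+" else r.end - 1) for r in group]
        three = [(r.end - 1 if strand == "+" else r.start) for r in group]
        sign = 1 if strand == "+" else -1
        order = sorted(
            range(len(group)), key=lambda i: (sign * five[i], sign * three[i])
        )
        for a, b in zip(order, order[1:]):
            d = sign * (five[b] - three[a])
            if 1 <= d <= max_dist:
                hist[d] += 1
    return hist


def trf_rule_table(s, e, length, anticodon_start, loop_halfwidth=3):
    """Set-based restatement of the tRF positional classes."""
    loop = set(range(anticodon_start - loop_halfwidth,
                     anticodon_start + 2 + loop_halfwidth + 1))
    terminus = set(range(length - 2, length + 1))
    starts_5p = s in (1, 2)
    ends_3p = e in terminus
    if starts_5p and e in loop:
        return "five_tRH"
    if ends_3p and s in loop:
        return "three_tRH"
    if starts_5p and e not in loop and e not in terminus:
        return "five_tRF"
    if ends_3p and s not in loop:
        return "three_tRF"
    return "i_tRF"


def bh_stepup(p):
    """Textbook Benjamini-Hochberg step-up, coded independently."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def exact_test_enumeration(y_a, y_b, n_a, n_b, phi):
    """Conditional two-sided p by explicit enumeration from the NB joint.

    The group sums are NB(r_g, p0) with r_g = n_g / phi (Poisson limit for
    phi = 0 handled through the binomial split); conditioning on the total
    normalises the joint over all splits.
    """
    t = y_a + y_b
    if t == 0:
        return 1.0
    ks = np.arange(t + 1)
    if phi <= 0:
        probs = binom.pmf(ks, t, n_a / (n_a + n_b))
    else:
        r_a, r_b = n_a / phi, n_b / phi
        p0 = 0.5  # cancels under conditioning for any common p0
        joint = nbinom.pmf(ks, r_a, p0) * nbinom.pmf(t - ks, r_b, p0)
        probs = joint / joint.sum()
    return float(probs[probs <= probs[y_a] * (1 + 1e-12)].sum())
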