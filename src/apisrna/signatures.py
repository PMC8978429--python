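"""piRNA biogenesis signatures.

Three diagnostics of piRNA production:

* the 1U / 10A nucleotide biases (uridine at read position 1, adenine at
  position 10), read in 5'->3' orientation;
* the ping-pong signature: enrichment of opposite-strand read pairs whose
  5' ends overlap by exactly 10 nt, summarised as a Z-score of the 10-nt
  bin against the 1-30 nt overlap background;
* the phasing signature: enrichment of head-to-tail (3'-to-5' distance = 1)
  arrangements of consecutive same-strand reads, summarised as a Z-score of
  the distance-1 bin against the 2-50 nt background.

Z-scores are flagged undefined when the background has zero spread or when
fewer than ``min_reads`` reads are available.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import ReadSet, collapse_reads

DEFAULT_MIN_READS = 50


@dataclass
class SignatureResult:
    n_reads: int
    u1_fraction: float
    a10_fraction: float
    overlap_hist: dict[int, float]
    pingpong_z: float
    distance_hist: dict[int, int]
    phasing_z: float
    phasing_p: float
    defined: bool


def u1_a10_bias(rs: ReadSet) -> tuple[float, float]:
    """Copy-weighted fractions of reads with T at position 1 and A at
    position 10 (among reads of length >= 10)."""
    n = u1 = 0
    n10 = a10 = 0
    for r in rs:
        n += r.copy_count
        if r.sequence[:1] == "T":
            u1 += r.copy_count
        if r.length >= 10:
            n10 += r.copy_count
            if r.sequence[9] == "A":
                a10 += r.copy_count
    if n == 0:
        return float("nan"), float("nan")
    return u1 / n, (a10 / n10 if n10 else float("nan"))


def pingpong_overlap_histogram(
    rs: ReadSet, max_overlap: int = 30, weighted: bool = True
) -> dict[int, float]:
    """Histogram of 5'-5' overlaps between opposite-strand read pairs.

    For a + read with 5' end p and a - read with 5' end q >= p, the overlap
    is q - p + 1; bins 1..max_overlap.  Pairs are weighted by the product of
    copy counts unless ``weighted`` is False (then unique collapsed loci
    count once each).
    """
    reads = rs if weighted else collapse_reads(rs)
    plus: dict[str, Counter] = defaultdict(Counter)
    minus: dict[str, Counter] = defaultdict(Counter)
    for r in reads:
        w = r.copy_count if weighted else 1
        if r.strand == "+":
            plus[r.chrom][r.five_prime] += w
        else:
            minus[r.chrom][r.five_prime] += w
    hist = {o: 0.0 for o in range(1, max_overlap + 1)}
    for chrom, pcounts in plus.items():
        mcounts = minus.get(chrom)
        if not mcounts:
            continue
        for p, wp in pcounts.items():
            for o in range(1, max_overlap + 1):
                wq = mcounts.get(p + o - 1)
                if wq:
                    hist[o] += wp * wq
    return hist


def _signature_z(hist: dict[int, float], signal_bin: int) -> float:
    background = np.array([v for k, v in hist.items() if k != signal_bin], dtype=float)
    sd = background.std(ddof=0)
    if sd == 0:
        # a perfectly flat background carries no spread: the Z is 0 when the
        # signal bin sits on the background level, undefined otherwise
        return 0.0 if hist[signal_bin] == background.mean() else float("nan")
    return (hist[signal_bin] - background.mean()) / sd


def pingpong_zscore(overlap_hist: dict[int, float]) -> float:
    """Z of the 10-nt overlap bin against the 1-30 background (10 excluded)."""
    return _signature_z(overlap_hist, 10)


def phasing_distance_histogram(rs: ReadSet, max_dist: int = 50) -> dict[int, int]:
    """3'-to-5' distances between consecutive same-strand collapsed reads.

    Reads are grouped per chromosome and strand and sorted by 5' position in
    transcription direction; for each consecutive pair the distance is
    (downstream 5') - (upstream 3'), so d = 1 means head-to-tail adjacency.
    Distances in [1, max_dist] are recorded.
    """
    collapsed = collapse_reads(rs)
    groups: dict[tuple[str, str], list] = defaultdict(list)
    for r in collapsed:
        groups[(r.chrom, r.strand)].append(r)
    hist = {d: 0 for d in range(1, max_dist + 1)}
    for (chrom, strand), reads in groups.items():
        if strand == "+":
            reads.sort(key=lambda r: (r.five_prime, r.three_prime))
            for a, b in zip(reads, reads[1:]):
                d = b.five_prime - a.three_prime
                if 1 <= d <= max_dist:
                    hist[d] += 1
        else:
            reads.sort(key=lambda r: (-r.five_prime, -r.three_prime))
            for a, b in zip(reads, reads[1:]):
                d = a.three_prime - b.five_prime
                if 1 <= d <= max_dist:
                    hist[d] += 1
    return hist


def phasing_zscore(distance_hist: dict[int, int]) -> tuple[float, float]:
    """Z of the distance-1 bin against the 2-50 background, with the
    one-sided normal-tail p-value."""
    z = _signature_z(distance_hist, 1)
    p = float(stats.norm.sf(z)) if np.isfinite(z) else float("nan")
    return z, p


def signature_report(
    rs: ReadSet,
    max_overlap: int = 30,
    max_dist: int = 50,
    min_reads: int = DEFAULT_MIN_READS,
    weighted: bool = True,
) -> SignatureResult:
    """All biogenesis signatures for one read set (e.g. one cluster)."""
    n = rs.n_alignments()
    u1, a10 = u1_a10_bias(rs)
    overlap = pingpong_overlap_histogram(rs, max_overlap, weighted=weighted)
    dist = phasing_distance_histogram(rs, max_dist)
    if n >= min_reads:
        pp_z = pingpong_zscore(overlap)
        ph_z, ph_p = phasing_zscore(dist)
        defined = np.isfinite(pp_z) and np.isfinite(ph_z)
    else:
        pp_z = ph_z = ph_p = float("nan")
        defined = False
    return SignatureResult(
        n_reads=n,
        u1_fraction=u1,
        a10_fraction=a10,
        overlap_hist=overlap,
        pingpong_z=pp_z,
        distance_hist=dist,
        phasing_z=ph_z,
        phasing_p=ph_p,
        defined=defined,
    )
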