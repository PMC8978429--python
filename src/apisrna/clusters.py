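"""Density-based piRNA cluster calling with the post-filters used for
putative-piRNA loci: the 50% size-fraction rule, merging of clusters that
overlap or lie within 1 kb of each other, a 200 bp minimum length, and the
strand-call rule (one strand must carry more than double the collapsed reads
of the other in every tissue where the cluster is detected, otherwise the
cluster is bidirectional).

Cluster seeding scans ncRNA-filtered reads of all lengths; the 26-31 nt
window enters through the size-fraction filter and the per-strand tallies,
mirroring the order of operations the filtering rules imply.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .biotype import assign_biotype
from .model import AlignedRead, AnnotationSet, ReadSet, collapse_reads, rpm_normalize

PIRNA_MIN_LEN = 26
PIRNA_MAX_LEN = 31

#: biotypes excluded from the putative piRNA set (protein-coding kept)
NCRNA_BIOTYPES = ("rRNA", "tRNA", "pre_miRNA", "other_ncRNA")


@dataclass
class ClusterParams:
    max_gap: int = 1000          # bp between consecutive read starts within an island
    min_reads: int = 35          # unique (collapsed) reads required per island
    min_density: float = 10.0    # collapsed reads per kb
    min_size_fraction: float = 0.5
    merge_dist: int = 1000       # bp; clusters overlapping or closer are merged
    min_len: int = 200           # bp minimum final cluster length


@dataclass
class PiRNACluster:
    cluster_id: str
    chrom: str
    start: int
    end: int
    plus_collapsed: int = 0
    minus_collapsed: int = 0
    total_reads: int = 0          # alignment count (copy-weighted), all lengths
    in_size_reads: int = 0        # alignment count within 26-31 nt
    size_fraction: float = float("nan")
    strand_call: Optional[str] = None   # plus / minus / bidirectional
    tissues_detected: set = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.end - self.start


class _ReadIndex:
    """Per-chromosome sorted arrays for interval overlap queries on reads."""

    def __init__(self, rs: ReadSet) -> None:
        self._by_chrom: dict[str, list[AlignedRead]] = {}
        for r in rs:
            self._by_chrom.setdefault(r.chrom, []).append(r)
        self._starts: dict[str, list[int]] = {}
        for chrom, reads in self._by_chrom.items():
            reads.sort(key=lambda r: (r.start, r.end))
            self._starts[chrom] = [r.start for r in reads]

    def overlapping(self, chrom: str, start: int, end: int) -> list[AlignedRead]:
        reads = self._by_chrom.get(chrom, [])
        if not reads:
            return []
        hi = bisect.bisect_left(self._starts[chrom], end)
        return [r for r in reads[:hi] if r.end > start]


def filter_putative_pirnas(
    rs: ReadSet, annots: AnnotationSet, length_filter: bool = False
) -> ReadSet:
    """Remove reads annotated as structural/other ncRNA (protein-coding kept);
    optionally restrict to the 26-31 nt piRNA-size window."""
    keep = []
    for r in rs:
        if length_filter and not (PIRNA_MIN_LEN <= r.length <= PIRNA_MAX_LEN):
            continue
        if assign_biotype(r, annots) in NCRNA_BIOTYPES:
            continue
        keep.append(r)
    out = rs.subset(keep)
    out.sort()
    return out


def call_clusters(rs: ReadSet, params: ClusterParams = ClusterParams()) -> list[PiRNACluster]:
    """Maximal read islands where consecutive collapsed-read starts are within
    ``max_gap``; islands kept iff unique reads >= min_reads and density
    (collapsed reads per kb of span) >= min_density."""
    collapsed = collapse_reads(rs)
    clusters: list[PiRNACluster] = []
    island: list[AlignedRead] = []

    def flush(island: list[AlignedRead]) -> None:
        if not island:
            return
        start = min(r.start for r in island)
        end = max(r.end for r in island)
        n_unique = len(island)
        density = n_unique / ((end - start) / 1000.0) if end > start else float("inf")
        if n_unique >= params.min_reads and density >= params.min_density:
            clusters.append(
                PiRNACluster(
                    cluster_id=f"raw_{len(clusters)}",
                    chrom=island[0].chrom,
                    start=start,
                    end=end,
                )
            )

    prev: Optional[AlignedRead] = None
    for r in collapsed:
        if prev is not None and (r.chrom != prev.chrom or r.start - prev.start > params.max_gap):
            flush(island)
            island = []
        island.append(r)
        prev = r
    flush(island)
    for i, c in enumerate(clusters):
        c.cluster_id = f"raw_{i}"
    return clusters


def annotate_cluster_reads(clusters: list[PiRNACluster], rs: ReadSet) -> None:
    """Fill read tallies and the size fraction from the all-length putative set."""
    idx = _ReadIndex(rs)
    collapsed_idx = _ReadIndex(collapse_reads(rs))
    for c in clusters:
        hits = idx.overlapping(c.chrom, c.start, c.end)
        c.total_reads = sum(r.copy_count for r in hits)
        c.in_size_reads = sum(
            r.copy_count for r in hits if PIRNA_MIN_LEN <= r.length <= PIRNA_MAX_LEN
        )
        c.size_fraction = c.in_size_reads / c.total_reads if c.total_reads else float("nan")
        chits = collapsed_idx.overlapping(c.chrom, c.start, c.end)
        c.plus_collapsed = sum(
            1 for r in chits
            if r.strand == "+" and PIRNA_MIN_LEN <= r.length <= PIRNA_MAX_LEN
        )
        c.minus_collapsed = sum(
            1 for r in chits
            if r.strand == "-" and PIRNA_MIN_LEN <= r.length <= PIRNA_MAX_LEN
        )


def filter_size_fraction(
    clusters: list[PiRNACluster], rs: ReadSet, min_fraction: float = 0.5
) -> list[PiRNACluster]:
    """Drop clusters whose fraction of 26-31 nt reads is below ``min_fraction``
    (strictly-less-than removal: a cluster at exactly 50% is retained)."""
    annotate_cluster_reads(clusters, rs)
    return [c for c in clusters if c.total_reads and c.size_fraction >= min_fraction]


def merge_and_min_length(
    clusters: list[PiRNACluster], merge_dist: int = 1000, min_len: int = 200
) -> list[PiRNACluster]:
    """Transitively merge clusters that overlap or lie within ``merge_dist``
    of each other, then drop merged clusters shorter than ``min_len``."""
    merged: list[PiRNACluster] = []
    for c in sorted(clusters, key=lambda c: (c.chrom, c.start, c.end)):
        if merged and merged[-1].chrom == c.chrom and c.start - merged[-1].end <= merge_dist:
            m = merged[-1]
            m.end = max(m.end, c.end)
            m.plus_collapsed += c.plus_collapsed
            m.minus_collapsed += c.minus_collapsed
            m.total_reads += c.total_reads
            m.in_size_reads += c.in_size_reads
            m.size_fraction = m.in_size_reads / m.total_reads if m.total_reads else float("nan")
            m.tissues_detected |= c.tissues_detected
        else:
            merged.append(
                PiRNACluster(
                    cluster_id=f"m_{len(merged)}",
                    chrom=c.chrom,
                    start=c.start,
                    end=c.end,
                    plus_collapsed=c.plus_collapsed,
                    minus_collapsed=c.minus_collapsed,
                    total_reads=c.total_reads,
                    in_size_reads=c.in_size_reads,
                    size_fraction=c.size_fraction,
                    tissues_detected=set(c.tissues_detected),
                )
            )
    out = [c for c in merged if c.length >= min_len]
    for i, c in enumerate(out):
        c.cluster_id = f"cluster_{i + 1}"
    return out


def assign_strandedness(per_tissue_counts: dict[str, tuple[int, int]]) -> str:
    """Strand call from per-tissue (plus, minus) collapsed counts.

    ``plus``/``minus`` only if that strand carries strictly more than double
    the other strand's collapsed reads in every tissue where the cluster is
    detected (>=1 collapsed read); otherwise ``bidirectional``.
    """
    detected = {t: pm for t, pm in per_tissue_counts.items() if pm[0] + pm[1] >= 1}
    if not detected:
        raise ValueError("cluster has zero reads in all tissues")
    if all(p > 2 * m for p, m in detected.values()):
        return "plus"
    if all(m > 2 * p for p, m in detected.values()):
        return "minus"
    return "bidirectional"


def cluster_read_fractions(
    clusters: list[PiRNACluster], rs: ReadSet
) -> tuple[pd.DataFrame, float]:
    """Per-cluster fraction of clustered (total, copy-weighted) putative
    piRNAs, plus the fraction of all putative piRNAs inside any cluster."""
    idx = _ReadIndex(rs)
    total = rs.n_alignments()
    rows = []
    clustered = 0
    for c in clusters:
        n = sum(r.copy_count for r in idx.overlapping(c.chrom, c.start, c.end))
        rows.append((c.cluster_id, c.chrom, c.start, c.end, n))
        clustered += n
    df = pd.DataFrame(rows, columns=["cluster_id", "chrom", "start", "end", "reads"])
    df["fraction_of_clustered"] = df["reads"] / clustered if clustered else 0.0
    clustered_fraction = clustered / total if total else 0.0
    return df, clustered_fraction


def cluster_overlap_sets(
    per_tissue: dict[str, list[PiRNACluster]], merge_dist: int = 1000
) -> list[PiRNACluster]:
    """Unify per-tissue cluster lists with the same <=1 kb merge rule; each
    unified cluster is annotated with the set of tissues that detected it."""
    tagged = []
    for tissue, clusters in per_tissue.items():
        for c in clusters:
            cc = replace_cluster(c)
            cc.tissues_detected = {tissue}
            tagged.append(cc)
    return merge_and_min_length(tagged, merge_dist=merge_dist, min_len=0)


def replace_cluster(c: PiRNACluster) -> PiRNACluster:
    return PiRNACluster(
        cluster_id=c.cluster_id,
        chrom=c.chrom,
        start=c.start,
        end=c.end,
        plus_collapsed=c.plus_collapsed,
        minus_collapsed=c.minus_collapsed,
        total_reads=c.total_reads,
        in_size_reads=c.in_size_reads,
        size_fraction=c.size_fraction,
        strand_call=c.strand_call,
        tissues_detected=set(c.tissues_detected),
    )


def coverage_track(
    cluster: PiRNACluster, rs: ReadSet, total_mapped: int
) -> dict[str, np.ndarray]:
    """Per-position log10(RPM + 1) coverage within the cluster, per strand."""
    span = cluster.length
    tracks = {s: np.zeros(span) for s in "+-"}
    idx = _ReadIndex(rs)
    for r in idx.overlapping(cluster.chrom, cluster.start, cluster.end):
        a = max(r.start, cluster.start) - cluster.start
        b = min(r.end, cluster.end) - cluster.start
        tracks[r.strand][a:b] += r.copy_count
    return {
        s: np.log10(rpm_normalize(depth, total_mapped) + 1.0)
        for s, depth in tracks.items()
    }


def write_bedgraph(track: np.ndarray, chrom: str, offset: int, path: str) -> None:
    """Emit a per-base track as bedGraph, run-length compressed."""
    with open(path, "w") as fh:
        i = 0
        n = len(track)
        while i < n:
            j = i
            while j < n and track[j] == track[i]:
                j += 1
            if track[i] != 0:
                fh.write(f"{chrom}\t{offset + i}\t{offset + j}\t{track[i]:.4f}\n")
            i = j


def clusters_to_frame(clusters: list[PiRNACluster]) -> pd.DataFrame:
    """BED6+-style table of final clusters."""
    rows = []
    for c in clusters:
        rows.append(
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "cluster_id": c.cluster_id,
                "total_reads": c.total_reads,
                "strand_call": c.strand_call or "NA",
                "size_fraction": round(c.size_fraction, 4) if c.total_reads else float("nan"),
                "plus_collapsed": c.plus_collapsed,
                "minus_collapsed": c.minus_collapsed,
                "tissues": ",".join(sorted(c.tissues_detected)) or "NA",
            }
        )
    return pd.DataFrame(rows)


def pirna_clusters(
    rs: ReadSet,
    annots: AnnotationSet,
    params: ClusterParams = ClusterParams(),
) -> tuple[list[PiRNACluster], ReadSet]:
    """End-to-end single-library cluster call.

    Returns the final clusters (strand-called against this library alone)
    and the length-filtered putative piRNA set used for the tallies.
    """
    putative = filter_putative_pirnas(rs, annots, length_filter=False)
    raw = call_clusters(putative, params)
    kept = filter_size_fraction(raw, putative, params.min_size_fraction)
    final = merge_and_min_length(kept, params.merge_dist, params.min_len)
    for c in final:
        c.tissues_detected = {rs.tissue}
        if c.plus_collapsed + c.minus_collapsed >= 1:
            c.strand_call = assign_strandedness({rs.tissue: (c.plus_collapsed, c.minus_collapsed)})
    sized = rs.subset([r for r in putative if PIRNA_MIN_LEN <= r.length <= PIRNA_MAX_LEN])
    return final, sized
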