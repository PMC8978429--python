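"""Core in-memory data model shared by every analysis stage.

Coordinates are 0-based half-open throughout; GFF3 I/O converts from the
1-based inclusive convention at the boundary.  Read sequences are stored in
read (5'->3') orientation with T standing in for U.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Biotype labels recognised by the annotation layer.
BIOTYPES = ("rRNA", "tRNA", "pre_miRNA", "other_ncRNA", "exon", "intron", "gene", "TE")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignedRead:
    """One genomic alignment of a small-RNA read.

    ``copy_count`` carries the multiplicity of identical alignments after
    collapsing; ``n_hits`` is the number of genomic loci this read maps to.
    """

    read_id: str
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    n_hits: int = 1
    copy_count: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: span {self.end - self.start} != "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (start on +, end-1 on -)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the 3' end (end-1 on +, start on -)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class Feature:
    """A genomic annotation interval with its biotype and attributes."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    attributes: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"feature {self.feature_id}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class ReadSet:
    """An ordered collection of :class:`AlignedRead` with library metadata."""

    def __init__(
        self,
        reads: Iterable[AlignedRead] = (),
        sample_id: str = "sample",
        tissue: str = "unknown",
        total_mapped: Optional[int] = None,
    ) -> None:
        self.reads: list[AlignedRead] = list(reads)
        self.sample_id = sample_id
        self.tissue = tissue
        # total mapped alignments of the library; defaults to the alignment
        # count actually held, but can exceed it (e.g. after filtering).
        self._total_mapped = total_mapped

    @property
    def total_mapped(self) -> int:
        if self._total_mapped is not None:
            return self._total_mapped
        return sum(r.copy_count for r in self.reads)

    @total_mapped.setter
    def total_mapped(self, value: int) -> None:
        self._total_mapped = value

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[AlignedRead]:
        return iter(self.reads)

    def __getitem__(self, i):
        return self.reads[i]

    def sort(self) -> "ReadSet":
        self.reads.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand))
        return self

    def subset(self, reads: Iterable[AlignedRead]) -> "ReadSet":
        """A new ReadSet with the same metadata but different reads."""
        return ReadSet(
            reads,
            sample_id=self.sample_id,
            tissue=self.tissue,
            total_mapped=self._total_mapped,
        )

    def n_alignments(self) -> int:
        """Total alignment count including collapsed multiplicities."""
        return sum(r.copy_count for r in self.reads)


class AnnotationSet:
    """Strand-aware interval index over :class:`Feature` records.

    Introns are derived as within-gene gaps between the exons of each gene
    and indexed like any other feature.
    """

    def __init__(self, features: Iterable[Feature] = ()) -> None:
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._by_biotype: dict[str, list[Feature]] = defaultdict(list)
        self.features: list[Feature] = []
        for f in features:
            self.add(f)

    def add(self, f: Feature) -> None:
        self.features.append(f)
        self._trees[f.chrom].addi(f.start, f.end, f)
        self._by_biotype[f.biotype].append(f)

    def __len__(self) -> int:
        return len(self.features)

    def overlapping(
        self,
        chrom: str,
        start: int,
        end: int,
        strand: Optional[str] = None,
        biotype: Optional[str] = None,
    ) -> list[Feature]:
        """All features overlapping [start, end); optionally strand/biotype filtered."""
        if chrom not in self._trees:
            return []
        hits = [iv.data for iv in self._trees[chrom].overlap(start, end)]
        if strand is not None:
            hits = [f for f in hits if f.strand == strand]
        if biotype is not None:
            hits = [f for f in hits if f.biotype == biotype]
        hits.sort(key=lambda f: (f.start, f.end, f.feature_id))
        return hits

    def by_biotype(self, biotype: str) -> list[Feature]:
        return list(self._by_biotype.get(biotype, []))

    def biotype_counts(self) -> dict[str, int]:
        return {bt: len(fs) for bt, fs in self._by_biotype.items()}

    def derive_introns(self) -> None:
        """Add an intron feature for every gap between exons of a gene."""
        exons_by_parent: dict[str, list[Feature]] = defaultdict(list)
        for ex in self._by_biotype.get("exon", []):
            parent = ex.attributes.get("parent")
            if parent:
                exons_by_parent[parent].append(ex)
        genes = {g.feature_id: g for g in self._by_biotype.get("gene", [])}
        for parent, exons in sorted(exons_by_parent.items()):
            exons.sort(key=lambda f: f.start)
            gene = genes.get(parent)
            for i, (a, b) in enumerate(zip(exons, exons[1:])):
                if a.end < b.start:
                    self.add(
                        Feature(
                            feature_id=f"{parent}.intron{i + 1}",
                            chrom=a.chrom,
                            start=a.end,
                            end=b.start,
                            strand=gene.strand if gene else a.strand,
                            biotype="intron",
                            attributes={"parent": parent},
                        )
                    )


def collapse_reads(rs: ReadSet) -> ReadSet:
    """Collapse alignments sharing (sequence, chrom, start, strand).

    The collapsed ``copy_count`` sums the input multiplicities, so the total
    alignment count is conserved exactly.
    """
    acc: dict[tuple, AlignedRead] = {}
    for r in rs:
        key = (r.sequence, r.chrom, r.start, r.strand)
        if key in acc:
            prev = acc[key]
            acc[key] = replace(prev, copy_count=prev.copy_count + r.copy_count)
        else:
            acc[key] = r
    out = rs.subset(acc.values())
    out.sort()
    return out


def rpm_normalize(count: float, total_mapped: int) -> float:
    """Reads-per-million normalisation: count * 1e6 / total_mapped."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive for RPM normalisation")
    return count * 1e6 / total_mapped
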