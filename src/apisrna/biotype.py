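"""Biotype assignment, read-length histograms and positional nucleotide
frequency profiles (the library-composition views).

Biotype assignment uses a fixed precedence ladder so that a read overlapping
several annotation classes gets a single label:

    rRNA > tRNA > pre_miRNA > other_ncRNA > mRNA (exon or intron) > unannotated

Structural RNAs outrank mRNA so that tRNA fragments are never mislabelled as
mRNA fragments.  Assignment is strand-agnostic by default (a read antisense
to a tRNA still reflects tRNA origin ambiguity); strand-aware counting lives
in the feature-targeting stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AlignedRead, AnnotationSet, ReadSet

#: precedence ladder, highest first
PRECEDENCE = ("rRNA", "tRNA", "pre_miRNA", "other_ncRNA")

#: reporting categories (pie-chart view); rRNA folds into other_ncRNA
REPORT_CATEGORIES = ("tRNA", "pre_miRNA", "mRNA", "other_ncRNA", "unannotated")


@dataclass
class BiotypeProfile:
    """Length histogram, biotype fractions and the length-by-biotype matrix."""

    length_counts: dict[int, int]
    biotype_fractions: dict[str, float]
    length_by_biotype: pd.DataFrame  # index: length, columns: REPORT_CATEGORIES
    n_reads: int


@dataclass
class NucleotideFrequencyProfile:
    """Per-position base fractions over reads in a length window."""

    fractions: pd.DataFrame  # index: position 1..max, columns A/C/G/T
    n_reads: int
    defined: bool


def assign_biotype(
    read: AlignedRead, annots: AnnotationSet, stranded: bool = False
) -> str:
    """Label a read by the highest-precedence overlapping annotation."""
    strand = read.strand if stranded else None
    hits = annots.overlapping(read.chrom, read.start, read.end, strand=strand)
    present = {f.biotype for f in hits}
    for bt in PRECEDENCE:
        if bt in present:
            return bt
    if "exon" in present or "intron" in present:
        return "mRNA"
    return "unannotated"


def length_histogram(rs: ReadSet, lo: int = 13, hi: int = 43) -> dict[int, int]:
    """Read counts for every length in [lo, hi]; out-of-range reads excluded."""
    if lo > hi:
        raise ValueError("lo must be <= hi")
    counts = {length: 0 for length in range(lo, hi + 1)}
    for r in rs:
        if lo <= r.length <= hi:
            counts[r.length] += r.copy_count
    return counts


def biotype_profile(
    rs: ReadSet, annots: AnnotationSet, lo: int = 13, hi: int = 43
) -> BiotypeProfile:
    """The library-composition view: length histogram plus biotype fractions."""
    lengths = range(lo, hi + 1)
    mat = pd.DataFrame(0, index=list(lengths), columns=list(REPORT_CATEGORIES))
    total = 0
    for r in rs:
        if not (lo <= r.length <= hi):
            continue
        bt = assign_biotype(r, annots)
        if bt == "rRNA":
            bt = "other_ncRNA"
        mat.loc[r.length, bt] += r.copy_count
        total += r.copy_count
    length_counts = mat.sum(axis=1).to_dict()
    if total > 0:
        fractions = (mat.sum(axis=0) / total).to_dict()
    else:
        fractions = {c: 0.0 for c in REPORT_CATEGORIES}
    return BiotypeProfile(
        length_counts=length_counts,
        biotype_fractions=fractions,
        length_by_biotype=mat,
        n_reads=total,
    )


def nucleotide_frequency(
    rs: ReadSet,
    len_range: tuple[int, int] = (26, 31),
    max_position: int = 31,
) -> NucleotideFrequencyProfile:
    """Per-position base fractions among reads within ``len_range``.

    Position ``p`` (1-based, read orientation) is computed over the reads long
    enough to have that position; N bases are ignored in the normalisation.
    """
    lo, hi = len_range
    counts = np.zeros((max_position, 4))
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    n = 0
    for r in rs:
        if not (lo <= r.length <= hi):
            continue
        n += r.copy_count
        for p, base in enumerate(r.sequence[:max_position]):
            j = base_idx.get(base)
            if j is not None:
                counts[p, j] += r.copy_count
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, counts / totals, np.nan)
    df = pd.DataFrame(
        frac, index=range(1, max_position + 1), columns=["A", "C", "G", "T"]
    )
    return NucleotideFrequencyProfile(fractions=df, n_reads=n, defined=n > 0)


def profile_tables(profile: BiotypeProfile) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TSV-ready tables: per-length counts and per-biotype fractions."""
    lengths = pd.DataFrame(
        {"length": list(profile.length_counts), "reads": list(profile.length_counts.values())}
    )
    fractions = pd.DataFrame(
        {
            "biotype": list(profile.biotype_fractions),
            "fraction": list(profile.biotype_fractions.values()),
        }
    )
    return lengths, fractions
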