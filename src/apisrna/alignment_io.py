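"""Readers and writers for alignments (SAM/BAM or TSV), GFF3 annotation
and sample sheets.

The TSV alignment alternative is a 7-column table:
``chrom  start  end  read_id  copy_count  strand  sequence``
with 0-based half-open coordinates, one row per alignment.

GFF3 conventions understood here:

* feature types ``gene``, ``exon``, ``rRNA``, ``tRNA``, ``pre_miRNA`` (or
  ``miRNA_primary_transcript``), ``transposable_element`` (or ``TE`` /
  ``repeat_region``), anything else -> ``other_ncRNA`` with a warning;
* TE lines carry ``te_class=I|II;te_family=<name>`` attributes;
* tRNA lines carry ``anticodon_start=<0-based offset>;cca=true|false`` and
  optionally ``isodecoder=<label>``.
"""

from __future__ import annotations

import logging
import os
from typing import Optional

import gffutils
import pandas as pd
import pysam

from .model import AlignedRead, AnnotationSet, Feature, ReadSet, revcomp

logger = logging.getLogger(__name__)

_GFF_TYPE_TO_BIOTYPE = {
    "gene": "gene",
    "exon": "exon",
    "intron": "intron",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "pre_miRNA": "pre_miRNA",
    "miRNA_primary_transcript": "pre_miRNA",
    "transposable_element": "TE",
    "TE": "TE",
    "repeat_region": "TE",
    "ncRNA": "other_ncRNA",
}


def read_alignments(
    path: str,
    min_len: int = 13,
    max_len: int = 43,
    sample_id: Optional[str] = None,
    tissue: str = "unknown",
) -> ReadSet:
    """Load alignments from SAM/BAM or the 7-column TSV alternative.

    Only primary alignments are retained; reads outside ``[min_len, max_len]``
    are dropped.  Records without a sequence are skipped (count logged).
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    sample_id = sample_id or os.path.splitext(os.path.basename(path))[0]
    ext = os.path.splitext(path)[1].lower()
    if ext in (".sam", ".bam", ".cram"):
        reads = _read_sam(path, min_len, max_len)
    else:
        reads = _read_tsv(path, min_len, max_len)
    rs = ReadSet(reads, sample_id=sample_id, tissue=tissue)
    rs.sort()
    return rs


def _read_sam(path: str, min_len: int, max_len: int) -> list[AlignedRead]:
    mode = "rb" if path.endswith(".bam") else "r"
    reads: list[AlignedRead] = []
    n_noseq = 0
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for i, rec in enumerate(fh):
            try:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                seq = rec.query_sequence
                if not seq:
                    n_noseq += 1
                    continue
                strand = "-" if rec.is_reverse else "+"
                if strand == "-":
                    seq = revcomp(seq)
                length = rec.reference_end - rec.reference_start
                if length < min_len or length > max_len:
                    continue
                n_hits = rec.get_tag("NH") if rec.has_tag("NH") else 1
                copies = rec.get_tag("XC") if rec.has_tag("XC") else 1
                reads.append(
                    AlignedRead(
                        read_id=rec.query_name,
                        sequence=seq.upper(),
                        chrom=rec.reference_name,
                        start=rec.reference_start,
                        end=rec.reference_end,
                        strand=strand,
                        n_hits=int(n_hits),
                        copy_count=int(copies),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"unparseable record {i} in {path}: {exc}") from exc
    if n_noseq:
        logger.warning("%s: skipped %d records without sequence", path, n_noseq)
    return reads


_TSV_COLS = ["chrom", "start", "end", "read_id", "copy_count", "strand", "sequence"]


def _read_tsv(path: str, min_len: int, max_len: int) -> list[AlignedRead]:
    df = pd.read_csv(path, sep="\t", names=_TSV_COLS, comment="#", dtype=str)
    reads = []
    n_noseq = 0
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            seq = row.sequence
            if not isinstance(seq, str) or not seq:
                n_noseq += 1
                continue
            start, end = int(row.start), int(row.end)
            if not (min_len <= end - start <= max_len):
                continue
            reads.append(
                AlignedRead(
                    read_id=str(row.read_id),
                    sequence=seq.upper(),
                    chrom=str(row.chrom),
                    start=start,
                    end=end,
                    strand=str(row.strand),
                    copy_count=int(row.copy_count),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"unparseable record at line {i + 1} of {path}: {exc}") from exc
    if n_noseq:
        logger.warning("%s: skipped %d records without sequence", path, n_noseq)
    return reads


def write_sam(rs: ReadSet, path: str, chrom_sizes: dict[str, int]) -> None:
    """Write a ReadSet as SAM, preserving copy counts in the XC tag."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_sizes.items()],
    }
    tid = {c: i for i, c in enumerate(chrom_sizes)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in sorted(rs, key=lambda x: (tid[x.chrom], x.start)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence if r.strand == "+" else revcomp(r.sequence)
            a.flag = 0 if r.strand == "+" else 16
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = 255
            a.cigarstring = f"{r.length}M"
            a.set_tag("NH", r.n_hits)
            a.set_tag("XC", r.copy_count)
            out.write(a)


def write_tsv(rs: ReadSet, path: str) -> None:
    df = pd.DataFrame(
        [
            (r.chrom, r.start, r.end, r.read_id, r.copy_count, r.strand, r.sequence)
            for r in rs
        ],
        columns=_TSV_COLS,
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def _first(attrs, *keys):
    for k in keys:
        if k in attrs:
            return attrs[k][0]
    return None


def read_annotations(gff_path: str) -> AnnotationSet:
    """Parse GFF3 into an AnnotationSet; introns are derived from exon gaps."""
    try:
        db = gffutils.create_db(
            gff_path,
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="create_unique",
            sort_attribute_values=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return AnnotationSet()
    annots = AnnotationSet()
    unknown_types = set()
    for rec in db.all_features():
        if rec.end < rec.start:
            raise ValueError(f"feature {rec.id}: end {rec.end} < start {rec.start}")
        biotype = _GFF_TYPE_TO_BIOTYPE.get(rec.featuretype)
        if biotype is None:
            bt_attr = _first(rec.attributes, "biotype", "gbkey")
            biotype = _GFF_TYPE_TO_BIOTYPE.get(bt_attr) if bt_attr else None
        if biotype is None:
            unknown_types.add(rec.featuretype)
            biotype = "other_ncRNA"
        attrs: dict = {}
        parent = _first(rec.attributes, "Parent")
        if parent:
            attrs["parent"] = parent
        if biotype == "TE":
            attrs["te_class"] = _first(rec.attributes, "te_class")
            attrs["te_family"] = _first(rec.attributes, "te_family") or "Other"
        if biotype == "tRNA":
            ac = _first(rec.attributes, "anticodon_start")
            attrs["anticodon_start"] = int(ac) if ac is not None else None
            cca = _first(rec.attributes, "cca")
            attrs["cca"] = str(cca).lower() == "true" if cca is not None else False
            iso = _first(rec.attributes, "isodecoder")
            if iso:
                attrs["isodecoder"] = iso
        annots.add(
            Feature(
                feature_id=rec.id or f"{rec.featuretype}:{rec.seqid}:{rec.start}",
                chrom=rec.seqid,
                start=rec.start - 1,  # GFF3 is 1-based inclusive
                end=rec.end,
                strand=rec.strand if rec.strand in ("+", "-") else "+",
                biotype=biotype,
                attributes=attrs,
            )
        )
    if unknown_types:
        logger.warning(
            "unknown GFF3 feature types categorised as other_ncRNA: %s",
            ", ".join(sorted(unknown_types)),
        )
    annots.derive_introns()
    return annots


def read_sample_sheet(path: str) -> pd.DataFrame:
    """Sample sheet TSV with columns sample_id, tissue, replicate, path."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "tissue", "replicate", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {sorted(missing)}")
    return df
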