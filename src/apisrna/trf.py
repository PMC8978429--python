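"""tRNA-fragment (tRF) positional classification and abundance tables.

Reads mapping sense to a tRNA gene are projected onto 1-based mature-tRNA
coordinates and assigned to one of five positional classes:

* ``five_tRH``  - 5' half: starts at the 5' terminus, ends in the anticodon loop
* ``three_tRH`` - 3' half: starts in the anticodon loop, ends at the 3' terminus
* ``five_tRF``  - starts at the 5' terminus, ends before the anticodon loop region
* ``three_tRF`` - ends at the 3' terminus, starts outside the anticodon loop
* ``i_tRF``     - internal fragment, everything else

The class boundaries are parameterised: 5'-start tolerance (s <= 2), 3'
terminus zone (the last three bases, accommodating the CCA tail) and an
anticodon loop window of anticodon_start +/- ``loop_halfwidth`` around the
three anticodon bases.  The five classes partition all valid (s, e) pairs.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .model import AlignedRead, AnnotationSet, Feature, ReadSet

logger = logging.getLogger(__name__)

TRF_CLASSES = ("five_tRH", "three_tRH", "five_tRF", "three_tRF", "i_tRF")

FIVE_START_MAX = 2    # s <= 2 counts as the 5' terminus
THREE_ZONE = 2        # e >= L - 2 counts as the 3' terminus
RUNOVER_MAX = 2       # <= 2 nt past the CCA is clipped, more is rejected


@dataclass(frozen=True)
class MatureTRNA:
    """A mature tRNA: length (CCA included when present) and anticodon position."""

    trna_id: str
    isodecoder: str       # e.g. GlyGCC
    length: int
    anticodon_start: int  # 1-based position of the anticodon's first base
    has_cca: bool = True

    def __post_init__(self) -> None:
        if not (1 < self.anticodon_start < self.length - 2):
            raise ValueError(
                f"{self.trna_id}: anticodon_start {self.anticodon_start} "
                f"outside (1, {self.length - 2})"
            )


@dataclass(frozen=True)
class TRFRecord:
    trna_id: str
    isodecoder: str
    start: int   # 1-based inclusive on the mature tRNA
    end: int
    trf_class: str
    copy_count: int


def mature_trna_from_feature(f: Feature) -> MatureTRNA:
    """Build a MatureTRNA from a tRNA annotation feature."""
    offset = f.attributes.get("anticodon_start")
    if offset is None:
        raise ValueError(f"tRNA feature {f.feature_id} lacks anticodon_start")
    return MatureTRNA(
        trna_id=f.feature_id,
        isodecoder=f.attributes.get("isodecoder", f.feature_id),
        length=f.length,
        anticodon_start=int(offset) + 1,  # attribute is a 0-based offset
        has_cca=bool(f.attributes.get("cca", False)),
    )


def map_to_mature(read: AlignedRead, trna: Feature) -> Optional[tuple[int, int]]:
    """Project a read onto 1-based mature-tRNA coordinates (strand-aware).

    Returns None for antisense reads, reads starting upstream of the tRNA,
    or reads running more than ``RUNOVER_MAX`` nt past the 3' end; runs of
    <= ``RUNOVER_MAX`` nt past the end are clipped to the mature length.
    """
    if read.strand != trna.strand:
        return None
    L = trna.length
    if trna.strand == "+":
        s = read.start - trna.start + 1
        e = read.end - trna.start
    else:
        s = trna.end - read.end + 1
        e = trna.end - read.start
    if s < 1:
        return None
    if e > L:
        if e - L > RUNOVER_MAX:
            return None
        e = L
    return s, e


def classify_trf(s: int, e: int, trna: MatureTRNA, loop_halfwidth: int = 3) -> str:
    """Assign the positional class of a fragment at mature coordinates (s, e)."""
    L = trna.length
    a = trna.anticodon_start
    loop_lo, loop_hi = a - loop_halfwidth, a + 2 + loop_halfwidth
    at_5p = s <= FIVE_START_MAX
    at_3p = e >= L - THREE_ZONE
    if at_5p and loop_lo <= e <= loop_hi:
        return "five_tRH"
    if at_3p and loop_lo <= s <= loop_hi:
        return "three_tRH"
    if at_5p and e < L - THREE_ZONE and not (loop_lo <= e <= loop_hi):
        return "five_tRF"
    if at_3p and not (loop_lo <= s <= loop_hi):
        return "three_tRF"
    return "i_tRF"


def classify_reads(
    rs: ReadSet, annots: AnnotationSet, loop_halfwidth: int = 3
) -> list[TRFRecord]:
    """Map every tRNA-overlapping read of a sample to mature coordinates and
    classify it; antisense or out-of-range reads are excluded (count logged)."""
    records: list[TRFRecord] = []
    n_excluded = 0
    for f in annots.by_biotype("tRNA"):
        trna = mature_trna_from_feature(f)
        for r in _reads_over(rs, f):
            pos = map_to_mature(r, f)
            if pos is None:
                n_excluded += 1
                continue
            s, e = pos
            records.append(
                TRFRecord(
                    trna_id=trna.trna_id,
                    isodecoder=trna.isodecoder,
                    start=s,
                    end=e,
                    trf_class=classify_trf(s, e, trna, loop_halfwidth),
                    copy_count=r.copy_count,
                )
            )
    if n_excluded:
        logger.info("%s: excluded %d antisense/out-of-range tRNA reads",
                    rs.sample_id, n_excluded)
    return records


def _reads_over(rs: ReadSet, f: Feature) -> Iterable[AlignedRead]:
    for r in rs:
        if r.chrom == f.chrom and r.start < f.end and r.end > f.start:
            yield r


def trf_abundance_table(
    records_by_sample: dict[str, list[TRFRecord]], top_k: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-sample tRF table.

    Returns (full table, top-k table).  tRFs are keyed by (trna_id, s, e);
    proportions are normalised within each sample's tRF total, so each
    sample column sums to 1 (all-zero columns are flagged by NaN).
    """
    counts: dict[tuple, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    classes: dict[tuple, str] = {}
    for sample, records in records_by_sample.items():
        for rec in records:
            key = (rec.trna_id, rec.isodecoder, rec.start, rec.end)
            counts[key][sample] += rec.copy_count
            classes[key] = rec.trf_class
    rows = []
    samples = list(records_by_sample)
    for key, per_sample in counts.items():
        trna_id, isodecoder, s, e = key
        row = {
            "trna_id": trna_id,
            "isodecoder": isodecoder,
            "start": s,
            "end": e,
            "trf_class": classes[key],
        }
        for sample in samples:
            row[sample] = per_sample.get(sample, 0)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df, df
    for sample in samples:
        total = df[sample].sum()
        df[f"{sample}_prop"] = df[sample] / total if total else float("nan")
    ref = samples[0]
    top = df.sort_values(f"{ref}_prop", ascending=False).head(top_k)
    return df.reset_index(drop=True), top.reset_index(drop=True)


def positional_abundance(
    records: Iterable[TRFRecord], isodecoder: str, length: int
) -> pd.DataFrame:
    """Copy-weighted coverage of an isodecoder's mature positions by its tRFs."""
    depth = [0] * length
    for rec in records:
        if rec.isodecoder != isodecoder:
            continue
        for pos in range(rec.start, min(rec.end, length) + 1):
            depth[pos - 1] += rec.copy_count
    return pd.DataFrame({"position": range(1, length + 1), "reads": depth})
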