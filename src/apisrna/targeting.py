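"""Strand-aware counting of putative piRNAs over TEs, exons, introns and
intergenic space; TE class/family tables; chi-squared tissue comparisons;
and differential antisense targeting of genes/TEs.

Each read is assigned to at most one category by the precedence
TE > exon > intron (configurable); a read counts toward a feature when the
overlap covers at least half the read.  Orientation relative to the feature
strand is recorded as sense/antisense.  Intergenic reads are whatever is
left: assigned + intergenic = total, exactly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import AlignedRead, AnnotationSet, Feature, ReadSet

DEFAULT_PRECEDENCE = ("TE", "exon", "intron")
MIN_OVERLAP_FRACTION = 0.5


@dataclass
class TargetingTable:
    """Per-feature sense/antisense counts plus per-category totals."""

    per_feature: pd.DataFrame   # feature_id, category, te_class, te_family, sense, antisense
    assigned: int
    intergenic: int
    total: int

    def category_counts(self) -> pd.DataFrame:
        g = (
            self.per_feature.groupby("category")[["sense", "antisense"]]
            .sum()
            .reset_index()
        )
        return g


def _assign_read(
    read: AlignedRead,
    annots: AnnotationSet,
    precedence: Sequence[str],
    min_overlap: float,
) -> Optional[Feature]:
    hits = annots.overlapping(read.chrom, read.start, read.end)
    need = min_overlap * read.length
    eligible = [
        f
        for f in hits
        if f.biotype in precedence
        and (min(read.end, f.end) - max(read.start, f.start)) >= need
    ]
    if not eligible:
        return None
    rank = {bt: i for i, bt in enumerate(precedence)}
    eligible.sort(key=lambda f: (rank[f.biotype], f.start, f.feature_id))
    return eligible[0]


def count_feature_reads(
    rs: ReadSet,
    annots: AnnotationSet,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    min_overlap: float = MIN_OVERLAP_FRACTION,
) -> TargetingTable:
    """Assign each read to at most one feature by category precedence and
    tally sense/antisense counts (copy-weighted)."""
    sense: dict[str, int] = defaultdict(int)
    anti: dict[str, int] = defaultdict(int)
    meta: dict[str, Feature] = {}
    assigned = 0
    total = 0
    for r in rs:
        total += r.copy_count
        f = _assign_read(r, annots, precedence, min_overlap)
        if f is None:
            continue
        assigned += r.copy_count
        meta[f.feature_id] = f
        if r.strand == f.strand:
            sense[f.feature_id] += r.copy_count
        else:
            anti[f.feature_id] += r.copy_count
    rows = []
    for fid, f in sorted(meta.items()):
        rows.append(
            {
                "feature_id": fid,
                "category": f.biotype,
                "te_class": f.attributes.get("te_class"),
                "te_family": f.attributes.get("te_family"),
                "sense": sense.get(fid, 0),
                "antisense": anti.get(fid, 0),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["feature_id", "category", "te_class", "te_family", "sense", "antisense"],
    )
    return TargetingTable(
        per_feature=df, assigned=assigned, intergenic=total - assigned, total=total
    )


def intergenic_count(rs: ReadSet, table: TargetingTable) -> int:
    """Putative piRNAs minus feature-assigned reads; must be non-negative."""
    n = rs.n_alignments() - table.assigned
    if n < 0:
        raise RuntimeError("assigned reads exceed total: double counting bug")
    return n


def te_family_table(table: TargetingTable) -> pd.DataFrame:
    """Percentage of TE-mapped piRNAs per TE family (sums to 100)."""
    te = table.per_feature[table.per_feature["category"] == "TE"].copy()
    if te.empty:
        return pd.DataFrame(columns=["te_class", "te_family", "reads", "percent"])
    te["reads"] = te["sense"] + te["antisense"]
    g = te.groupby(["te_class", "te_family"], dropna=False)["reads"].sum().reset_index()
    total = g["reads"].sum()
    g["percent"] = 100.0 * g["reads"] / total
    return g.sort_values("percent", ascending=False).reset_index(drop=True)


def te_class_counts(table: TargetingTable) -> tuple[int, int]:
    """(class I, class II) TE-mapped read counts."""
    te = table.per_feature[table.per_feature["category"] == "TE"]
    reads = te["sense"] + te["antisense"]
    c1 = int(reads[te["te_class"] == "I"].sum())
    c2 = int(reads[te["te_class"] == "II"].sum())
    return c1, c2


def compare_class_proportions(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> tuple[float, int, float, bool]:
    """Pearson chi-squared (no continuity correction) on the 2x2 table of
    (class I, class II) x (tissue A, tissue B) read counts.

    Returns (chi2, df, p, expected_ok); ``expected_ok`` is False when any
    expected cell is below 1.
    """
    obs = np.array([counts_a, counts_b], dtype=float)
    if obs.sum() == 0 or (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        return 0.0, 1, 1.0, False
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(dof), float(p), bool((expected >= 1).all())


def antisense_count_matrix(
    tables_by_sample: dict[str, TargetingTable],
    categories: Sequence[str] = ("TE", "exon", "intron"),
) -> pd.DataFrame:
    """Feature x sample matrix of antisense read counts (for differential
    targeting via the exact test)."""
    samples = list(tables_by_sample)
    features: set[str] = set()
    for t in tables_by_sample.values():
        sub = t.per_feature[t.per_feature["category"].isin(categories)]
        features |= set(sub["feature_id"])
    mat = pd.DataFrame(0, index=sorted(features), columns=samples)
    for sample, t in tables_by_sample.items():
        sub = t.per_feature[t.per_feature["category"].isin(categories)]
        for fid, count in zip(sub["feature_id"], sub["antisense"]):
            mat.loc[fid, sample] = count
    return mat


def differential_targeting(
    antisense_matrix: pd.DataFrame,
    sample_tissues: dict[str, str],
    tissue_pair: tuple[str, str],
    fdr_max: float = 0.01,
    fc_min: float = 5.0,
    min_count: float = 5.0,
    top_k: int = 10,
):
    """Differentially targeted genes/TEs between two tissues: features with
    significantly more antisense piRNAs in one tissue than the other, by the
    negative-binomial exact test at the standard thresholds."""
    from .diffexp import CountMatrix, call_de

    cm = CountMatrix(antisense_matrix, sample_tissues)
    result = call_de(cm, tissue_pair, fdr_max=fdr_max, fc_min=fc_min, min_count=min_count)
    de = result.table[result.table["de"]].copy()
    de = de.sort_values(["fdr", "p_value"]).head(top_k) if top_k else de
    return result, de
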