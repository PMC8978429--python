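"""Strand-aware feature targeting, TE tables, chi-squared comparisons."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from apisrna import (
    AnnotationSet,
    Feature,
    compare_class_proportions,
    count_feature_reads,
    differential_targeting,
    intergenic_count,
    simulate_tissue_library,
    te_family_table,
)
from apisrna.targeting import antisense_count_matrix, te_class_counts
from conftest import make_reads


def _annots(features):
    a = AnnotationSet(features)
    a.derive_introns()
    return a


TE_MINUS = Feature("te1", "c", 100, 600, "-", "TE", {"te_class": "II", "te_family": "Mariner/TC1"})
TE_PLUS = Feature("te2", "c", 5000, 5600, "+", "TE", {"te_class": "I", "te_family": "R2"})
GENE = Feature("g1", "c", 2000, 3400, "+", "gene", {})
EXON1 = Feature("g1.e1", "c", 2000, 2400, "+", "exon", {"parent": "g1"})
EXON2 = Feature("g1.e2", "c", 3000, 3400, "+", "exon", {"parent": "g1"})


class TestCountFeatureReads:
    def test_plus_read_in_minus_te_is_antisense(self):
        annots = _annots([TE_MINUS])
        rs = make_reads([("c", 200, 28, "+")])
        table = count_feature_reads(rs, annots)
        row = table.per_feature.iloc[0]
        assert row["antisense"] == 1 and row["sense"] == 0

    def test_te_precedence_over_exon(self):
        te_on_exon = Feature("te3", "c", 2000, 2400, "+", "TE",
                             {"te_class": "II", "te_family": "PiggyBac"})
        annots = _annots([GENE, EXON1, EXON2, te_on_exon])
        rs = make_reads([("c", 2100, 28, "+")])
        table = count_feature_reads(rs, annots)
        assert table.per_feature.iloc[0]["category"] == "TE"

    def test_half_overlap_rule(self):
        annots = _annots([TE_MINUS])
        # read of 28 nt with only 10 nt inside the TE -> unassigned
        rs = make_reads([("c", 590, 28, "+")])
        table = count_feature_reads(rs, annots)
        assert table.assigned == 0 and table.intergenic == 1

    def test_conservation_assigned_plus_intergenic(self, ovary_library, annots):
        from apisrna import filter_putative_pirnas

        rs, _ = ovary_library
        sized = filter_putative_pirnas(rs, annots, length_filter=True)
        table = count_feature_reads(sized, annots)
        assert table.assigned + table.intergenic == sized.n_alignments()
        assert intergenic_count(sized, table) == table.intergenic

    def test_orientation_flip_swaps_columns(self):
        annots = _annots([TE_MINUS, TE_PLUS])
        rs = make_reads([("c", 200, 28, "+"), ("c", 5100, 28, "+"),
                         ("c", 5200, 28, "-")])
        table = count_feature_reads(rs, annots)
        flipped = _annots(
            [
                Feature(f.feature_id, f.chrom, f.start, f.end,
                        "-" if f.strand == "+" else "+", f.biotype, f.attributes)
                for f in [TE_MINUS, TE_PLUS]
            ]
        )
        table_f = count_feature_reads(rs, flipped)
        merged = table.per_feature.merge(
            table_f.per_feature, on="feature_id", suffixes=("", "_f")
        )
        assert (merged["sense"] == merged["antisense_f"]).all()
        assert (merged["antisense"] == merged["sense_f"]).all()

    def test_precedence_change_conserves_assigned_total(self):
        te_on_exon = Feature("te3", "c", 2000, 2400, "+", "TE",
                             {"te_class": "II", "te_family": "PiggyBac"})
        annots = _annots([GENE, EXON1, EXON2, te_on_exon])
        rs = make_reads([("c", 2100, 28, "+"), ("c", 2500, 28, "+"),
                         ("c", 3100, 28, "-")])
        t1 = count_feature_reads(rs, annots, precedence=("TE", "exon", "intron"))
        t2 = count_feature_reads(rs, annots, precedence=("exon", "intron", "TE"))
        assert t1.assigned == t2.assigned


class TestTeTables:
    def test_single_family_is_hundred_percent(self):
        annots = _annots([TE_PLUS])
        rs = make_reads([("c", 5100, 28, "+")])
        fam = te_family_table(count_feature_reads(rs, annots))
        assert fam["percent"].tolist() == [100.0]

    def test_percent_arithmetic(self):
        annots = _annots([TE_MINUS, TE_PLUS])
        specs = [("c", 120 + i % 300, 28, "+") for i in range(690)]
        specs += [("c", 5100 + i % 300, 28, "+") for i in range(310)]
        fam = te_family_table(count_feature_reads(rs := make_reads(specs), annots))
        by_family = dict(zip(fam["te_family"], fam["percent"]))
        assert by_family["Mariner/TC1"] == pytest.approx(69.0)
        assert by_family["R2"] == pytest.approx(31.0)
        assert fam["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_family_percentages_sum_to_hundred_on_synthetic(self, ovary_library, annots):
        from apisrna import filter_putative_pirnas

        rs, _ = ovary_library
        sized = filter_putative_pirnas(rs, annots, length_filter=True)
        fam = te_family_table(count_feature_reads(sized, annots))
        assert fam["percent"].sum() == pytest.approx(100.0, abs=0.1)


class TestChiSquared:
    def test_identical_proportions(self):
        chi2, df, p, ok = compare_class_proportions((50, 50), (500, 500))
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0) and df == 1

    def test_hand_computed_example(self):
        # [[90,10],[50,50]] -> expected 70/30 rows -> chi2 = 38.095
        chi2, df, p, ok = compare_class_proportions((90, 10), (50, 50))
        assert chi2 == pytest.approx(800 / 21, rel=1e-9)
        assert p < 1e-9 and ok

    def test_low_expected_cell_flagged(self):
        _, _, _, ok = compare_class_proportions((1, 0), (0, 1))
        assert not ok

    def test_class_counts_from_synthetic(self, ovary_library, annots):
        from apisrna import filter_putative_pirnas

        rs, _ = ovary_library
        sized = filter_putative_pirnas(rs, annots, length_filter=True)
        c1, c2 = te_class_counts(count_feature_reads(sized, annots))
        assert c1 > 0 and c2 > 0  # both classes planted inside clusters


class TestDifferentialTargeting:
    def _matrices(self, seed=14, fold=10.0):
        rng = np.random.default_rng(seed)
        features = [f"feat{i}" for i in range(40)]
        samples = {f"a{i}": "tisA" for i in range(3)} | {
            f"b{i}": "tisB" for i in range(3)
        }
        base = rng.poisson(40, size=(40, 6)).astype(float)
        base[0, :3] *= fold  # planted antisense enrichment in tisA
        mat = pd.DataFrame(base.astype(int), index=features, columns=list(samples))
        return mat, samples

    def test_planted_enrichment_called_with_direction(self):
        mat, samples = self._matrices()
        result, top = differential_targeting(mat, samples, ("tisA", "tisB"))
        assert result.table.loc["feat0", "de"]
        assert result.table.loc["feat0", "direction"] == "tisA"
        assert "feat0" in top.index

    def test_label_swap_maps_up_t1_to_up_t2(self):
        mat, samples = self._matrices()
        r1, _ = differential_targeting(mat, samples, ("tisA", "tisB"))
        r2, _ = differential_targeting(mat, samples, ("tisB", "tisA"))
        # the winning tissue is unchanged, only the t1/t2 bookkeeping swaps
        assert (r1.table["direction"] == r2.table["direction"]).all()
        assert r1.summary["n_up_t1"] == r2.summary["n_up_t2"]
        assert r1.summary["n_up_t2"] == r2.summary["n_up_t1"]

    def test_zero_count_feature_never_called(self):
        mat, samples = self._matrices()
        mat.loc["feat39"] = 0
        result, _ = differential_targeting(mat, samples, ("tisA", "tisB"))
        assert not result.table.loc["feat39", "de"]

    def test_antisense_matrix_assembles_from_tables(self, genome, config, annots):
        from apisrna import count_feature_reads, filter_putative_pirnas

        tables = {}
        for seed, sample in [(1, "ovary_a"), (2, "ovary_b")]:
            rs, _ = simulate_tissue_library(
                genome, config.profiles["ovary"], config.trf_mixture,
                n_reads=2000, seed=seed, sample_id=sample,
            )
            sized = filter_putative_pirnas(rs, annots, length_filter=True)
            tables[sample] = count_feature_reads(sized, annots)
        mat = antisense_count_matrix(tables)
        assert set(mat.columns) == {"ovary_a", "ovary_b"}
        assert (mat.to_numpy() >= 0).all() and mat.to_numpy().sum() > 0
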