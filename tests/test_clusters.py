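"""Cluster calling: oracle equivalence, rule boundaries, planted recovery."""

from __future__ import annotations

import numpy as np
import pytest

from apisrna import (
    ClusterParams,
    assign_strandedness,
    call_clusters,
    cluster_overlap_sets,
    cluster_read_fractions,
    collapse_reads,
    coverage_track,
    filter_putative_pirnas,
    filter_size_fraction,
    merge_and_min_length,
    pirna_clusters,
    simulate_tissue_library,
)
from apisrna.clusters import PiRNACluster
from conftest import make_reads, random_reads
from oracles import brute_force_islands, brute_force_merge


def _intervals(clusters):
    return sorted((c.chrom, c.start, c.end) for c in clusters)


def _mk_clusters(intervals):
    return [
        PiRNACluster(cluster_id=f"c{i}", chrom=c, start=s, end=e)
        for i, (c, s, e) in enumerate(intervals)
    ]


class TestFilterPutative:
    def test_ncrna_reads_removed_regardless_of_length(self, annots):
        rs = make_reads([("chr1", 170_010, 29, "+")])  # inside tRNA-Gly1
        assert len(filter_putative_pirnas(rs, annots)) == 0

    def test_length_filter_drops_short_reads(self, annots):
        rs = make_reads([("chr1", 50, 25, "+"), ("chr1", 500, 29, "+")])
        assert len(filter_putative_pirnas(rs, annots, length_filter=True)) == 1
        assert len(filter_putative_pirnas(rs, annots, length_filter=False)) == 2

    def test_survivors_match_manifest(self, ovary_library, annots):
        rs, truth = ovary_library
        surviving = filter_putative_pirnas(rs, annots, length_filter=False)
        expected = sum(
            n
            for bt, n in truth["expected_biotype_counts"].items()
            if bt in ("mRNA", "unannotated")
        )
        assert len(surviving) == expected


class TestCallClusters:
    def test_single_island_by_construction(self):
        rng = np.random.default_rng(0)
        starts = sorted(rng.integers(0, 2000, size=40))
        rs = make_reads([("c", int(s), 28, "+") for s in starts])
        clusters = call_clusters(rs)
        assert len(clusters) == 1
        assert clusters[0].start == min(starts)

    def test_below_min_reads_no_cluster(self):
        rs = make_reads([("c", i * 30, 28, "+") for i in range(10)])
        assert call_clusters(rs) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_island_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rs = random_reads(rng, 400, chrom_len=30_000)
        params = ClusterParams(max_gap=500, min_reads=10, min_density=2.0)
        got = _intervals(call_clusters(rs, params))
        expected = brute_force_islands(
            collapse_reads(rs), params.max_gap, params.min_reads, params.min_density
        )
        assert got == expected


class TestSizeFraction:
    def _cluster_with_fraction(self, origin, n_in, n_out):
        specs = [("c", origin + 3 * i, 28, "+") for i in range(n_in)]
        specs += [("c", origin + 3 * i + 1, 20, "+") for i in range(n_out)]
        return specs

    def test_boundary_half_retained_below_removed(self):
        specs = self._cluster_with_fraction(0, 40, 60)       # 0.40 -> removed
        specs += self._cluster_with_fraction(10_000, 50, 50)  # 0.50 -> retained
        rs = make_reads(specs)
        clusters = _mk_clusters([("c", 0, 200), ("c", 10_000, 10_200)])
        kept = filter_size_fraction(clusters, rs)
        assert _intervals(kept) == [("c", 10_000, 10_200)]
        assert kept[0].size_fraction == pytest.approx(0.5)

    def test_planted_fractions(self):
        planted = {0: 0.3, 20_000: 0.6, 40_000: 0.9}
        specs = []
        for origin, frac in planted.items():
            n_in = int(round(100 * frac))
            specs += self._cluster_with_fraction(origin, n_in, 100 - n_in)
        rs = make_reads(specs)
        clusters = _mk_clusters([("c", o, o + 400) for o in planted])
        kept = filter_size_fraction(clusters, rs)
        assert sorted(round(c.size_fraction, 2) for c in kept) == [0.6, 0.9]


class TestMerge:
    def test_gap_at_most_1kb_merges(self):
        merged = merge_and_min_length(_mk_clusters([("c", 100, 400), ("c", 1300, 1500)]))
        assert _intervals(merged) == [("c", 100, 1500)]

    def test_short_cluster_removed(self):
        assert merge_and_min_length(_mk_clusters([("c", 0, 150)])) == []

    def test_gap_above_threshold_not_merged(self):
        merged = merge_and_min_length(_mk_clusters([("c", 0, 400), ("c", 1401, 1800)]))
        assert len(merged) == 2

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        intervals = []
        for _ in range(60):
            chrom = "c" + str(rng.integers(2))
            s = int(rng.integers(0, 50_000))
            intervals.append((chrom, s, s + int(rng.integers(200, 2000))))
        got = _intervals(merge_and_min_length(_mk_clusters(intervals), min_len=0))
        assert got == brute_force_merge(intervals, 1000)

    def test_idempotent(self):
        rng = np.random.default_rng(42)
        intervals = []
        for _ in range(40):
            s = int(rng.integers(0, 40_000))
            intervals.append(("c", s, s + int(rng.integers(250, 1500))))
        once = merge_and_min_length(_mk_clusters(intervals))
        twice = merge_and_min_length(once)
        assert _intervals(once) == _intervals(twice)


class TestStrandedness:
    def test_more_than_double_is_strict(self):
        assert assign_strandedness({"t": (21, 10)}) == "plus"
        assert assign_strandedness({"t": (20, 10)}) == "bidirectional"
        assert assign_strandedness({"t": (10, 21)}) == "minus"

    def test_all_tissues_conjunction(self):
        assert (
            assign_strandedness({"a": (30, 5), "b": (8, 5)}) == "bidirectional"
        )
        assert assign_strandedness({"a": (30, 5), "b": (11, 5)}) == "plus"

    def test_undetected_tissue_ignored(self):
        assert assign_strandedness({"a": (30, 5), "b": (0, 0)}) == "plus"

    def test_zero_everywhere_raises(self):
        with pytest.raises(ValueError):
            assign_strandedness({"a": (0, 0)})


class TestReadFractions:
    def test_fraction_arithmetic(self):
        specs = [("c", 3 * i, 28, "+") for i in range(75)]
        specs += [("c", 10_000 + 3 * i, 28, "+") for i in range(25)]
        rs = make_reads(specs)
        clusters = _mk_clusters([("c", 0, 300), ("c", 10_000, 10_300)])
        df, clustered_fraction = cluster_read_fractions(clusters, rs)
        assert df["fraction_of_clustered"].tolist() == pytest.approx([0.75, 0.25])
        assert clustered_fraction == 1.0

    def test_no_clusters(self):
        rs = make_reads([("c", 0, 28, "+")])
        df, clustered_fraction = cluster_read_fractions([], rs)
        assert clustered_fraction == 0.0 and df.empty


class TestOverlapSets:
    def test_same_interval_two_tissues(self):
        per_tissue = {
            "ovary": _mk_clusters([("c", 0, 500)]),
            "egg": _mk_clusters([("c", 0, 500)]),
        }
        unified = cluster_overlap_sets(per_tissue)
        assert len(unified) == 1
        assert unified[0].tissues_detected == {"ovary", "egg"}

    def test_distant_intervals_stay_tissue_specific(self):
        per_tissue = {
            "ovary": _mk_clusters([("c", 0, 500)]),
            "egg": _mk_clusters([("c", 5000, 5500)]),
        }
        unified = cluster_overlap_sets(per_tissue)
        assert sorted(len(c.tissues_detected) for c in unified) == [1, 1]

    def test_membership_matches_union_find(self):
        rng = np.random.default_rng(21)
        per_tissue = {}
        all_intervals = []
        for tissue in ("a", "b", "c"):
            intervals = []
            for _ in range(20):
                s = int(rng.integers(0, 60_000))
                intervals.append(("c1", s, s + int(rng.integers(200, 1200))))
            per_tissue[tissue] = _mk_clusters(intervals)
            all_intervals += intervals
        unified = cluster_overlap_sets(per_tissue)
        assert _intervals(unified) == brute_force_merge(all_intervals, 1000)


class TestCoverage:
    def test_zero_and_single_read_values(self):
        cluster = PiRNACluster("c1", "c", 0, 100)
        rs = make_reads([("c", 10, 28, "+")])
        tracks = coverage_track(cluster, rs, total_mapped=1_000_000)
        assert tracks["+"][0] == 0.0
        assert tracks["+"][10] == pytest.approx(np.log10(2.0))
        assert tracks["-"].sum() == 0.0

    def test_track_conserves_length_weighted_rpm(self):
        rng = np.random.default_rng(9)
        rs = random_reads(rng, 100, chrom_len=900, chroms=("c",))
        cluster = PiRNACluster("c1", "c", 0, 1000)
        total = rs.n_alignments()
        tracks = coverage_track(cluster, rs, total)
        recovered = sum((10 ** tracks[s] - 1).sum() for s in "+-")
        expected = sum(r.length * r.copy_count for r in rs) * 1e6 / total
        assert recovered == pytest.approx(expected, rel=1e-9)


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", [1, 2])
    def test_planted_clusters_recovered(self, seed, config, genome, annots):
        rs, _ = simulate_tissue_library(
            genome, config.profiles["ovary"], config.trf_mixture,
            n_reads=5000, seed=seed, sample_id=f"ovary_s{seed}",
        )
        final, _ = pirna_clusters(rs, annots)
        planted = [(c.chrom, c.start, c.end) for c in genome.clusters]
        called = _intervals(final)
        matched = 0
        for pc, ps, pe in planted:
            for cc, cs, ce in called:
                inter = max(0, min(pe, ce) - max(ps, cs))
                union = max(pe, ce) - min(ps, cs)
                if cc == pc and inter / union >= 0.5:
                    matched += 1
                    break
        assert matched >= 0.9 * len(planted)
        assert len(called) <= len(planted) + 1

    def test_final_clusters_satisfy_filters(self, config, genome, annots):
        rs, _ = simulate_tissue_library(
            genome, config.profiles["ovary"], config.trf_mixture,
            n_reads=5000, seed=3, sample_id="ovary_post",
        )
        final, _ = pirna_clusters(rs, annots)
        assert final, "expected clusters from a piRNA-rich library"
        for c in final:
            assert c.length >= 200
            assert c.size_fraction >= 0.5
            assert c.plus_collapsed + c.minus_collapsed >= 1

    def test_planted_strand_modes_called_correctly(self, config, genome, annots):
        rs, _ = simulate_tissue_library(
            genome, config.profiles["ovary"], config.trf_mixture,
            n_reads=8000, seed=4, sample_id="ovary_strand",
        )
        final, _ = pirna_clusters(rs, annots)
        mode_of = {}
        for spec in genome.clusters:
            mid = (spec.start + spec.end) // 2
            for c in final:
                if c.start <= mid < c.end:
                    mode_of[spec.strand_mode] = mode_of.get(spec.strand_mode, [])
                    mode_of[spec.strand_mode].append(c.strand_call)
        for call in mode_of.get("uni_plus", []):
            assert call == "plus"
        for call in mode_of.get("uni_minus", []):
            assert call == "minus"
        for call in mode_of.get("bidirectional", []):
            assert call == "bidirectional"
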