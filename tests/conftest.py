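from __future__ import annotations

import numpy as np
import pytest

from apisrna import (
    AlignedRead,
    ReadSet,
    default_config,
    make_toy_genome,
    read_annotations,
    simulate_tissue_library,
)
from apisrna.simulate import ClusterSpec, TissueProfile, write_gff3


@pytest.fixture(scope="session")
def config():
    return default_config(seed=1)


@pytest.fixture(scope="session")
def genome(config):
    return make_toy_genome(config)


@pytest.fixture(scope="session")
def annots(genome, tmp_path_factory):
    gff = tmp_path_factory.mktemp("gff") / "annotation.gff3"
    write_gff3(genome, str(gff))
    return read_annotations(str(gff))


@pytest.fixture(scope="session")
def ovary_library(genome, config):
    rs, truth = simulate_tissue_library(
        genome, config.profiles["ovary"], config.trf_mixture, seed=1,
        sample_id="ovary_1",
    )
    return rs, truth


@pytest.fixture(scope="session")
def semen_library(genome, config):
    rs, truth = simulate_tissue_library(
        genome, config.profiles["semen"], config.trf_mixture, seed=2,
        sample_id="semen_1",
    )
    return rs, truth


def make_reads(specs, **kw):
    """Compact ReadSet builder: specs = (chrom, start, length, strand[, seq])."""
    reads = []
    for i, spec in enumerate(specs):
        chrom, start, length, strand = spec[:4]
        seq = spec[4] if len(spec) > 4 else "A" * length
        reads.append(
            AlignedRead(
                read_id=f"r{i}",
                sequence=seq,
                chrom=chrom,
                start=start,
                end=start + length,
                strand=strand,
            )
        )
    return ReadSet(reads, **kw)


def random_reads(rng, n, chrom_len=20_000, lengths=(20, 35), chroms=("c1", "c2")):
    """Uniform random reads for oracle-equivalence tests."""
    reads = []
    for i in range(n):
        length = int(rng.integers(lengths[0], lengths[1] + 1))
        start = int(rng.integers(0, chrom_len - length))
        reads.append(
            AlignedRead(
                read_id=f"r{i}",
                sequence="A" * length,
                chrom=chroms[int(rng.integers(len(chroms)))],
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
                copy_count=int(rng.integers(1, 4)),
            )
        )
    rs = ReadSet(reads)
    rs.sort()
    return rs


from functools import lru_cache


@lru_cache(maxsize=12)
def single_cluster_genome(
    seed, strand_mode, u1_bias, pingpong_fraction, phased_fraction,
    span=4_000, chrom_size=200_000,
):
    """Toy genome whose only piRNA source is one planted cluster."""
    cfg = default_config(seed)
    cfg.chrom_sizes = {"chr1": chrom_size}
    cfg.clusters = [
        ClusterSpec(
            cluster_id="only",
            chrom="chr1",
            start=50_000,
            end=50_000 + span,
            strand_mode=strand_mode,
            weight=1.0,
            u1_bias=u1_bias,
            pingpong_fraction=pingpong_fraction,
            phased_fraction=phased_fraction,
        )
    ]
    return make_toy_genome(cfg), cfg


def single_cluster_library(
    seed,
    n_reads,
    strand_mode="bidirectional",
    u1_bias=0.25,
    pingpong_fraction=0.0,
    phased_fraction=0.0,
    sample_id="lib_1",
    span=4_000,
    chrom_size=200_000,
):
    """A library whose piRNA reads all come from one planted cluster
    (used by the signature planted-vs-null simulations)."""
    g, cfg = single_cluster_genome(
        seed, strand_mode, u1_bias, pingpong_fraction, phased_fraction,
        span, chrom_size,
    )
    profile = TissueProfile(
        tissue="synthetic", mirna=0.0, pirna=1.0, trf=0.0, background=0.0,
        library_size=n_reads,
    )
    rs, truth = simulate_tissue_library(
        g, profile, cfg.trf_mixture, n_reads=n_reads, seed=seed,
        sample_id=sample_id,
    )
    return rs, truth


@lru_cache(maxsize=4)
def pingpong_null_small_z_count(n_rep=100):
    """Replicates of a pair-free bidirectional cluster in which the ping-pong
    Z stays below 2 (or is undefined).  The 20 kb / 2000-read design keeps
    per-bin pair counts high so the studentized Z is close to normal."""
    import numpy as np
    from apisrna import pingpong_overlap_histogram, pingpong_zscore

    small = 0
    for i in range(n_rep):
        rs, _ = single_cluster_library(
            seed=8, n_reads=2000, strand_mode="bidirectional",
            pingpong_fraction=0.0, sample_id=f"ppnull_{i}", span=20_000,
        )
        z = pingpong_zscore(pingpong_overlap_histogram(rs, weighted=False))
        if not np.isfinite(z) or abs(z) < 2:
            small += 1
    return small


@lru_cache(maxsize=4)
def phasing_null_small_z_count(n_rep=100):
    """Replicates of uniform random 5' ends (no phasing) in which the phasing
    Z stays below 2.  Intermediate density (1000 reads over 400 kb) keeps the
    exponential nearest-neighbour gap distribution approximately flat across
    the 1-50 nt window, so the d=1 bin is not enriched under the null."""
    import numpy as np
    from apisrna import phasing_distance_histogram, phasing_zscore

    small = 0
    for i in range(n_rep):
        rs, _ = single_cluster_library(
            seed=10, n_reads=1000, strand_mode="uni_plus",
            phased_fraction=0.0, sample_id=f"phnull_{i}",
            span=400_000, chrom_size=600_000,
        )
        z, _ = phasing_zscore(phasing_distance_histogram(rs))
        if not np.isfinite(z) or abs(z) < 2:
            small += 1
    return small
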