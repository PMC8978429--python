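"""Synthetic toy genome and small-RNA library generator.

The generator plants every structure the analysis downstream is meant to
recover, and writes a machine-readable truth manifest alongside:

* a random toy genome with TE remnants (class I families Copia, Gypsy,
  BelPao, R2, Jockey, I; class II Mariner/TC1, PiggyBac), protein-coding
  genes with exons and introns, tRNA genes (CCA-terminated, with anticodon
  positions), miRNA hairpins and an rRNA locus;
* designated piRNA cluster intervals, uni- or bi-directional, each with a
  planted 1U bias, ping-pong pair fraction and phased-trail fraction;
* per-tissue read libraries mixing miRNA-sized (21-23 nt), piRNA-sized
  (26-31 nt, mode 29), tRF (32-33 nt dominated) and background reads.

Tissue profiles default to reproductive-tissue-like mixtures: a semen-like
library dominated by tRFs (~60%), testis-like dominated by miRNAs (~82%),
ovary/egg-like dominated by 29-nt piRNA-sized reads.  The background
category models unclustered piRNA-sized degradation rain; its default rate
is set per kilobase of toy genome so that, as in germline tissue data, the
overwhelming majority of piRNA-sized reads fall inside clusters.

All randomness flows from numpy Generators seeded per library as
(master seed, CRC32 of the sample id), so adding a sample never perturbs
the reads of another.  Fixed seeds give byte-identical output files.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import AlignedRead, Feature, ReadSet, revcomp
from .trf import MatureTRNA

PIRNA_LENGTHS = np.arange(26, 32)
PIRNA_LENGTH_WEIGHTS = np.array([0.05, 0.10, 0.20, 0.40, 0.15, 0.10])  # mode 29 nt
MIRNA_LENGTHS = np.arange(21, 24)
MIRNA_LENGTH_WEIGHTS = np.array([0.25, 0.50, 0.25])
BACKGROUND_LENGTHS = np.arange(13, 44)


@dataclass
class ClusterSpec:
    """A planted piRNA cluster and its biogenesis parameters."""

    cluster_id: str
    chrom: str
    start: int
    end: int
    strand_mode: str          # uni_plus / uni_minus / bidirectional
    weight: float             # share of the library's piRNA reads
    u1_bias: float = 0.8
    pingpong_fraction: float = 0.0
    phased_fraction: float = 0.1


@dataclass
class TissueProfile:
    """Mixture weights over read categories for one tissue."""

    tissue: str
    mirna: float
    pirna: float
    trf: float
    background: float
    library_size: int = 5000

    def __post_init__(self) -> None:
        total = self.mirna + self.pirna + self.trf + self.background
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.tissue}: mixture weights sum to {total}, not 1")


@dataclass
class SimulationConfig:
    seed: int = 1
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 200_000})
    clusters: list = field(default_factory=list)
    profiles: dict = field(default_factory=dict)
    trf_mixture: list = field(default_factory=list)  # (isodecoder, s, e, weight)
    include_tes: bool = True


@dataclass
class ToyGenome:
    seqs: dict
    features: list          # Feature records (GFF-level truth)
    trnas: list             # MatureTRNA records
    clusters: list          # ClusterSpec
    chrom_sizes: dict
    manifest: dict

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        s = self.seqs[chrom][start:end]
        return s if strand == "+" else revcomp(s)


# --------------------------------------------------------------------------
# default study-condition configuration

_CLUSTER_SIZES = [5000, 3000, 2000, 1500, 1200, 1000, 800, 600, 500, 300]
_CLUSTER_WEIGHTS = [0.50, 0.14, 0.08, 0.07, 0.06, 0.05, 0.04, 0.03, 0.02, 0.01]
_CLUSTER_MODES = [
    "uni_plus", "uni_minus", "bidirectional", "uni_plus", "uni_minus",
    "uni_plus", "uni_minus", "bidirectional", "uni_plus", "uni_minus",
]
_CLUSTER_U1 = [0.85, 0.80, 0.70, 0.90, 0.75, 0.80, 0.85, 0.65, 0.80, 0.75]
_CLUSTER_PP = [0.10, 0.15, 0.30, 0.00, 0.10, 0.20, 0.05, 0.30, 0.00, 0.10]
_CLUSTER_PH = [0.10, 0.10, 0.05, 0.15, 0.10, 0.05, 0.10, 0.05, 0.10, 0.10]

_TRF_MIXTURE = [
    ("GlyGCC", 1, 33, 0.25),    # five_tRH
    ("GlyGCC", 20, 52, 0.20),   # i_tRF (the dominant internal fragment)
    ("GlyGCC", 38, 76, 0.10),   # three_tRH
    ("GlyGCC", 30, 62, 0.04),   # i_tRF
    ("GluCTC", 1, 32, 0.15),    # five_tRH
    ("GluCTC", 1, 18, 0.10),    # five_tRF
    ("LysCTT", 58, 76, 0.10),   # three_tRF
    ("LysCTT", 1, 33, 0.06),    # five_tRH
]

_PROFILES = {
    "ovary": dict(mirna=0.10, pirna=0.826, trf=0.07, background=0.004),
    "egg": dict(mirna=0.12, pirna=0.806, trf=0.07, background=0.004),
    "spermatheca": dict(mirna=0.58, pirna=0.32, trf=0.08, background=0.02),
    "testis": dict(mirna=0.82, pirna=0.10, trf=0.04, background=0.04),
    "semen": dict(mirna=0.09, pirna=0.08, trf=0.60, background=0.23),
}

_TE_FAMILIES = [
    # (family, te_class, length)
    ("Mariner/TC1", "II", 700),
    ("Mariner/TC1", "II", 600),
    ("Mariner/TC1", "II", 500),
    ("PiggyBac", "II", 600),
    ("PiggyBac", "II", 450),
    ("R2", "I", 800),
    ("R2", "I", 700),
    ("Gypsy", "I", 650),
    ("Copia", "I", 500),
    ("BelPao", "I", 550),
    ("Jockey", "I", 400),
    ("I", "I", 400),
]


def default_config(seed: int = 1) -> SimulationConfig:
    clusters = []
    pos = 10_000
    for i, (size, w, mode, u1, pp, ph) in enumerate(
        zip(_CLUSTER_SIZES, _CLUSTER_WEIGHTS, _CLUSTER_MODES,
            _CLUSTER_U1, _CLUSTER_PP, _CLUSTER_PH)
    ):
        clusters.append(
            ClusterSpec(
                cluster_id=f"planted_{i + 1}",
                chrom="chr1",
                start=pos,
                end=pos + size,
                strand_mode=mode,
                weight=w,
                u1_bias=u1,
                pingpong_fraction=pp,
                phased_fraction=ph,
            )
        )
        pos += 13_000
    profiles = {
        t: TissueProfile(tissue=t, **kw) for t, kw in _PROFILES.items()
    }
    return SimulationConfig(
        seed=seed,
        chrom_sizes={"chr1": 200_000},
        clusters=clusters,
        profiles=profiles,
        trf_mixture=list(_TRF_MIXTURE),
    )


# --------------------------------------------------------------------------
# genome construction

def make_toy_genome(config: Optional[SimulationConfig] = None, seed: int = 1) -> ToyGenome:
    """Build the toy genome, its annotation and the genome-level manifest."""
    config = config or default_config(seed)
    rng = np.random.default_rng([config.seed, 0])
    seqs = {
        chrom: "".join(rng.choice(list("ACGT"), size=size))
        for chrom, size in config.chrom_sizes.items()
    }
    features: list[Feature] = []
    trnas: list[MatureTRNA] = []

    for spec in config.clusters:
        if spec.end > config.chrom_sizes[spec.chrom]:
            raise ValueError(f"cluster {spec.cluster_id} extends past the chromosome")

    # TE remnants inside the three biggest clusters (TE graveyards), with a
    # class-II-dominated mixture plus some class I, and the full family
    # roster in open chromatin beyond the cluster region.
    cluster_te_plan = [
        [("Mariner/TC1", "II", 700), ("PiggyBac", "II", 600), ("R2", "I", 500)],
        [("Mariner/TC1", "II", 500), ("R2", "I", 600)],
        [("PiggyBac", "II", 450), ("BelPao", "I", 400)],
    ]
    if not config.include_tes:
        cluster_te_plan = [[], [], []]
    te_id = 0
    for spec, plan in zip(config.clusters[:3], cluster_te_plan):
        cursor = spec.start + 100
        for fam, cls, length in plan:
            if cursor + length >= spec.end:
                break
            te_id += 1
            features.append(
                Feature(
                    feature_id=f"TE_{te_id}",
                    chrom=spec.chrom,
                    start=cursor,
                    end=cursor + length,
                    strand="+" if te_id % 2 == 0 else "-",
                    biotype="TE",
                    attributes={"te_class": cls, "te_family": fam},
                )
            )
            cursor += length + 300
    pos = 156_000
    standalone = _TE_FAMILIES if config.include_tes else []
    for i, (fam, cls, length) in enumerate(standalone):
        features.append(
            Feature(
                feature_id=f"TE_s{i + 1}",
                chrom="chr1",
                start=pos,
                end=pos + length,
                strand="+" if i % 2 == 0 else "-",
                biotype="TE",
                attributes={"te_class": cls, "te_family": fam},
            )
        )
        pos += length + 300

    # protein-coding genes: 3 exons of 400 bp separated by 600 bp introns
    for g in range(4):
        gstart = 140_000 + g * 4000
        strand = "+" if g % 2 == 0 else "-"
        gid = f"gene{g + 1}"
        exons = [(gstart + k * 1000, gstart + k * 1000 + 400) for k in range(3)]
        features.append(
            Feature(gid, "chr1", gstart, exons[-1][1], strand, "gene", {}))
        for k, (a, b) in enumerate(exons):
            features.append(
                Feature(f"{gid}.e{k + 1}", "chr1", a, b, strand, "exon",
                        {"parent": gid}))

    # tRNA genes (genomic = mature, CCA written into the genome sequence)
    trna_specs = [
        ("tRNA-Gly1", "GlyGCC", "+"),
        ("tRNA-Gly2", "GlyGCC", "-"),
        ("tRNA-Glu1", "GluCTC", "+"),
        ("tRNA-Lys1", "LysCTT", "+"),
    ]
    for i, (tid, iso, strand) in enumerate(trna_specs):
        start = 170_000 + i * 200
        L = 76
        features.append(
            Feature(
                tid, "chr1", start, start + L, strand, "tRNA",
                {"anticodon_start": 33, "cca": True, "isodecoder": iso},
            )
        )
        trnas.append(MatureTRNA(tid, iso, L, 34, True))
        seq = seqs["chr1"]
        if strand == "+":
            seqs["chr1"] = seq[: start + L - 3] + "CCA" + seq[start + L:]
        else:
            seqs["chr1"] = seq[:start] + "TGG" + seq[start + 3:]

    # miRNA hairpins and one rRNA locus
    for i in range(5):
        start = 175_000 + i * 200
        features.append(
            Feature(f"mir{i + 1}", "chr1", start, start + 70,
                    "+" if i % 2 == 0 else "-", "pre_miRNA", {}))
    features.append(Feature("rRNA1", "chr1", 180_000, 181_500, "+", "rRNA", {}))

    manifest = {
        "seed": config.seed,
        "chrom_sizes": dict(config.chrom_sizes),
        "feature_counts": _count_types(features),
        "clusters": [
            {
                "cluster_id": c.cluster_id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "strand_mode": c.strand_mode,
                "weight": c.weight,
                "u1_bias": c.u1_bias,
                "pingpong_fraction": c.pingpong_fraction,
                "phased_fraction": c.phased_fraction,
            }
            for c in config.clusters
        ],
        "libraries": {},
    }
    return ToyGenome(
        seqs=seqs,
        features=features,
        trnas=trnas,
        clusters=list(config.clusters),
        chrom_sizes=dict(config.chrom_sizes),
        manifest=manifest,
    )


def _count_types(features: list[Feature]) -> dict:
    counts: dict[str, int] = {}
    for f in features:
        counts[f.biotype] = counts.get(f.biotype, 0) + 1
    return counts


# --------------------------------------------------------------------------
# genome-truth biotype accounting (generator-side interval math, used by the
# manifest so planted expectations are independent of the annotation index)

_PRECEDENCE = ("rRNA", "tRNA", "pre_miRNA", "other_ncRNA")


def expected_biotype(genome: ToyGenome, chrom: str, start: int, end: int) -> str:
    hit_types = set()
    for f in genome.features:
        if f.chrom == chrom and f.start < end and f.end > start:
            hit_types.add(f.biotype)
    for bt in _PRECEDENCE:
        if bt in hit_types:
            return bt
    if "exon" in hit_types:
        return "mRNA"
    if "gene" in hit_types:
        return "mRNA"  # within the gene body but not an exon -> intron
    return "unannotated"


# --------------------------------------------------------------------------
# read simulation

def _lib_rng(master_seed: int, sample_id: str) -> np.random.Generator:
    return np.random.default_rng(
        [int(master_seed) % (2**31), zlib.crc32(sample_id.encode()) % (2**31)]
    )


def _read(genome, sample_id, i, chrom, start, end, strand) -> AlignedRead:
    return AlignedRead(
        read_id=f"{sample_id}_r{i}",
        sequence=genome.fetch(chrom, start, end, strand),
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
    )


def simulate_tissue_library(
    genome: ToyGenome,
    profile: TissueProfile,
    trf_mixture: list,
    n_reads: Optional[int] = None,
    seed: int = 1,
    sample_id: Optional[str] = None,
) -> tuple[ReadSet, dict]:
    """Draw one tissue library; returns the reads and its truth record.

    Ping-pong partner reads are generated in addition to a cluster's primary
    allocation, so the realized library can slightly exceed ``n_reads``.
    """
    if n_reads is None:
        n_reads = profile.library_size
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    sample_id = sample_id or f"{profile.tissue}_1"
    rng = _lib_rng(seed, sample_id)
    weights = np.array([profile.mirna, profile.pirna, profile.trf, profile.background])
    n_mirna, n_pirna, n_trf, n_bg = rng.multinomial(n_reads, weights)

    reads: list[AlignedRead] = []
    counter = iter(range(10**9))
    truth = {
        "sample_id": sample_id,
        "tissue": profile.tissue,
        "category_counts": {},
        "clusters": {},
        "trf_fragments": {},
        "expected_biotype_counts": {},
    }

    # --- miRNA-sized reads from hairpins, sense strand
    hairpins = [f for f in genome.features if f.biotype == "pre_miRNA"]
    for _ in range(n_mirna):
        h = hairpins[rng.integers(len(hairpins))]
        length = int(rng.choice(MIRNA_LENGTHS, p=MIRNA_LENGTH_WEIGHTS))
        start = int(rng.integers(h.start, h.end - length + 1))
        reads.append(_read(genome, sample_id, next(counter), h.chrom,
                           start, start + length, h.strand))

    # --- piRNA-sized reads in planted clusters
    cw = np.array([c.weight for c in genome.clusters], dtype=float)
    cw = cw / cw.sum()
    alloc = rng.multinomial(n_pirna, cw)
    for spec, n_alloc in zip(genome.clusters, alloc):
        stats = _simulate_cluster_reads(
            genome, spec, int(n_alloc), rng, reads, sample_id, counter)
        stats.update(
            {
                "strand_mode": spec.strand_mode,
                "u1_bias": spec.u1_bias,
                "pingpong_fraction": spec.pingpong_fraction,
                "phased_fraction": spec.phased_fraction,
            }
        )
        truth["clusters"][spec.cluster_id] = stats

    # --- tRFs from the fragment mixture
    frag_w = np.array([w for *_, w in trf_mixture], dtype=float)
    frag_w = frag_w / frag_w.sum()
    frag_alloc = rng.multinomial(n_trf, frag_w)
    trna_by_iso: dict[str, list[Feature]] = {}
    for f in genome.features:
        if f.biotype == "tRNA":
            trna_by_iso.setdefault(f.attributes["isodecoder"], []).append(f)
    for (iso, s, e, _w), n_frag in zip(trf_mixture, frag_alloc):
        genes = trna_by_iso[iso]
        for _ in range(int(n_frag)):
            g = genes[rng.integers(len(genes))]
            if g.strand == "+":
                start, end = g.start + s - 1, g.start + e
            else:
                start, end = g.end - e, g.end - s + 1
            reads.append(_read(genome, sample_id, next(counter),
                               g.chrom, start, end, g.strand))
        key = f"{iso}:{s}-{e}"
        truth["trf_fragments"][key] = int(n_frag)

    # --- background rain, uniform over the genome
    chroms = list(genome.chrom_sizes)
    for _ in range(n_bg):
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.choice(BACKGROUND_LENGTHS))
        start = int(rng.integers(0, genome.chrom_sizes[chrom] - length))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(_read(genome, sample_id, next(counter),
                           chrom, start, start + length, strand))

    truth["category_counts"] = {
        "mirna": int(n_mirna),
        "pirna_primary": int(n_pirna),
        "trf": int(n_trf),
        "background": int(n_bg),
        "total_reads": len(reads),
    }
    bt_counts: dict[str, int] = {}
    for r in reads:
        bt = expected_biotype(genome, r.chrom, r.start, r.end)
        bt_counts[bt] = bt_counts.get(bt, 0) + 1
    truth["expected_biotype_counts"] = bt_counts

    rs = ReadSet(reads, sample_id=sample_id, tissue=profile.tissue)
    rs.sort()
    return rs, truth


def _simulate_cluster_reads(
    genome: ToyGenome,
    spec: ClusterSpec,
    n_alloc: int,
    rng: np.random.Generator,
    reads: list,
    sample_id: str,
    counter,
) -> dict:
    """Primary reads plus ping-pong partners for one cluster; returns the
    realized truth record (counts and realized biases) for the manifest.

    The realized 1U/10A fractions are recorded because phased reads (whose
    position is forced by the upstream read) and ping-pong partners dilute
    the planted primary-read bias."""
    chrom = spec.chrom
    seq = genome.seqs[chrom]
    last_three_prime: dict[str, Optional[int]] = {"+": None, "-": None}
    emitted: list[AlignedRead] = []

    def emit(read: AlignedRead) -> None:
        reads.append(read)
        emitted.append(read)

    n_primary = n_partner = 0
    for _ in range(n_alloc):
        if spec.strand_mode == "uni_plus":
            strand = "+"
        elif spec.strand_mode == "uni_minus":
            strand = "-"
        else:
            strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.choice(PIRNA_LENGTHS, p=PIRNA_LENGTH_WEIGHTS))

        phased = (
            last_three_prime[strand] is not None
            and rng.random() < spec.phased_fraction
        )
        if phased:
            if strand == "+":
                start = last_three_prime["+"] + 1
            else:
                start = last_three_prime["-"] - length
            if start < spec.start or start + length > spec.end:
                phased = False
        if not phased:
            want_u = rng.random() < spec.u1_bias
            start = _place_with_bias(rng, seq, spec, length, strand, want_u)
        end = start + length
        emit(_read(genome, sample_id, next(counter), chrom, start, end, strand))
        n_primary += 1
        last_three_prime[strand] = end - 1 if strand == "+" else start

        if rng.random() < spec.pingpong_fraction:
            plen = int(rng.choice(PIRNA_LENGTHS, p=PIRNA_LENGTH_WEIGHTS))
            if strand == "+":
                q = start + 9           # partner 5' on the minus strand
                p_start, p_end, p_strand = q - plen + 1, q + 1, "-"
            else:
                q = end - 1 - 9         # partner 5' on the plus strand
                p_start, p_end, p_strand = q, q + plen, "+"
            if p_start >= 0 and p_end <= genome.chrom_sizes[chrom]:
                emit(_read(genome, sample_id, next(counter),
                           chrom, p_start, p_end, p_strand))
                n_partner += 1

    n_total = len(emitted)
    return {
        "primary_reads": n_primary,
        "partner_reads": n_partner,
        "total_reads": n_total,
        "plus_reads": sum(1 for r in emitted if r.strand == "+"),
        "minus_reads": sum(1 for r in emitted if r.strand == "-"),
        "realized_u1": (
            sum(1 for r in emitted if r.sequence[0] == "T") / n_total
            if n_total else float("nan")
        ),
        "realized_a10": (
            sum(1 for r in emitted if r.length >= 10 and r.sequence[9] == "A") / n_total
            if n_total else float("nan")
        ),
    }


def _place_with_bias(rng, seq, spec, length, strand, want_u, max_tries=200) -> int:
    """Uniform start within the cluster, rejection-sampled so the 5' genomic
    base is (or is not) a U template, realising the planted 1U bias."""
    lo, hi = spec.start, spec.end - length
    for _ in range(max_tries):
        start = int(rng.integers(lo, hi + 1))
        base = seq[start] if strand == "+" else seq[start + length - 1]
        is_u = (base == "T") if strand == "+" else (base == "A")
        if is_u == want_u:
            return start
    return int(rng.integers(lo, hi + 1))


# --------------------------------------------------------------------------
# count-matrix simulation (drives the differential-expression calibration)

def simulate_count_matrix(
    n_features: int,
    sample_tissues: dict[str, str],
    phi: float = 0.1,
    effects: Optional[dict[int, tuple[str, float]]] = None,
    base_mean: float = 50.0,
    seed: int = 1,
):
    """NB count matrix with optional planted fold effects.

    ``effects`` maps feature index -> (tissue, fold); counts of that feature
    in that tissue's samples are drawn at fold times the base mean.  Returns
    (CountMatrix, truth dict).
    """
    from .diffexp import CountMatrix

    if phi < 0:
        raise ValueError("phi must be >= 0")
    effects = effects or {}
    rng = np.random.default_rng([int(seed) % (2**31), 7919])
    means = rng.lognormal(mean=np.log(base_mean), sigma=0.5, size=n_features)
    samples = list(sample_tissues)
    mat = np.zeros((n_features, len(samples)), dtype=int)
    for j, s in enumerate(samples):
        tissue = sample_tissues[s]
        mu = means.copy()
        for idx, (eff_tissue, fold) in effects.items():
            if tissue == eff_tissue:
                mu[idx] = mu[idx] * fold
        if phi == 0:
            mat[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / phi
            p = r / (r + mu)
            mat[:, j] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(
        mat, index=[f"f{i}" for i in range(n_features)], columns=samples
    )
    truth = {
        "phi": phi,
        "base_means": means,
        "effects": {f"f{i}": eff for i, eff in effects.items()},
    }
    return CountMatrix(counts, sample_tissues), truth


# --------------------------------------------------------------------------
# writers

def write_fasta(genome: ToyGenome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_sizes:
            fh.write(f">{chrom}\n")
            seq = genome.seqs[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_GFF_TYPES = {
    "gene": "gene", "exon": "exon", "tRNA": "tRNA", "pre_miRNA": "pre_miRNA",
    "rRNA": "rRNA", "TE": "transposable_element", "other_ncRNA": "ncRNA",
}


def write_gff3(genome: ToyGenome, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in genome.chrom_sizes.items():
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for f in sorted(genome.features, key=lambda f: (f.chrom, f.start, f.end)):
            attrs = [f"ID={f.feature_id}"]
            if "parent" in f.attributes:
                attrs.append(f"Parent={f.attributes['parent']}")
            if f.biotype == "TE":
                attrs.append(f"te_class={f.attributes['te_class']}")
                attrs.append(f"te_family={f.attributes['te_family']}")
            if f.biotype == "tRNA":
                attrs.append(f"anticodon_start={f.attributes['anticodon_start']}")
                attrs.append(f"cca={'true' if f.attributes['cca'] else 'false'}")
                attrs.append(f"isodecoder={f.attributes['isodecoder']}")
            fh.write(
                "\t".join(
                    [
                        f.chrom, "apisrna_sim", _GFF_TYPES[f.biotype],
                        str(f.start + 1), str(f.end), ".", f.strand, ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def write_trna_table(genome: ToyGenome, path: str) -> None:
    df = pd.DataFrame(
        [
            (t.trna_id, t.isodecoder, t.length, t.anticodon_start, t.has_cca)
            for t in genome.trnas
        ],
        columns=["trna_id", "isodecoder", "length", "anticodon_start", "cca"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_fastq(rs: ReadSet, path: str) -> None:
    with open(path, "w") as fh:
        for r in rs:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * r.length}\n")


def write_manifest(manifest: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
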