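# Methods

This note documents the models, rules and numerical choices behind
`apisrna`, and what the synthetic-data generator does and does not emulate.

## Coordinates and data model

All internal coordinates are 0-based half-open; GFF3 I/O converts from the
1-based inclusive convention at the boundary, which keeps every overlap and
distance computation free of off-by-one adjustments.  Read sequences are
stored in read (5′→3′) orientation with T standing in for U, so the 5′
genomic coordinate of a read is its `start` on the plus strand and
`end − 1` on the minus strand.

Multimapped reads are counted once per reported alignment by default, the
behaviour of a mapper that reports up to *k* hits.  "Collapsed" reads are
unique (sequence, chromosome, start, strand) entries whose `copy_count`
carries the multiplicity; collapsing exactly conserves the total alignment
count, and all per-strand cluster tallies are locus-resolved because the
collapsing key includes the locus.

## Biotype assignment

A read overlapping several annotation classes receives a single label from
the precedence ladder rRNA > tRNA > pre-miRNA > other ncRNA > mRNA
(exon ∪ intron) > unannotated.  Structural RNAs outrank mRNA so tRNA
fragments are never mislabelled as mRNA fragments.  Assignment is
strand-agnostic by default — a read antisense to a tRNA still reflects tRNA
origin ambiguity — and a `stranded` flag is available.  Introns are derived
as within-gene gaps between the exons of each gene.  For the five-way
reporting view, rRNA folds into "other ncRNA".

## piRNA cluster calling

Putative piRNAs are the mapped reads not assigned to any structural/other
ncRNA biotype (protein-coding overlap is allowed).  Cluster seeding scans
this set at all read lengths; the 26–31 nt piRNA window enters through the
size-fraction filter and the per-strand tallies.

The caller finds maximal islands in which consecutive collapsed-read starts
lie within `max_gap` of each other, and keeps an island when it has at least
`min_reads` unique reads and a collapsed-read density of at least
`min_density` per kb.  Defaults: `max_gap` = 1000 bp (mirroring the 1 kb
merge radius used downstream), `min_reads` = 35 and `min_density` = 10/kb.
Post-filters, applied in order:

1. clusters with a 26–31 nt read fraction strictly below 0.5 are removed
   (a cluster at exactly 50 % is retained);
2. clusters overlapping or within 1 kb are merged transitively, per-strand
   tallies summed;
3. merged clusters shorter than 200 bp are dropped.

Strand call: a cluster is `plus` (or `minus`) only when that strand carries
strictly more than double the collapsed 26–31 nt reads of the other strand
in **every** tissue where the cluster is detected (detection = at least one
collapsed read); ties or any tissue failing the 2× test give
`bidirectional`.  Density and tallies use collapsed reads; per-cluster read
fractions and coverage tracks use total (uncollapsed) reads.  Coverage is
emitted as log10(RPM + 1) per base and strand — the pseudocount of 1 makes
zero-coverage positions exactly 0.

Cross-tissue overlap sets unify per-tissue cluster lists with the same
≤1 kb merge rule and annotate each unified cluster with its detecting-tissue
set.

## Biogenesis signatures

* **1U / 10A** — copy-weighted fractions of reads with T at position 1 and
  (among reads of ≥10 nt) A at position 10, in read orientation.
* **Ping-pong** — for every opposite-strand pair whose 5′ ends satisfy
  q ≥ p, the overlap q − p + 1 is binned over 1–30 nt; pairs are weighted by
  the product of copy counts by default, with an unweighted unique-pair mode.
  The Z-score compares bin 10 with the mean and standard deviation of the
  other bins.
* **Phasing** — reads are collapsed, grouped per chromosome and strand and
  sorted by 5′ position in transcription direction; for each consecutive
  pair the distance is (downstream 5′) − (upstream 3′), binned over 1–50 nt
  (d = 1 is head-to-tail adjacency).  The Z-score compares bin 1 with bins
  2–50, with a one-sided normal-tail p-value.

When a background has zero spread the Z is 0 if the signal bin equals the
background level and flagged undefined otherwise; Z-scores are not computed
below 50 reads.

Two statistical properties of this construction matter for interpretation.
First, a Z studentized against 29 (or 49) empirical background bins has
t-like tails: even on a perfect null, |Z| ≥ 2 occurs in roughly 5–6 % of
replicates, slightly above the Gaussian 4.6 %.  Second, the adjacent-pair
phasing statistic is density-sensitive: when mean read spacing approaches
the read length, nearest-neighbour distances concentrate at small d under a
uniform null (exponential gap distribution), biasing the d = 1 bin upward,
and at very high density adjacent reads overlap and the histogram starves.
Phasing is therefore best measured at moderate density; the calibration
simulations use ~1 read per 400 bp, where the gap distribution is flat
across the 50 nt window.

## tRF classification

Reads mapping sense to a tRNA gene are projected onto 1-based mature
coordinates (strand-aware; up to 2 nt of run-over past the 3′ CCA is
clipped, reflecting common non-templated additions; longer run-over and
antisense reads are excluded with a logged count).  With mature length L,
anticodon start a, loop window W = [a − 3, a + 5] and 3′ zone e ≥ L − 2,
the classes are assigned in order: 5′ half (s ≤ 2 and e ∈ W), 3′ half
(e ≥ L − 2 and s ∈ W), 5′ tRF (s ≤ 2, e below the 3′ zone and ∉ W), 3′ tRF
(e ≥ L − 2, s ∉ W), internal tRF otherwise.  The five classes are proved
mutually exclusive and exhaustive by enumeration of every (s, e) pair in the
test suite.  Abundance tables key tRFs by (tRNA gene, s, e) with
within-sample proportions; isodecoder-level views sum gene copies sharing an
anticodon label.

## Feature targeting

Each putative piRNA (26–31 nt, ncRNA-filtered) is assigned to at most one
category by the precedence TE > exon > intron, counting a feature only when
the overlap covers at least half the read; orientation relative to the
feature strand is recorded as sense/antisense.  Intergenic reads are the
exact remainder, so assigned + intergenic = total holds as an integer
identity.  TE family tables report percentages of TE-mapped reads per
family; class I vs class II proportions between two tissues are compared
with Pearson's chi-squared without continuity correction (a flag marks
expected cells below 1).  Differential antisense targeting feeds per-feature
antisense counts into the expression machinery below.

## Differential expression

The test is a conditioned exact negative-binomial test in the
Robinson–Smyth style.  Counts are scaled to a common effective library size
(per-sample factors = library size over the geometric mean of sizes,
a quantile-free approximation), summed within each tissue and rounded.
Under the null of equal means and common dispersion φ, the group-A sum
conditional on the feature total t is Binomial(t, n_A/(n_A+n_B)) when φ = 0
and Beta-Binomial(t, n_A/φ, n_B/φ) otherwise; the two-sided p-value sums the
probabilities of all splits at most as probable as the one observed, so
p ∈ (0, 1] and a zero total gives p = 1.  φ is estimated by the method of
moments on normalized counts, pooled over tissues with ≥2 replicates, and
floored at 0.

Fold change is the ratio of tissue-mean normalized counts (≥1, with
direction; infinite when one tissue is all-zero, and such features flow into
the "unique" accounting rather than producing numeric overflow).  A feature
is DE when FDR < 0.01, fold change > 5 and the mean raw count is ≥ 5 in at
least one tissue; it is uniquely expressed in a tissue when the other tissue
has zero raw counts in every sample and its own mean normalized count is
≥ 5 (comparison with a 10⁻⁹ relative tolerance to absorb normalization
round-off).  Summaries report unique calls within the up-regulated set.
PCA of expression profiles uses feature-centered SVD of log2(CPM + 1) with
a deterministic sign convention.  Tag-wise dispersion shrinkage and GLM
designs are out of scope.

## Synthetic data

The generator builds a 200 kb toy chromosome carrying ten designated piRNA
clusters (300–5000 bp), TE remnants inside the three largest clusters and a
twelve-element family roster (class I: Copia, Gypsy, BelPao, R2, Jockey, I;
class II: Mariner/TC1, PiggyBac) in open chromatin, four protein-coding
genes with exons/introns, four CCA-terminated tRNA genes (GlyGCC ×2,
GluCTC, LysCTT; anticodon at mature position 34), five miRNA hairpins and
an rRNA locus.  All reads are exact substrings of the genome (no mismatch
model): the analysis operates post-mapping, so exact placement suffices.

Tissue profiles are mixtures over four read categories — miRNA-sized
(21–23 nt), piRNA-sized (26–31 nt, mode 29), tRF (drawn from a planted
fragment mixture dominated by 32–33 nt GlyGCC fragments) and background
rain (13–43 nt, uniform over the genome).  The shipped profiles emulate the
tissue types of germline small-RNA studies: semen-like (60 % tRF),
testis-like (82 % miRNA), spermatheca-like (58 % miRNA), and ovary/egg-like
(~80 % piRNA, modal length 29 nt).  Library size defaults to 5000 reads, a
toy scale at which every stage's statistics are well-populated.

One deliberately scale-dependent choice: on a real ~230 Mb genome, the few
percent of piRNA-sized reads that fall outside clusters spread at far less
than one read per kb.  On a 1000-fold smaller toy genome one cannot match
both that unclustered *fraction* and that unclustered *rain rate*; the
generator keeps the per-kb rain rate realistic (~0.1 reads/kb for
ovary/egg-like libraries), because the rain rate — not the fraction — is
what drives island chaining in a gap-based cluster caller.  The realized
clustered fraction in ovary-like libraries is accordingly ≥99 %.

Cluster reads realise a planted 1U bias by rejection-sampling 5′ positions
against the genomic template.  Ping-pong partners are emitted opposite the
primary read with 5′ ends offset by 9 (a 10 nt overlap); when the primary
has 5′ U, the partner's position 10 is automatically a templated A.  Phased
reads continue head-to-tail from the previous read's 3′ end.  Because
partner and phased reads cannot also be bias-sampled, the manifest records
the *realized* per-cluster 1U/10A fractions alongside the planted
parameters; recovery tests compare against both (planted value where the
cluster is partner- and trail-free, realized value otherwise).

Each library draws from `numpy` Generator seeded with (master seed,
CRC32(sample id)), so adding a sample never perturbs another sample's
reads, and fixed seeds give byte-identical FASTA/GFF3/SAM/FASTQ output.

What passing tests on this generator do **not** show: robustness to
sequencing error and multimapping ambiguity, to incomplete or wrong
annotation, to the heavy-tailed cluster size distribution of real genomes,
or to chimeric/adapter artefacts.  The generator is a correctness harness
for the implemented rules, not a realism benchmark.

## Problem sizes used in the shipped checks

The automated checks run at deliberately small scale: libraries of
400–8000 reads, 100-replicate null calibrations for the signature
Z-scores, 1000 simulations for the chi-squared type-I rate, and count
matrices of 2000–2100 features with 3 + 3 replicates.  At these sizes the
whole suite and the acceptance script each complete in well under a minute
on one CPU.

## Known limitations

* One consensus cluster caller is implemented; combining multiple external
  callers is out of scope, as is read mapping itself.
* The exact-test replication of any proprietary DE implementation is a
  non-goal; the test here is fully specified and oracle-checked instead.
* The phasing statistic uses adjacent reads only (no all-pairs variant) and
  is density-sensitive as described above.
* tRNA genes in the toy genome coincide with their mature form (CCA written
  into the genomic sequence); intron-containing or CCA-less tRNAs are
  handled by the classifier (`has_cca`, run-over clipping) but not planted
  by the generator.
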