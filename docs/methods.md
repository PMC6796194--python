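# Methods

This note documents the models and procedures implemented in piratlas,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Coordinates and ingestion

All coordinates are 0-based half-open (BED-compatible); GFF3 is shifted
by (−1, 0) on ingest. Overlap means ≥ 1 shared base — no
fraction-of-read thresholds anywhere. Only primary SAM alignments are
ingested; multi-mapper status is carried through the NH tag, strand
through flag 0x10, and alignments of ≤ 15 nt are dropped (the
post-trimming small-RNA floor). Spike-in counts come from a separate
TSV (`sample_id`, `spike_id`, `count`) rather than from alignments,
since spike references are not part of the genome. On the minus strand
the 5' end of a read is its rightmost aligned base.

## Biotype classification

Rules fire in fixed precedence — structural > miRNA > siRNA > piRNA >
other — because a read can overlap several annotation categories and the
classification must be a partition. Parameters (`ClassifierParams`, all
nt): `mirna_max_len` 24, `sirna_max_len` 22, `sirna_te_exact_len` 21,
piRNA window 23–30, discovery window up to 35. Overlap tests are
strand-blind at this layer; strand enters only in quantification and
signatures. The 21-nt TE rule fires for TE-consensus alignments *or*
genomic TE-insertion overlaps. Two read selections exist: `counting`
(label piRNA, uniquely mapping, 23–30 nt) and `discovery` (23–35 nt, not
structural/miRNA/siRNA, multi-mappers retained). The classifier is
verified against an independently written nested-conditional oracle on
all 2,560 length × flag combinations.

## Cluster discovery

The scan is the 1-nt-step limit of a sliding window: seed regions are
the union of deduplicated read footprints, which a 250-nt merge then
coarsens. This is parameter-free (no window length/step to choose) and
equivalent to any window shorter than the merge gap. Unique reads are
alignments deduplicated by (chrom, start, end, strand) — the alternative
reading, "uniquely mapping", is handled separately by the read
selections above.

Steps and comparisons:

1. union of unique-read footprints;
2. merge regions with gap ≤ 250 nt (inclusive, "within");
3. drop regions with < 3.0 unique reads per kb of the current extent;
4. merge survivors with gap ≤ 1,000 nt (inclusive) and **re-apply the
   density filter on the merged extent**;
5. keep regions strictly > 2,000 nt ("greater than").

The density re-check in step 4 is a deliberate resolution of an
ambiguity: single-read regions trivially pass the per-kb density filter
(a 26-nt footprint holding one read is ~38 reads/kb), so without a
re-check, chains of isolated reads with gaps just under 1,000 nt could
merge into > 2,000-nt "clusters" with final density below threshold.
Density is recomputed after every merge using the current region extent,
and every reported cluster therefore satisfies the density threshold
over its final, reported interval. A consequence worth knowing: a
2,500-nt merged region holding 7 unique reads (2.8/kb) is never
reported, whichever merge produced it.

Discovered clusters are unstranded intervals; strand composition is a
derived statistic (`plus_fraction`), classed uni_plus (≥ 0.9), uni_minus
(≤ 0.1) or dual. Canonical-cluster harmonization collapses overlapping
fragments, merges fragments separated by strictly less than 25 kb, and
keeps the longest remaining piece (ties: smaller start). The
implementation is checked interval-for-interval against a brute-force
reference that materialises per-base read presence and applies the five
steps by explicit pairwise gap scanning.

## Ping-pong signatures

5'-overlap distance between a plus read (5' at *p*) and a minus read
(5' at *q*): *d = q − p + 1*, so *d* = 10 means the 5' ends overlap over
10 nt. Histograms run over *d* ∈ [1, 30] on deduplicated reads. Two
counting modes are exposed because the natural unit is genuinely
ambiguous: pair counts weighted by the product of position
multiplicities (default), and a distinct-(plus-position, minus-position)
count used as the per-cluster "signature count" (a count of loci, not of
read pairs). The enrichment statistic is

    z10 = (c10 − mean(c_d, d ≠ 10)) / sd(c_d, d ≠ 10)

with the sample standard deviation. It is this package's own statistic,
named `z10` in every output header. When the background sd is zero the
statistic is undefined (reported as missing) unless the histogram is
perfectly flat, which scores exactly 0. No FDR is attached to z10.

## 1U-bias matrices

Reads are collapsed to unique (chrom, 5' position, strand) sites; the
10-nt genomic sequence starting at the 5' end is extracted in read
orientation (reverse-complemented on the minus strand) and per-position
base fractions are tallied with T reported as U. Sites within 10 nt of a
contig end are skipped with a warning. Using the genome (not the read
sequence) makes the matrix independent of sequencing artefacts and is
exact for the synthetic data by construction (below).

## Quantification, normalization, significance

Counting is whole-read, ≥ 1 bp, with multi-assignment: a read increments
every feature it overlaps, with no fractional weights. TE counts are
sense/antisense by alignment strand against the consensus; 21-nt reads
are excluded from TE piRNA counts (they are siRNAs). 3'UTR piRNA
production classes per gene (sense / antisense / both / none) require
the respective count to reach `min_count` (default 1; the choice of
threshold is exposed because no canonical value exists), and
`has_te_fragment` flags 3'UTRs overlapping annotated TE insertions.

Normalization modes: `total` (mapped reads), `mirna`, `spikein`.
miRNA denominators are each sample's miRNA-count total after excluding
the two most differentially expressed miRNAs; "most differential" is
operationalised as the largest |log2 ratio of group-mean CPM| with each
candidate's CPM computed against the miRNA total *excluding itself*
(leave-one-out). The leave-one-out form matters: with a plain
miRNA-total denominator, one strongly shifted miRNA drags the
denominator with it and makes every flat miRNA look differential.
Spike-in factors are ∝ 1/spike-total, rescaled to geometric mean 1;
the effective library size is total mapped reads × factor.

Expression filters keep features with CPM > cutoff in ≥ `min_samples`
samples (defaults 20 and 3; the cutoff is the piRNA-cluster default, and
700/1,000 are the appropriate values for antisense/sense 3'UTR
analyses). Significance calls use inclusive boundaries: |log2FC| ≥ 1 and
BH q ≤ 0.05. Benjamini–Hochberg is the step-up rule
q(i) = min_{j≥i} (m/j) p(j), clipped at 1. The two-group test is an
explicitly labelled stand-in — a two-sided exact binomial test of the
pooled group-A count against the expectation implied by the groups'
summed denominators — not a negative-binomial GLM; output columns name
it `pvalue_binomial_standin` to prevent conflation. log2FC uses
group-mean CPM with a pseudo-count (default 1) in numerator and
denominator.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:
23–30-nt piRNAs with a peaked length distribution
{23: 0.10, 24: 0.17, 25: 0.22, 26: 0.22, 27: 0.17, 28: 0.07, 29: 0.03,
30: 0.02} (a symmetric peak over 24–27 nt; the exact shape is a fixture
choice, not a claim), a first-position U probability of 0.8, clustered
genomic origin with uni- and dual-strand clusters, ping-pong partner
reads at exact 10-nt 5' overlap, 22-nt-peaked miRNAs on pre-miRNA loci,
21-nt siRNAs (endo-siRNA loci and TE consensus), structural
contamination on rRNA/tRNA/snoRNA/snRNA loci, mostly antisense
TE-consensus piRNAs, and multinomially split per-sample spike-in totals.
Every read carries exactly one provenance label in the truth record.

Key design points:

- **1U bias by genome editing.** At each chosen unique 5' site the
  genome base is rewritten before sequence extraction: U with
  probability `u1_prob`, otherwise a uniformly chosen non-U base, so the
  realised per-site U probability is exactly `u1_prob` and the
  frequency-matrix stage recovers the bias from the FASTA. Because every
  library edits the genome, a study's FASTA is written after all
  libraries, and read sequences are re-extracted from the final genome
  so SAM, FASTA and matrices agree byte-for-byte. Within dense
  dual-strand clusters a small fraction of sites collide (a plus site
  and a minus site demanding complementary bases at the same position),
  which is why pooled multi-sample U frequencies land a few percent
  below `u1_prob` while dedicated single-library measurements recover
  0.80 ± 0.02.
- **Poisson read counts.** Per-cluster counts are
  Poisson(reads/kb × kb × `global_scale`), so density-filter behaviour
  near threshold is exercised stochastically; recovery fixtures use
  expected per-cluster read counts far above the detectability boundary.
- **What scales and what does not.** `global_scale` multiplies piRNA
  content only (cluster, background and TE piRNAs); miRNA, siRNA and
  structural counts stay flat. This is exactly the situation
  miRNA-based and spike-in normalization are designed for, and is what
  makes the 2-fold-shift recovery test meaningful.
- **Ping-pong switch.** `pingpong_fraction` is a per-cluster property;
  a per-sample boolean turns partner generation on (GSC-like) or off
  (SC-like), giving the two-condition contrast of the default study:
  three GSC-like replicates (scale 3×, ping-pong on) versus three
  SC-like replicates (scale 1×, ping-pong off) on a 2 × 1-Mb genome
  with 8 planted clusters.
- **Background rate.** Default 0.01 unique background piRNA reads per kb
  per sample. The toy genome is ~70× smaller than the fly genome while
  planted-cluster densities are life-sized, so the out-of-cluster rate
  is scaled down with it; it also keeps the pooled background (~0.1/kb
  across six samples) in the regime where chains of isolated background
  reads merging across ≤ 1-kb gaps into spurious > 2-kb regions are
  expected ≪ 1 times per study.
- Annotation features are placed uniformly, non-overlapping, outside
  planted clusters; TE insertions are 1%-mutated, possibly truncated
  consensus copies embedded into the genome sequence. Gene models (with
  3'UTRs) and TE-space piRNA reads are generated so the 3'UTR and TE
  quantification stages run end to end.

Not emulated: sequencing errors, adapter remnants, quality scores,
multi-mapping reads (all synthetic alignments are unique, NH:i:1),
chromatin context, and any relationship between cluster sequence and TE
content. Passing recovery tests therefore demonstrates correctness of
the analysis chain on data satisfying its assumptions — not robustness
to alignment artefacts or annotation errors in real libraries.

## Problem sizes and determinism

The shipped verification suite uses: 50 random 200-read sets on 100 kb
for oracle equivalence; a 2-Mb genome with 20 planted clusters
(2.5–30 kb; 5–50 unique reads/kb, with short clusters paired to high
densities so every cluster stays well above the detectability boundary)
for recovery; 20 seeds for ping-pong detection and null rejection; 10
seeds each for the condition contrast and spike-in recovery; ~11,000
unique sites for the 1U check; 1,000 random p-vectors for BH; and the
six-sample default study (~130,000 reads) for the end-to-end run. All
randomness flows from explicit integer seeds; identical config + seed
reproduces byte-identical FASTA/SAM/TSV outputs, and pipeline runs are
pure functions of (inputs, config) — rerun outputs are diff-identical.

## Known limitations

- The two-group test is a pooled binomial stand-in; it ignores
  biological replicate dispersion and will be anticonservative on real
  data. It exists to exercise the significance-calling machinery, not to
  replace a count-model GLM.
- The ping-pong z10 uses the 29 off-10 distances as background; in very
  sparse regions the background sd is zero and the statistic is
  undefined rather than inflated.
- Biotype precedence for reads overlapping multiple categories
  (e.g., a 21-nt read over both a pre-miRNA and a TE) is a documented
  convention, not an inferred ground truth.
- Cluster discovery density filtering on very short regions is
  permissive by construction (single reads pass); the size filter and
  the step-4 density re-check are what keep isolated reads from
  becoming clusters.
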