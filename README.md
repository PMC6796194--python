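# piratlas

Small-RNA analysis toolkit for PIWI-interacting RNA (piRNA) studies in
*Drosophila* ovarian germline cells: biotype classification of aligned
small-RNA reads, de-novo piRNA cluster discovery, ping-pong signature
scanning, transposable-element (TE) and 3'UTR piRNA quantification, and
library normalization — together with a deterministic synthetic-data
generator that emulates the statistical structure of ovarian small-RNA
libraries and provides ground truth for recovery testing.

It is aimed at computational biologists who work with aligned small-RNA
libraries (SAM/BED against a genome and a TE-consensus set, GFF3/BED
annotations, FASTA genome, spike-in count tables) and want a tested,
reproducible implementation of this analysis chain.

## The methods in brief

**Biotype classification.** Reads longer than 15 nt are assigned exactly
one biotype by length and annotation overlap, in fixed precedence:
reads touching rRNA/tRNA/snoRNA/snRNA are excluded as structural; reads
≤ 24 nt over pre-miRNA loci are miRNAs; reads ≤ 22 nt over endo-siRNA
loci, or exactly 21 nt and TE-derived, are siRNAs; remaining 23–30-nt
reads are piRNAs.

**Cluster discovery.** A density-based scan over deduplicated unique
alignments (the 1-nt-step limit of a sliding window): seed regions are
the union of read footprints of 23–35-nt putative piRNAs; regions within
250 nt are merged; regions with fewer than 3 unique reads/kb are
discarded; survivors within 1,000 nt are merged (density re-checked on
the merged extent); only clusters strictly longer than 2,000 nt are
reported. Canonical cluster fragments are harmonized by collapsing
overlaps, merging fragments closer than 25 kb and keeping the largest
remaining piece.

**Ping-pong signature.** For a plus-strand read with 5' end *p* and a
minus-strand read with 5' end *q*, the 5'-overlap distance is
*d = q − p + 1*. The ping-pong amplification loop produces pairs at
exactly *d* = 10; the statistic `z10` is the enrichment of the overlap-10
pair count over the mean and standard deviation of counts at distances
1–30 (excluding 10).

**Quantification and normalization.** Whole-read ≥ 1 bp overlap counting
(sense/antisense aware for TEs and 3'UTRs), CPM/RPKM, miRNA-count
denominators (the two most differentially expressed miRNAs excluded),
spike-in factors (∝ 1/spike total, geometric mean 1) with effective
library sizes, CPM expression filters, an exact-binomial two-group
stand-in test, Benjamini–Hochberg q-values, and |FC| ≥ 2 & FDR ≤ 0.05
significance calls.

**1U bias.** piRNA reads are collapsed to unique 5' start sites, the
10-nt genomic sequence at each site (reverse-complemented on the minus
strand) is extracted, and per-position base frequencies are tallied
(T reported as U); position 1 shows the characteristic U bias.

## Worked example

Generate the default synthetic study (six samples: three GSC-like with
ping-pong on and 3× piRNA abundance, three SC-like with ping-pong off)
and run the full pipeline:

```bash
piratlas simulate --out study --seed 1
cat > run.yaml <<'YAML'
genome_fasta: study/genome.fa
annotations_gff3: study/annotations.gff3
spike_table: study/spikes.tsv
normalization: spikein
output_dir: out
samples:
  - {sample_id: GSC_1, condition: GSC, genome_sam: study/GSC_1.genome.sam, te_sam: study/GSC_1.te.sam}
  - {sample_id: GSC_2, condition: GSC, genome_sam: study/GSC_2.genome.sam, te_sam: study/GSC_2.te.sam}
  - {sample_id: GSC_3, condition: GSC, genome_sam: study/GSC_3.genome.sam, te_sam: study/GSC_3.te.sam}
  - {sample_id: SC_1, condition: SC, genome_sam: study/SC_1.genome.sam, te_sam: study/SC_1.te.sam}
  - {sample_id: SC_2, condition: SC, genome_sam: study/SC_2.genome.sam, te_sam: study/SC_2.te.sam}
  - {sample_id: SC_3, condition: SC, genome_sam: study/SC_3.genome.sam, te_sam: study/SC_3.te.sam}
YAML
piratlas all --config run.yaml
```

which prints

```
completed stages: classify, discover, pingpong, quantify, logo; 8 clusters
```

and writes, among others, `out/clusters.tsv`:

```
cluster_id   chrom  start   end     length  n_unique_reads  density_per_kb  strandedness
cluster_0001 chr2L  49999   58013   8014    2665            332.5           dual
cluster_0002 chr2L  149888  153972  4084    701             171.6           uni_plus
...
cluster_0008 chr3R  699286  719994  20708   2555            123.4           dual
```

All 8 discovered clusters coincide with the 8 planted ones
(`canonical_covered_fraction: 1.0` in `out/run_report.json`). The
per-sample ping-pong z-scores separate the conditions cleanly — z10 ≈
108–161 for the GSC-like samples versus −0.2–0.6 for the SC-like ones —
and the pooled first-position U frequency in `out/logo_matrix.tsv` is
0.76 (the generator's per-site U probability is 0.8; a few percent is
lost to overlapping sites within dense clusters). The differential
table `out/dge_clusters.tsv` marks 7 of 8 clusters as significant with
log2FC ≈ −1.6 for SC over GSC, the planted 3-fold piRNA shift under
spike-in normalization.

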