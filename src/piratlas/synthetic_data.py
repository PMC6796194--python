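"""Deterministic generator of toy genomes, annotations and small-RNA libraries.

The generator emulates the statistical structure of ovarian small-RNA
libraries: 23-30 nt piRNAs peaking at 24-27 nt with a first-position U
bias, clustered genomic origin (uni- and dual-strand clusters), ping-pong
partner reads with exact 10-nt 5' overlap, 22-nt-peaked miRNAs from
pre-miRNA loci, 21-nt siRNAs (endo-siRNA loci and TE consensus),
structural-RNA contamination, TE-consensus piRNAs, and per-sample
spike-in totals.  Every read carries a ground-truth provenance label.

The 1U bias is realised by rewriting the genome base at each chosen unique
5' site before sequence extraction (U with probability ``u1_prob``, else a
uniformly chosen non-U base, so the realised first-base U probability is
exactly ``u1_prob``).  Because libraries edit the genome, a study's FASTA
is written only after all libraries have been generated, keeping read
sequences and genome consistent for logo extraction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pysam
from intervaltree import IntervalTree

from piratlas.core_model import (
    GENOME,
    MINUS,
    PLUS,
    TE_CONSENSUS,
    UNSTRANDED,
    AlignedRead,
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    ReadLibrary,
    write_bed,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G (byte values)

#: default piRNA length distribution: symmetric peak over 24-27 nt
DEFAULT_LENGTH_DISTRIBUTION = {
    23: 0.10, 24: 0.17, 25: 0.22, 26: 0.22,
    27: 0.17, 28: 0.07, 29: 0.03, 30: 0.02,
}
MIRNA_LENGTH_DISTRIBUTION = {21: 0.10, 22: 0.65, 23: 0.15, 24: 0.10}
SIRNA_LENGTH_DISTRIBUTION = {20: 0.10, 21: 0.80, 22: 0.10}


@dataclass(frozen=True)
class PlantedCluster:
    contig: str
    start: int
    length: int
    reads_per_kb: float                 # unique reads per kb at scale 1
    strand_mode: str = "dual"           # uni_plus | uni_minus | dual
    pingpong_fraction: float = 0.0

    @property
    def end(self) -> int:
        return self.start + self.length

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start, self.end, UNSTRANDED)


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    condition: str
    global_scale: float = 1.0           # multiplies piRNA read counts only
    spike_total: int = 100_000
    pingpong: bool = True               # condition-level ping-pong switch


@dataclass
class SyntheticConfig:
    seed: int = 0
    contigs: List[Tuple[str, int]] = field(
        default_factory=lambda: [("chr2L", 1_000_000), ("chr3R", 1_000_000)]
    )
    planted_clusters: List[PlantedCluster] = field(default_factory=list)
    length_distribution: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    u1_prob: float = 0.8
    n_premirna: int = 40
    n_endosirna: int = 20
    n_structural: int = 28
    n_te_insertions: int = 30
    n_genes: int = 30
    te_consensus: List[Tuple[str, int]] = field(
        default_factory=lambda: [
            ("ZAM", 5000), ("roo", 6000), ("blood", 4500), ("412", 4000)
        ]
    )
    background_reads_per_kb: float = 0.01
    mirna_reads: int = 8000
    sirna_reads: int = 3000
    structural_reads: int = 3000
    te_pirna_reads: int = 3000
    samples: List[SampleSpec] = field(default_factory=list)

    def validate(self) -> None:
        errors: List[str] = []
        if not (0.0 <= self.u1_prob <= 1.0):
            errors.append("u1_prob must lie in [0, 1]")
        total = sum(self.length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            errors.append(f"length_distribution sums to {total}, not 1")
        contig_len = dict(self.contigs)
        for i, cl in enumerate(self.planted_clusters):
            if cl.contig not in contig_len:
                errors.append(f"cluster {i}: unknown contig {cl.contig}")
            elif not (0 <= cl.start and cl.end <= contig_len[cl.contig]):
                errors.append(f"cluster {i}: outside contig bounds")
            if not (0.0 <= cl.pingpong_fraction <= 1.0):
                errors.append(f"cluster {i}: pingpong_fraction outside [0,1]")
            if cl.strand_mode not in ("uni_plus", "uni_minus", "dual"):
                errors.append(f"cluster {i}: bad strand_mode {cl.strand_mode}")
        for i, a in enumerate(self.planted_clusters):
            for b in self.planted_clusters[i + 1:]:
                if a.contig == b.contig:
                    gap = max(b.start - a.end, a.start - b.end)
                    if gap <= 2000:
                        errors.append(
                            f"clusters on {a.contig} separated by {gap} nt "
                            "(need > 2 kb)"
                        )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            errors.append("duplicate sample ids")
        if errors:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(errors))


def default_config(seed: int = 0) -> SyntheticConfig:
    """The default two-condition study: GSC-like (ping-pong on, 3x piRNA
    scale) versus SC-like (ping-pong off, 1x), three replicates each."""
    clusters = [
        PlantedCluster("chr2L", 50_000, 8_000, 20.0, "dual", 0.5),
        PlantedCluster("chr2L", 150_000, 4_000, 15.0, "uni_plus", 0.0),
        PlantedCluster("chr2L", 300_000, 12_000, 10.0, "dual", 0.4),
        PlantedCluster("chr2L", 500_000, 3_000, 25.0, "uni_minus", 0.0),
        PlantedCluster("chr3R", 80_000, 6_000, 18.0, "dual", 0.5),
        PlantedCluster("chr3R", 250_000, 10_000, 12.0, "uni_plus", 0.0),
        PlantedCluster("chr3R", 450_000, 5_000, 20.0, "dual", 0.3),
        PlantedCluster("chr3R", 700_000, 20_000, 8.0, "dual", 0.4),
    ]
    samples = [
        SampleSpec(f"GSC_{i}", "GSC", 3.0, 100_000, True) for i in (1, 2, 3)
    ] + [
        SampleSpec(f"SC_{i}", "SC", 1.0, 100_000, False) for i in (1, 2, 3)
    ]
    return SyntheticConfig(
        seed=seed, planted_clusters=clusters, samples=samples
    )


@dataclass
class TruthRecord:
    """Ground truth for recovery tests."""

    clusters: List[PlantedCluster] = field(default_factory=list)
    provenance: Dict[str, str] = field(default_factory=dict)
    scales: Dict[str, float] = field(default_factory=dict)
    pingpong_pairs: Dict[str, List[Tuple[str, str]]] = field(
        default_factory=dict
    )


@dataclass
class SyntheticGenome:
    """Mutable toy genome plus TE consensus sequences (byte arrays)."""

    contigs: Dict[str, bytearray]
    te_consensus: Dict[str, bytearray]

    def as_strings(self) -> Dict[str, str]:
        return {name: seq.decode() for name, seq in self.contigs.items()}

    def write_fasta(self, path: str | Path, which: str = "contigs") -> None:
        seqs = self.contigs if which == "contigs" else self.te_consensus
        with open(path, "w") as fh:
            for name in seqs:
                fh.write(f">{name}\n")
                s = seqs[name].decode()
                for i in range(0, len(s), 70):
                    fh.write(s[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# genome + annotation generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, size=n)].tobytes())


def _place_feature(
    rng: np.random.Generator,
    contig: str,
    contig_len: int,
    size: int,
    occupied: IntervalTree,
    margin: int = 100,
    max_tries: int = 200,
) -> Optional[int]:
    """Pick a start so [start, start+size) clears the occupied tree."""
    for _ in range(max_tries):
        start = int(rng.integers(0, contig_len - size))
        if not occupied.overlaps(start - margin, start + size + margin):
            occupied.addi(start, start + size)
            return start
    return None


def generate_genome(
    config: SyntheticConfig,
    outdir: Optional[str | Path] = None,
) -> Tuple[SyntheticGenome, AnnotationSet, TruthRecord]:
    """Build the random genome, place annotations and embed TE copies.

    Annotation features are placed uniformly outside the planted clusters
    and do not overlap one another.  TE insertions are mutated (1%) copies
    of a consensus, embedded into the genome sequence at recorded
    positions.  With ``outdir`` set, FASTA/GFF3/BED files are written.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    contigs = {name: _random_seq(rng, length) for name, length in config.contigs}
    te_seqs = {name: _random_seq(rng, length) for name, length in config.te_consensus}
    genome = SyntheticGenome(contigs, te_seqs)

    occupied: Dict[str, IntervalTree] = {name: IntervalTree() for name, _ in config.contigs}
    for cl in config.planted_clusters:
        occupied[cl.contig].addi(cl.start, cl.end)

    ann = AnnotationSet(
        te_consensus_names={name for name, _ in config.te_consensus},
        spike_in_ids={f"spike_{i:02d}" for i in range(1, 9)},
        canonical_clusters=[cl.interval() for cl in config.planted_clusters],
    )
    truth = TruthRecord(clusters=list(config.planted_clusters))

    contig_names = [name for name, _ in config.contigs]
    contig_len = dict(config.contigs)

    def place(size: int) -> Tuple[str, int]:
        for _ in range(50):
            chrom = contig_names[int(rng.integers(0, len(contig_names)))]
            start = _place_feature(rng, chrom, contig_len[chrom], size,
                                   occupied[chrom])
            if start is not None:
                return chrom, start
        raise RuntimeError(
            "could not place annotation feature without overlap; "
            "use a larger genome or fewer features"
        )

    def rand_strand() -> str:
        return PLUS if rng.random() < 0.5 else MINUS

    for _ in range(config.n_premirna):
        size = int(rng.integers(60, 121))
        chrom, start = place(size)
        ann.pre_mirna.append(GenomicInterval(chrom, start, start + size,
                                             rand_strand()))
    for _ in range(config.n_endosirna):
        size = int(rng.integers(300, 1501))
        chrom, start = place(size)
        ann.endo_sirna.append(GenomicInterval(chrom, start, start + size,
                                              rand_strand()))
    structural_specs = [
        ("rrna", 1000, 3000), ("trna", 70, 90),
        ("snorna", 100, 200), ("snrna", 100, 200),
    ]
    for i in range(config.n_structural):
        bucket, lo, hi = structural_specs[i % len(structural_specs)]
        size = int(rng.integers(lo, hi + 1))
        chrom, start = place(size)
        getattr(ann, bucket).append(
            GenomicInterval(chrom, start, start + size, rand_strand())
        )
    # TE insertions: mutated copies of a consensus embedded in the genome
    te_names = list(te_seqs)
    for _ in range(config.n_te_insertions):
        name = te_names[int(rng.integers(0, len(te_names)))]
        consensus = te_seqs[name]
        frac = rng.uniform(0.5, 1.0)
        size = max(500, int(len(consensus) * frac))
        offset = int(rng.integers(0, len(consensus) - size + 1))
        chrom, start = place(size)
        strand = rand_strand()
        copy = bytearray(consensus[offset:offset + size])
        n_mut = max(1, int(0.01 * size))
        for pos in rng.integers(0, size, size=n_mut):
            copy[pos] = _BASES[rng.integers(0, 4)][0]
        if strand == MINUS:
            copy = bytearray(
                bytes(_COMPLEMENT.get(b, 78) for b in reversed(copy))
            )
        contigs[chrom][start:start + size] = copy
        ann.te_insertions.append(GenomicInterval(chrom, start, start + size,
                                                 strand))
    for i in range(config.n_genes):
        span = int(rng.integers(2000, 6001))
        chrom, start = place(span)
        strand = rand_strand()
        gid = f"gene_{i + 1:04d}"
        gene = GeneModel(gid, GenomicInterval(chrom, start, start + span,
                                              strand), strand)
        utr_len = int(rng.integers(300, 801))
        mid = start + span // 2
        if strand == PLUS:
            gene.exons = [
                GenomicInterval(chrom, start, mid - 100, strand),
                GenomicInterval(chrom, mid, start + span, strand),
            ]
            gene.utr3 = [GenomicInterval(chrom, start + span - utr_len,
                                         start + span, strand)]
        else:
            gene.exons = [
                GenomicInterval(chrom, start, mid - 100, strand),
                GenomicInterval(chrom, mid, start + span, strand),
            ]
            gene.utr3 = [GenomicInterval(chrom, start, start + utr_len,
                                         strand)]
        ann.genes[gid] = gene
    ann.invalidate_index()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genome.write_fasta(outdir / "genome.fa")
        genome.write_fasta(outdir / "te_consensus.fa", which="te_consensus")
        write_gff3(ann, outdir / "annotations.gff3")
        write_bed(
            [cl.interval() for cl in config.planted_clusters],
            outdir / "planted_clusters.bed",
            names=[f"planted_{i + 1}" for i in range(len(config.planted_clusters))],
        )
    return genome, ann, truth


def write_gff3(ann: AnnotationSet, path: str | Path) -> None:
    """Write the annotation set as GFF3 (1-based inclusive coordinates)."""
    type_of = [
        ("pre_mirna", "pre_miRNA"), ("endo_sirna", "endo_siRNA"),
        ("rrna", "rRNA"), ("trna", "tRNA"), ("snorna", "snoRNA"),
        ("snrna", "snRNA"), ("te_insertions", "transposable_element"),
        ("canonical_clusters", "piRNA_cluster"),
    ]
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        counter = 0
        for attr, gff_type in type_of:
            for iv in getattr(ann, attr):
                counter += 1
                strand = iv.strand if iv.strand != UNSTRANDED else "."
                fh.write(
                    f"{iv.chrom}\tpiratlas\t{gff_type}\t{iv.start + 1}\t"
                    f"{iv.end}\t.\t{strand}\t.\tID={gff_type}_{counter}\n"
                )
        for gid, gene in ann.genes.items():
            g = gene.span
            fh.write(
                f"{g.chrom}\tpiratlas\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{gene.strand}\t.\tID={gid}\n"
            )
            for j, iv in enumerate(gene.exons):
                fh.write(
                    f"{iv.chrom}\tpiratlas\texon\t{iv.start + 1}\t{iv.end}"
                    f"\t.\t{gene.strand}\t.\tID={gid}.e{j + 1};Parent={gid}\n"
                )
            for j, iv in enumerate(gene.utr3):
                fh.write(
                    f"{iv.chrom}\tpiratlas\tthree_prime_UTR\t{iv.start + 1}"
                    f"\t{iv.end}\t.\t{gene.strand}\t.\t"
                    f"ID={gid}.u{j + 1};Parent={gid}\n"
                )


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

def _sample_lengths(
    rng: np.random.Generator, dist: Mapping[int, float], n: int
) -> np.ndarray:
    lengths = np.array(sorted(dist.keys()))
    probs = np.array([dist[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(lengths, size=n, p=probs)


def _apply_u1_bias(
    rng: np.random.Generator,
    seqs: Dict[str, bytearray],
    sites: Sequence[Tuple[str, int, str]],
    u1_prob: float,
) -> None:
    """Rewrite the base at each unique 5' site: U w.p. u1_prob, else non-U.

    On the plus strand the 5' base is the genome base itself (U -> T); on
    the minus strand it is the complement of the genome base (U -> A).
    """
    non_u_plus = np.frombuffer(b"ACG", dtype="S1")
    non_u_minus = np.frombuffer(b"CGT", dtype="S1")
    for chrom, pos, strand in sorted(set(sites)):
        if rng.random() < u1_prob:
            seqs[chrom][pos] = ord("T") if strand == PLUS else ord("A")
        else:
            pool = non_u_plus if strand == PLUS else non_u_minus
            seqs[chrom][pos] = pool[rng.integers(0, 3)][0]


def generate_library(
    config: SyntheticConfig,
    genome: SyntheticGenome,
    ann: AnnotationSet,
    truth: TruthRecord,
    sample: SampleSpec,
    outdir: Optional[str | Path] = None,
    rng: Optional[np.random.Generator] = None,
) -> ReadLibrary:
    """Generate one sample's reads, editing the genome to realise 1U bias.

    Cluster read counts are Poisson(reads_per_kb x len_kb x global_scale);
    ping-pong partners (exact 10-nt 5' overlap, opposite strand) are added
    for a ``pingpong_fraction`` of cluster reads when the sample's
    ping-pong switch is on.  miRNA/siRNA/structural read counts are *not*
    scaled by ``global_scale`` (the shift is a piRNA-specific effect, which
    is what miRNA-based normalization assumes).  With ``outdir`` set,
    genome- and TE-space SAM files and a BED6 mirror are written.
    """
    if rng is None:
        idx = [s.sample_id for s in config.samples].index(sample.sample_id)
        rng = np.random.default_rng([config.seed, 2, idx])
    contig_len = {name: len(seq) for name, seq in genome.contigs.items()}
    scale = sample.global_scale
    pp_on = sample.pingpong

    records: List[Tuple[str, str, int, int, str, str]] = []
    # (space, target, start, end, strand, provenance)
    pair_ids: List[Tuple[int, int]] = []

    def add(space: str, target: str, start: int, length: int, strand: str,
            prov: str) -> int:
        records.append((space, target, start, start + length, strand, prov))
        return len(records) - 1

    # --- planted cluster piRNAs (+ ping-pong partners) ---
    for ci, cl in enumerate(config.planted_clusters):
        lam = cl.reads_per_kb * cl.length / 1000.0 * scale
        n = int(rng.poisson(lam))
        lengths = _sample_lengths(rng, config.length_distribution, n)
        for L in lengths:
            L = int(L)
            start = int(rng.integers(cl.start, cl.end - L + 1))
            if cl.strand_mode == "uni_plus":
                strand = PLUS
            elif cl.strand_mode == "uni_minus":
                strand = MINUS
            else:
                strand = PLUS if rng.random() < 0.5 else MINUS
            i1 = add(GENOME, cl.contig, start, L, strand, f"cluster_{ci}")
            if pp_on and rng.random() < cl.pingpong_fraction:
                L2 = int(_sample_lengths(rng, config.length_distribution, 1)[0])
                if strand == PLUS:
                    q = start + 9            # partner minus 5' end
                    p_start = q - L2 + 1
                    p_end = q + 1
                    p_strand = MINUS
                else:
                    q = start + L - 1        # this read's minus 5' end
                    p_start = q - 9
                    p_end = p_start + L2
                    p_strand = PLUS
                if 0 <= p_start and p_end <= contig_len[cl.contig]:
                    i2 = add(GENOME, cl.contig, p_start, p_end - p_start,
                             p_strand, f"cluster_{ci}")
                    pair_ids.append((i1, i2))

    # --- background genome piRNAs (outside clusters and annotations) ---
    blocked: Dict[str, IntervalTree] = {c: IntervalTree() for c in contig_len}
    for cl in config.planted_clusters:
        blocked[cl.contig].addi(cl.start, cl.end)
    for cat_attr in ("pre_mirna", "endo_sirna", "rrna", "trna", "snorna",
                     "snrna", "te_insertions"):
        for iv in getattr(ann, cat_attr):
            blocked[iv.chrom].addi(iv.start, iv.end)
    for chrom, clen in contig_len.items():
        n_bg = int(rng.poisson(config.background_reads_per_kb * clen / 1000.0
                               * scale))
        for _ in range(n_bg):
            L = int(_sample_lengths(rng, config.length_distribution, 1)[0])
            for _try in range(100):
                start = int(rng.integers(0, clen - L))
                if not blocked[chrom].overlaps(start, start + L):
                    add(GENOME, chrom, start, L,
                        PLUS if rng.random() < 0.5 else MINUS, "background")
                    break

    # --- miRNAs on pre-miRNA loci ---
    if config.mirna_reads and not ann.pre_mirna:
        raise ValueError("mirna_reads > 0 but no pre-miRNA loci")
    for _ in range(config.mirna_reads):
        locus = ann.pre_mirna[int(rng.integers(0, len(ann.pre_mirna)))]
        L = int(_sample_lengths(rng, MIRNA_LENGTH_DISTRIBUTION, 1)[0])
        start = int(rng.integers(locus.start, locus.end - L + 1))
        add(GENOME, locus.chrom, start, L, locus.strand, "mirna")

    # --- siRNAs: endo-siRNA loci (80%) and 21-nt TE-consensus reads ---
    te_names = list(genome.te_consensus)
    for _ in range(config.sirna_reads):
        if ann.endo_sirna and rng.random() < 0.8:
            locus = ann.endo_sirna[int(rng.integers(0, len(ann.endo_sirna)))]
            L = int(_sample_lengths(rng, SIRNA_LENGTH_DISTRIBUTION, 1)[0])
            start = int(rng.integers(locus.start, locus.end - L + 1))
            add(GENOME, locus.chrom, start, L,
                PLUS if rng.random() < 0.5 else MINUS, "sirna")
        else:
            te = te_names[int(rng.integers(0, len(te_names)))]
            L = 21
            start = int(rng.integers(0, len(genome.te_consensus[te]) - L))
            add(TE_CONSENSUS, te, start, L,
                PLUS if rng.random() < 0.5 else MINUS, "sirna")

    # --- structural contamination on rRNA/tRNA/snoRNA/snRNA loci ---
    structural_loci = ann.rrna + ann.trna + ann.snorna + ann.snrna
    if config.structural_reads and not structural_loci:
        raise ValueError("structural_reads > 0 but no structural loci")
    for _ in range(config.structural_reads):
        locus = structural_loci[int(rng.integers(0, len(structural_loci)))]
        max_l = min(30, locus.length())
        L = int(rng.integers(20, max_l + 1))
        start = int(rng.integers(locus.start, locus.end - L + 1))
        add(GENOME, locus.chrom, start, L, locus.strand, "structural")

    # --- TE-consensus piRNAs (mostly antisense), scaled with piRNA content ---
    n_te = int(rng.poisson(config.te_pirna_reads * scale))
    for _ in range(n_te):
        te = te_names[int(rng.integers(0, len(te_names)))]
        L = int(_sample_lengths(rng, config.length_distribution, 1)[0])
        start = int(rng.integers(0, len(genome.te_consensus[te]) - L))
        add(TE_CONSENSUS, te, start, L,
            MINUS if rng.random() < 0.75 else PLUS, "te")

    # --- realise the 1U bias at unique piRNA 5' sites, then extract ---
    genome_sites = [
        (target, start if strand == PLUS else end - 1, strand)
        for space, target, start, end, strand, prov in records
        if space == GENOME and (prov.startswith("cluster")
                                or prov == "background")
    ]
    te_sites = [
        (target, start if strand == PLUS else end - 1, strand)
        for space, target, start, end, strand, prov in records
        if space == TE_CONSENSUS and prov == "te"
    ]
    _apply_u1_bias(rng, genome.contigs, genome_sites, config.u1_prob)
    _apply_u1_bias(rng, genome.te_consensus, te_sites, config.u1_prob)

    reads: List[AlignedRead] = []
    for i, (space, target, start, end, strand, prov) in enumerate(records):
        seqs = genome.contigs if space == GENOME else genome.te_consensus
        seq = seqs[target][start:end].decode()
        rid = f"{sample.sample_id}_r{i:07d}"
        reads.append(AlignedRead(rid, space, target,
                                 GenomicInterval(target, start, end, strand),
                                 n_hits=1, sequence=seq))
        truth.provenance[rid] = (
            "cluster" if prov.startswith("cluster") else prov
        )
    truth.scales[sample.sample_id] = scale
    truth.pingpong_pairs[sample.sample_id] = [
        (reads[i].read_id, reads[j].read_id) for i, j in pair_ids
    ]

    spike_ids = sorted(ann.spike_in_ids)
    spike_alloc = rng.multinomial(
        sample.spike_total, np.full(len(spike_ids), 1.0 / len(spike_ids))
    )
    spike_counts = {sid: int(c) for sid, c in zip(spike_ids, spike_alloc)}

    lib = ReadLibrary(sample.sample_id, sample.condition, reads,
                      spike_counts, total_mapped=len(reads))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sam(
            [r for r in reads if r.space == GENOME],
            {name: len(seq) for name, seq in genome.contigs.items()},
            outdir / f"{sample.sample_id}.genome.sam",
        )
        write_sam(
            [r for r in reads if r.space == TE_CONSENSUS],
            {name: len(seq) for name, seq in genome.te_consensus.items()},
            outdir / f"{sample.sample_id}.te.sam",
        )
        write_bed(
            [r.interval for r in reads if r.space == GENOME],
            outdir / f"{sample.sample_id}.genome.bed",
            names=[r.read_id for r in reads if r.space == GENOME],
        )
        with open(outdir / f"{sample.sample_id}.spikes.tsv", "w") as fh:
            fh.write("sample_id\tspike_id\tcount\n")
            for sid in spike_ids:
                fh.write(f"{sample.sample_id}\t{sid}\t{spike_counts[sid]}\n")
    return lib


def write_sam(
    reads: Sequence[AlignedRead],
    references: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write reads as SAM (NH tag, SEQ in forward-reference orientation)."""
    ref_names = list(references)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": references[n]} for n in ref_names],
    })
    ref_id = {n: i for i, n in enumerate(ref_names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.read_id
            seg.flag = 16 if r.interval.strand == MINUS else 0
            seg.reference_id = ref_id[r.target]
            seg.reference_start = r.interval.start
            seg.mapping_quality = 255
            seg.cigartuples = [(0, r.length())]
            if r.sequence is not None:
                seg.query_sequence = r.sequence
            seg.set_tag("NH", r.n_hits)
            out.write(seg)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class StudyFixture:
    config: SyntheticConfig
    genome: SyntheticGenome
    annotations: AnnotationSet
    truth: TruthRecord
    libraries: List[ReadLibrary]
    manifest: Dict[str, object]


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def generate_study(
    config: Optional[SyntheticConfig] = None,
    outdir: str | Path = "synthetic_study",
) -> StudyFixture:
    """Generate the full fixture set a pipeline run needs.

    Writes genome + TE FASTA, GFF3/BED annotations, per-sample SAM (genome
    and TE space) with BED6 mirrors, the spike-in TSV, a truth JSON and a
    manifest listing every path, the seed and per-file MD5 checksums.  The
    genome FASTA is written after all libraries so that the per-library 1U
    edits are reflected in the sequence.
    """
    if config is None:
        config = default_config()
    config.validate()
    if not config.samples:
        raise ValueError("need at least one sample")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome, ann, truth = generate_genome(config)
    libraries = [
        generate_library(config, genome, ann, truth, sample)
        for sample in config.samples
    ]
    # later libraries may rewrite 5' bases under earlier libraries' reads;
    # re-extract every sequence from the final genome before writing, so
    # read sequences and the emitted FASTA agree exactly
    import dataclasses as _dc

    for lib in libraries:
        refreshed = []
        for r in lib.reads:
            seqs = genome.contigs if r.space == GENOME else genome.te_consensus
            seq = seqs[r.target][r.interval.start:r.interval.end].decode()
            refreshed.append(_dc.replace(r, sequence=seq))
        lib.reads = refreshed
        write_sam(
            [r for r in lib.reads if r.space == GENOME],
            {name: len(seq) for name, seq in genome.contigs.items()},
            outdir / f"{lib.sample_id}.genome.sam",
        )
        write_sam(
            [r for r in lib.reads if r.space == TE_CONSENSUS],
            {name: len(seq) for name, seq in genome.te_consensus.items()},
            outdir / f"{lib.sample_id}.te.sam",
        )
        write_bed(
            [r.interval for r in lib.reads if r.space == GENOME],
            outdir / f"{lib.sample_id}.genome.bed",
            names=[r.read_id for r in lib.reads if r.space == GENOME],
        )
        with open(outdir / f"{lib.sample_id}.spikes.tsv", "w") as fh:
            fh.write("sample_id\tspike_id\tcount\n")
            for sid in sorted(lib.spike_counts):
                fh.write(f"{lib.sample_id}\t{sid}\t{lib.spike_counts[sid]}\n")
    genome.write_fasta(outdir / "genome.fa")
    genome.write_fasta(outdir / "te_consensus.fa", which="te_consensus")
    write_gff3(ann, outdir / "annotations.gff3")
    write_bed(
        [cl.interval() for cl in config.planted_clusters],
        outdir / "planted_clusters.bed",
        names=[f"planted_{i + 1}" for i in range(len(config.planted_clusters))],
    )
    with open(outdir / "spikes.tsv", "w") as fh:
        fh.write("sample_id\tspike_id\tcount\n")
        for lib in libraries:
            for sid in sorted(lib.spike_counts):
                fh.write(f"{lib.sample_id}\t{sid}\t{lib.spike_counts[sid]}\n")
    truth_json = {
        "seed": config.seed,
        "clusters": [asdict(cl) for cl in truth.clusters],
        "scales": truth.scales,
        "provenance_counts": {
            lib.sample_id: {
                label: sum(
                    1 for r in lib.reads
                    if truth.provenance[r.read_id] == label
                )
                for label in sorted(set(truth.provenance.values()))
            }
            for lib in libraries
        },
        "n_pingpong_pairs": {
            s: len(p) for s, p in truth.pingpong_pairs.items()
        },
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)

    files = sorted(p for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "samples": [
            {"sample_id": s.sample_id, "condition": s.condition,
             "genome_sam": f"{s.sample_id}.genome.sam",
             "te_sam": f"{s.sample_id}.te.sam"}
            for s in config.samples
        ],
        "genome_fasta": "genome.fa",
        "te_fasta": "te_consensus.fa",
        "annotations_gff3": "annotations.gff3",
        "spike_table": "spikes.tsv",
        "files": {p.name: _md5(p) for p in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return StudyFixture(config, genome, ann, truth, libraries, manifest)
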