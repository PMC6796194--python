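"""Core coordinate types, annotation containers, overlap engine and format IO.

All genomic coordinates are 0-based half-open (BED-compatible) throughout the
package; GFF3 input (1-based inclusive) is converted on ingest.  Strand is
encoded as ``"+"``, ``"-"`` or ``"."`` (unstranded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pysam
from intervaltree import IntervalTree

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."

GENOME = "genome"
TE_CONSENSUS = "te_consensus"

#: annotation categories reported by :func:`overlapping_categories`
CATEGORIES = (
    "pre_mirna",
    "endo_sirna",
    "rrna",
    "trna",
    "snorna",
    "snrna",
    "te_insertion",
    "utr3",
    "exon",
    "canonical_cluster",
)

STRUCTURAL_CATEGORIES = frozenset({"rrna", "trna", "snorna", "snrna"})


class ParseError(ValueError):
    """Raised when a standard-format file cannot be parsed."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on a named contig."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "need 0 <= start < end"
            )
        if self.strand not in (PLUS, MINUS, UNSTRANDED):
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class AlignedRead:
    """One aligned small-RNA read, in genome or TE-consensus space.

    ``n_hits`` is the number of reported alignments for the read (NH tag);
    multi-mappers are retained only for cluster discovery downstream.
    The 5' end is ``interval.start`` on the plus strand and
    ``interval.end - 1`` on the minus strand.
    """

    read_id: str
    space: str
    target: str
    interval: GenomicInterval
    n_hits: int = 1
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.space not in (GENOME, TE_CONSENSUS):
            raise ValueError(f"invalid space {self.space!r}")
        if not (15 < self.length() <= 50):
            raise ValueError(
                f"read {self.read_id}: length {self.length()} outside (15, 50]"
            )
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length():
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= interval length {self.length()}"
            )

    def length(self) -> int:
        return self.interval.length()

    def five_prime(self) -> int:
        """0-based genomic position of the 5' end."""
        if self.interval.strand == MINUS:
            return self.interval.end - 1
        return self.interval.start


@dataclass
class GeneModel:
    """A gene with its span, exons and 3'UTR intervals."""

    gene_id: str
    span: GenomicInterval
    strand: str
    exons: List[GenomicInterval] = field(default_factory=list)
    utr3: List[GenomicInterval] = field(default_factory=list)


@dataclass
class AnnotationSet:
    """The annotation universe consumed by classification and quantification."""

    pre_mirna: List[GenomicInterval] = field(default_factory=list)
    endo_sirna: List[GenomicInterval] = field(default_factory=list)
    rrna: List[GenomicInterval] = field(default_factory=list)
    trna: List[GenomicInterval] = field(default_factory=list)
    snorna: List[GenomicInterval] = field(default_factory=list)
    snrna: List[GenomicInterval] = field(default_factory=list)
    te_insertions: List[GenomicInterval] = field(default_factory=list)
    canonical_clusters: List[GenomicInterval] = field(default_factory=list)
    genes: Dict[str, GeneModel] = field(default_factory=dict)
    te_consensus_names: Set[str] = field(default_factory=set)
    spike_in_ids: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._index: Optional[Dict[str, Dict[str, IntervalTree]]] = None

    def _intervals_for(self, category: str) -> Iterable[GenomicInterval]:
        if category == "te_insertion":
            return self.te_insertions
        if category == "canonical_cluster":
            return self.canonical_clusters
        if category == "utr3":
            return [iv for g in self.genes.values() for iv in g.utr3]
        if category == "exon":
            return [iv for g in self.genes.values() for iv in g.exons]
        return getattr(self, category)

    def category_index(self) -> Dict[str, Dict[str, IntervalTree]]:
        """Lazy per-category, per-chrom interval trees for overlap queries."""
        if self._index is None:
            idx: Dict[str, Dict[str, IntervalTree]] = {}
            for cat in CATEGORIES:
                per_chrom: Dict[str, IntervalTree] = {}
                for iv in self._intervals_for(cat):
                    per_chrom.setdefault(iv.chrom, IntervalTree()).addi(
                        iv.start, iv.end
                    )
                idx[cat] = per_chrom
            self._index = idx
        return self._index

    def invalidate_index(self) -> None:
        self._index = None


@dataclass
class ReadLibrary:
    """One sample's aligned reads plus its spike-in counts."""

    sample_id: str
    condition: str
    reads: List[AlignedRead]
    spike_counts: Dict[str, int] = field(default_factory=dict)
    total_mapped: int = 0

    def __post_init__(self) -> None:
        if self.total_mapped == 0:
            self.total_mapped = len(self.reads)
        if self.total_mapped < len(self.reads):
            raise ValueError("total_mapped must be >= number of reads")
        if any(c < 0 for c in self.spike_counts.values()):
            raise ValueError("spike counts must be >= 0")

    def spike_total(self) -> int:
        return sum(self.spike_counts.values())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> List[GenomicInterval]:
    """Read BED3/BED6 into intervals (0-based half-open, as BED encodes)."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            strand = fields[5] if len(fields) >= 6 else UNSTRANDED
            if strand not in (PLUS, MINUS):
                strand = UNSTRANDED
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Optional[Sequence[str]] = None,
    scores: Optional[Sequence[float]] = None,
) -> None:
    """Write intervals as BED6 (name ``.``, score 0 unless given)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def _gff3_attributes(col9: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for part in col9.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


#: GFF3 feature type -> AnnotationSet bucket
_GFF3_TYPE_MAP = {
    "pre_miRNA": "pre_mirna",
    "pre_mirna": "pre_mirna",
    "miRNA_primary_transcript": "pre_mirna",
    "endo_siRNA": "endo_sirna",
    "endo_sirna": "endo_sirna",
    "rRNA": "rrna",
    "tRNA": "trna",
    "snoRNA": "snorna",
    "snRNA": "snrna",
    "transposable_element": "te_insertions",
    "te_insertion": "te_insertions",
    "piRNA_cluster": "canonical_clusters",
}


def read_gff3(
    path: str | Path,
    feature_types: Optional[Set[str]] = None,
) -> AnnotationSet:
    """Parse GFF3 into an :class:`AnnotationSet`.

    Coordinates are converted from 1-based inclusive to 0-based half-open
    (start-1, end).  ``gene`` rows require an ``ID`` attribute; ``exon`` and
    ``three_prime_UTR`` rows require ``Parent`` and are attached to their
    gene.  Non-gene feature rows are bucketed by type.
    """
    ann = AnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: fewer than 9 GFF3 columns")
            chrom, _, ftype, start_s, end_s, _, strand, _, col9 = fields[:9]
            if feature_types is not None and ftype not in feature_types:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if strand not in (PLUS, MINUS):
                strand = UNSTRANDED
            try:
                iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            attrs = _gff3_attributes(col9)
            if ftype == "gene":
                gene_id = attrs.get("ID")
                if gene_id is None:
                    raise ParseError(f"{path}:{lineno}: gene row lacks ID")
                ann.genes[gene_id] = GeneModel(gene_id, iv, strand)
            elif ftype in ("exon", "three_prime_UTR"):
                parent = attrs.get("Parent")
                if parent is None:
                    raise ParseError(
                        f"{path}:{lineno}: {ftype} row lacks Parent"
                    )
                gene = ann.genes.get(parent)
                if gene is None:
                    raise ParseError(
                        f"{path}:{lineno}: Parent {parent!r} not seen as gene"
                    )
                (gene.exons if ftype == "exon" else gene.utr3).append(iv)
            elif ftype in _GFF3_TYPE_MAP:
                getattr(ann, _GFF3_TYPE_MAP[ftype]).append(iv)
            # unrecognised feature types are ignored
    return ann


def read_alignments(
    path: str | Path,
    space: str = GENOME,
    min_length: int = 16,
) -> List[AlignedRead]:
    """Read primary alignments from SAM/BAM (or BED6) into AlignedReads.

    Strand comes from SAM flag 0x10, ``n_hits`` from the NH tag (1 when
    absent).  Unmapped, secondary and supplementary records are skipped, as
    are alignments shorter than ``min_length`` (default keeps reads longer
    than 15 nt).  Missing sequence (``*``) is tolerated.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return [
            AlignedRead(f"{path.stem}_{i}", space, iv.chrom, iv)
            for i, iv in enumerate(read_bed(path))
            if iv.length() >= min_length
        ]
    reads: List[AlignedRead] = []
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        for i, rec in enumerate(sam):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            ref_len = rec.reference_length
            if ref_len is None or ref_len < min_length:
                continue
            strand = MINUS if rec.is_reverse else PLUS
            try:
                iv = GenomicInterval(
                    rec.reference_name, rec.reference_start,
                    rec.reference_start + ref_len, strand,
                )
                n_hits = rec.get_tag("NH") if rec.has_tag("NH") else 1
                seq = rec.query_sequence
                if seq is not None and len(seq) != ref_len:
                    seq = None  # indel/clipped alignment; keep coordinates only
                reads.append(
                    AlignedRead(rec.query_name, space, rec.reference_name,
                                iv, int(n_hits), seq)
                )
            except ValueError as exc:
                raise ParseError(f"{path}: record {i}: {exc}") from exc
    return reads


def read_spike_table(path: str | Path) -> Dict[str, Dict[str, int]]:
    """Read a spike-in TSV (sample_id, spike_id, count) into nested dicts."""
    out: Dict[str, Dict[str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:3] == ["sample_id", "spike_id", "count"]:
                continue
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: need 3 columns")
            try:
                count = int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer count") from exc
            if count < 0:
                raise ParseError(f"{path}:{lineno}: negative count")
            out.setdefault(fields[0], {})[fields[1]] = count
    return out


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Load a (small) FASTA into a chrom -> uppercase sequence dict."""
    import pyfaidx

    with pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# overlap engine and coverage
# ---------------------------------------------------------------------------

def overlapping_categories(read: AlignedRead, ann: AnnotationSet) -> Set[str]:
    """Annotation categories overlapping the read by >= 1 bp (strand-blind).

    Only defined for genome-space reads; strand handling is left to callers.
    """
    if read.space != GENOME:
        raise ValueError("overlapping_categories requires a genome-space read")
    idx = ann.category_index()
    iv = read.interval
    hits: Set[str] = set()
    for cat in CATEGORIES:
        tree = idx[cat].get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            hits.add(cat)
    return hits


def coverage_track(
    reads: Iterable[AlignedRead],
    region: GenomicInterval,
    strand_mode: str = "both",
    pseudo_count: int = 0,
) -> np.ndarray:
    """Per-base read coverage over ``region`` plus a constant pseudo-count.

    ``strand_mode`` selects reads on ``"plus"``, ``"minus"`` or ``"both"``
    strands.  An empty read set yields a constant pseudo-count vector.
    """
    if strand_mode not in ("both", "plus", "minus"):
        raise ValueError(f"invalid strand_mode {strand_mode!r}")
    cov = np.zeros(region.length(), dtype=np.int64)
    want = {"plus": PLUS, "minus": MINUS}.get(strand_mode)
    for read in reads:
        iv = read.interval
        if iv.chrom != region.chrom:
            continue
        if want is not None and iv.strand != want:
            continue
        lo = max(iv.start, region.start) - region.start
        hi = min(iv.end, region.end) - region.start
        if lo < hi:
            cov[lo:hi] += 1
    return cov + pseudo_count
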