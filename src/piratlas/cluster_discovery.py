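"""De-novo piRNA cluster discovery and canonical-cluster harmonization.

Discovery is a density-based scan over deduplicated read footprints, the
limit of a 1-nt-step sliding window:

1. seed regions = union of unique read footprints (overlapping/adjacent
   reads merged);
2. merge regions whose gap is <= ``seed_merge_gap`` (250 nt);
3. discard regions with fewer than ``min_density`` (3.0) unique reads per
   kilobase of the current region extent;
4. merge survivors whose gap is <= ``region_merge_gap`` (1,000 nt), and
   re-apply the density filter on the merged extents;
5. keep regions strictly longer than ``min_size`` (2,000 nt).

Gap merges are inclusive ("within N nt"); the final size filter is strict
("greater than").  Unique reads are alignments deduplicated by
(chrom, start, end, strand); density is recomputed, and re-checked,
after every merge, so every reported cluster satisfies the density
threshold over its final extent.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from piratlas.core_model import (
    MINUS,
    PLUS,
    UNSTRANDED,
    AlignedRead,
    GenomicInterval,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterParams:
    seed_merge_gap: int = 250          # nt, inclusive
    min_density: float = 3.0           # unique reads per kb
    region_merge_gap: int = 1000       # nt, inclusive
    min_size: int = 2000               # nt, strict (>)
    canonical_collapse_gap: int = 25000  # nt, strict (<)

    def __post_init__(self) -> None:
        if min(self.seed_merge_gap, self.region_merge_gap,
               self.canonical_collapse_gap) < 0 or self.min_density < 0:
            raise ValueError("gaps and density must be >= 0")
        if self.min_size <= 0:
            raise ValueError("min_size must be > 0")


@dataclass(frozen=True)
class UniqueRead:
    """A deduplicated alignment position with its copy number."""

    chrom: str
    start: int
    end: int
    strand: str
    multiplicity: int = 1


@dataclass(frozen=True)
class ClusterCall:
    interval: GenomicInterval
    n_unique_reads: int
    density: float                     # unique reads per kb of the interval
    n_total_reads: int
    plus_fraction: float
    source: str = "discovered"


def dedupe_reads(reads: Iterable[AlignedRead]) -> List[UniqueRead]:
    """Collapse reads to distinct (chrom, start, end, strand) positions."""
    counter: Counter = Counter(
        (r.interval.chrom, r.interval.start, r.interval.end, r.interval.strand)
        for r in reads
    )
    return [
        UniqueRead(chrom, start, end, strand, mult)
        for (chrom, start, end, strand), mult in sorted(counter.items())
    ]


def _merge_gap(regions: List[Tuple[int, int]], gap: int) -> List[Tuple[int, int]]:
    """Merge sorted half-open regions whose inter-region gap is <= gap."""
    merged: List[Tuple[int, int]] = []
    for start, end in regions:
        if merged and start - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _region_stats(
    region: Tuple[int, int], uniques: Sequence[UniqueRead]
) -> Tuple[int, float, int, float]:
    """(n_unique, density/kb, n_total, plus_fraction) of reads in region."""
    start, end = region
    inside = [u for u in uniques if u.start < end and start < u.end]
    n_unique = len(inside)
    n_total = sum(u.multiplicity for u in inside)
    n_plus = sum(u.multiplicity for u in inside if u.strand == PLUS)
    density = n_unique / ((end - start) / 1000.0)
    plus_fraction = n_plus / n_total if n_total else 0.0
    return n_unique, density, n_total, plus_fraction


def discover_clusters(
    reads: Iterable[AlignedRead],
    params: ClusterParams = ClusterParams(),
) -> List[ClusterCall]:
    """Run the five-step density scan over putative piRNA reads (23-35 nt).

    Returns non-overlapping calls sorted by (chrom, start), each with the
    unique-read count and density recomputed over its final extent.  An
    empty read set yields an empty list.
    """
    uniques = dedupe_reads(reads)
    by_chrom: Dict[str, List[UniqueRead]] = {}
    for u in uniques:
        by_chrom.setdefault(u.chrom, []).append(u)

    calls: List[ClusterCall] = []
    for chrom in sorted(by_chrom):
        chrom_uniques = sorted(by_chrom[chrom], key=lambda u: (u.start, u.end))
        footprints = [(u.start, u.end) for u in chrom_uniques]
        # 1. union of footprints (overlapping or adjacent merged)
        regions = _merge_gap(footprints, 0)
        # 2. close small gaps
        regions = _merge_gap(regions, params.seed_merge_gap)
        # 3. density filter on the current extent
        regions = [
            r for r in regions
            if _region_stats(r, chrom_uniques)[1] >= params.min_density
        ]
        # 4. merge surviving neighbours; density re-checked on merged extent
        regions = _merge_gap(regions, params.region_merge_gap)
        regions = [
            r for r in regions
            if _region_stats(r, chrom_uniques)[1] >= params.min_density
        ]
        # 5. strict size filter
        regions = [r for r in regions if r[1] - r[0] > params.min_size]
        for start, end in regions:
            n_unique, density, n_total, plus_frac = _region_stats(
                (start, end), chrom_uniques
            )
            calls.append(
                ClusterCall(
                    GenomicInterval(chrom, start, end, UNSTRANDED),
                    n_unique, density, n_total, plus_frac,
                )
            )
    return calls


def harmonize_canonical(
    fragments: Dict[str, List[GenomicInterval]],
    collapse_gap: int = 25000,
) -> Dict[str, GenomicInterval]:
    """Collapse each named cluster's fragments to one representative interval.

    Overlapping fragments are unioned, fragments separated by strictly less
    than ``collapse_gap`` are merged, and among the remaining disjoint
    pieces the longest is kept (ties broken by smaller start).  Names with
    no fragments are omitted with a warning.
    """
    out: Dict[str, GenomicInterval] = {}
    for name, frags in fragments.items():
        if not frags:
            logger.warning("cluster %s has no fragments; omitted", name)
            continue
        chroms = {f.chrom for f in frags}
        best: Tuple[int, int] | None = None
        best_chrom = None
        for chrom in sorted(chroms):
            regions = sorted(
                (f.start, f.end) for f in frags if f.chrom == chrom
            )
            regions = _merge_gap(regions, 0)          # collapse overlaps
            regions = _merge_gap(regions, collapse_gap - 1)  # strict < gap
            for start, end in regions:
                if best is None or (end - start, -start) > (
                    best[1] - best[0], -best[0]
                ):
                    best = (start, end)
                    best_chrom = chrom
        assert best is not None and best_chrom is not None
        out[name] = GenomicInterval(best_chrom, best[0], best[1], UNSTRANDED)
    return out


def compare_to_reference(
    calls: Sequence[ClusterCall],
    reference: Sequence[GenomicInterval],
) -> Dict[str, object]:
    """Overlap report between discovered calls and a reference cluster set.

    A reference cluster counts as covered when any call shares >= 1 bp with
    it; a call overlapping no reference cluster is novel.
    """
    call_ivs = [c.interval for c in calls]
    best_overlap = [
        max((iv.overlap_length(ref) for iv in call_ivs), default=0)
        for ref in reference
    ]
    n_covered = sum(1 for b in best_overlap if b > 0)
    n_novel = sum(
        1 for iv in call_ivs
        if all(iv.overlap_length(ref) == 0 for ref in reference)
    )
    return {
        "n_reference": len(reference),
        "n_calls": len(calls),
        "reference_covered_fraction": (
            n_covered / len(reference) if reference else 0.0
        ),
        "novel_call_fraction": n_novel / len(calls) if calls else 0.0,
        "best_overlap_lengths": best_overlap,
    }


def strandedness(
    call: ClusterCall,
    reads: Iterable[AlignedRead],
    uni_threshold: float = 0.9,
) -> str:
    """Classify a cluster as uni_plus / uni_minus / dual from its reads.

    Plus-strand fraction >= 0.9 is uni_plus, <= 0.1 is uni_minus, anything
    in between (including exactly 0.89) is dual.
    """
    iv = call.interval
    n_plus = n_total = 0
    for r in reads:
        if r.interval.chrom == iv.chrom and r.interval.overlaps(iv):
            n_total += 1
            if r.interval.strand == PLUS:
                n_plus += 1
    if n_total == 0:
        raise ValueError("cannot assess strandedness with zero reads")
    frac = n_plus / n_total
    if frac >= uni_threshold:
        return "uni_plus"
    if frac <= 1.0 - uni_threshold:
        return "uni_minus"
    return "dual"
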