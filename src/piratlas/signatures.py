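"""Ping-pong 5'-overlap signatures and first-10-nt (1U bias) matrices.

The ping-pong amplification loop produces sense/antisense piRNA pairs whose
5' ends overlap by exactly 10 nt.  For a plus-strand read with 5' end at
``p`` and a minus-strand read with 5' end at ``q`` (the rightmost aligned
base), the 5'-overlap distance is ``d = q - p + 1``; the signature is the
enrichment of pair counts at d = 10 over the other distances.

The z-score reported here (``z10``) is defined as
``(c10 - mean(c_d, d != 10)) / sd(c_d, d != 10)`` with the sample standard
deviation over distances 1..30; it is this package's own statistic and is
named ``z10`` in all outputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from piratlas.core_model import (
    MINUS,
    PLUS,
    AlignedRead,
    GenomicInterval,
)
from piratlas.cluster_discovery import ClusterCall, dedupe_reads

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
BASES = ("A", "C", "G", "U")


@dataclass
class PingPongProfile:
    """Histogram of 5'-overlap distances with the overlap-10 statistic."""

    overlap_counts: Dict[int, int]
    z10: Optional[float] = None        # None while unset or undefined
    max_distance: int = 30

    @property
    def n_pairs_total(self) -> int:
        return sum(self.overlap_counts.values())


@dataclass
class NucleotideFrequencyMatrix:
    """Per-position base fractions over the first 10 nt of unique 5' sites."""

    freq: pd.DataFrame                 # index 1..10, columns A/C/G/U
    n_sites: int


def _five_prime_position_counts(
    reads: Iterable[AlignedRead],
    weighted: bool = True,
) -> Tuple[Counter, Counter]:
    """Multiplicity-weighted 5'-end counts per (chrom, pos) by strand."""
    plus: Counter = Counter()
    minus: Counter = Counter()
    for u in dedupe_reads(reads):
        w = u.multiplicity if weighted else 1
        if u.strand == PLUS:
            plus[(u.chrom, u.start)] += w
        elif u.strand == MINUS:
            minus[(u.chrom, u.end - 1)] += w
    return plus, minus


def ping_pong_histogram(
    reads: Iterable[AlignedRead],
    max_distance: int = 30,
    weighted: bool = True,
) -> PingPongProfile:
    """Count 5'-overlap pairs at each distance d in [1, max_distance].

    Pairs are counted on deduplicated reads; by default each (plus, minus)
    position pair contributes the product of the two positions' read
    multiplicities (``weighted=False`` counts distinct position pairs).
    """
    plus, minus = _five_prime_position_counts(reads, weighted)
    counts = {d: 0 for d in range(1, max_distance + 1)}
    for (chrom, p), w_plus in plus.items():
        for d in range(1, max_distance + 1):
            w_minus = minus.get((chrom, p + d - 1))
            if w_minus:
                counts[d] += (w_plus * w_minus) if weighted else 1
    return PingPongProfile(counts, max_distance=max_distance)


def ping_pong_zscore(profile: PingPongProfile) -> Optional[float]:
    """Overlap-10 enrichment over the distance 1..30 background.

    Returns None (undefined) when the background standard deviation is
    zero and the overlap-10 count deviates from it; a perfectly flat
    histogram scores exactly 0.
    """
    counts = profile.overlap_counts
    background = np.array(
        [counts.get(d, 0) for d in range(1, profile.max_distance + 1) if d != 10],
        dtype=float,
    )
    sd = background.std(ddof=1)
    delta = counts.get(10, 0) - background.mean()
    if sd == 0:
        return 0.0 if delta == 0 else None
    return float(delta / sd)


def ping_pong_scan(
    reads: Sequence[AlignedRead],
    clusters: Sequence[ClusterCall],
    max_distance: int = 30,
) -> pd.DataFrame:
    """Per-cluster ping-pong table, sorted by signature count descending.

    The signature count is the number of distinct (plus 5' position,
    minus 5' position) pairs at exact distance 10 inside the cluster (a
    count of loci, not of read pairs); z10 uses the weighted histogram.
    """
    rows: List[Dict[str, object]] = []
    for i, cl in enumerate(clusters):
        iv = cl.interval
        inside = [
            r for r in reads
            if r.interval.chrom == iv.chrom and r.interval.overlaps(iv)
        ]
        weighted = ping_pong_histogram(inside, max_distance, weighted=True)
        distinct = ping_pong_histogram(inside, max_distance, weighted=False)
        z10 = ping_pong_zscore(weighted)
        rows.append({
            "cluster": f"{iv.chrom}:{iv.start}-{iv.end}",
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "signature_count": distinct.overlap_counts.get(10, 0),
            "pair_count_weighted": weighted.overlap_counts.get(10, 0),
            "z10": np.nan if z10 is None else z10,
        })
    table = pd.DataFrame(
        rows,
        columns=["cluster", "chrom", "start", "end",
                 "signature_count", "pair_count_weighted", "z10"],
    )
    return table.sort_values(
        "signature_count", ascending=False, kind="stable"
    ).reset_index(drop=True)


def _fetch(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    seq = genome[chrom][start:end]
    if not isinstance(seq, str):   # pyfaidx raw sequence
        seq = str(seq)
    return seq.upper()


def first10_frequency_matrix(
    reads: Iterable[AlignedRead],
    genome: Mapping[str, str],
) -> NucleotideFrequencyMatrix:
    """Base-frequency matrix of the first 10 nt at unique piRNA start sites.

    Reads are collapsed to unique (chrom, 5' position, strand) sites; for
    each site the 10-nt genomic sequence starting at the 5' end is taken in
    read orientation (reverse-complemented on the minus strand).  T is
    reported as U.  Sites within 10 nt of a contig end are skipped with a
    warning; zero usable sites is an error.
    """
    import warnings

    sites = {
        (u.chrom, u.start if u.strand == PLUS else u.end - 1, u.strand)
        for u in dedupe_reads(reads)
        if u.strand in (PLUS, MINUS)
    }
    tally = np.zeros((10, 4), dtype=np.int64)
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}   # T column reported as U
    n_used = 0
    for chrom, pos, strand in sorted(sites):
        contig_len = len(genome[chrom])
        if strand == PLUS:
            if pos + 10 > contig_len:
                warnings.warn(f"site {chrom}:{pos}+ within 10 nt of contig end")
                continue
            tenmer = _fetch(genome, chrom, pos, pos + 10)
        else:
            if pos - 9 < 0:
                warnings.warn(f"site {chrom}:{pos}- within 10 nt of contig end")
                continue
            tenmer = _fetch(genome, chrom, pos - 9, pos + 1)
            tenmer = tenmer.translate(_COMPLEMENT)[::-1]
        usable = True
        for j, base in enumerate(tenmer):
            if base not in base_index:
                usable = False
                break
        if not usable:
            continue
        for j, base in enumerate(tenmer):
            tally[j, base_index[base]] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable start sites for frequency matrix")
    freq = pd.DataFrame(
        tally / n_used, index=range(1, 11), columns=list(BASES)
    )
    return NucleotideFrequencyMatrix(freq, n_used)
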