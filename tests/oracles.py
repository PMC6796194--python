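"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: the classifier oracle is
a flat nested conditional over annotation flags, the cluster oracle
materialises per-base read presence and applies the five discovery steps by
explicit pairwise gap scanning, the ping-pong oracle enumerates all read
pairs, and the BH oracle evaluates the step-up definition directly.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np


def classify_oracle(
    length: int,
    flags: Set[str],
    space: str = "genome",
    mirna_max: int = 24,
    sirna_max: int = 22,
    sirna_te: int = 21,
    pirna_min: int = 23,
    pirna_max: int = 30,
) -> str:
    """Flat nested-conditional biotype reference."""
    if "rrna" in flags or "trna" in flags or "snorna" in flags \
            or "snrna" in flags:
        return "structural_excluded"
    else:
        if length <= mirna_max and "pre_mirna" in flags:
            return "miRNA"
        else:
            if length <= sirna_max and "endo_sirna" in flags:
                return "siRNA"
            elif length == sirna_te and (
                space == "te_consensus" or "te_insertion" in flags
            ):
                return "siRNA"
            else:
                if pirna_min <= length <= pirna_max:
                    return "piRNA"
                else:
                    return "other"


Footprint = Tuple[str, int, int, str]  # chrom, start, end, strand


def _pairwise_merge(
    regions: List[Tuple[int, int]], gap: int
) -> List[Tuple[int, int]]:
    """Repeatedly merge any two regions whose gap is <= gap, until stable."""
    regions = sorted(regions)
    changed = True
    while changed:
        changed = False
        for i in range(len(regions) - 1):
            a, b = regions[i], regions[i + 1]
            if b[0] - a[1] <= gap:
                regions[i:i + 2] = [(a[0], max(a[1], b[1]))]
                changed = True
                break
    return regions


def cluster_oracle(
    footprints: Sequence[Footprint],
    seed_merge_gap: int = 250,
    min_density: float = 3.0,
    region_merge_gap: int = 1000,
    min_size: int = 2000,
) -> List[Tuple[str, int, int]]:
    """Per-base brute-force discovery reference.

    Footprints must already be the deduplicated unique alignments; returns
    the final (chrom, start, end) regions.
    """
    uniq = sorted(set(footprints))
    out: List[Tuple[str, int, int]] = []
    for chrom in sorted({f[0] for f in uniq}):
        mine = [f for f in uniq if f[0] == chrom]
        hi = max(f[2] for f in mine)
        present = np.zeros(hi + 1, dtype=bool)
        for _, s, e, _ in mine:
            present[s:e] = True
        # step 1: contiguous runs of covered bases
        regions: List[Tuple[int, int]] = []
        i = 0
        while i <= hi:
            if present[i]:
                j = i
                while j <= hi and present[j]:
                    j += 1
                regions.append((i, j))
                i = j
            else:
                i += 1
        # step 2
        regions = _pairwise_merge(regions, seed_merge_gap)
        # step 3: density over current extent

        def n_unique(region: Tuple[int, int]) -> int:
            return sum(1 for _, s, e, _ in mine
                       if s < region[1] and region[0] < e)

        regions = [
            r for r in regions
            if n_unique(r) / ((r[1] - r[0]) / 1000.0) >= min_density
        ]
        # step 4 (density recomputed and re-checked on the merged extent)
        regions = _pairwise_merge(regions, region_merge_gap)
        regions = [
            r for r in regions
            if n_unique(r) / ((r[1] - r[0]) / 1000.0) >= min_density
        ]
        # step 5
        regions = [r for r in regions if r[1] - r[0] > min_size]
        out.extend((chrom, s, e) for s, e in regions)
    return out


def pingpong_pairs_oracle(
    reads: Sequence[Tuple[str, int, int, str]],
    distance: int = 10,
) -> int:
    """All-pairs count of (plus, minus) unique-position pairs at a 5'-overlap
    distance, weighted by position multiplicities."""
    from collections import Counter

    uniq = Counter(reads)
    total = 0
    for (c1, s1, e1, st1), w1 in uniq.items():
        if st1 != "+":
            continue
        for (c2, s2, e2, st2), w2 in uniq.items():
            if st2 != "-" or c2 != c1:
                continue
            if (e2 - 1) - s1 + 1 == distance:
                total += w1 * w2
    return total


def bh_oracle(pvalues: Sequence[float]) -> np.ndarray:
    """Direct evaluation of q_(i) = min_{j >= i} (m/j) p_(j), input order."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(m / rank_j * p[order[rank_j - 1]]
                for rank_j in range(rank_i, m + 1)),
            1.0,
        )
    return np.array(q)
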