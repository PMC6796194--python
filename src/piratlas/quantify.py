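"""Feature counting, normalization, filtering and significance calling.

Counting is whole-read, >= 1 bp overlap, with no fractional assignment: a
read increments every feature it overlaps.  Normalization supports plain
totals, miRNA-count denominators (with the two most differentially
expressed miRNAs excluded) and spike-in factors anchored at geometric mean
one ("effective library size" = total mapped reads x factor).

The inferential test here is an explicitly labelled stand-in: a two-sided
exact binomial test of the pooled group-A count against the expectation
implied by the two groups' summed denominators.  It is not a
negative-binomial GLM and outputs name it ``binomial_standin``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

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
)


@dataclass
class CountMatrix:
    """Features x samples integer counts with optional normalization info."""

    feature_ids: List[str]
    sample_ids: List[str]
    counts: np.ndarray
    feature_lengths: Optional[np.ndarray] = None
    norm_denominators: Optional[np.ndarray] = None
    norm_factors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape inconsistent with ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        for name in ("norm_denominators", "norm_factors"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (len(self.sample_ids),) or np.any(v <= 0):
                    raise ValueError(f"{name} must be positive per sample")
                setattr(self, name, v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.feature_ids, columns=self.sample_ids
        )


@dataclass(frozen=True)
class DGEParams:
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    cpm_cutoff: float = 20.0      # piRNA-cluster default; 700/1000 for 3'UTRs
    min_samples: int = 3
    pseudo_count: float = 1.0

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must be in (0, 1)")


def _feature_trees(
    features: Mapping[str, GenomicInterval]
) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for fid, iv in features.items():
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, fid)
    return trees


def count_features(
    reads: Iterable[AlignedRead],
    features: Mapping[str, GenomicInterval],
    strand_mode: str = "both",
) -> pd.Series:
    """Count reads per feature (>= 1 bp overlap; multi-assignment allowed).

    ``sense``/``antisense`` judge the read's strand against the feature's;
    those modes require stranded features.
    """
    if strand_mode not in ("both", "sense", "antisense"):
        raise ValueError(f"invalid strand_mode {strand_mode!r}")
    if strand_mode != "both":
        unstranded = [f for f, iv in features.items() if iv.strand == UNSTRANDED]
        if unstranded:
            raise ValueError(
                f"strand_mode={strand_mode} with unstranded features: "
                f"{unstranded[:3]}"
            )
    trees = _feature_trees(features)
    counts = pd.Series(0, index=list(features.keys()), dtype=np.int64)
    for read in reads:
        iv = read.interval
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            fid = hit.data
            fstrand = features[fid].strand
            if strand_mode == "sense" and iv.strand != fstrand:
                continue
            if strand_mode == "antisense" and (
                iv.strand == fstrand or iv.strand == UNSTRANDED
            ):
                continue
            counts[fid] += 1
    return counts


def te_expression(
    reads: Iterable[AlignedRead],
    te_names: Iterable[str],
    pirna_mode: bool = True,
    sirna_length: int = 21,
) -> pd.DataFrame:
    """Per-TE sense/antisense counts from TE-consensus-space reads.

    Plus-strand alignments to the consensus are sense, minus are antisense.
    In piRNA mode, reads of exactly 21 nt are excluded (they are siRNAs).
    Reads aligned to a TE not in ``te_names`` raise an error listing the
    offenders.
    """
    te_names = list(te_names)
    table = pd.DataFrame(
        0, index=te_names, columns=["sense", "antisense"], dtype=np.int64
    )
    unknown = set()
    for read in reads:
        if read.space != TE_CONSENSUS:
            continue
        if pirna_mode and read.length() == sirna_length:
            continue
        if read.target not in table.index:
            unknown.add(read.target)
            continue
        col = "sense" if read.interval.strand == PLUS else "antisense"
        table.loc[read.target, col] += 1
    if unknown:
        raise ValueError(f"unknown TE names: {sorted(unknown)}")
    return table


def cpm(
    matrix: CountMatrix,
    denominators: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Counts per million of the per-sample denominator."""
    if denominators is None:
        denominators = matrix.norm_denominators
    if denominators is None:
        raise ValueError("no denominators available")
    denom = np.asarray(denominators, dtype=float)
    if np.any(denom <= 0):
        raise ValueError("denominators must be > 0")
    return pd.DataFrame(
        matrix.counts / denom[None, :] * 1e6,
        index=matrix.feature_ids, columns=matrix.sample_ids,
    )


def rpkm(matrix: CountMatrix, library_totals: Sequence[float]) -> pd.DataFrame:
    """Reads per kilobase of feature per million library reads."""
    if matrix.feature_lengths is None:
        raise ValueError("feature_lengths required for RPKM")
    lengths = np.asarray(matrix.feature_lengths, dtype=float)
    totals = np.asarray(library_totals, dtype=float)
    if np.any(totals <= 0) or np.any(lengths <= 0):
        raise ValueError("lengths and library totals must be > 0")
    return pd.DataFrame(
        matrix.counts / (lengths[:, None] / 1000.0) / (totals[None, :] / 1e6),
        index=matrix.feature_ids, columns=matrix.sample_ids,
    )


def mirna_denominators(
    mirna_counts: CountMatrix,
    n_exclude: int = 2,
    groups: Optional[Mapping[str, str]] = None,
    pseudo_count: float = 1.0,
) -> pd.Series:
    """Per-sample miRNA-count denominators, dropping the most DE miRNAs.

    miRNAs are ranked by |log2 ratio of group-mean CPM| between the two
    condition groups, with each candidate's CPM computed against the miRNA
    total *excluding itself* (leave-one-out; otherwise a single dominant
    shifted miRNA distorts the denominator and makes the flat miRNAs look
    differential).  The top ``n_exclude`` are dropped and the denominator
    is each sample's sum of the remaining miRNA counts.  Without two
    groups the ranking falls back to cross-sample log-CPM variance, with a
    warning.
    """
    if len(mirna_counts.feature_ids) < n_exclude + 1:
        raise ValueError("need more miRNA features than n_exclude")
    totals = mirna_counts.counts.sum(axis=0).astype(float)
    if np.any(totals <= 0):
        raise ValueError("each sample needs a positive miRNA total")
    loo = np.maximum(totals[None, :] - mirna_counts.counts, 1.0)
    cpm_mat = mirna_counts.counts / loo * 1e6
    conditions = (
        [groups[s] for s in mirna_counts.sample_ids] if groups else []
    )
    unique_conditions = sorted(set(conditions))
    if groups and len(unique_conditions) == 2:
        mask_a = np.array([c == unique_conditions[0] for c in conditions])
        mean_a = cpm_mat[:, mask_a].mean(axis=1)
        mean_b = cpm_mat[:, ~mask_a].mean(axis=1)
        score = np.abs(
            np.log2((mean_a + pseudo_count) / (mean_b + pseudo_count))
        )
    else:
        if groups:
            warnings.warn(
                "need exactly two condition groups to rank miRNAs by group "
                "ratio; falling back to cross-sample log-CPM variance"
            )
        else:
            warnings.warn(
                "no groups given; ranking miRNAs by cross-sample log-CPM "
                "variance"
            )
        score = np.log2(cpm_mat + pseudo_count).var(axis=1)
    keep = np.argsort(-score, kind="stable")[n_exclude:]
    denominators = mirna_counts.counts[keep, :].sum(axis=0).astype(float)
    return pd.Series(denominators, index=mirna_counts.sample_ids)


def spikein_factors(
    spike_totals: Mapping[str, float],
    total_mapped: Optional[Mapping[str, float]] = None,
) -> Tuple[pd.Series, Optional[pd.Series]]:
    """Spike-in normalization factors and effective library sizes.

    Factors are proportional to 1/spike_total, rescaled so their geometric
    mean is 1; the effective library size is total_mapped x factor.
    """
    samples = list(spike_totals.keys())
    totals = np.array([spike_totals[s] for s in samples], dtype=float)
    if np.any(totals <= 0):
        raise ValueError("spike totals must be > 0")
    inv = 1.0 / totals
    factors = inv / np.exp(np.mean(np.log(inv)))
    factors_s = pd.Series(factors, index=samples)
    if total_mapped is None:
        return factors_s, None
    eff = pd.Series(
        [total_mapped[s] * factors_s[s] for s in samples], index=samples
    )
    return factors_s, eff


def expression_filter(
    matrix: CountMatrix,
    cpm_cutoff: float,
    min_samples: int,
    denominators: Optional[Sequence[float]] = None,
) -> CountMatrix:
    """Keep features with CPM > cutoff in at least ``min_samples`` samples."""
    cpm_mat = cpm(matrix, denominators).to_numpy()
    keep = (cpm_mat > cpm_cutoff).sum(axis=1) >= min_samples
    return CountMatrix(
        [f for f, k in zip(matrix.feature_ids, keep) if k],
        list(matrix.sample_ids),
        matrix.counts[keep, :],
        None if matrix.feature_lengths is None
        else np.asarray(matrix.feature_lengths)[keep],
        matrix.norm_denominators,
        matrix.norm_factors,
    )


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} (m/j) p_(j), clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_significant(
    log2fc: Sequence[float],
    qvalues: Sequence[float],
    params: DGEParams = DGEParams(),
) -> List[str]:
    """Per-feature up/down/ns with inclusive fold-change and FDR bounds."""
    lfc = np.asarray(log2fc, dtype=float)
    q = np.asarray(qvalues, dtype=float)
    if lfc.shape != q.shape:
        raise ValueError("log2fc and qvalues must align")
    cut = np.log2(params.fc_threshold)
    out = []
    for f, qq in zip(lfc, q):
        if qq <= params.fdr_threshold and f >= cut:
            out.append("up")
        elif qq <= params.fdr_threshold and f <= -cut:
            out.append("down")
        else:
            out.append("ns")
    return out


def two_group_test(
    counts: Sequence[int],
    groups: Sequence[str],
    denominators: Sequence[float],
) -> float:
    """Two-sided exact binomial stand-in test for one feature.

    Pools counts within each of the two groups and tests the group-A count
    against Binomial(n = total count, p = denominator share of group A).
    Zero total count gives p = 1.
    """
    counts = np.asarray(counts)
    denom = np.asarray(denominators, dtype=float)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError("two_group_test needs exactly two groups")
    mask_a = np.array([g == labels[0] for g in groups])
    k_a = int(counts[mask_a].sum())
    n = int(counts.sum())
    if n == 0:
        return 1.0
    p_a = denom[mask_a].sum() / denom.sum()
    return float(stats.binomtest(k_a, n, p_a, alternative="two-sided").pvalue)


def group_log2fc(
    matrix: CountMatrix,
    groups: Mapping[str, str],
    denominators: Sequence[float],
    pseudo_count: float = 1.0,
) -> pd.Series:
    """log2 of group-mean CPM ratio, second sorted condition label over the
    first, with the pseudo-count added to both means."""
    cpm_mat = cpm(matrix, denominators)
    conditions = [groups[s] for s in matrix.sample_ids]
    labels = sorted(set(conditions))
    if len(labels) != 2:
        raise ValueError("group_log2fc needs exactly two groups")
    mask_a = np.array([c == labels[0] for c in conditions])
    mean_a = cpm_mat.to_numpy()[:, mask_a].mean(axis=1)
    mean_b = cpm_mat.to_numpy()[:, ~mask_a].mean(axis=1)
    return pd.Series(
        np.log2((mean_b + pseudo_count) / (mean_a + pseudo_count)),
        index=matrix.feature_ids,
    )


def utr3_pirna_report(
    reads: Iterable[AlignedRead],
    genes: Mapping[str, GeneModel],
    te_insertions: Sequence[GenomicInterval],
    min_count: int = 1,
) -> pd.DataFrame:
    """Per-gene 3'UTR piRNA production classes (sense/antisense/both/none).

    Sense counts piRNA reads on the gene's strand overlapping any 3'UTR
    interval; antisense the opposite strand.  A class requires its count to
    reach ``min_count``.  ``has_te_fragment`` flags 3'UTRs overlapping an
    annotated TE insertion.  Genes without a 3'UTR report class none.
    """
    te_trees: Dict[str, IntervalTree] = {}
    for iv in te_insertions:
        te_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    utr_trees: Dict[str, IntervalTree] = {}
    for gid, gene in genes.items():
        for iv in gene.utr3:
            utr_trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, gid
            )
    sense: Dict[str, int] = {g: 0 for g in genes}
    antisense: Dict[str, int] = {g: 0 for g in genes}
    for read in reads:
        iv = read.interval
        tree = utr_trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in {h.data for h in tree.overlap(iv.start, iv.end)}:
            if iv.strand == genes[hit].strand:
                sense[hit] += 1
            elif iv.strand != UNSTRANDED:
                antisense[hit] += 1
    rows = []
    for gid, gene in genes.items():
        s, a = sense[gid], antisense[gid]
        if not gene.utr3:
            cls = "none"
        elif s >= min_count and a >= min_count:
            cls = "both"
        elif s >= min_count:
            cls = "sense"
        elif a >= min_count:
            cls = "antisense"
        else:
            cls = "none"
        has_te = any(
            iv.chrom in te_trees and te_trees[iv.chrom].overlaps(iv.start, iv.end)
            for iv in gene.utr3
        )
        rows.append({
            "gene_id": gid, "sense_count": s, "antisense_count": a,
            "producer_class": cls, "has_te_fragment": has_te,
        })
    return pd.DataFrame(
        rows, columns=["gene_id", "sense_count", "antisense_count",
                       "producer_class", "has_te_fragment"],
    ).set_index("gene_id")
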