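"""Small-RNA biotype classification by length + annotation rules.

Rules are applied in a fixed precedence (structural > miRNA > siRNA >
piRNA > other):

1. overlap with rRNA/tRNA/snoRNA/snRNA          -> structural_excluded
2. length <= 24 nt and overlap with pre-miRNA   -> miRNA
3. length <= 22 nt and overlap with endo-siRNA, or exactly 21 nt and
   TE-derived (TE-consensus alignment or genomic TE insertion) -> siRNA
4. 23-30 nt                                     -> piRNA
5. otherwise                                    -> other

Annotation overlap is strand-blind at this layer; strand only matters in
quantification and signature stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Set, Tuple

from piratlas.core_model import (
    GENOME,
    STRUCTURAL_CATEGORIES,
    TE_CONSENSUS,
    AlignedRead,
    AnnotationSet,
    ReadLibrary,
    overlapping_categories,
)

LABELS = ("structural_excluded", "miRNA", "siRNA", "piRNA", "other")


@dataclass(frozen=True)
class ClassifierParams:
    """Length windows for the biotype rules (all in nt)."""

    mirna_max_len: int = 24
    sirna_max_len: int = 22
    sirna_te_exact_len: int = 21
    pirna_min_len: int = 23
    pirna_max_len: int = 30
    discovery_max_len: int = 35

    def __post_init__(self) -> None:
        if not (0 < self.pirna_min_len <= self.pirna_max_len
                <= self.discovery_max_len):
            raise ValueError(
                "need 0 < pirna_min_len <= pirna_max_len <= discovery_max_len"
            )
        for name in ("mirna_max_len", "sirna_max_len", "sirna_te_exact_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class BiotypeCall:
    label: str
    basis: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def classify_from_flags(
    length: int,
    flags: Set[str],
    space: str = GENOME,
    params: ClassifierParams = ClassifierParams(),
) -> BiotypeCall:
    """Classify from a read length and its set of overlapping categories."""
    if flags & STRUCTURAL_CATEGORIES:
        return BiotypeCall("structural_excluded", "structural_overlap")
    if length <= params.mirna_max_len and "pre_mirna" in flags:
        return BiotypeCall("miRNA", "premirna_overlap_le24")
    if length <= params.sirna_max_len and "endo_sirna" in flags:
        return BiotypeCall("siRNA", "endosirna_overlap_le22")
    if length == params.sirna_te_exact_len and (
        space == TE_CONSENSUS or "te_insertion" in flags
    ):
        return BiotypeCall("siRNA", "te_exact21")
    if params.pirna_min_len <= length <= params.pirna_max_len:
        return BiotypeCall("piRNA", "length_23_30")
    return BiotypeCall("other", "no_rule")


def classify_read(
    read: AlignedRead,
    ann: AnnotationSet,
    params: ClassifierParams = ClassifierParams(),
) -> BiotypeCall:
    """Assign the read exactly one biotype label.

    TE-consensus-space reads have no genomic annotation overlaps: only the
    exact-21-nt siRNA rule and the piRNA length window can fire for them.
    """
    flags = (
        overlapping_categories(read, ann) if read.space == GENOME else set()
    )
    return classify_from_flags(read.length(), flags, read.space, params)


def classify_library(
    lib: ReadLibrary,
    ann: AnnotationSet,
    params: ClassifierParams = ClassifierParams(),
) -> Tuple[Dict[str, List[AlignedRead]], Dict[str, int]]:
    """Partition a library's reads by biotype; counts sum to the read count."""
    by_label: Dict[str, List[AlignedRead]] = {lab: [] for lab in LABELS}
    for read in lib.reads:
        by_label[classify_read(read, ann, params).label].append(read)
    counts = {lab: len(reads) for lab, reads in by_label.items()}
    return by_label, counts


def select_putative_pirnas(
    lib: ReadLibrary,
    ann: AnnotationSet,
    params: ClassifierParams = ClassifierParams(),
    purpose: str = "counting",
) -> List[AlignedRead]:
    """Select genome-space putative piRNA reads for a downstream stage.

    ``counting``: reads labelled piRNA (23-30 nt window) that map uniquely
    (n_hits == 1); multi-mappers are discarded.
    ``discovery``: reads of 23-35 nt that are not structural/miRNA/siRNA;
    multi-mappers are retained for this step only.
    """
    if purpose not in ("counting", "discovery"):
        raise ValueError(f"invalid purpose {purpose!r}")
    out: List[AlignedRead] = []
    for read in lib.reads:
        if read.space != GENOME:
            continue
        call = classify_read(read, ann, params)
        if purpose == "counting":
            if call.label == "piRNA" and read.n_hits == 1:
                out.append(read)
        else:
            if call.label in ("structural_excluded", "miRNA", "siRNA"):
                continue
            if params.pirna_min_len <= read.length() <= params.discovery_max_len:
                out.append(read)
    return out
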