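import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from piratlas.core_model import (
    AlignedRead,
    AnnotationSet,
    GeneModel,
    GenomicInterval,
)


def make_read(
    chrom="chr1",
    start=100,
    length=26,
    strand="+",
    read_id=None,
    space="genome",
    n_hits=1,
    sequence=None,
):
    make_read.counter += 1
    return AlignedRead(
        read_id or f"r{make_read.counter}",
        space,
        chrom,
        GenomicInterval(chrom, start, start + length, strand),
        n_hits,
        sequence,
    )


make_read.counter = 0


@pytest.fixture
def toy_ann():
    """Hand-built annotation universe on chr1 with one of everything.

    Layout (0-based half-open):
      pre-miRNA   [1000, 1100) +      endo-siRNA [2000, 2500) +
      rRNA        [3000, 4000) +      tRNA       [5000, 5080) -
      snoRNA      [6000, 6150) +      snRNA      [7000, 7150) -
      TE insert   [8000, 9000) +      canonical  [20000, 30000)
      gene_plus   [40000, 46000) + with 3'UTR [45000, 46000)
      gene_minus  [50000, 56000) - with 3'UTR [50000, 51000)
    """
    ann = AnnotationSet(
        pre_mirna=[GenomicInterval("chr1", 1000, 1100, "+")],
        endo_sirna=[GenomicInterval("chr1", 2000, 2500, "+")],
        rrna=[GenomicInterval("chr1", 3000, 4000, "+")],
        trna=[GenomicInterval("chr1", 5000, 5080, "-")],
        snorna=[GenomicInterval("chr1", 6000, 6150, "+")],
        snrna=[GenomicInterval("chr1", 7000, 7150, "-")],
        te_insertions=[GenomicInterval("chr1", 8000, 9000, "+")],
        canonical_clusters=[GenomicInterval("chr1", 20000, 30000)],
        te_consensus_names={"ZAM"},
    )
    gp = GeneModel("gene_plus", GenomicInterval("chr1", 40000, 46000, "+"), "+")
    gp.exons = [GenomicInterval("chr1", 40000, 46000, "+")]
    gp.utr3 = [GenomicInterval("chr1", 45000, 46000, "+")]
    gm = GeneModel("gene_minus", GenomicInterval("chr1", 50000, 56000, "-"), "-")
    gm.exons = [GenomicInterval("chr1", 50000, 56000, "-")]
    gm.utr3 = [GenomicInterval("chr1", 50000, 51000, "-")]
    ann.genes = {"gene_plus": gp, "gene_minus": gm}
    return ann
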