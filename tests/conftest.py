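import numpy as np
import pytest

import lncdiscover as ld
from lncdiscover.intervals import GenomicInterval
from lncdiscover.models import GeneModel, TranscriptModel


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle, shared read-only across tests."""
    return ld.generate_bundle(ld.SimConfig(seed=1))


@pytest.fixture(scope="session")
def cascade_result(bundle):
    return ld.run_cascade(
        bundle.candidates, bundle.reference, bundle.expr,
        bundle.strand_counts, bundle.de, bundle.repeats, bundle.cage,
    )


def make_tx(tid, exons, strand="+", chrom="chr1", gene=None):
    return TranscriptModel(
        tid, gene or tid.split(".")[0], chrom, strand,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
    )


def make_gene(gid, exon_sets, strand="+", chrom="chr1", biotype="other"):
    txs = [
        make_tx(f"{gid}.t{i+1}", exons, strand, chrom, gene=gid)
        for i, exons in enumerate(exon_sets)
    ]
    return GeneModel(gid, txs, biotype=biotype)


def random_transcript(rng, tid="t", chrom="chr1", max_pos=100_000):
    """Random multi-exon transcript for oracle comparisons."""
    n = int(rng.integers(1, 5))
    strand = "+" if rng.random() < 0.5 else "-"
    pos = int(rng.integers(0, max_pos))
    exons = []
    for _ in range(n):
        length = int(rng.integers(50, 400))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(50, 500))
    return make_tx(tid, exons, strand, chrom)
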