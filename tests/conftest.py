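"""Shared fixtures and independent oracles.

The per-base oracle labels every base of a small genome with explicit
numpy arrays — deliberately brute-force and independent of the interval
algebra under test.
"""

import numpy as np
import pytest

from repeatrna.intervals import (
    ChromSizes,
    GeneModel,
    GenomicInterval,
    EXONIC,
    INTRONIC,
    INTERGENIC,
)

LABEL_CODE = {EXONIC: 0, INTRONIC: 1, INTERGENIC: 2}
CODE_LABEL = {v: k for k, v in LABEL_CODE.items()}


def per_base_labels(sizes: ChromSizes, genes) -> dict:
    """Brute-force per-base context labeling: intergenic everywhere, then
    paint gene spans intronic, then exons exonic."""
    labels = {c: np.full(length, 2, dtype=np.int8) for c, length in sizes.items()}
    for g in genes:
        labels[g.chrom][g.span.start:g.span.end] = np.minimum(
            labels[g.chrom][g.span.start:g.span.end], 1
        )
    for g in genes:
        for exons in g.transcripts.values():
            for e in exons:
                labels[e.chrom][e.start:e.end] = 0
    return labels


def partition_as_labels(partition) -> dict:
    out = {}
    for chrom, tiles in partition.tiles.items():
        arr = np.empty(partition.sizes[chrom], dtype=np.int8)
        for s, e, lab in tiles:
            arr[s:e] = LABEL_CODE[lab]
        out[chrom] = arr
    return out


def random_gene_models(rng, sizes: ChromSizes, max_genes: int = 8) -> list:
    """Random non-overlapping multi-exon genes, built directly (not via
    the package's simulator) for oracle-equivalence tests."""
    genes = []
    gid = 0
    for chrom, length in sizes.items():
        cursor = int(rng.integers(0, max(1, length // 10)))
        n_genes = int(rng.integers(0, max_genes + 1))
        for _ in range(n_genes):
            n_exons = int(rng.integers(1, 6))
            exons = []
            pos = cursor
            for k in range(n_exons):
                el = int(rng.integers(10, 200))
                if pos + el >= length:
                    break
                exons.append(GenomicInterval(chrom, pos, pos + el, "+"))
                pos += el + int(rng.integers(20, 500))
            if not exons:
                break
            gid += 1
            genes.append(
                GeneModel.from_exons(f"g{gid}", {f"g{gid}.t1": tuple(exons)})
            )
            cursor = exons[-1].end + int(rng.integers(50, 1000))
            if cursor >= length - 50:
                break
    return genes


@pytest.fixture
def toy_sizes():
    return ChromSizes({"chr1": 2000})


@pytest.fixture
def three_exon_gene(toy_sizes):
    exons = (
        GenomicInterval("chr1", 99, 200, "+"),
        GenomicInterval("chr1", 300, 400, "+"),
        GenomicInterval("chr1", 800, 1000, "+"),
    )
    return GeneModel.from_exons("g1", {"g1.t1": exons})


@pytest.fixture
def four_exon_gene():
    # exons at [100,200), [300,400), [500,600), [700,800); introns between
    exons = tuple(
        GenomicInterval("chr1", s, s + 100, "+") for s in (100, 300, 500, 700)
    )
    return GeneModel.from_exons("g4", {"g4.t1": exons})
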