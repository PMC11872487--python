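"""Interval algebra and annotation I/O against a per-base oracle."""

import numpy as np
import pytest

from repeatrna.intervals import (
    AnnotationParseError,
    ChromSizes,
    GeneModel,
    GenomicInterval,
    ValidationError,
    apportion_bp,
    build_partition,
    derive_intergenic,
    derive_introns,
    read_annotation,
)

from conftest import (
    CODE_LABEL,
    partition_as_labels,
    per_base_labels,
    random_gene_models,
)

GFF_TWO_EXONS = """##gff-version 3
chr1\tsim\tgene\t100\t400\t.\t+\t.\tID=g1
chr1\tsim\tmRNA\t100\t400\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\tsim\texon\t100\t200\t.\t+\t.\tID=e1;Parent=g1.t1
chr1\tsim\texon\t301\t400\t.\t+\t.\tID=e2;Parent=g1.t1
"""


class TestReadAnnotation:
    def test_one_based_closed_becomes_zero_based_half_open(self, toy_sizes):
        genes = read_annotation(GFF_TWO_EXONS, toy_sizes)
        assert len(genes) == 1
        exons = genes[0].transcripts["g1.t1"]
        assert [(e.start, e.end) for e in exons] == [(99, 200), (300, 400)]
        assert (genes[0].span.start, genes[0].span.end) == (99, 400)

    def test_gtf_dialect_equivalent(self, toy_sizes):
        gtf = (
            'chr1\tsim\texon\t100\t200\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1";\n'
            'chr1\tsim\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1";\n'
        )
        genes = read_annotation(gtf, toy_sizes)
        assert [(e.start, e.end) for e in genes[0].transcripts["g1.t1"]] == [
            (99, 200),
            (300, 400),
        ]

    def test_gene_without_exons_warned_and_excluded(self, toy_sizes):
        gff = "##gff-version 3\nchr1\tsim\tgene\t100\t400\t.\t+\t.\tID=lonely\n"
        with pytest.warns(UserWarning, match="lonely"):
            genes = read_annotation(gff, toy_sizes)
        assert genes == []

    def test_malformed_line_names_line_number(self, toy_sizes):
        bad = "##gff-version 3\nchr1\tsim\tgene\tnot_a_number\n"
        with pytest.raises(AnnotationParseError, match="line 2"):
            read_annotation(bad, toy_sizes)

    def test_exon_beyond_chromosome_rejected(self):
        sizes = ChromSizes({"chr1": 150})
        with pytest.raises(ValidationError):
            read_annotation(GFF_TWO_EXONS, sizes)

    def test_ten_gene_file_matches_naive_reparse(self):
        rng = np.random.default_rng(42)
        sizes = ChromSizes({"chrA": 50_000, "chrB": 50_000})
        lines = ["##gff-version 3\n"]
        expected_spans = {}
        for i in range(10):
            chrom = "chrA" if i < 5 else "chrB"
            start = 1 + i % 5 * 9000 + int(rng.integers(0, 500))
            exon1 = (start, start + int(rng.integers(50, 200)))
            exon2 = (exon1[1] + 300, exon1[1] + 300 + int(rng.integers(50, 200)))
            gid = f"g{i}"
            lines.append(
                f"{chrom}\tx\tgene\t{exon1[0]}\t{exon2[1]}\t.\t+\t.\tID={gid}\n"
            )
            lines.append(
                f"{chrom}\tx\tmRNA\t{exon1[0]}\t{exon2[1]}\t.\t+\t.\t"
                f"ID={gid}.t;Parent={gid}\n"
            )
            for j, (s, e) in enumerate((exon1, exon2)):
                lines.append(
                    f"{chrom}\tx\texon\t{s}\t{e}\t.\t+\t.\t"
                    f"ID={gid}.t.e{j};Parent={gid}.t\n"
                )
            expected_spans[gid] = (exon1[0] - 1, exon2[1])
        text = "".join(lines)
        # independent oracle: minimal per-record scan of exon rows
        oracle = {}
        for line in text.splitlines():
            f = line.split("\t")
            if len(f) == 9 and f[2] == "exon":
                gid = f[8].split("Parent=")[1].split(";")[0].rsplit(".t", 1)[0]
                s, e = int(f[3]) - 1, int(f[4])
                cur = oracle.get(gid, (s, e))
                oracle[gid] = (min(cur[0], s), max(cur[1], e))
        genes = read_annotation(text, sizes)
        spans = {g.gene_id: (g.span.start, g.span.end) for g in genes}
        assert spans == oracle == expected_spans


class TestDerivations:
    def test_single_exon_gene_has_no_introns(self):
        g = GeneModel.from_exons(
            "g", {"t": (GenomicInterval("chr1", 10, 50, "+"),)}
        )
        assert derive_introns(g) == []

    def test_three_exon_gene_introns(self, three_exon_gene):
        assert [(i.start, i.end) for i in derive_introns(three_exon_gene)] == [
            (200, 300),
            (400, 800),
        ]

    def test_transcript_union_can_close_introns(self):
        t1 = (
            GenomicInterval("chr1", 0, 100, "+"),
            GenomicInterval("chr1", 200, 300, "+"),
        )
        t2 = (GenomicInterval("chr1", 0, 300, "+"),)
        g = GeneModel.from_exons("g", {"t1": t1, "t2": t2})
        assert derive_introns(g) == []

    @pytest.mark.parametrize(
        "spans,expected",
        [
            ([], [(0, 500)]),
            ([(100, 200), (150, 300)], [(0, 100), (300, 500)]),
            ([(0, 500)], []),
        ],
    )
    def test_derive_intergenic(self, spans, expected):
        sizes = ChromSizes({"chr1": 500})
        genes = [
            GeneModel.from_exons(
                f"g{i}", {"t": (GenomicInterval("chr1", s, e, "+"),)}
            )
            for i, (s, e) in enumerate(spans)
        ]
        got = [(iv.start, iv.end) for iv in derive_intergenic(sizes, genes)]
        assert got == expected


class TestPartition:
    def test_empty_annotation_is_all_intergenic(self, toy_sizes):
        part = build_partition(toy_sizes, [])
        assert part.label_lengths() == {
            "exonic": 0,
            "intronic": 0,
            "intergenic": 2000,
        }

    def test_three_exon_gene_label_lengths(self, toy_sizes, three_exon_gene):
        part = build_partition(toy_sizes, [three_exon_gene])
        assert part.label_lengths() == {
            "exonic": 401,
            "intronic": 500,
            "intergenic": 1099,
        }

    def test_tiling_is_exact(self, toy_sizes, three_exon_gene):
        part = build_partition(toy_sizes, [three_exon_gene])
        assert sum(part.label_lengths().values()) == toy_sizes.genome_size

    def test_random_genomes_match_per_base_oracle(self):
        rng = np.random.default_rng(20240901)
        for _ in range(25):
            sizes = ChromSizes(
                {
                    f"c{i}": int(rng.integers(500, 20_000))
                    for i in range(int(rng.integers(1, 4)))
                }
            )
            genes = random_gene_models(rng, sizes)
            part = build_partition(sizes, genes)
            oracle = per_base_labels(sizes, genes)
            got = partition_as_labels(part)
            for chrom in sizes:
                assert np.array_equal(got[chrom], oracle[chrom])
            # derived intron/intergenic views agree with the same oracle
            for g in genes:
                for iv in derive_introns(g):
                    assert (oracle[iv.chrom][iv.start:iv.end] == 1).all()
            for iv in derive_intergenic(sizes, genes):
                assert (oracle[iv.chrom][iv.start:iv.end] == 2).all()


class TestApportion:
    def test_straddling_repeat_split(self, toy_sizes, three_exon_gene):
        part = build_partition(toy_sizes, [three_exon_gene])
        got = apportion_bp([GenomicInterval("chr1", 150, 250)], part)
        assert got == {"exonic": 50, "intronic": 50, "intergenic": 0}

    def test_intergenic_query_fully_counted(self, toy_sizes):
        part = build_partition(toy_sizes, [])
        got = apportion_bp([GenomicInterval("chr1", 100, 300)], part)
        assert got == {"exonic": 0, "intronic": 0, "intergenic": 200}

    def test_unknown_chromosome_rejected(self, toy_sizes):
        part = build_partition(toy_sizes, [])
        with pytest.raises(ValidationError):
            apportion_bp([GenomicInterval("chrX", 0, 10)], part)

    def test_random_queries_match_per_base_counts(self):
        rng = np.random.default_rng(7)
        sizes = ChromSizes({"c1": 10_000, "c2": 5_000})
        genes = random_gene_models(rng, sizes)
        part = build_partition(sizes, genes)
        oracle = per_base_labels(sizes, genes)
        queries = []
        for _ in range(200):
            chrom = "c1" if rng.random() < 0.5 else "c2"
            s = int(rng.integers(0, sizes[chrom] - 10))
            queries.append(
                GenomicInterval(chrom, s, s + int(rng.integers(1, 500)))
            )
        queries = [
            GenomicInterval(q.chrom, q.start, min(q.end, sizes[q.chrom]))
            for q in queries
        ]
        got = apportion_bp(queries, part)
        counts = {0: 0, 1: 0, 2: 0}
        for q in queries:
            vals, ns = np.unique(
                oracle[q.chrom][q.start:q.end], return_counts=True
            )
            for v, n in zip(vals, ns):
                counts[int(v)] += int(n)
        assert got == {CODE_LABEL[c]: n for c, n in counts.items()}
        assert sum(got.values()) == sum(q.length for q in queries)
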