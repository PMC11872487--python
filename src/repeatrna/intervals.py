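"""Genomic interval algebra and annotation I/O.

Everything downstream of the gene annotation — intron derivation, the
exonic/intronic/intergenic partition of the genome, and base-pair
apportionment of arbitrary query intervals — lives here.  Internal
coordinates are 0-based half-open throughout; GFF3/GTF input (1-based
closed) is converted on read.  Strand is carried on intervals but ignored
for context partitioning, mirroring the strand-blind complement/intersect
recipe the partition reproduces.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field

import gffutils

EXONIC = "exonic"
INTRONIC = "intronic"
INTERGENIC = "intergenic"
LABELS = (EXONIC, INTRONIC, INTERGENIC)

#: label precedence used when one base could take several labels
PRECEDENCE = {EXONIC: 0, INTRONIC: 1, INTERGENIC: 2}


class AnnotationParseError(ValueError):
    """Raised for malformed annotation lines (carries the line number)."""


class ValidationError(ValueError):
    """Raised when coordinates contradict the declared chromosome sizes."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on ``chrom``.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp."""

    def __init__(self, sizes=()):
        super().__init__(sizes)
        for name, length in self.items():
            if not isinstance(length, int) or length <= 0:
                raise ValueError(f"chromosome {name!r} has invalid length {length!r}")

    @property
    def genome_size(self) -> int:
        return sum(self.values())

    @classmethod
    def from_tsv(cls, source) -> "ChromSizes":
        """Read a two-column (name, length) TSV, as produced by faidx."""
        text = _read_text(source)
        sizes = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise AnnotationParseError(f"sizes line {lineno}: expected 2 columns")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise AnnotationParseError(f"sizes line {lineno}: bad length") from exc
            if fields[0] in sizes:
                raise ValidationError(f"duplicate chromosome {fields[0]!r}")
            sizes[fields[0]] = length
        return cls(sizes)

    def to_tsv(self) -> str:
        return "".join(f"{name}\t{length}\n" for name, length in self.items())


@dataclass
class GeneModel:
    """A gene with its transcripts' exons and the derived introns.

    ``transcripts`` maps transcript id -> ordered tuple of exon intervals.
    ``merged_exons`` is the strand-blind union of all exons across
    transcripts; ``introns`` are exactly the within-span gaps between them.
    """

    gene_id: str
    span: GenomicInterval
    transcripts: dict = field(default_factory=dict)
    merged_exons: list = field(default_factory=list)
    introns: list = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @classmethod
    def from_exons(cls, gene_id: str, transcripts: dict) -> "GeneModel":
        all_exons = [e for exons in transcripts.values() for e in exons]
        if not all_exons:
            raise ValueError(f"gene {gene_id!r} has no exons")
        chroms = {e.chrom for e in all_exons}
        if len(chroms) != 1:
            raise ValidationError(f"gene {gene_id!r} spans multiple chromosomes")
        strand = all_exons[0].strand
        span = GenomicInterval(
            all_exons[0].chrom,
            min(e.start for e in all_exons),
            max(e.end for e in all_exons),
            strand,
        )
        gene = cls(gene_id=gene_id, span=span, transcripts=dict(transcripts))
        gene.merged_exons = merge_intervals(all_exons)
        gene.introns = derive_introns(gene)
        return gene


def merge_intervals(intervals) -> list:
    """Union of intervals as a sorted, disjoint list (strand dropped)."""
    by_chrom = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def complement_intervals(merged, chrom: str, start: int, end: int) -> list:
    """Gaps of an already-merged interval list within ``[start, end)``."""
    out = []
    cursor = start
    for iv in merged:
        if iv.chrom != chrom or iv.end <= start or iv.start >= end:
            continue
        if iv.start > cursor:
            out.append(GenomicInterval(chrom, cursor, iv.start))
        cursor = max(cursor, iv.end)
    if cursor < end:
        out.append(GenomicInterval(chrom, cursor, end))
    return out


def derive_introns(gene: GeneModel) -> list:
    """Introns = complement of the merged exon union within the gene span."""
    merged = gene.merged_exons or merge_intervals(
        [e for exons in gene.transcripts.values() for e in exons]
    )
    return [
        GenomicInterval(iv.chrom, iv.start, iv.end, gene.strand)
        for iv in complement_intervals(merged, gene.chrom, gene.span.start, gene.span.end)
    ]


def derive_intergenic(sizes: ChromSizes, genes) -> list:
    """Complement of the union of gene spans over every chromosome."""
    merged = merge_intervals([g.span for g in genes]) if genes else []
    out = []
    for chrom, length in sizes.items():
        out.extend(complement_intervals(merged, chrom, 0, length))
    return out


class ContextPartition:
    """Disjoint exonic/intronic/intergenic tiling of a genome.

    Tiles are stored per chromosome as an ordered list of
    ``(start, end, label)`` covering ``[0, length)`` end-to-end.
    """

    def __init__(self, tiles: dict, sizes: ChromSizes):
        self.sizes = sizes
        self.tiles = {c: list(t) for c, t in tiles.items()}
        self._starts = {c: [t[0] for t in ts] for c, ts in self.tiles.items()}
        self._validate()

    def _validate(self) -> None:
        for chrom, length in self.sizes.items():
            ts = self.tiles.get(chrom, [])
            if not ts:
                raise ValidationError(f"no tiles for chromosome {chrom!r}")
            if ts[0][0] != 0 or ts[-1][1] != length:
                raise ValidationError(f"tiles do not span chromosome {chrom!r}")
            for (s0, e0, l0), (s1, e1, l1) in zip(ts, ts[1:]):
                if e0 != s1:
                    raise ValidationError(f"gap/overlap in tiles on {chrom!r}")
                if l0 == l1:
                    raise ValidationError(f"adjacent tiles share label on {chrom!r}")
            for s, e, lab in ts:
                if not (0 <= s < e <= length) or lab not in LABELS:
                    raise ValidationError(f"bad tile ({s}, {e}, {lab}) on {chrom!r}")

    def label_lengths(self) -> dict:
        out = {lab: 0 for lab in LABELS}
        for ts in self.tiles.values():
            for s, e, lab in ts:
                out[lab] += e - s
        return out

    def label_fractions(self) -> dict:
        total = self.sizes.genome_size
        return {lab: bp / total for lab, bp in self.label_lengths().items()}

    def label_at(self, chrom: str, pos: int) -> str:
        ts = self.tiles[chrom]
        i = bisect_right(self._starts[chrom], pos) - 1
        s, e, lab = ts[i]
        if not (s <= pos < e):
            raise ValueError(f"position {pos} outside {chrom!r}")
        return lab

    def to_bed6(self) -> str:
        lines = []
        for chrom in self.tiles:
            for s, e, lab in self.tiles[chrom]:
                lines.append(f"{chrom}\t{s}\t{e}\t{lab}\t0\t.\n")
        return "".join(lines)


def build_partition(sizes: ChromSizes, genes) -> ContextPartition:
    """Label every base: exonic beats intronic beats intergenic.

    A base covered by any exon of any gene is exonic; covered by a gene
    span but by no exon is intronic; everything else is intergenic.
    """
    exons = merge_intervals(
        [e for g in genes for exons in g.transcripts.values() for e in exons]
    ) if genes else []
    spans = merge_intervals([g.span for g in genes]) if genes else []
    tiles = {}
    for chrom, length in sizes.items():
        # boundary sweep: every exon/span edge inside [0, length)
        edges = {0, length}
        for iv in exons:
            if iv.chrom == chrom:
                edges.update((iv.start, iv.end))
        for iv in spans:
            if iv.chrom == chrom:
                edges.update((iv.start, iv.end))
        edges = sorted(e for e in edges if 0 <= e <= length)
        exon_chrom = [(iv.start, iv.end) for iv in exons if iv.chrom == chrom]
        span_chrom = [(iv.start, iv.end) for iv in spans if iv.chrom == chrom]
        exon_starts = [s for s, _ in exon_chrom]
        span_starts = [s for s, _ in span_chrom]

        def _covered(pos, starts, spans_):
            i = bisect_right(starts, pos) - 1
            return i >= 0 and spans_[i][1] > pos

        chrom_tiles = []
        for s, e in zip(edges, edges[1:]):
            if _covered(s, exon_starts, exon_chrom):
                lab = EXONIC
            elif _covered(s, span_starts, span_chrom):
                lab = INTRONIC
            else:
                lab = INTERGENIC
            if chrom_tiles and chrom_tiles[-1][2] == lab:
                chrom_tiles[-1] = (chrom_tiles[-1][0], e, lab)
            else:
                chrom_tiles.append((s, e, lab))
        tiles[chrom] = chrom_tiles
    return ContextPartition(tiles, sizes)


def apportion_bp(query, partition: ContextPartition) -> dict:
    """Split query interval lengths among context labels by exact overlap.

    Returns ``{label: bp}``; totals sum to the total query bp.  Raises for
    queries on chromosomes absent from the partition.
    """
    out = {lab: 0 for lab in LABELS}
    for iv in query:
        if iv.chrom not in partition.tiles:
            raise ValidationError(f"query on unknown chromosome {iv.chrom!r}")
        ts = partition.tiles[iv.chrom]
        starts = partition._starts[iv.chrom]
        i = max(0, bisect_right(starts, iv.start) - 1)
        while i < len(ts) and ts[i][0] < iv.end:
            s, e, lab = ts[i]
            out[lab] += max(0, min(e, iv.end) - max(s, iv.start))
            i += 1
    return out


# ---------------------------------------------------------------------------
# annotation I/O


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, str):
        if "\n" in source or source == "":
            return source
        if not os.path.exists(source):
            raise FileNotFoundError(source)
    with open(source) as fh:
        return fh.read()


def _prevalidate(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise AnnotationParseError(
                f"annotation line {lineno}: expected 9 tab-separated columns, "
                f"got {len(fields)}"
            )
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise AnnotationParseError(
                f"annotation line {lineno}: non-integer coordinates"
            ) from exc
        if start < 1 or end < start:
            raise AnnotationParseError(
                f"annotation line {lineno}: invalid coordinate range {start}-{end}"
            )


def read_annotation(source, sizes: ChromSizes) -> list:
    """Read gene models from GFF3 or GTF text (file path, handle, or string).

    1-based closed coordinates become 0-based half-open.  Genes without any
    exon feature are excluded with a warning.  Gene spans are recomputed
    from exon extremes regardless of any declared gene row.
    """
    text = _read_text(source)
    _prevalidate(text)
    tmp = tempfile.NamedTemporaryFile(
        "w", suffix=".gff", delete=False, encoding="utf-8"
    )
    try:
        tmp.write(text)
        tmp.close()
        db = gffutils.create_db(
            tmp.name, ":memory:", merge_strategy="create_unique", verbose=False
        )
        per_gene: dict = {}
        for exon in db.features_of_type("exon"):
            parents = list(db.parents(exon, featuretype="gene"))
            if parents:
                gid = parents[0].id
            elif "gene_id" in exon.attributes:
                gid = exon.attributes["gene_id"][0]
            else:
                raise AnnotationParseError(
                    f"exon at {exon.seqid}:{exon.start}-{exon.end} has no gene"
                )
            if "transcript_id" in exon.attributes:
                tid = exon.attributes["transcript_id"][0]
            elif "Parent" in exon.attributes:
                tid = exon.attributes["Parent"][0]
            else:
                tid = f"{gid}.t1"
            if exon.seqid not in sizes:
                raise ValidationError(
                    f"exon on undeclared chromosome {exon.seqid!r}"
                )
            if exon.end > sizes[exon.seqid]:
                raise ValidationError(
                    f"exon {exon.seqid}:{exon.start}-{exon.end} exceeds "
                    f"chromosome length {sizes[exon.seqid]}"
                )
            iv = GenomicInterval(
                exon.seqid,
                exon.start - 1,
                exon.end,
                exon.strand if exon.strand in "+-" else ".",
            )
            per_gene.setdefault(gid, {}).setdefault(tid, []).append(iv)
        for gene in db.features_of_type("gene"):
            if gene.id not in per_gene:
                warnings.warn(
                    f"gene {gene.id!r} has no exon features and was excluded",
                    stacklevel=2,
                )
        genes = []
        for gid, transcripts in per_gene.items():
            ordered = {
                tid: tuple(sorted(exons, key=lambda e: e.start))
                for tid, exons in transcripts.items()
            }
            genes.append(GeneModel.from_exons(gid, ordered))
        genes.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
        return genes
    finally:
        os.unlink(tmp.name)
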