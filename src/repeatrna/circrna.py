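"""Consensus backsplice junctions, flanking introns, inverted repeat pairs.

A backsplice junction (BSJ) joins a downstream splice donor back to an
upstream acceptor, producing a circular RNA.  The pipeline intersects BSJ
call sets from several detection programs at exact coordinates, validates
junctions against annotated exon boundaries, resolves the flanking
introns, compares their lengths with a random-junction null, and searches
the flanks for the junction-nearest repeat copies on opposite strands
(the inverted-repeat configuration that promotes circularization).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from intervaltree import IntervalTree

from .intervals import GenomicInterval
from .repeats import RepeatCopy, matches_group
from .stats import (
    EnrichmentResult,
    StatTestResult,
    adjust_enrichment,
    binomial_enrichment,
    welch_t,
)


@dataclass(frozen=True)
class BackspliceJunction:
    """One BSJ call: ``acceptor`` is the 0-based start of the upstream exon,
    ``donor`` the 0-based (exclusive) end of the downstream exon, so the
    circle covers ``[acceptor, donor)`` and ``acceptor < donor``."""

    chrom: str
    acceptor: int
    donor: int
    strand: str
    caller_id: str
    read_count: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.acceptor < self.donor):
            raise ValueError("require 0 <= acceptor < donor")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.acceptor, self.donor, self.strand)


@dataclass(frozen=True)
class InvertedRepeatPair:
    """Junction-nearest repeats in the two flanking introns, on opposite
    strands; distances are bp from each repeat's junction-proximal edge to
    the backsplice junction (0 when overlapping)."""

    up: RepeatCopy
    down: RepeatCopy
    up_distance: int
    down_distance: int

    def __post_init__(self) -> None:
        if self.up.strand == self.down.strand:
            raise ValueError("inverted pair requires opposite strands")


@dataclass
class CircRNA:
    chrom: str
    acceptor: int
    donor: int
    strand: str
    callers: frozenset
    read_counts: dict = field(default_factory=dict)
    host_gene: str | None = None
    upstream_intron: GenomicInterval | None = None
    downstream_intron: GenomicInterval | None = None
    splice_site_validated: bool = False
    flank_missing: bool = False
    inverted_pair: InvertedRepeatPair | None = None

    @property
    def key(self) -> tuple:
        return (self.chrom, self.acceptor, self.donor, self.strand)

    @property
    def has_both_flanks(self) -> bool:
        return self.upstream_intron is not None and self.downstream_intron is not None


def consensus_circrnas(callsets, min_callers: int = 3) -> list:
    """Group junctions by exact coordinates; keep those seen by at least
    ``min_callers`` distinct callers.  Read counts sum within a caller,
    never across callers."""
    if min_callers < 1:
        raise ValueError("min_callers must be >= 1")
    grouped: dict = {}
    for callset in callsets:
        for j in callset:
            entry = grouped.setdefault(j.key, {})
            if j.read_count is not None:
                entry[j.caller_id] = entry.get(j.caller_id, 0) + j.read_count
            else:
                entry.setdefault(j.caller_id, None)
    out = []
    for key in sorted(grouped):
        callers = grouped[key]
        if len(callers) >= min_callers:
            chrom, acceptor, donor, strand = key
            out.append(
                CircRNA(
                    chrom=chrom,
                    acceptor=acceptor,
                    donor=donor,
                    strand=strand,
                    callers=frozenset(callers),
                    read_counts={c: r for c, r in callers.items() if r is not None},
                )
            )
    return out


def validate_and_flank(circ: CircRNA, genes) -> CircRNA:
    """Annotate a circRNA with its host gene and flanking introns.

    The junction is splice-site validated iff the acceptor equals a merged
    exon start and the donor a merged exon end of one gene on the matching
    strand.  The upstream flank is the intron immediately 5' of the
    acceptor and the downstream flank the intron immediately 3' of the
    donor (genomic orientation for + genes, mirrored for -).  A missing
    flank (terminal exon) sets ``flank_missing``.
    """
    for gene in genes:
        if gene.chrom != circ.chrom or gene.strand != circ.strand:
            continue
        starts = {e.start for e in gene.merged_exons}
        ends = {e.end for e in gene.merged_exons}
        if circ.acceptor in starts and circ.donor in ends:
            intron_by_end = {iv.end: iv for iv in gene.introns}
            intron_by_start = {iv.start: iv for iv in gene.introns}
            left = intron_by_end.get(circ.acceptor)   # genomically left flank
            right = intron_by_start.get(circ.donor)   # genomically right flank
            if circ.strand == "+":
                up, down = left, right
            else:
                up, down = right, left
            return replace(
                circ,
                host_gene=gene.gene_id,
                splice_site_validated=True,
                upstream_intron=up,
                downstream_intron=down,
                flank_missing=(up is None or down is None),
            )
    return replace(circ, splice_site_validated=False)


def _eligible_pairs(gene) -> int:
    m = len(gene.merged_exons) - 2  # internal exons
    return m * (m + 1) // 2 if m > 0 else 0


def random_backsplice_null(genes, count: int, seed: int) -> list:
    """Random BSJs over internal exon pairs, the permutation null for the
    flanking-intron length comparison.

    A gene is drawn with probability proportional to its number of ordered
    internal exon pairs (acceptor exon at or before donor exon, terminal
    exons excluded), then a pair uniformly; every draw is splice-site
    valid with both flanking introns present.
    """
    eligible = [g for g in genes if _eligible_pairs(g) > 0]
    if not eligible:
        raise ValueError("no genes with internal exon pairs")
    weights = np.array([_eligible_pairs(g) for g in eligible], dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    gene_idx = rng.choice(len(eligible), size=count, p=weights / weights.sum())
    for gi in gene_idx:
        gene = eligible[gi]
        internal = gene.merged_exons[1:-1]
        m = len(internal)
        pairs = [(i, j) for i in range(m) for j in range(i, m)]
        i, j = pairs[rng.integers(len(pairs))]
        circ = CircRNA(
            chrom=gene.chrom,
            acceptor=internal[i].start,
            donor=internal[j].end,
            strand=gene.strand,
            callers=frozenset({"random_null"}),
        )
        out.append(validate_and_flank(circ, [gene]))
    return out


def pooled_flank_lengths(circs) -> list:
    """Upstream and downstream flanking intron lengths, pooled."""
    lengths = []
    for c in circs:
        if c.has_both_flanks:
            lengths.append(c.upstream_intron.length)
            lengths.append(c.downstream_intron.length)
    return lengths


def flanking_length_test(observed, null) -> tuple:
    """Welch's t on pooled flanking-intron lengths, observed vs null.

    Returns ``(StatTestResult, {"observed_mean": .., "null_mean": ..})``.
    """
    obs = pooled_flank_lengths(observed)
    nul = pooled_flank_lengths(null)
    if not obs or not nul:
        raise ValueError("both groups need circRNAs with both flanks")
    res = welch_t(obs, nul)
    means = {
        "observed_mean": float(np.mean(obs)),
        "null_mean": float(np.mean(nul)),
    }
    return res, means


class RepeatIndex:
    """Per-chromosome interval tree over repeat copies."""

    def __init__(self, repeats):
        self.trees: dict = {}
        for c in repeats:
            self.trees.setdefault(c.chrom, IntervalTree())[c.start:c.end] = c

    def overlapping(self, chrom: str, start: int, end: int) -> list:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def _flank_candidates(intron, junction_at_end, repeats_or_index, overlap_frac):
    """Repeats overlapping >= overlap_frac of their own length with the
    intron, annotated with distance to the junction-proximal intron edge."""
    index = (
        repeats_or_index
        if isinstance(repeats_or_index, RepeatIndex)
        else RepeatIndex(repeats_or_index)
    )
    out = []
    for rep in index.overlapping(intron.chrom, intron.start, intron.end):
        ov = rep.location.overlap_bp(intron)
        if ov / rep.location.length < overlap_frac:
            continue
        if junction_at_end:
            dist = max(0, intron.end - rep.end)
        else:
            dist = max(0, rep.start - intron.start)
        out.append((rep, dist, ov))
    return out


def _select_nearest(candidates):
    # distance, then larger intron overlap, then leftmost genomic start
    return min(candidates, key=lambda t: (t[1], -t[2], t[0].start))


def find_inverted_repeat_pairs(
    circ: CircRNA, repeats, overlap_frac: float = 0.5
) -> InvertedRepeatPair | None:
    """Junction-nearest repeat on each flank; a pair iff strands oppose.

    On each flanking intron, candidates must overlap the intron by at
    least ``overlap_frac`` of the repeat's own length; the candidate with
    the smallest distance to the backsplice junction is selected (ties:
    larger intron overlap, then leftmost start).
    """
    if not circ.has_both_flanks:
        return None
    index = repeats if isinstance(repeats, RepeatIndex) else RepeatIndex(repeats)
    up_intron, down_intron = circ.upstream_intron, circ.downstream_intron
    # the junction-proximal edge of each flank is the edge touching the
    # circle: the intron ending at the acceptor, or starting at the donor
    up_at_end = up_intron.end == circ.acceptor
    down_at_end = down_intron.end == circ.acceptor
    up_c = _flank_candidates(up_intron, up_at_end, index, overlap_frac)
    down_c = _flank_candidates(down_intron, down_at_end, index, overlap_frac)
    if not up_c or not down_c:
        return None
    up, up_d, _ = _select_nearest(up_c)
    down, down_d, _ = _select_nearest(down_c)
    if up.strand == down.strand:
        return None
    return InvertedRepeatPair(up=up, down=down, up_distance=up_d, down_distance=down_d)


def annotate_pairs(circs, repeats, overlap_frac: float = 0.5) -> list:
    """Attach inverted repeat pairs to a list of flanked circRNAs."""
    index = repeats if isinstance(repeats, RepeatIndex) else RepeatIndex(repeats)
    return [
        replace(c, inverted_pair=find_inverted_repeat_pairs(c, index, overlap_frac))
        for c in circs
    ]


def family_pair_enrichment(circs, coverage, families) -> dict:
    """Coverage-null binomial test per repeat family.

    k counts circRNAs whose inverted pair involves at least one member of
    the family (a circRNA counts once per family), n is all consensus
    circRNAs, and the null probability is the family's genome fraction;
    two-sided tests, BH-adjusted across the tested families.
    """
    n = len(circs)
    results = {}
    for fam in families:
        k = sum(
            1
            for c in circs
            if c.inverted_pair is not None
            and (
                matches_group(c.inverted_pair.up.family_name, fam)
                or matches_group(c.inverted_pair.down.family_name, fam)
            )
        )
        results[fam] = binomial_enrichment(
            k, n, coverage.fraction(fam), alternative="two_sided"
        )
    return adjust_enrichment(results)


def hotspot_genes(circs, threshold: int = 15) -> list:
    """Host genes with at least ``threshold`` distinct circRNA isoforms,
    as (gene_id, isoform_count) sorted by count descending."""
    per_gene: dict = {}
    for c in circs:
        if c.host_gene is not None:
            per_gene.setdefault(c.host_gene, set()).add(c.key)
    counted = [(g, len(keys)) for g, keys in per_gene.items()]
    return sorted(
        [(g, n) for g, n in counted if n >= threshold],
        key=lambda t: (-t[1], t[0]),
    )


# ---------------------------------------------------------------------------
# BSJ TSV I/O (1-based inclusive on disk)

BSJ_COLUMNS = ("chrom", "start", "end", "strand", "caller", "reads")


def read_bsj_tsv(source) -> list:
    """Normalized BSJ TSV: chrom, start, end, strand, caller, reads with
    1-based inclusive coordinates; start-1 becomes the acceptor and end
    the donor."""
    from .intervals import _read_text

    junctions = []
    for lineno, line in enumerate(_read_text(source).splitlines(), 1):
        if not line.strip() or line.startswith("#") or line.startswith("chrom\t"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 5:
            raise ValueError(f"BSJ line {lineno}: expected >=5 columns")
        chrom, start_s, end_s, strand, caller = fields[:5]
        reads = int(fields[5]) if len(fields) > 5 and fields[5] != "." else None
        junctions.append(
            BackspliceJunction(
                chrom=chrom,
                acceptor=int(start_s) - 1,
                donor=int(end_s),
                strand=strand,
                caller_id=caller,
                read_count=reads,
            )
        )
    return junctions


def write_bsj_tsv(junctions) -> str:
    lines = ["\t".join(BSJ_COLUMNS) + "\n"]
    for j in junctions:
        reads = "." if j.read_count is None else str(j.read_count)
        lines.append(
            f"{j.chrom}\t{j.acceptor + 1}\t{j.donor}\t{j.strand}\t"
            f"{j.caller_id}\t{reads}\n"
        )
    return "".join(lines)
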