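"""miRNA candidate filtering, genomic context, and repeat association.

Candidates come from a discovery-score table (miRDeep2-style CSV): a
precursor locus, mature/star sequences, and a confidence score.  The
pipeline keeps candidates at or above the score cutoff, labels each
precursor's genomic context against the exon/intron/intergenic partition,
associates loci with the nearest repeat copy within a window, tests
repeat-class embedding against the class's genome coverage, and groups
loci sharing an identical mature sequence (recent duplications).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .intervals import (
    ContextPartition,
    GenomicInterval,
    LABELS,
    PRECEDENCE,
    apportion_bp,
)
from .repeats import matches_group
from .stats import EnrichmentResult, binomial_enrichment

_RC = str.maketrans("ACGU", "UGCA")


def _revcomp_rna(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class MirnaLocus:
    """One predicted miRNA precursor locus."""

    locus: GenomicInterval
    precursor_seq: str
    mature_seq: str
    score: float
    star_seq: str | None = None
    name: str | None = None
    context: str | None = None
    repeat_assoc: tuple | None = None  # (family_name, distance bp)

    def __post_init__(self) -> None:
        pre = self.precursor_seq.upper()
        mat = self.mature_seq.upper()
        if mat not in pre and _revcomp_rna(mat) not in pre:
            raise ValueError(
                "mature sequence is not a substring of the precursor "
                "(or its reverse complement)"
            )

    @property
    def key(self) -> tuple:
        return (self.locus.chrom, self.locus.start, self.locus.end, self.locus.strand)


@dataclass(frozen=True)
class MirnaGroup:
    """Loci at distinct genomic positions sharing one mature sequence."""

    mature_seq: str
    members: tuple

    @property
    def size(self) -> int:
        return len(self.members)


def filter_candidates(candidates, min_score: float = 3.9) -> list:
    """Keep candidates scoring at or above the cutoff (order preserved)."""
    return [c for c in candidates if c.score >= min_score]


def classify_context(locus: MirnaLocus, partition: ContextPartition) -> str:
    """Context with maximal bp overlap against the precursor interval;
    ties break exonic > intronic > intergenic."""
    split = apportion_bp([locus.locus], partition)
    return max(LABELS, key=lambda lab: (split[lab], -PRECEDENCE[lab]))


def annotate_contexts(loci, partition: ContextPartition) -> list:
    return [replace(l, context=classify_context(l, partition)) for l in loci]


def associate_repeat(locus: MirnaLocus, repeats, window: int = 100):
    """Nearest repeat within ``window`` bp of the precursor (inclusive).

    Distance is 0 for any overlap, otherwise the bp gap; returns
    ``(family_name, distance)`` or ``None``.  Ties break toward the
    leftmost repeat start.
    """
    iv = locus.locus
    best = None
    for rep in repeats:
        if rep.chrom != iv.chrom:
            continue
        if rep.end > iv.start and rep.start < iv.end:
            dist = 0
        elif rep.end <= iv.start:
            dist = iv.start - rep.end
        else:
            dist = rep.start - iv.end
        if dist <= window:
            key = (dist, rep.start, rep.end)
            if best is None or key < best[0]:
                best = (key, rep)
    if best is None:
        return None
    return (best[1].family_name, best[0][0])


def annotate_repeat_associations(loci, repeats, window: int = 100) -> list:
    return [
        replace(l, repeat_assoc=associate_repeat(l, repeats, window)) for l in loci
    ]


def repeat_class_enrichment(
    loci, coverage, class_of_interest: str
) -> EnrichmentResult:
    """Is embedding in a repeat class more frequent than its coverage?

    k = loci associated with the class, n = all loci given, p = the
    class's fraction of the genome; one-sided (greater) exact binomial.
    """
    k = sum(
        1
        for l in loci
        if l.repeat_assoc is not None and matches_group(l.repeat_assoc[0], class_of_interest)
    )
    return binomial_enrichment(
        k, len(loci), coverage.fraction(class_of_interest), alternative="greater"
    )


def group_identical_matures(loci, min_size: int = 2) -> list:
    """Exact-string groups of duplicated mature sequences, largest first.

    Duplicate rows at the same genomic locus count once; only groups with
    at least ``min_size`` distinct loci are returned.
    """
    by_mature: dict = {}
    for l in loci:
        by_mature.setdefault(l.mature_seq.upper(), {})[l.key] = l
    groups = [
        MirnaGroup(mature_seq=m, members=tuple(members.values()))
        for m, members in by_mature.items()
        if len(members) >= min_size
    ]
    return sorted(groups, key=lambda g: (-g.size, g.mature_seq))


def chromosome_distribution(loci) -> pd.DataFrame:
    """Per-chromosome locus counts with a context breakdown."""
    rows = [
        {
            "chrom": l.locus.chrom,
            "context": l.context if l.context is not None else "unset",
        }
        for l in loci
    ]
    if not rows:
        return pd.DataFrame(columns=["chrom", "total"]).set_index("chrom")
    df = pd.DataFrame(rows)
    table = df.groupby(["chrom", "context"]).size().unstack(fill_value=0)
    table["total"] = table.sum(axis=1)
    return table


# ---------------------------------------------------------------------------
# candidate CSV I/O (1-based inclusive on disk)

MIRNA_COLUMNS = (
    "name", "chrom", "start", "end", "strand", "score", "precursor", "mature", "star",
)


def read_candidates_csv(source) -> list:
    from .intervals import _read_text
    import io

    df = pd.read_csv(io.StringIO(_read_text(source)))
    loci = []
    for row in df.itertuples(index=False):
        star = getattr(row, "star", None)
        loci.append(
            MirnaLocus(
                locus=GenomicInterval(
                    str(row.chrom), int(row.start) - 1, int(row.end), row.strand
                ),
                precursor_seq=str(row.precursor),
                mature_seq=str(row.mature),
                star_seq=None if star is None or pd.isna(star) else str(star),
                score=float(row.score),
                name=str(row.name),
            )
        )
    return loci


def write_candidates_csv(loci) -> str:
    rows = []
    for l in loci:
        rows.append(
            {
                "name": l.name or "",
                "chrom": l.locus.chrom,
                "start": l.locus.start + 1,
                "end": l.locus.end,
                "strand": l.locus.strand,
                "score": l.score,
                "precursor": l.precursor_seq,
                "mature": l.mature_seq,
                "star": l.star_seq or "",
            }
        )
    return pd.DataFrame(rows, columns=list(MIRNA_COLUMNS)).to_csv(index=False)
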