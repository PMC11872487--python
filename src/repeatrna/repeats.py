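"""Repeat annotation input, taxonomy lookup, coverage and context summaries.

Repeat copies come from RepeatMasker output — either the classic
15-column ``.out`` table or a GFF dialect — and are mapped onto a bundled
class / subclass / superfamily / category taxonomy by token matching on
the masker's family string.  Coverage summaries give each group's share
of the genome, which downstream modules use as the null success
probability in coverage-null binomial tests.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass
from functools import lru_cache

from .intervals import (
    ChromSizes,
    ContextPartition,
    GenomicInterval,
    LABELS,
    ValidationError,
    apportion_bp,
    merge_intervals,
)
from .stats import EnrichmentResult, adjust_enrichment, binomial_enrichment

UNCLASSIFIED = "Unclassified"


@dataclass(frozen=True)
class RepeatCopy:
    """One masked repeat instance."""

    location: GenomicInterval
    family_name: str
    kimura_div: float | None = None

    def __post_init__(self) -> None:
        if self.location.strand not in ("+", "-"):
            raise ValueError("repeat copies must be stranded (+/-)")

    @property
    def chrom(self) -> str:
        return self.location.chrom

    @property
    def start(self) -> int:
        return self.location.start

    @property
    def end(self) -> int:
        return self.location.end

    @property
    def strand(self) -> str:
        return self.location.strand


@dataclass(frozen=True)
class RepeatClassification:
    te_class: str
    subclass: str
    superfamily: str
    category: str

    @property
    def is_classified(self) -> bool:
        return self.te_class != UNCLASSIFIED


_UNCLASSIFIED_ROW = RepeatClassification(
    UNCLASSIFIED, UNCLASSIFIED, UNCLASSIFIED, UNCLASSIFIED
)


@lru_cache(maxsize=1)
def _classification_table() -> tuple:
    """Rows of the bundled taxonomy plus a token -> row alias map."""
    text = (
        importlib.resources.files("repeatrna.data")
        .joinpath("repeat_classification.tsv")
        .read_text()
    )
    rows = []
    aliases = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        te_class, subclass, superfamily, category, alias_field = line.split("\t")
        row = RepeatClassification(te_class, subclass, superfamily, category)
        rows.append(row)
        aliases[superfamily.lower()] = row
        for alias in alias_field.split(","):
            aliases[alias.strip().lower()] = row
    return tuple(rows), aliases


def _tokens(name: str) -> list:
    return [t for t in re.split(r"[/\s|;,?]+", name.strip()) if t]


@lru_cache(maxsize=4096)
def classify_repeat(family_name: str) -> RepeatClassification:
    """Deterministic, case-insensitive taxonomy lookup for a family string.

    The full name is tried first, then its slash/space-separated tokens
    from the most specific (last) to the least specific.  Unknown names
    map to the ``Unclassified`` sentinel.
    """
    _, aliases = _classification_table()
    name = family_name.strip().lower()
    if name in aliases:
        return aliases[name]
    for token in reversed(_tokens(family_name)):
        tok = token.lower()
        if tok in aliases:
            return aliases[tok]
        # strip trailing sub-family qualifiers, e.g. "hAT-Charlie76a"
        base = re.split(r"[-_.]", tok)[0]
        if base in aliases:
            return aliases[base]
    return _UNCLASSIFIED_ROW


def matches_group(family_name: str, group: str) -> bool:
    """Does a masker family string belong to a named taxonomy group?

    ``group`` may be a family string, a superfamily (e.g. ``hAT``,
    ``nMITE``) or a category (e.g. ``LTR``, ``DNA``); matching is
    case-insensitive.
    """
    g = group.strip().lower()
    if g == family_name.strip().lower() or g in (t.lower() for t in _tokens(family_name)):
        return True
    cls = classify_repeat(family_name)
    return g in (cls.superfamily.lower(), cls.category.lower(), cls.te_class.lower())


# ---------------------------------------------------------------------------
# readers


class RepeatFormatError(ValueError):
    pass


def _parse_out(text: str, sizes: ChromSizes) -> list:
    copies = []
    for lineno, line in enumerate(text.splitlines(), 1):
        s = line.strip()
        if not s:
            continue
        low = s.lower()
        if low.startswith(("sw", "score", "there were no")):
            continue
        fields = s.split()
        if len(fields) < 11:
            raise RepeatFormatError(f".out line {lineno}: expected >=11 columns")
        try:
            div = float(fields[1])
            chrom = fields[4]
            start = int(fields[5]) - 1
            end = int(fields[6])
        except ValueError as exc:
            raise RepeatFormatError(f".out line {lineno}: bad numeric field") from exc
        strand = "-" if fields[8] in ("C", "-") else "+"
        family = fields[10] if len(fields) > 10 else fields[9]
        _check_bounds(chrom, start, end, sizes, lineno)
        copies.append(
            RepeatCopy(GenomicInterval(chrom, start, end, strand), family, div)
        )
    return copies


def _parse_gff(text: str, sizes: ChromSizes) -> list:
    copies = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise RepeatFormatError(f"GFF line {lineno}: expected 9 columns")
        chrom, _, _, start_s, end_s, _, strand, _, attrs = fields[:9]
        start, end = int(start_s) - 1, int(end_s)
        family, div = None, None
        m = re.search(r'(?:family|Name|name)[=\s]"?([^";]+)"?', attrs)
        if m:
            family = m.group(1).strip()
        else:
            m = re.search(r'Target[=\s]+"?(?:Motif:)?([^\s";]+)', attrs)
            if m:
                family = m.group(1)
        if family is None:
            raise RepeatFormatError(f"GFF line {lineno}: no repeat family attribute")
        m = re.search(r"(?:kimura|div)=([0-9.]+)", attrs)
        if m:
            div = float(m.group(1))
        strand = "-" if strand in ("C", "-") else "+"
        _check_bounds(chrom, start, end, sizes, lineno)
        copies.append(
            RepeatCopy(GenomicInterval(chrom, start, end, strand), family, div)
        )
    return copies


def _check_bounds(chrom, start, end, sizes, lineno):
    if chrom not in sizes:
        raise ValidationError(f"line {lineno}: unknown chromosome {chrom!r}")
    if not (0 <= start < end <= sizes[chrom]):
        raise ValidationError(f"line {lineno}: repeat outside chromosome bounds")


def read_repeatmasker(source, sizes: ChromSizes) -> list:
    """Read repeat copies from .out or GFF-dialect text (path/handle/string).

    Both dialects yield identical ``RepeatCopy`` lists for equivalent
    content; RepeatMasker's ``C`` strand normalizes to ``-``.
    """
    from .intervals import _read_text

    text = _read_text(source)
    data_lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
    ]
    if not data_lines:
        return []
    if any("\t" in ln for ln in data_lines):
        return _parse_gff(text, sizes)
    return _parse_out(text, sizes)


def write_out(copies) -> str:
    """Serialize copies in the 15-column RepeatMasker .out layout."""
    header = (
        "   SW   perc perc perc  query      position in query     matching"
        "       repeat              position in repeat\n"
        "score   div. del. ins.  sequence   begin  end    (left)  repeat"
        "         class/family      begin  end    (left)  ID\n\n"
    )
    lines = []
    for i, c in enumerate(copies, 1):
        div = 0.0 if c.kimura_div is None else c.kimura_div
        strand = "C" if c.strand == "-" else "+"
        lines.append(
            f"  225 {div:6.1f}  0.0  0.0  {c.chrom} {c.start + 1} {c.end} (0) "
            f"{strand} {c.family_name.split('/')[-1]} {c.family_name} 1 "
            f"{c.end - c.start} (0) {i}\n"
        )
    return header + "".join(lines)


# ---------------------------------------------------------------------------
# summaries


class CoverageSummary:
    """Per-group genomic coverage (bp and fraction of the genome).

    Groups are tracked at three levels: the raw masker family string, the
    taxonomy superfamily, and the category.  ``fraction(group)`` looks the
    name up across levels (family first).
    """

    def __init__(self, family_bp: dict, genome_size: int, merge_policy: str):
        if genome_size <= 0:
            raise ValueError("genome_size must be positive")
        self.family_bp = dict(family_bp)
        self.genome_size = genome_size
        self.merge_policy = merge_policy
        self.superfamily_bp: dict = {}
        self.category_bp: dict = {}
        for fam, bp in self.family_bp.items():
            cls = classify_repeat(fam)
            self.superfamily_bp[cls.superfamily] = (
                self.superfamily_bp.get(cls.superfamily, 0) + bp
            )
            self.category_bp[cls.category] = (
                self.category_bp.get(cls.category, 0) + bp
            )

    def total_bp(self, group: str) -> int:
        for level in (self.family_bp, self.superfamily_bp, self.category_bp):
            for name, bp in level.items():
                if name.lower() == group.lower():
                    return bp
        # fall back to token membership across raw family names
        bp = sum(
            v for fam, v in self.family_bp.items() if matches_group(fam, group)
        )
        if bp == 0:
            raise KeyError(f"no coverage recorded for group {group!r}")
        return bp

    def fraction(self, group: str) -> float:
        return self.total_bp(group) / self.genome_size


def coverage_summary(
    repeats, sizes: ChromSizes, merge_policy: str = "merge_within_family"
) -> CoverageSummary:
    """Total bp and genome fraction per repeat family.

    ``merge_within_family`` union-merges overlapping same-family copies
    before summing; ``raw_sum`` adds raw copy lengths.
    """
    if merge_policy not in ("raw_sum", "merge_within_family"):
        raise ValueError(f"unknown merge_policy {merge_policy!r}")
    per_family: dict = {}
    for c in repeats:
        per_family.setdefault(c.family_name, []).append(c.location)
    family_bp = {}
    for fam, locs in per_family.items():
        if merge_policy == "merge_within_family":
            family_bp[fam] = sum(iv.length for iv in merge_intervals(locs))
        else:
            family_bp[fam] = sum(iv.length for iv in locs)
    return CoverageSummary(family_bp, sizes.genome_size, merge_policy)


def context_apportionment(
    repeats, partition: ContextPartition, group_by: str = "superfamily"
) -> dict:
    """Per-group exonic/intronic/intergenic bp of repeat coverage.

    ``group_by`` is ``family`` (raw masker string), ``superfamily``, or
    ``category``.  Returns ``{group: {label: bp}}``; each group's context
    bp sums to its total raw bp.
    """
    if group_by not in ("family", "superfamily", "category"):
        raise ValueError(f"unknown group_by {group_by!r}")
    out: dict = {}
    for c in repeats:
        if group_by == "family":
            key = c.family_name
        else:
            cls = classify_repeat(c.family_name)
            key = cls.superfamily if group_by == "superfamily" else cls.category
        split = apportion_bp([c.location], partition)
        bucket = out.setdefault(key, {lab: 0 for lab in LABELS})
        for lab in LABELS:
            bucket[lab] += split[lab]
    return out


def context_percentages(context_bp: dict) -> dict:
    total = sum(context_bp.values())
    return {lab: 100.0 * bp / total for lab, bp in context_bp.items()}


def context_enrichment_test(
    observed_bp: dict, total_group_bp: float, context_fractions: dict
) -> dict:
    """Over/under-representation of a repeat group across genomic contexts.

    For each context: k = round(observed bp in that context), n = round of
    the group's total bp, p = the context's genome-wide fraction; exact
    two-sided binomial, BH-adjusted across the three contexts.
    """
    if abs(sum(context_fractions.values()) - 1.0) > 1e-9:
        raise ValueError("context fractions must sum to 1")
    n = round(total_group_bp)
    results = {}
    for lab in LABELS:
        k = round(observed_bp.get(lab, 0.0))
        if k > n:
            raise ValueError(f"observed bp in {lab} exceeds group total")
        results[lab] = binomial_enrichment(
            k, n, context_fractions[lab], alternative="two_sided"
        )
    return adjust_enrichment(results)
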