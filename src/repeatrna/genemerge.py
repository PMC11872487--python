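"""Gene nomenclature: collapse consecutively numbered isoform predictions
sharing a homology hit into named genes, and filter transposon genes.

Gene predictors emit one record per isoform with sequential raw ids
(``gene47``, ``gene48``, ...).  Isoforms of one real gene typically hit
the same UniProt entry (e.g. ``XYNB_NEOPA``); maximal runs of consecutive
ids with the same hit are merged into one named gene (``XYNB.1``) whose
isoforms get an extra index (``XYNB.1.1``, ...).  Additional genes with
the same mnemonic get larger suffixes in ascending id order.  Genes whose
mnemonic is on a curated transposable-element stem list are removed from
the conserved protein-coding count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .intervals import GenomicInterval

_RAW_ID = re.compile(r"^gene(\d+)$")


@dataclass(frozen=True)
class PredictedIsoform:
    raw_id: str
    homology_hit: str | None = None
    location: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if _RAW_ID.match(self.raw_id) is None:
            raise ValueError(f"raw id {self.raw_id!r} does not match 'gene<N>'")
        if self.homology_hit is not None and "_" not in self.homology_hit:
            raise ValueError(
                f"homology hit {self.homology_hit!r} lacks a mnemonic_species form"
            )

    @property
    def number(self) -> int:
        return int(_RAW_ID.match(self.raw_id).group(1))

    @property
    def mnemonic(self) -> str | None:
        if self.homology_hit is None:
            return None
        return self.homology_hit.split("_")[0]


@dataclass
class NamedGene:
    name: str
    mnemonic: str | None
    isoforms: list = field(default_factory=list)  # (isoform_name, PredictedIsoform)
    is_te: bool = False

    @property
    def isoform_count(self) -> int:
        return len(self.isoforms)


def merge_isoforms(isoforms) -> list:
    """Collapse maximal runs of consecutive raw-id numbers with the same
    homology hit into one named gene.

    Per mnemonic, gene counters increment in ascending run order; isoform
    indices within a run follow ascending raw-id number (so the output is
    invariant to input shuffling).  Isoforms without a hit keep their raw
    id as the gene name.
    """
    isoforms = list(isoforms)
    seen = set()
    for iso in isoforms:
        if iso.raw_id in seen:
            raise ValueError(f"duplicate raw id {iso.raw_id!r}")
        seen.add(iso.raw_id)
    ordered = sorted(isoforms, key=lambda i: i.number)
    runs = []
    for iso in ordered:
        if (
            runs
            and iso.homology_hit is not None
            and runs[-1][-1].homology_hit == iso.homology_hit
            and iso.number == runs[-1][-1].number + 1
        ):
            runs[-1].append(iso)
        else:
            runs.append([iso])
    counters: dict = {}
    genes = []
    for run in runs:
        mnemonic = run[0].mnemonic
        if mnemonic is None:
            for iso in run:  # unnamed isoforms stay singleton genes
                genes.append(
                    NamedGene(
                        name=iso.raw_id,
                        mnemonic=None,
                        isoforms=[(iso.raw_id, iso)],
                    )
                )
            continue
        counters[mnemonic] = counters.get(mnemonic, 0) + 1
        g = counters[mnemonic]
        name = f"{mnemonic}.{g}"
        genes.append(
            NamedGene(
                name=name,
                mnemonic=mnemonic,
                isoforms=[
                    (f"{name}.{i}", iso) for i, iso in enumerate(run, start=1)
                ],
            )
        )
    return genes


def filter_te_genes(genes, te_stems) -> tuple:
    """Remove genes whose homology mnemonic is a transposable-element stem.

    Returns ``(kept, removed_count, kept_count)``.
    """
    stems = {s.strip() for s in te_stems if s.strip()}
    kept = []
    removed = 0
    for gene in genes:
        if gene.mnemonic is not None and gene.mnemonic in stems:
            gene.is_te = True
            removed += 1
        else:
            kept.append(gene)
    return kept, removed, len(kept)


def read_te_stems(source) -> set:
    """One mnemonic per line, '#' comments allowed."""
    from .intervals import _read_text

    return {
        line.strip()
        for line in _read_text(source).splitlines()
        if line.strip() and not line.startswith("#")
    }
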