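"""Synthetic genome-annotation fixtures with planted ground truth.

Every pipeline stage in this package is exercised against data whose true
parameters are known: a multi-chromosome gene annotation, a repeat
catalog drawn from a configurable family mixture, three backsplice call
sets sharing a planted consensus whose flanking introns carry inverted
repeat pairs at a controlled excess, and miRNA candidate tables with a
controlled repeat-embedding rate and planted duplicated mature sequences.
Each generator is a pure function of its configuration: one root seed
spawns independent substreams per layer, so regenerating one layer never
perturbs another, and outputs are byte-identical across runs.

Default parameters are scaled-down study conditions: a few megabases of
genome instead of 20.3 Gb, with the genomic context split, repeat family
mixture (hAT at 11.4% of the genome, LTR/Gypsy, Harbinger, nMITE), the
three-caller consensus structure, and the score-filter funnel shaped to
match the empirical setting they stand in for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .intervals import ChromSizes, GenomicInterval
from .repeats import RepeatCopy, write_out
from .circrna import BackspliceJunction, write_bsj_tsv
from .mirna import MirnaLocus, write_candidates_csv


class TruthManifest(dict):
    """Planted parameter values for one generated layer."""

    def to_json(self) -> str:
        return json.dumps(self, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


@dataclass
class SimConfig:
    """All knobs for the generator stack.

    Lengths are bp.  ``repeat_families`` maps family string to (target
    genome fraction, probability of the + strand).  ``circ_pair_prob`` is
    the probability that a planted consensus circRNA receives an inverted
    pair of ``circ_pair_family`` repeats in its flanking introns.
    """

    seed: int = 0
    # genome & genes
    chrom_lengths: dict = field(
        default_factory=lambda: {f"chr{i}": 500_000 for i in range(1, 7)}
    )
    gene_count: int = 60
    mean_exons_per_gene: float = 6.0
    min_four_exon_share: float = 0.6
    exon_len_mu: float = 5.0   # lognormal log-scale (median ~150 bp)
    exon_len_sigma: float = 0.4
    intron_len_mu: float = 7.3  # median ~1.5 kb
    intron_len_sigma: float = 0.8
    long_intron_gene_fraction: float = 0.0
    long_intron_scale: float = 1.0
    # repeats
    repeat_families: dict = field(
        default_factory=lambda: {
            "DNA/hAT": (0.114, 0.5),
            "LTR/Gypsy": (0.10, 0.5),
            "DNA/PIF-Harbinger": (0.08, 0.5),
            "DNA/nMITE": (0.0322, 0.5),
        }
    )
    repeat_len_mu: float = 6.0  # median ~400 bp
    repeat_len_sigma: float = 0.7
    repeat_len_max: int = 5000
    context_mix: dict | None = None  # e.g. {"intergenic": .70, "intronic": .29, "exonic": .01}
    # circRNAs
    circ_count: int = 150
    caller_ids: tuple = ("circexplorer2", "find_circ2", "ciri2")
    caller_dropout: tuple = (0.05, 0.05, 0.05)
    decoys_per_caller: int = 30
    circ_pair_family: str = "DNA/hAT"
    circ_pair_prob: float = 0.3
    circ_on_long_intron_genes: bool = False
    # miRNAs
    mirna_count: int = 300
    mirna_passing_count: int = 120
    mirna_min_score: float = 3.9
    precursor_len: int = 70
    mature_len: int = 22
    embed_class: str = "LTR/Gypsy"
    embed_prob: float = 0.4
    embed_window: int = 100
    mature_groups: tuple = (3, 2, 2, 2)

    def validate(self) -> None:
        fractions = sum(f for f, _ in self.repeat_families.values())
        if fractions > 1.0:
            raise ValueError("repeat family fractions must sum to <= 1")
        for prob in (self.circ_pair_prob, self.embed_prob, *self.caller_dropout):
            if not (0.0 <= prob <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.context_mix is not None:
            if abs(sum(self.context_mix.values()) - 1.0) > 1e-9:
                raise ValueError("context_mix must sum to 1")

    def rng(self, layer: str) -> np.random.Generator:
        layers = {"annotation": 0, "repeats": 1, "circ": 2, "mirna": 3}
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(layers[layer],))
        )


# ---------------------------------------------------------------------------
# annotation


@dataclass
class SimGene:
    gene_id: str
    chrom: str
    strand: str
    exons: list       # list[(start, end)] sorted
    introns: list     # list[(start, end)]
    is_long_intron: bool = False

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class AnnotationSim:
    gff_text: str
    sizes: ChromSizes
    genes: list  # list[SimGene]
    manifest: TruthManifest


def _draw_gene_structures(config: SimConfig, rng) -> list:
    """Exon/intron length skeletons (coordinates assigned at placement)."""
    structures = []
    n_four = int(np.ceil(config.min_four_exon_share * config.gene_count))
    long_ids = set(
        rng.choice(
            config.gene_count,
            size=int(round(config.long_intron_gene_fraction * config.gene_count)),
            replace=False,
        ).tolist()
    )
    for i in range(config.gene_count):
        n_exons = 1 + rng.poisson(config.mean_exons_per_gene - 1)
        if i < n_four:
            n_exons = max(n_exons, 4)
        exon_lens = np.maximum(
            20, rng.lognormal(config.exon_len_mu, config.exon_len_sigma, n_exons)
        ).astype(int)
        scale = config.long_intron_scale if i in long_ids else 1.0
        intron_lens = np.maximum(
            50,
            scale * rng.lognormal(
                config.intron_len_mu, config.intron_len_sigma, max(0, n_exons - 1)
            ),
        ).astype(int)
        structures.append((exon_lens.tolist(), intron_lens.tolist(), i in long_ids))
    return structures


def generate_annotation(config: SimConfig) -> AnnotationSim:
    """Non-overlapping multi-exon gene models over the configured genome.

    Genes are packed chromosome by chromosome with random intergenic gaps
    scaled to fill the remaining space; raises if the drawn genes exceed
    the genome.
    """
    config.validate()
    rng = config.rng("annotation")
    sizes = ChromSizes(config.chrom_lengths)
    structures = _draw_gene_structures(config, rng)
    gene_lengths = [sum(e) + sum(i) for e, i, _ in structures]
    chroms = list(sizes)
    # round-robin assignment, largest genes first, onto least-filled chrom
    filled = {c: 0 for c in chroms}
    assignment: dict = {c: [] for c in chroms}
    order = sorted(range(len(structures)), key=lambda i: -gene_lengths[i])
    for gi in order:
        target = min(chroms, key=lambda c: filled[c] / sizes[c])
        if filled[target] + gene_lengths[gi] > sizes[target]:
            raise ValueError("genes exceed chromosome space; reduce gene_count")
        assignment[target].append(gi)
        filled[target] += gene_lengths[gi]

    genes = []
    for chrom in chroms:
        idxs = sorted(assignment[chrom])
        free = sizes[chrom] - sum(gene_lengths[i] for i in idxs)
        gaps = rng.dirichlet(np.ones(len(idxs) + 1)) * free if idxs else []
        cursor = 0
        for slot, gi in enumerate(idxs):
            cursor += int(gaps[slot])
            exon_lens, intron_lens, is_long = structures[gi]
            exons, pos = [], cursor
            for k, el in enumerate(exon_lens):
                exons.append((pos, pos + el))
                pos += el
                if k < len(intron_lens):
                    pos += intron_lens[k]
            introns = [
                (exons[k][1], exons[k + 1][0]) for k in range(len(exons) - 1)
            ]
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                SimGene(
                    gene_id=f"gene{gi + 1}",
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    introns=introns,
                    is_long_intron=is_long,
                )
            )
            cursor = pos
    genes.sort(key=lambda g: (g.chrom, g.span[0]))

    exonic_bp = sum(e[1] - e[0] for g in genes for e in g.exons)
    intronic_bp = sum(i[1] - i[0] for g in genes for i in g.introns)
    genome = sizes.genome_size
    n_introns = sum(max(0, len(s[0]) - 1) for s in structures)
    expected_intron = float(
        np.exp(config.intron_len_mu + config.intron_len_sigma**2 / 2)
    )
    manifest = TruthManifest(
        seed=config.seed,
        gene_count=len(genes),
        context_fractions={
            "exonic": exonic_bp / genome,
            "intronic": intronic_bp / genome,
            "intergenic": 1.0 - (exonic_bp + intronic_bp) / genome,
        },
        expected_intronic_fraction=n_introns * expected_intron / genome,
        long_intron_genes=sorted(g.gene_id for g in genes if g.is_long_intron),
    )
    return AnnotationSim(
        gff_text=_to_gff3(genes, sizes), sizes=sizes, genes=genes, manifest=manifest
    )


def _to_gff3(genes, sizes: ChromSizes) -> str:
    lines = ["##gff-version 3\n"]
    for chrom, length in sizes.items():
        lines.append(f"##sequence-region {chrom} 1 {length}\n")
    for g in genes:
        s, e = g.span
        lines.append(
            f"{g.chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
        )
        tid = f"{g.gene_id}.t1"
        lines.append(
            f"{g.chrom}\tsim\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
            f"ID={tid};Parent={g.gene_id}\n"
        )
        for k, (es, ee) in enumerate(g.exons, 1):
            lines.append(
                f"{g.chrom}\tsim\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                f"ID={tid}.e{k};Parent={tid}\n"
            )
    return "".join(lines)


# ---------------------------------------------------------------------------
# repeats


@dataclass
class RepeatSim:
    out_text: str
    repeats: list
    manifest: TruthManifest


def _context_intervals(annotation: AnnotationSim) -> dict:
    """Exonic/intronic/intergenic intervals from the generator's own
    bookkeeping (independent of the pipeline's partition code)."""
    out = {"exonic": [], "intronic": [], "intergenic": []}
    per_chrom: dict = {c: [] for c in annotation.sizes}
    for g in annotation.genes:
        per_chrom[g.chrom].append(g)
        out["exonic"].extend((g.chrom, s, e) for s, e in g.exons)
        out["intronic"].extend((g.chrom, s, e) for s, e in g.introns)
    for chrom, length in annotation.sizes.items():
        cursor = 0
        for g in sorted(per_chrom[chrom], key=lambda g: g.span[0]):
            s, e = g.span
            if s > cursor:
                out["intergenic"].append((chrom, cursor, s))
            cursor = max(cursor, e)
        if cursor < length:
            out["intergenic"].append((chrom, cursor, length))
    return out


def generate_repeats(config: SimConfig, annotation: AnnotationSim) -> RepeatSim:
    """Repeat copies placed to hit each family's target genome fraction.

    Copies are placed until the family's bp budget is met (realized
    coverage lands within a copy length of the target).  With a
    ``context_mix``, each copy is placed entirely inside an interval of a
    context drawn to meet per-context bp budgets, so the realized context
    shares track the mix tightly.
    """
    config.validate()
    rng = config.rng("repeats")
    sizes = annotation.sizes
    genome = sizes.genome_size
    chroms = list(sizes)
    chrom_p = np.array([sizes[c] for c in chroms], dtype=float)
    chrom_p /= chrom_p.sum()
    contexts = _context_intervals(annotation) if config.context_mix else None

    copies = []
    realized: dict = {}
    realized_context: dict = {}
    for family, (fraction, plus_prob) in config.repeat_families.items():
        budget = fraction * genome
        placed = 0
        ctx_budget = (
            {lab: share * budget for lab, share in config.context_mix.items()}
            if config.context_mix
            else None
        )
        ctx_placed = {lab: 0 for lab in ("exonic", "intronic", "intergenic")}
        while placed < budget:
            length = int(
                min(
                    config.repeat_len_max,
                    max(30, rng.lognormal(config.repeat_len_mu, config.repeat_len_sigma)),
                )
            )
            if ctx_budget is not None:
                deficits = {
                    lab: ctx_budget.get(lab, 0.0) - ctx_placed[lab]
                    for lab in ctx_placed
                }
                lab = max(deficits, key=lambda l: deficits[l])
                pool = [iv for iv in contexts[lab] if iv[2] - iv[1] >= 40]
                caps = np.array([iv[2] - iv[1] for iv in pool], dtype=float)
                iv = pool[rng.choice(len(pool), p=caps / caps.sum())]
                length = min(length, iv[2] - iv[1])
                start = int(iv[1] + rng.integers(0, iv[2] - iv[1] - length + 1))
                chrom = iv[0]
                ctx_placed[lab] += length
            else:
                chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
                start = int(rng.integers(0, sizes[chrom] - length + 1))
            strand = "+" if rng.random() < plus_prob else "-"
            copies.append(
                RepeatCopy(
                    GenomicInterval(chrom, start, start + length, strand),
                    family,
                    kimura_div=round(float(rng.uniform(0, 40)), 1),
                )
            )
            placed += length
        realized[family] = placed
        realized_context[family] = dict(ctx_placed)

    manifest = TruthManifest(
        seed=config.seed,
        genome_size=genome,
        target_fractions={f: frac for f, (frac, _) in config.repeat_families.items()},
        realized_bp=realized,
        realized_fractions={f: bp / genome for f, bp in realized.items()},
        context_mix=config.context_mix,
        realized_context_bp=realized_context,
    )
    return RepeatSim(out_text=write_out(copies), repeats=copies, manifest=manifest)


# ---------------------------------------------------------------------------
# circRNA call sets


@dataclass
class CircSim:
    callset_texts: dict       # caller_id -> BSJ TSV text
    callsets: dict            # caller_id -> list[BackspliceJunction]
    planted_repeats: list     # inverted-pair copies to append to the catalog
    manifest: TruthManifest


def _internal_pairs(gene: SimGene) -> list:
    internal = gene.exons[1:-1]
    m = len(internal)
    return [(internal[i][0], internal[j][1]) for i in range(m) for j in range(i, m)]


def generate_circ_callsets(
    config: SimConfig, annotation: AnnotationSim, repeats: RepeatSim | None = None
) -> CircSim:
    """Three call sets sharing a planted consensus, plus planted pairs.

    The consensus junctions are valid internal exon pairs; each caller
    misses a consensus junction with its dropout probability and adds its
    own decoy junctions.  A planted fraction of consensus circRNAs gets an
    inverted pair of ``circ_pair_family`` copies inserted at the
    junction-proximal ends of the flanking introns (distance 0, fully
    inside the intron, opposite strands); those copies are returned in
    ``planted_repeats`` for appending to the repeat catalog.
    """
    config.validate()
    rng = config.rng("circ")
    host_pool = [
        g
        for g in annotation.genes
        if len(g.exons) >= 3 and (not config.circ_on_long_intron_genes or g.is_long_intron)
    ]
    if not host_pool:
        raise ValueError("no eligible multi-exon genes for circRNA planting")
    weights = np.array([len(_internal_pairs(g)) for g in host_pool], dtype=float)
    consensus = {}
    while len(consensus) < config.circ_count:
        g = host_pool[rng.choice(len(host_pool), p=weights / weights.sum())]
        pairs = _internal_pairs(g)
        acceptor, donor = pairs[rng.integers(len(pairs))]
        key = (g.chrom, acceptor, donor, g.strand)
        if key not in consensus:
            consensus[key] = g

    planted_repeats = []
    paired_keys = []
    for key, g in consensus.items():
        if rng.random() >= config.circ_pair_prob:
            continue
        chrom, acceptor, donor, strand = key
        up = next(iv for iv in g.introns if iv[1] == acceptor)
        down = next(iv for iv in g.introns if iv[0] == donor)
        up_len = min(int(rng.integers(150, 400)), up[1] - up[0])
        down_len = min(int(rng.integers(150, 400)), down[1] - down[0])
        s = "+" if rng.random() < 0.5 else "-"
        planted_repeats.append(
            RepeatCopy(
                GenomicInterval(chrom, up[1] - up_len, up[1], s),
                config.circ_pair_family,
                0.0,
            )
        )
        planted_repeats.append(
            RepeatCopy(
                GenomicInterval(chrom, down[0], down[0] + down_len, "-" if s == "+" else "+"),
                config.circ_pair_family,
                0.0,
            )
        )
        paired_keys.append(key)

    callsets: dict = {}
    consensus_keys = list(consensus)
    for ci, caller in enumerate(config.caller_ids):
        junctions = []
        for key in consensus_keys:
            if rng.random() < config.caller_dropout[ci]:
                continue
            chrom, acceptor, donor, strand = key
            junctions.append(
                BackspliceJunction(
                    chrom, acceptor, donor, strand, caller,
                    read_count=int(rng.poisson(5) + 1),
                )
            )
        decoys = 0
        while decoys < config.decoys_per_caller:
            g = host_pool[rng.integers(len(host_pool))]
            pairs = _internal_pairs(g)
            acceptor, donor = pairs[rng.integers(len(pairs))]
            key = (g.chrom, acceptor, donor, g.strand)
            if key in consensus:
                continue
            junctions.append(
                BackspliceJunction(
                    g.chrom, acceptor, donor, g.strand, caller,
                    read_count=int(rng.poisson(2) + 1),
                )
            )
            decoys += 1
        callsets[caller] = junctions

    manifest = TruthManifest(
        seed=config.seed,
        consensus_keys=[list(k) for k in consensus_keys],
        pair_family=config.circ_pair_family,
        pair_prob=config.circ_pair_prob,
        paired_keys=[list(k) for k in paired_keys],
        planted_pair_count=len(paired_keys),
    )
    return CircSim(
        callset_texts={c: write_bsj_tsv(js) for c, js in callsets.items()},
        callsets=callsets,
        planted_repeats=planted_repeats,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# miRNA candidates

_BASES = np.array(list("ACGU"))


def _random_rna(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_mirna_loci(
    config: SimConfig, annotation: AnnotationSim, repeats: RepeatSim | None
) -> tuple:
    """Candidate loci with a controlled embedding rate and planted groups.

    A configured fraction of passing loci is placed inside, or within a
    uniform 0-100 bp gap of, a repeat copy of ``embed_class``; the rest
    are placed at least ``embed_window`` + 1 bp away from any such copy.
    Scores are drawn so exactly ``mirna_passing_count`` candidates reach
    the discovery-score cutoff, and the configured duplicated-mature
    groups are planted among the passing loci.

    Returns ``(csv_text, loci, TruthManifest)``.
    """
    config.validate()
    rng = config.rng("mirna")
    sizes = annotation.sizes
    chroms = list(sizes)
    chrom_p = np.array([sizes[c] for c in chroms], dtype=float)
    chrom_p /= chrom_p.sum()
    class_repeats = [
        r
        for r in (repeats.repeats if repeats is not None else [])
        if r.family_name == config.embed_class
    ]

    n = config.mirna_count
    n_pass = config.mirna_passing_count
    if n_pass > n:
        raise ValueError("mirna_passing_count exceeds mirna_count")
    pass_idx = set(range(n_pass))  # deterministic: first n_pass pass the filter
    embed_flags = {}
    for i in range(n_pass):
        embed_flags[i] = bool(class_repeats) and rng.random() < config.embed_prob

    loci = []
    embedded_ids = []
    plen = config.precursor_len
    for i in range(n):
        if embed_flags.get(i, False):
            rep = class_repeats[rng.integers(len(class_repeats))]
            if rng.random() < 0.5 and rep.location.length > plen:
                start = int(
                    rep.start + rng.integers(0, rep.location.length - plen + 1)
                )
            else:
                gap = int(rng.integers(0, config.embed_window + 1))
                start = rep.end + gap
            chrom = rep.chrom
            start = min(start, sizes[chrom] - plen)
        else:
            for _ in range(200):
                chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
                start = int(rng.integers(0, sizes[chrom] - plen + 1))
                iv = GenomicInterval(chrom, start, start + plen)
                near = any(
                    r.chrom == chrom
                    and r.start - iv.end <= config.embed_window
                    and iv.start - r.end <= config.embed_window
                    for r in class_repeats
                )
                if not near:
                    break
            else:
                raise ValueError("could not place a repeat-free miRNA locus")
        strand = "+" if rng.random() < 0.5 else "-"
        if i in pass_idx:
            score = round(float(rng.uniform(config.mirna_min_score, 12.0)), 2)
        else:
            score = round(float(rng.uniform(-5.0, config.mirna_min_score - 0.01)), 2)
        loci.append(
            {
                "i": i,
                "chrom": chrom,
                "start": start,
                "strand": strand,
                "score": score,
                "embedded": embed_flags.get(i, False),
            }
        )
        if embed_flags.get(i, False):
            embedded_ids.append(f"mir-{i + 1}")

    # mature sequences: planted identical groups among passing loci
    matures = {}
    group_matures = []
    cursor = 0
    for size in config.mature_groups:
        seq = _random_rna(rng, config.mature_len)
        group_matures.append(seq)
        for _ in range(size):
            if cursor >= n_pass:
                raise ValueError("mature_groups larger than passing count")
            matures[cursor] = seq
            cursor += 1
    seen = set(group_matures)
    for i in range(n):
        if i not in matures:
            while True:
                seq = _random_rna(rng, config.mature_len)
                if seq not in seen:
                    break
            seen.add(seq)
            matures[i] = seq

    out = []
    for rec in loci:
        i = rec["i"]
        mature = matures[i]
        offset = int(rng.integers(0, plen - config.mature_len + 1))
        precursor = (
            _random_rna(rng, offset)
            + mature
            + _random_rna(rng, plen - offset - config.mature_len)
        )
        out.append(
            MirnaLocus(
                locus=GenomicInterval(
                    rec["chrom"], rec["start"], rec["start"] + plen, rec["strand"]
                ),
                precursor_seq=precursor,
                mature_seq=mature,
                score=rec["score"],
                name=f"mir-{i + 1}",
            )
        )

    manifest = TruthManifest(
        seed=config.seed,
        candidate_count=n,
        passing_count=n_pass,
        embed_class=config.embed_class,
        embed_prob=config.embed_prob,
        embedded_ids=embedded_ids,
        embedded_count=len(embedded_ids),
        group_sizes=list(config.mature_groups),
        group_matures=group_matures,
    )
    return write_candidates_csv(out), out, manifest


# ---------------------------------------------------------------------------
# one-call bundle


def simulate_all(config: SimConfig, outdir=None) -> dict:
    """Run every generator and (optionally) write the fixture files.

    Returns a dict with the in-memory layers and the combined manifest;
    when ``outdir`` is given, writes annotation.gff3, chrom.sizes,
    repeats.out, <caller>.bsj.tsv, mirna_candidates.csv and
    truth_manifest.json there.
    """
    annotation = generate_annotation(config)
    repeats = generate_repeats(config, annotation)
    circ = generate_circ_callsets(config, annotation, repeats)
    all_repeats = repeats.repeats + circ.planted_repeats
    mirna_csv, mirna_loci, mirna_manifest = generate_mirna_loci(
        config, annotation, repeats
    )
    combined = TruthManifest(
        annotation=annotation.manifest,
        repeats=repeats.manifest,
        circ=circ.manifest,
        mirna=mirna_manifest,
    )
    bundle = {
        "annotation": annotation,
        "repeats": repeats,
        "all_repeats": all_repeats,
        "circ": circ,
        "mirna_loci": mirna_loci,
        "mirna_csv": mirna_csv,
        "manifest": combined,
    }
    if outdir is not None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "annotation.gff3").write_text(annotation.gff_text)
        (outdir / "chrom.sizes").write_text(annotation.sizes.to_tsv())
        (outdir / "repeats.out").write_text(write_out(all_repeats))
        for caller, text in circ.callset_texts.items():
            (outdir / f"{caller}.bsj.tsv").write_text(text)
        (outdir / "mirna_candidates.csv").write_text(mirna_csv)
        (outdir / "truth_manifest.json").write_text(combined.to_json())
    return bundle
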