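# Methods

## Coordinate model and the context partition

All internal coordinates are 0-based half-open; GFF3/GTF input (1-based
closed) is converted on read and on write. This removes every off-by-one
ambiguity from overlap arithmetic: interval length is `end - start`, and
two intervals abut exactly when one's `end` equals the other's `start`.

A gene's span is the range from its first to its last exon across all
transcripts (any declared gene row is ignored for coordinates). Introns
are derived once per gene from the union of all transcripts' exons — not
per transcript — so a base covered by an exon in any isoform is never
intronic. Intergenic space is the complement of the union of gene spans;
a base inside any gene (including genes nested in other genes' introns)
is never intergenic. The partition labels every base with precedence
exonic > intronic > intergenic and tiles each chromosome end-to-end; the
tiling invariant (label lengths sum exactly to genome length) is checked
on construction. Strand is carried on intervals but deliberately ignored
by the partition, matching the strand-blind complement/intersect recipe
this stage reproduces.

Base-pair apportionment of query intervals (repeat copies, miRNA
precursors) splits each query's length among labels by exact overlap, so
per-label totals always sum to the total query bp.

## Repeat taxonomy and coverage

Repeat copies are read from RepeatMasker 15-column `.out` tables or a GFF
dialect (both yield identical copies for equivalent content; the `C`
strand code maps to `-`). Family strings are mapped onto a bundled
class / subclass / superfamily / category table
(`src/repeatrna/data/repeat_classification.tsv`, editable TSV) by
case-insensitive token matching, trying the most specific (last) token of
strings like `DNA/hAT-Charlie` first; unknown names map to an
`Unclassified` sentinel, so classification is total. Kimura divergence is
parsed and carried but not analyzed.

Coverage summaries support two policies: `merge_within_family` (default)
union-merges overlapping same-family copies before summing, `raw_sum`
adds raw copy lengths. The underlying data source does not fix this
choice; the default avoids double-counting nested fragments, and raw
sums remain available (and are what the simulator's manifest records,
since planted copies may overlap).

## Enrichment statistics

Every enrichment test is an exact binomial test with the null success
probability taken from coverage: a feature class's bp divided by genome
bp (or a context's fraction of the genome). Because trial counts at bp
scale push p-values far below the smallest normal double (the context
tests produce values around 1e-3000 on real-genome scales), all pmf and
tail computation is done in log space: tails use the incomplete-beta
route while the linear value is representable (≥ 1e-280) and otherwise
an explicit log-sum-exp walk over pmf terms, which terminates quickly
because terms decay geometrically away from the mode. Results carry both
`p_value` (possibly subnormal or zero) and `log10_p` (always finite);
comparisons should use the log scale below ~1e-300.

The two-sided convention is minimum likelihood: sum P(X = x) over all x
with P(X = x) ≤ P(X = k)·(1 + 1e-7). The relative tolerance absorbs
floating-point ties and reproduces the convention of the standard
`binom_test` routines. The opposite-side boundary is located by binary
search on the monotone flank of the unimodal pmf.

Fractional bp "counts" entering the context tests are rounded to the
nearest integer first — an exact fractional-count binomial is not
defined, and at bp scales the rounding perturbs nothing.

Benjamini–Hochberg adjustment is applied within each analysis family
(the three contexts of one group's context test; the set of repeat
families tested for circRNA pairs), never across families. Welch's
unequal-variance t (two-sided, Welch–Satterthwaite df) is used for the
flanking-intron length comparison; it requires ≥ 2 observations per
group and nonzero variance in at least one.

## circRNA stage

Call sets are intersected at exact junction coordinates
(chrom, acceptor, donor, strand); no matching tolerance is applied —
caller-specific coordinate conventions belong in input adapters, and
exact matching is reproducible and strand-safe. Read counts sum within a
caller and are never pooled across callers.

A consensus junction is splice-site validated when its acceptor equals a
merged-exon start and its donor a merged-exon end of one gene on the
matching strand. Flanking introns are the introns immediately adjacent
to the circle (5′ of the acceptor and 3′ of the donor in transcript
orientation; mirrored on the minus strand). Junctions at terminal exons
lack a flank and are excluded from flanking analyses.

The random-junction null draws a gene with probability proportional to
its number of ordered internal exon pairs (acceptor exon at or before
the donor exon, terminal exons excluded), then a pair uniformly; every
draw is therefore splice-valid with both flanks, which the comparison
requires. Drawing is deterministic given the seed.

Inverted-pair detection: on each flank, candidate repeats must overlap
the intron by at least 50 % of the repeat's own length (the fraction is
measured on the repeat, configurable); the candidate nearest the
backsplice junction is selected, measuring from the repeat's
junction-proximal edge (overlap with the junction counts as distance 0).
Distance ties break by larger intron overlap, then leftmost genomic
start, so outputs are deterministic. A pair is emitted only when the two
selections lie on opposite strands.

Per-family enrichment counts a circRNA once per family when either pair
member belongs to the family; n is all consensus circRNAs (not only
those with repeat-containing flanks), which is the denominator that
reproduces the published expected counts; tests are two-sided. Hotspot
genes are hosts of ≥ 15 distinct consensus junctions (threshold
configurable).

## miRNA stage

Context is assigned on the precursor interval (not the mature arm) as
the label with maximal overlap, ties broken by the exonic > intronic >
intergenic precedence. The repeat-association window is inclusive
(distance ≤ 100 bp; 0 for any overlap). The LTR-embedding test uses all
score-filtered loci as n — the published analysis code's denominator —
while the repeat-embedded subset count is also reported for the
alternative ratio. Mature-sequence grouping is exact string equality
with per-locus deduplication; no mismatch tolerance, since the quantity
of interest is identical mature duplication.

## Gene nomenclature

A merge run is a maximal set of isoforms with consecutive raw-id numbers
and the same homology hit; any gap in numbering or change of hit breaks
the run, even if the missing id is absent from the input. Per-mnemonic
gene counters increment in ascending run order. Isoform sub-numbering
follows ascending raw-id number within the run: the source procedure's
file order is ascending-id in practice, and this choice makes the output
invariant to input shuffling, which the module guarantees as a property.
Mnemonic case is preserved.

## Synthetic data

The generator stack is a pure function of (config, seed); one root seed
spawns independent substreams for annotation, repeats, circRNAs and
miRNAs, so regenerating one layer never changes another, and outputs are
byte-identical across runs. Defaults are the study conditions scaled
down ~7000×: six chromosomes of 500 kb; 60 non-overlapping genes with
lognormal exon (median ~150 bp) and intron (median ~1.5 kb) lengths,
yielding a ~77/21/2 intergenic/intronic/exonic split; a repeat mixture
led by hAT at 11.4 % of the genome (the published hAT fraction) plus
LTR/Gypsy, Harbinger and nMITE; three callers with 5 % dropout over a
150-junction planted consensus; a 300→120 score funnel standing in for
the published 3,046→855 one (generatable at full scale); 40 % repeat
embedding for miRNAs; and duplicated-mature groups of sizes 3, 2, 2, 2.

Repeat placement is budgeted: copies are placed until each family's bp
budget is met, so realized coverage lands within one copy length of the
target (well inside ±10 % relative). With a planted context mix, each
copy is placed entirely inside an interval of a context chosen to meet
per-context bp budgets, so realized context shares track the mix to a
fraction of a point. Planted inverted pairs are inserted at the
junction-proximal ends of both flanking introns (distance 0, fully
inside, opposite strands); a background copy can still displace a
planted one as the junction-nearest candidate, so round-trip recovery of
planted pairs is asserted at ≥ 85 %, not 100 %. Sequences are generated
only where the analysis needs them (precursor/mature strings); no genome
FASTA is emitted.

What the simulator does **not** emulate: sequence-level signals (splice
motifs, repeat consensus divergence structure), caller-specific
false-positive signatures, expression levels, nested/fragmented repeat
copies with biological structure, or overlapping genes. Passing tests
therefore demonstrate correctness of the interval arithmetic, counting,
and statistics under known truth — not robustness to every artifact of
real annotations.

## Problem sizes and numerical choices

Tests run the per-base oracle on 100 random genomes up to ~50 kb per
chromosome, power properties on 100 seeds (2,000 simulated circRNAs for
pair enrichment; 100 junctions per group for the flanking-length test),
and null calibration on 500 seeds per test, checking the empirical
rejection rate at α = 0.05 stays within [0.02, 0.09] — exact tests are
conservative, so rates sit slightly below 0.05. The flanking-length
power test plants a 2× intron-length scale on circRNA host genes.
Tolerances: coverage round trips at ±10 % relative; context-mix recovery
at ±0.5 points; the simulated intronic fraction matches its analytic
lognormal expectation within ±2 points averaged over 50 seeds.

## Known limitations

- Consensus matching is exact-coordinate only; callers that report
  shifted junctions need a normalization adapter first.
- The classification table covers the superfamilies relevant here plus
  common masker names; projects with exotic libraries should extend the
  TSV (unknowns degrade gracefully to `Unclassified`).
- `validate_and_flank` matches against merged exon boundaries per gene;
  isoform-specific flanks inside one gene are not distinguished.
- The bundled taxonomy maps each family string to a single row; chimeric
  annotations (`family1/family2` hybrids) resolve to the most specific
  token.
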