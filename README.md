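# repeatrna

Repeat elements dominate giant genomes — in the Iberian ribbed newt
(*Pleurodeles waltl*, ~20.3 Gb) they cover roughly three quarters of the
assembly — and they leave fingerprints on the non-coding transcriptome:
inverted repeat pairs in the introns flanking backsplice junctions promote
circular RNA formation, and many miRNA precursors sit inside or next to LTR
retrotransposon copies. `repeatrna` is a tested re-implementation of the
analysis chain behind those observations, for genomicists who want to run
(or stress-test) the same statistics on their own annotations without a
20 Gb genome in hand:

1. **Genomic context partition** — derive introns and intergenic regions
   from a GFF3/GTF annotation and tile every base of the genome as exonic,
   intronic, or intergenic (precedence exonic > intronic > intergenic).
2. **Repeat catalog** — read RepeatMasker output (15-column `.out` or a GFF
   dialect), map masker family strings onto a class / subclass /
   superfamily / category taxonomy, and summarize per-family genome
   coverage and per-context apportionment.
3. **Coverage-null enrichment tests** — exact binomial tests whose null
   success probability is a feature class's fraction of the genome,
   computed entirely in log space (the bp-scale context tests produce
   p-values far below linear double range), with Benjamini–Hochberg
   adjustment within each test family:
   for *k* observed among *n* trials at null probability *p*,
   the two-sided p-value is Σ P(X = x) over all x with
   P(X = x) ≤ P(X = k)·(1 + 10⁻⁷), X ~ Binomial(n, p).
4. **circRNA pipeline** — intersect backsplice-junction call sets from
   several detection programs at exact coordinates, validate junctions
   against annotated splice sites, resolve flanking introns, compare their
   lengths with a random-junction null (Welch's t), and find the
   junction-nearest opposite-strand repeat pair in the flanks (candidates
   must overlap the intron by ≥ 50 % of their own length).
5. **miRNA pipeline** — score filtering (≥ 3.9), precursor context
   classification, nearest-repeat association within 100 bp, LTR-embedding
   enrichment, and exact-string grouping of duplicated mature sequences.
6. **Gene nomenclature** — merge consecutively numbered isoform predictions
   sharing a homology hit into named genes and apply the
   transposable-element stem filter.
7. **Synthetic data** — a deterministic generator that plants every
   parameter the pipeline estimates (context fractions, family coverage,
   consensus sets, pair probabilities, embedding rates, duplicate groups)
   so each stage is verifiable against known truth.

## Worked example

The numbered scripts under `analysis/` run the full chain on a simulated
3 Mb genome (seed 42) and write tables under `results/`:

```sh
python analysis/01_simulate_data.py
python analysis/04_circrna_flanking.py
```

prints, among other things:

```
consensus circRNAs: 128 (128 at known splice sites, 128 with both flanking introns)
inverted repeat pairs in flanks: 49/128
  hAT    k=  46 expected=   14.9 log10 p=  -12.10 adj=2.376e-12
  LTR    k=   3 expected=   12.1 log10 p=   -2.46 adj=5.214e-03
  nMITE  k=   3 expected=    4.1 log10 p=   -0.10 adj=8.019e-01
published full-scale worked examples (n = 9,799 consensus circRNAs):
  hAT    k=2297 expected=1117.086 log10 p=-244.93
```

Reading: 128 of 150 planted consensus junctions survive the three callers'
5 % dropout; the simulator planted inverted hAT pairs on ~30 % of consensus
circRNAs against a genomic hAT fraction of 11.4 %, and the two-sided
coverage-null binomial flags exactly that excess (k = 46 observed vs 14.9
expected). The last block re-evaluates the published full-scale inputs:
with 2,297 of 9,799 circRNAs carrying hAT pairs at null probability 0.114,
the expected count is 1,117.086 and the two-sided p-value is 1.17e-245 —
a number only reachable with log-space tail accumulation.

The same stages are exposed as a CLI
(`repeatrna simulate | contexts | repeat-summary | circ | mirna |
merge-genes | report`); each stage writes a timestamp-free JSON summary
and `report` aggregates them.

## Layout

```
src/repeatrna/     library (intervals, repeats, stats, circrna, mirna,
                   genemerge, simulate, cli)
analysis/          numbered narrative drivers over the library
tests/             pytest suite incl. planted-truth acceptance properties
docs/methods.md    model, parameter, and design notes
```
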