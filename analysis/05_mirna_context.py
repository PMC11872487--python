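#!/usr/bin/env python
"""miRNA discovery-score filtering, genomic context, repeat embedding.

Applies the score >= 3.9 filter to the simulated candidate table, labels
each passing precursor's genomic context, associates loci with repeat
copies within 100 bp, tests LTR embedding against LTR's genome share
(one-sided binomial), groups duplicated identical mature sequences, and
tabulates the per-chromosome distribution.
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from repeatrna.intervals import ChromSizes, build_partition, read_annotation
from repeatrna.mirna import (
    annotate_contexts,
    annotate_repeat_associations,
    chromosome_distribution,
    filter_candidates,
    group_identical_matures,
    read_candidates_csv,
    repeat_class_enrichment,
)
from repeatrna.repeats import coverage_summary, read_repeatmasker

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    simdata = RESULTS / "simdata"
    if not simdata.exists():
        sys.exit("run analysis/01_simulate_data.py first")
    sizes = ChromSizes.from_tsv(str(simdata / "chrom.sizes"))
    genes = read_annotation(str(simdata / "annotation.gff3"), sizes)
    repeats = read_repeatmasker(str(simdata / "repeats.out"), sizes)
    partition = build_partition(sizes, genes)
    candidates = read_candidates_csv(str(simdata / "mirna_candidates.csv"))

    kept = filter_candidates(candidates, min_score=3.9)
    print(f"{len(kept)}/{len(candidates)} candidates at score >= 3.9")

    kept = annotate_contexts(kept, partition)
    counts = {}
    for l in kept:
        counts[l.context] = counts.get(l.context, 0) + 1
    for lab in ("intergenic", "intronic", "exonic"):
        n = counts.get(lab, 0)
        print(f"  {lab:<11} {n:>4} ({100 * n / len(kept):.0f} %)")

    kept = annotate_repeat_associations(kept, repeats, window=100)
    n_assoc = sum(1 for l in kept if l.repeat_assoc is not None)
    print(f"embedded in / within 100 bp of a repeat: {n_assoc} "
          f"({100 * n_assoc / len(kept):.0f} %)")

    cov = coverage_summary(repeats, sizes)
    res = repeat_class_enrichment(kept, cov, "LTR")
    # the test's denominator is all filtered loci; the share of the
    # repeat-embedded subset is the alternative ratio, reported alongside
    subset_pct = 100 * res.k / n_assoc if n_assoc else 0.0
    print(f"LTR embedding test: k={res.k}, n={res.n}, null p={res.p:.4f}, "
          f"p={res.p_value:.3g} ({subset_pct:.0f} % of the {n_assoc} "
          f"repeat-embedded loci)")

    groups = group_identical_matures(kept)
    print(f"duplicated-mature groups: sizes {[g.size for g in groups]}")

    table = chromosome_distribution(kept)
    table.to_csv(RESULTS / "mirna_chromosome_distribution.tsv", sep="\t")

    payload = {
        "candidates": len(candidates),
        "passing": len(kept),
        "context_counts": counts,
        "repeat_associated": n_assoc,
        "ltr_enrichment": res.to_dict(),
        "group_sizes": [g.size for g in groups],
    }
    (RESULTS / "mirna_context.json").write_text(json.dumps(payload, indent=2))
    print(f"summary written to {RESULTS / 'mirna_context.json'}")


if __name__ == "__main__":
    main()
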