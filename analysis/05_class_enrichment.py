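#!/usr/bin/env python
"""Test whether lost genes are depleted in disease / essential / lethal
genes and enriched in dispensable ones (two-sided Fisher's exact test,
each loss group against the no-loss background).

Writes results/analysis/enrichment.tsv and prints the directions.
"""

import os

import pandas as pd

from geneloss.enrichment import class_enrichment
from geneloss.io import read_class_table

OUT = "results/analysis"


def main() -> None:
    dollo = pd.read_csv(os.path.join(OUT, "dollo.tsv"), sep="\t")
    partition = {"no_loss": set(), "single_lineage": set(), "multi_lineage": set()}
    for rec in dollo.to_dict("records"):
        n = rec["n_independent_lineages"]
        key = "no_loss" if n == 0 else ("single_lineage" if n == 1 else "multi_lineage")
        partition[key].add(rec["gene"])
    classes = read_class_table("results/cohort/classes.tsv")
    result = class_enrichment(
        partition, classes, set(dollo["gene"]), pooled=True
    )
    result.to_csv(os.path.join(OUT, "enrichment.tsv"), sep="\t", index=False)
    for rec in result[result["group"] == "any_loss"].to_dict("records"):
        print(
            f"{rec['class']:12s} {rec['direction']:9s} OR = {rec['odds_ratio']:.3f}, "
            f"p = {rec['p_value']:.3g} "
            f"({rec['pct_group']:.1f}% of lost vs {rec['pct_background']:.1f}% of no-loss)"
        )


if __name__ == "__main__":
    main()
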