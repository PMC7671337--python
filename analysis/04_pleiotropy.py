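#!/usr/bin/env python
"""Quantify pleiotropy: propagate single-gene knockout phenotype
annotations up the ontology, count distinct terms per gene at levels
2/3/4, and compare no-loss vs single-lineage vs multi-lineage genes with
two-sided Wilcoxon rank-sum tests.

Writes pheno_counts.tsv and pleiotropy_tests.tsv under results/analysis/.
"""

import os

import pandas as pd

from geneloss.io import read_annotation_table
from geneloss.ontology import read_obo
from geneloss.phenotypes import gene_level_counts, pleiotropy_compare

OUT = "results/analysis"


def main() -> None:
    dag = read_obo("results/cohort/pheno.obo")
    rows = read_annotation_table("results/cohort/annotations.tsv")
    counts = gene_level_counts(rows, dag)
    counts.to_csv(os.path.join(OUT, "pheno_counts.tsv"), sep="\t")

    dollo = pd.read_csv(os.path.join(OUT, "dollo.tsv"), sep="\t")
    group_of = {
        0: "no_loss", 1: "single_lineage",
    }
    genes_by_group: dict[str, list[str]] = {"no_loss": [], "single_lineage": [], "multi_lineage": []}
    for rec in dollo.to_dict("records"):
        name = group_of.get(rec["n_independent_lineages"], "multi_lineage")
        genes_by_group[name].append(rec["gene"])

    frames = []
    for level in (2, 3, 4):
        groups = {
            name: [
                int(counts.loc[g, f"level{level}_count"])
                for g in genes
                if g in counts.index
            ]
            for name, genes in genes_by_group.items()
        }
        groups = {k: v for k, v in groups.items() if v}
        df = pleiotropy_compare(groups)
        df.insert(0, "level", level)
        frames.append(df)
    tests = pd.concat(frames, ignore_index=True)
    tests.to_csv(os.path.join(OUT, "pleiotropy_tests.tsv"), sep="\t", index=False)
    for rec in tests.to_dict("records"):
        direction = "<" if rec["rank_biserial"] < 0 else ">"
        print(
            f"level {rec['level']}: {rec['group_a']} {direction} {rec['group_b']} "
            f"(p = {rec['p_value']:.3g}, n = {rec['n_a']}/{rec['n_b']})"
        )


if __name__ == "__main__":
    main()
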