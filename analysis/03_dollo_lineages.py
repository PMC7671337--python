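#!/usr/bin/env python
"""Map loss calls onto the species tree with Dollo parsimony and count
independent loss lineages per gene.

Reads results/analysis/loss_matrix.tsv + results/cohort/tree.nwk, writes
results/analysis/dollo.tsv and prints the single- vs multi-lineage split.
"""

import os

import pandas as pd

from geneloss.dollo import histories_from_matrix, partition_by_lineage_count
from geneloss.io import read_newick

OUT = "results/analysis"


def main() -> None:
    tree = read_newick("results/cohort/tree.nwk")
    matrix = pd.read_csv(
        os.path.join(OUT, "loss_matrix.tsv"), sep="\t", index_col=0,
        keep_default_na=False,  # 'NA' is a real value, not a missing cell
    )
    histories = histories_from_matrix(tree, matrix)
    parts = partition_by_lineage_count(histories)
    pd.DataFrame(
        [
            {
                "gene": h.gene_id,
                "n_independent_lineages": h.n_independent_lineages,
                "event_branches": ";".join(sorted(h.event_branches)),
            }
            for h in histories
        ]
    ).sort_values("gene").to_csv(os.path.join(OUT, "dollo.tsv"), sep="\t", index=False)
    n_lost = len(parts["single_lineage"]) + len(parts["multi_lineage"])
    print(
        f"{n_lost} genes lost; {len(parts['multi_lineage'])} "
        f"({100 * len(parts['multi_lineage']) / max(n_lost, 1):.1f}%) lost repeatedly "
        "in independent lineages"
    )


if __name__ == "__main__":
    main()
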