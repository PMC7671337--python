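#!/usr/bin/env python
"""Scan every gene x species alignment for inactivating mutations and
apply the loss rule (<60% reading frame intact, >=20% exons hit; >=2
events for single-exon genes, every principal isoform affected).

Reads results/cohort/, writes mutations.tsv, exon_status.tsv,
loss_calls.tsv and loss_matrix.tsv under results/analysis/.
"""

import os

import pandas as pd

from geneloss.classify import build_loss_matrix
from geneloss.io import read_gene_models
from geneloss.maf import read_contexts, read_exon_alignments
from geneloss.models import Thresholds
from geneloss.pipeline import scan_and_classify

COHORT = "results/cohort"
OUT = "results/analysis"


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    models = read_gene_models(os.path.join(COHORT, "genes.bed"))
    aln_dir = os.path.join(COHORT, "aln")
    species = sorted(f[:-4] for f in os.listdir(aln_dir) if f.endswith(".maf"))
    alns = {
        sp: read_exon_alignments(os.path.join(aln_dir, f"{sp}.maf"), models)
        for sp in species
    }
    ctxs = {
        sp: read_contexts(os.path.join(aln_dir, f"{sp}.contexts.tsv"))
        for sp in species
    }
    mutations, calls, status = scan_and_classify(models, alns, ctxs, Thresholds())
    mutations.to_csv(os.path.join(OUT, "mutations.tsv"), sep="\t", index=False)
    status.to_csv(os.path.join(OUT, "exon_status.tsv"), sep="\t", index=False)
    matrix = build_loss_matrix(calls)
    matrix.to_csv(os.path.join(OUT, "loss_matrix.tsv"), sep="\t")
    calls_df = pd.DataFrame(
        [
            {
                "gene": c.gene_id, "species": c.species, "verdict": c.verdict.value,
                "best_intact_fraction": round(c.best_intact_fraction, 6),
                "exon_fraction_hit": round(c.exon_fraction_hit, 6),
                "n_mutations": c.n_mutations, "rationale": c.rationale.value,
            }
            for c in calls
        ]
    ).sort_values(["gene", "species"])
    calls_df.to_csv(os.path.join(OUT, "loss_calls.tsv"), sep="\t", index=False)
    by_kind = mutations["kind"].value_counts()
    print(f"{len(mutations)} inactivating mutations in {len(species)} species:")
    for kind, n in by_kind.items():
        print(f"  {kind:18s} {n}")
    print(f"{(matrix == 'LOST').to_numpy().sum()} lost gene x species pairs")


if __name__ == "__main__":
    main()
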