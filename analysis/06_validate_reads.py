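#!/usr/bin/env python
"""Validate a sample of detected point mutations against simulated
unassembled reads: extract the 50 bp flanked mutant and ancestral
contexts, assign reads by best gap-aware alignment, and apply the
confirmation rule (>=5 supporting reads, zero ancestral support).

Writes results/analysis/validation.tsv.
"""

import os
import sys

import numpy as np
import pandas as pd

from geneloss.io import read_fasta, read_gene_models
from geneloss.maf import read_exon_alignments
from geneloss.models import MutationKind, Thresholds
from geneloss.pipeline import mutations_from_frame
from geneloss.simulate import emit_reads
from geneloss.validate import extract_context, tally_support

COHORT = "results/cohort"
OUT = "results/analysis"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2
N_CHECKS = 60
POINT_KINDS = {
    MutationKind.PREMATURE_STOP, MutationKind.FRAMESHIFT_DEL,
    MutationKind.FRAMESHIFT_INS, MutationKind.SPLICE_DONOR,
    MutationKind.SPLICE_ACCEPTOR,
}


def main() -> None:
    rng = np.random.default_rng(SEED)
    thresholds = Thresholds()
    models = read_gene_models(os.path.join(COHORT, "genes.bed"))
    by_tx = {m.transcript_id: m for m in models}
    mutations = pd.read_csv(os.path.join(OUT, "mutations.tsv"), sep="\t")
    muts_by_key = mutations_from_frame(mutations)

    aln_cache: dict[str, dict] = {}
    genome_cache: dict[str, dict] = {}
    rows = []
    for (sp, tx), muts in sorted(muts_by_key.items()):
        if len(rows) >= N_CHECKS:
            break
        if sp not in aln_cache:
            alns = read_exon_alignments(
                os.path.join(COHORT, "aln", f"{sp}.maf"), models
            )
            aln_cache[sp] = {(a.transcript_id, a.exon_index): a for a in alns}
            genome_cache[sp] = read_fasta(os.path.join(COHORT, "query", f"{sp}.fa"))
        for m in muts:
            if m.kind not in POINT_KINDS or len(rows) >= N_CHECKS:
                continue
            aln = aln_cache[sp].get((tx, m.exon_index))
            if aln is None:
                continue
            pair = extract_context(m, aln, by_tx[tx], genome_cache[sp],
                                   thresholds.flank_bp)
            reads = emit_reads(rng, pair, coverage=10, read_length=80)
            verdict = tally_support(pair, reads, thresholds)
            rows.append(
                {
                    "gene": by_tx[tx].gene_id, "species": sp, "kind": m.kind.value,
                    "exon_index": m.exon_index, "codon_position": m.codon_position,
                    "n_supporting": verdict.n_supporting,
                    "n_ancestral": verdict.n_ancestral,
                    "status": verdict.status.value,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(OUT, "validation.tsv"), sep="\t", index=False)
    confirmed = int((df["status"] == "CONFIRMED").sum())
    print(f"{confirmed}/{len(df)} sampled mutations confirmed by reads")


if __name__ == "__main__":
    main()
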