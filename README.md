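# geneloss

Detection and comparative characterization of gene losses in mammalian
genomes.

During evolution, a lineage can fix mutations that destroy a protein-coding
gene: premature stop codons, frameshifting insertions and deletions, splice
site disruptions (deviation from the donor `GT`/`GC` or acceptor `AG`
dinucleotides), and deletions of whole exons or genes. Screening pairwise
coding-exon alignments between a reference genome and many query genomes for
such mutations identifies "natural knockouts" — species that live without a
gene that is essential or disease-associated in the reference species. This
package implements that screen and the comparative analyses built on it, for
researchers in molecular evolution and comparative genomics.

## What it computes

1. **Mutation scan** (`geneloss.scan`) — all five classes of inactivating
   mutation per gene × species, reading codons in the reference frame across
   exon junctions, and distinguishing assembly gaps (runs of `N`, missing
   data) from real exon deletions.
2. **Loss classification** (`geneloss.classify`) — a gene is called lost in
   a species when every principal isoform has less than 60% of its reading
   frame intact **and** at least 20% of its exons carry inactivating
   mutations (single-exon genes: at least two mutations). The intact
   fraction is `max((f−1)/L, (L−l)/L)` for first/last affected codon `f`/`l`
   on an `L`-codon CDS.
3. **Dollo parsimony** (`geneloss.dollo`) — an intact gene is never regained
   once lost, so shared losses in sister species are assigned to their
   common ancestor; the number of event branches is the number of
   independent loss lineages.
4. **Pleiotropy** (`geneloss.phenotypes`) — single-gene knockout phenotype
   annotations are propagated up the phenotype ontology; the number of
   distinct terms per gene at ontology levels 2/3/4 is compared between
   no-loss, single-lineage and multi-lineage genes with two-sided Wilcoxon
   rank-sum tests.
5. **Class enrichment** (`geneloss.enrichment`) — two-sided Fisher's exact
   tests (exact rational arithmetic) of disease / essential / lethal /
   dispensable gene-class membership in each loss group vs the no-loss
   background.
6. **Read validation** (`geneloss.validate`) — a candidate mutation is
   confirmed when at least five unassembled reads support the mutant allele
   (gap-aware alignment against the ±50 bp mutant and ancestral contexts)
   and none supports the ancestral allele.
7. **Synthetic cohorts** (`geneloss.simulate`) — a ledgered generator
   produces genomes, alignments, trees, ontologies, class tables and reads
   with known ground truth, so every stage is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the study on a synthetic cohort
(1500 genes × 8 species, seeded):

```bash
python analysis/01_simulate_cohort.py 1
python analysis/02_scan_and_classify.py
python analysis/03_dollo_lineages.py
python analysis/04_pleiotropy.py
python analysis/05_class_enrichment.py
python analysis/06_validate_reads.py
```

Output (seed 1):

```
ledger: 1500 genes, 323 lost in >=1 species (21.5%), 170 lost in >=2 independent lineages (52.6% of losses)
2944 inactivating mutations in 8 species:
  PREMATURE_STOP     1020
  FRAMESHIFT_DEL     663
  ...
323 genes lost; 170 (52.6%) lost repeatedly in independent lineages
level 3: no_loss > single_lineage (p = 1.91e-20, n = 1050/110)
DISEASE      DEPLETED  OR = 0.632, p = 0.031 (9.3% of lost vs 13.9% of no-loss)
ESSENTIAL    DEPLETED  OR = 0.164, p = 6.83e-07 (1.5% of lost vs 8.8% of no-loss)
LETHAL       DEPLETED  OR = 0.367, p = 1.91e-05 (5.6% of lost vs 13.8% of no-loss)
DISPENSABLE  ENRICHED  OR = 2.544, p = 2.21e-08 (23.5% of lost vs 10.8% of no-loss)
60/60 sampled mutations confirmed by reads
```

Reading this: about a fifth of genes are lost in at least one species and
half of those losses happened convergently in independent lineages. Lost
genes affect significantly fewer distinct knockout phenotypes per gene
(lower pleiotropy), are depleted in disease-associated, cell-essential and
prenatally lethal genes, and are enriched in genes whose knockout shows no
abnormal phenotype — the odds ratios and p-values quantify each contrast
against the no-loss background. Every sampled mutation is supported by at
least five reads with no ancestral-allele support.

The same stages are available as a CLI (`geneloss simulate / scan /
classify / dollo / pleiotropy / enrich / validate-reads / run-all`).

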