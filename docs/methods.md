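# Methods

This note documents the models, rules and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one reasonable convention
exists.

## Coordinate and orientation conventions

All genomic intervals are 0-based half-open (BED convention); GTF input is
converted on read. Exons of a transcript are stored in transcription order,
and every downstream computation operates in transcription orientation —
minus-strand sequences are reverse-complemented exactly once, at ingestion.
The CDS is taken to include the terminal stop codon, so the concatenated
coding length is divisible by 3 and the phase of exon *i* equals the
cumulative coding length of earlier exons mod 3.

## Mutation scan

Five mutation classes are detected per gene × species from per-exon
pairwise alignments:

* **Premature stops.** Codons are read on the spliced CDS in the
  *reference* frame: alignment columns where the reference is gapped
  (insertions) are excised, and any codon whose query side contains a gap
  or an `N` is skipped. A query codon `TAA`/`TAG`/`TGA` before the terminal
  codon is one event. Reading in the reference frame rather than the
  shifted query frame keeps frameshifts and stop codons as independent
  events — a frameshift would otherwise cascade into many spurious
  downstream "stops". The alternative (query-frame reading) was considered
  and rejected for that reason.
* **Frameshifts.** Each maximal gap run in either alignment row whose
  length is not a multiple of 3 is one event (query-side gap: deletion;
  reference-side gap: insertion), anchored at the reference codon
  overlapping the run start (insertions: the codon of the base immediately
  5′ of the run). Compensatory indel pairs count separately: there is no
  net-frame forgiveness window, because each indel is an observed lesion.
  An adjacent insertion and deletion are two runs (they live on different
  rows).
* **Splice sites.** A donor dinucleotide outside {`GT`, `GC`} or an
  acceptor other than `AG` (case-insensitive) is one event, anchored at the
  codon of the adjacent exon-boundary base. Dinucleotides containing `N`
  are missing data. Single-exon genes have no splice sites.
* **Exon and gene deletions.** An exon with no alignment is resolved
  through the query sequence spanning its syntenic interval: an `N`-run of
  at least `min_gap_run` (default 10; the length is a package choice, not a
  fixed community value) means assembly gap → missing data, no event; a
  gap-free interval means real deletion → one event covering the exon's
  codon span; an unresolvable interval is conservatively missing. If every
  exon is deleted, a single whole-gene deletion replaces the per-exon
  events.

Output is deterministically sorted by (exon, codon, kind).

## Loss classification

The intact reading-frame fraction of an isoform is
`max((f−1)/L, (L−l)/L)`, where `L` is the codon count and `f`/`l` the
first/last codon touched by any mutation (exon deletions contribute their
full codon span; splice events their boundary codon). This terminal-flank
definition measures the largest undamaged terminal stretch of the reading
frame; the alternative — the largest clean stretch between *any* two
consecutive mutations — is available as `rule="max_stretch"` but is not the
default, since an internal fragment bounded by two lesions is unlikely to
yield a functional protein.

An isoform is lost when intact fraction `< 0.60` (strict) **and** the
fraction of non-missing exons carrying mutations is `≥ 0.20`; single-exon
isoforms require `≥ 2` mutations. Missing exons contribute neither
mutations nor to the exon denominator — assembly gaps are not evidence. A
gene is lost only if **every** principal isoform is lost (one intact
isoform preserves gene function; this is the conservative aggregation). A
gene whose exons are all missing in a species yields no verdict (`NA`) and
is excluded from all denominators.

## Dollo parsimony

An intact gene is treated as a complex character that is never regained.
Loss events are placed on the maximal branches whose subtended non-missing
leaves are all lost (with at least one lost leaf); the event count is the
number of independent loss lineages. Missing (NA) leaves are transparent:
they never break an ancestral grouping, so adding an NA leaf can only
merge, never split, lineages. On multifurcations an event may sit on any
child branch; grouping at the multifurcating node requires all children to
qualify. The root branch is a legal event in the inference (all species
lost), although the simulator never draws it, because a gene ascertained as
present in the reference annotation cannot be lost in every species. With
missing data the *minimal* placement need not be unique; the maximal-subtree
choice is the most ancestral (most parsimonious-in-age) of the minimal
placements.

## Phenotype ontology and pleiotropy

Only phenotypes observed in single-gene (genotype arity 1) knockouts are
used. Direct annotations are closed under `is_a` ancestry; the root never
counts. A term's level is 1 + the length of its *shortest* path to the root
(root = level 1), so a term in a diamond counts at exactly one level —
this matches how ontology browsers render levels. Pleiotropy is the number
of distinct closed terms at levels 2, 3 and 4. The bookkeeping branch
'normal phenotype' (level 2) and its child 'no abnormal phenotype detected'
(level 3) are excluded from counting by default: counting "no phenotype" as
a phenotype would invert the measure. Genes with no countable annotation
are dropped from the distributions (configurable to keep them as zeros).

Group comparisons use the two-sided Wilcoxon rank-sum test: the exact
distribution when both groups have ≤ 25 observations and the pooled sample
has no ties, otherwise the normal approximation with midranks, tie-corrected
variance and continuity correction. The rank-biserial correlation
`2U/(n₁n₂) − 1` is reported as effect direction.

## Class enrichment

Gene classes (disease, essential, lethal, dispensable) are input data;
lethal and dispensable labels can alternatively be derived from the closed
annotations ('prenatal lethality' in the closure; only normal-branch
annotations, respectively). Each loss group is compared to the no-loss
background with a two-sided Fisher's exact test under the probability-mass
rule: the p-value is the sum of hypergeometric probabilities (margins
fixed) of all tables no more probable than the observed one. Because
two-sided Fisher definitions vary, this rule is stated explicitly and the
test is computed in exact rational arithmetic for tables up to N = 2000
(beyond that, the identical rule via scipy's floating-point
implementation, where big-integer enumeration would be needlessly slow).
The sample odds ratio `ad/bc` is reported (`inf` when `bc = 0` with
`ad > 0`, undefined when both vanish). No multiple-testing correction is
applied by default — the comparisons are reported per test — with Holm
adjustment available as a flag.

## Read validation

For each point-like mutation (stop, frameshift, splice) the query assembly
sequence 50 bp up- and downstream of the mutant allele is extracted, along
with the same locus carrying the ancestral allele. Each read (both
orientations) is aligned gap-aware (edlib, infix mode) to both contexts; it
must span the variant position and stay within 2 edits per 100 aligned bp
(approximating high-identity read mapping; configurable). A read counts
for the context it matches strictly better; ties and failures are
uninformative, as are reads matching neither context (possible
contaminants). A mutation is confirmed by ≥ 5 supporting reads with zero
ancestral-allele support; zero informative reads yield no verdict. Flanks
truncated by contig edges are shortened and flagged. Whole-exon and
whole-gene deletions are not read-validated — the rule is designed for
small lesions with a local ancestral context.

## Synthetic-data generator

The generator emulates the study design at desk scale. Defaults (chosen
once as the standing conditions): 8 query species on a random bifurcating
tree; per-branch first-loss probability 0.018 and convergent re-loss
probability 0.25, which give ≈ 22% of genes lost in at least one species
and ≈ 55% of lost genes lost in ≥ 2 independent lineages; genes of 1–20
coding exons with CDS 300–3000 bp; a neutral background of synonymous
substitutions (0.01/codon) and in-frame indels (0.02/exon) on intact
orthologs; assembly gaps hiding 2% of exons and whole-genome holes hiding
2% of gene × species pairs; shifted-Poisson pleiotropy counts (1 + Pois(3)
retained vs 1 + Pois(1.5) lost); class base rates 15% disease, 9%
essential (matching the reported 1734/19425 proportion), 15% lethal, 10%
dispensable with class-by-loss odds ratios 0.4 / 0.3 / 0.4 / 2.5; reads of
80 bp at 10× with error rate 0.

Loss histories are drawn per branch as Bernoulli events in preorder
(descendants of a loss are excluded; branch lengths are deliberately not
used, keeping expectations in closed form). For each lost lineage the
generator plans a mutation set that provably satisfies the loss rule by
rejection sampling (placements re-drawn until < 60% of the codon axis is
intact and ≥ 20% of exons are hit), with collision margins so injected
events never merge into one alignment feature; species in the same lineage
share the plan, mirroring shared inactivating mutations in sister species.
Neutral edits are restricted to synonymous swaps and length-3k indels and
provably cannot create an inactivating event. Dispensable genes are
annotated only with 'no abnormal phenotype detected'; lethal genes
additionally carry 'prenatal lethality'; random ontology terms never
descend from the class-defining lethality term, so class derivation from
annotations is uncontaminated. Every drawn quantity is recorded in a truth
ledger that fully determines the expected output of each stage.

What the generator does **not** emulate: realistic substitution models (no
GTR/codon models), alignment error, paralogous alignment, evolutionary
splice-site shifts, exon–intron structure change, realistic read-error
profiles, or branch-length-dependent loss rates. Passing tests therefore
demonstrate the correctness of the detection/classification logic under
clean and moderately incomplete data, not robustness to alignment artifacts
— on real alignments those artifacts are handled upstream by the alignment
and filtering pipeline that produces the exon alignments this package
ingests.

The generator emits one principal isoform per gene; the multi-isoform
aggregation rule is exercised by dedicated classifier tests instead.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on cohorts
of 1000–1500 genes × 8 species, exhaustive Dollo checks on all rooted
topologies with ≤ 5 leaves (all 3ⁿ state vectors) plus seeded random
8-leaf trees, all 635,375 Fisher tables with N ≤ 60 against an independent
rational oracle, and 200-replicate calibration/power studies — sizes at
which every check completes in minutes on one CPU. All randomness flows
through seeded `numpy.random.Generator` instances; identical seeds give
byte-identical cohort files and pipeline outputs, and the pipeline itself
is a pure function of its inputs.

## Known limitations

* The loss thresholds are applied to whatever isoform set is provided; no
  attempt is made to rescue genes via unannotated isoforms.
* The Dollo event count on a sparse species sample is a lower bound on the
  true number of independent losses.
* Pleiotropy counts inherit the annotation depth of the ontology used;
  levels beyond 4 are not compared.
* The read validator assumes the ancestral allele is reconstructable from
  the reference; it does not model polymorphism within the query species.
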