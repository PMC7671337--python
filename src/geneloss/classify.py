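"""Per-gene loss classification from mutation lists.

A gene is called lost in a species when every principal isoform
independently satisfies the loss rule: less than 60% of the reading frame
remains intact AND at least 20% of the (non-missing) exons carry
inactivating mutations; single-exon isoforms instead require at least two
inactivating mutations.  A completely deleted gene is lost outright.
Exons hidden by assembly gaps contribute neither mutations nor to the
exon denominator, and a transcript whose exons are all missing yields no
verdict at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .models import (
    ExonStatus,
    GeneModel,
    InactivatingMutation,
    LossCall,
    LossRationale,
    LossVerdict,
    MutationKind,
    Thresholds,
)

IntactRule = Literal["terminal_flanks", "max_stretch"]


def intact_fraction(
    model: GeneModel,
    mutations: Sequence[InactivatingMutation],
    rule: IntactRule = "terminal_flanks",
) -> float:
    """Maximum fraction of the CDS codon axis left undamaged.

    Under the default terminal-flank rule this is the larger of the clean
    5' and 3' segments: ``max((f-1)/L, (L-l)/L)`` with f/l the first/last
    affected codon (1-based) and L the codon count.  The ``max_stretch``
    alternative takes the largest clean stretch between ANY two
    consecutive mutations.  No mutations give 1.0.
    """
    if not mutations:
        return 1.0
    L = model.n_codons
    spans = sorted(
        (m.codon_first, m.codon_last)
        for m in mutations
        if m.codon_first is not None
    )
    if not spans:
        return 1.0
    f = min(s for s, _ in spans)
    l = max(e for _, e in spans)
    if rule == "terminal_flanks":
        return max((f - 1) / L, (L - l) / L)
    best = max(f - 1, L - l)
    prev_end = spans[0][1]
    for s, e in spans[1:]:
        best = max(best, s - prev_end - 1)
        prev_end = max(prev_end, e)
    return best / L


@dataclass(frozen=True)
class IsoformAssessment:
    transcript_id: str
    verdict: LossVerdict
    intact_fraction: float
    exon_fraction_hit: float
    n_mutations: int
    rationale: LossRationale


def assess_isoform(
    model: GeneModel,
    mutations: Sequence[InactivatingMutation],
    exon_status: Sequence[ExonStatus],
    thresholds: Thresholds = Thresholds(),
    rule: IntactRule = "terminal_flanks",
) -> IsoformAssessment:
    """Apply the loss rule to a single isoform."""
    n_assessable = sum(1 for s in exon_status if s is not ExonStatus.MISSING)
    if n_assessable == 0:
        return IsoformAssessment(
            model.transcript_id, LossVerdict.NO_DATA, 1.0, 0.0, 0, LossRationale.NO_DATA
        )
    if any(m.kind is MutationKind.GENE_DELETED for m in mutations):
        return IsoformAssessment(
            model.transcript_id, LossVerdict.LOST, 0.0, 1.0, len(mutations),
            LossRationale.GENE_DELETED,
        )
    frac = intact_fraction(model, mutations, rule=rule)
    hit_exons = {m.exon_index for m in mutations if m.exon_index is not None}
    exon_frac = len(hit_exons) / n_assessable
    if model.n_exons == 1:
        lost = len(mutations) >= thresholds.min_mutations_single_exon
        rationale = LossRationale.SINGLE_EXON_RULE if lost else LossRationale.INTACT
    else:
        lost = (
            frac < thresholds.max_intact_fraction
            and exon_frac >= thresholds.min_exon_fraction_hit
        )
        rationale = LossRationale.FRAME_AND_EXON_RULE if lost else LossRationale.INTACT
    return IsoformAssessment(
        model.transcript_id,
        LossVerdict.LOST if lost else LossVerdict.INTACT,
        frac,
        exon_frac,
        len(mutations),
        rationale,
    )


def classify_gene(
    models: Sequence[GeneModel],
    mutations_by_tx: dict[str, Sequence[InactivatingMutation]],
    status_by_tx: dict[str, Sequence[ExonStatus]],
    species: str,
    thresholds: Thresholds = Thresholds(),
    rule: IntactRule = "terminal_flanks",
) -> LossCall:
    """Aggregate the principal isoforms of one gene into a loss call.

    The gene is lost only if EVERY assessable principal isoform is lost
    (one intact isoform preserves gene function).  ``best_intact_fraction``
    is the maximum over isoforms, and the exon fraction / mutation count
    come from the isoform attaining it.
    """
    principals = [m for m in models if m.is_principal] or list(models)
    gene_id = principals[0].gene_id
    assessments = [
        assess_isoform(
            m,
            mutations_by_tx.get(m.transcript_id, ()),
            status_by_tx.get(m.transcript_id, ()),
            thresholds,
            rule,
        )
        for m in principals
    ]
    assessable = [a for a in assessments if a.verdict is not LossVerdict.NO_DATA]
    if not assessable:
        return LossCall(gene_id, species, LossVerdict.NO_DATA,
                        rationale=LossRationale.NO_DATA)
    best = max(assessable, key=lambda a: a.intact_fraction)
    lost = all(a.verdict is LossVerdict.LOST for a in assessable)
    return LossCall(
        gene_id=gene_id,
        species=species,
        verdict=LossVerdict.LOST if lost else LossVerdict.INTACT,
        best_intact_fraction=best.intact_fraction,
        exon_fraction_hit=best.exon_fraction_hit,
        n_mutations=best.n_mutations,
        rationale=best.rationale if lost else LossRationale.INTACT,
    )


def build_loss_matrix(calls: Sequence[LossCall]) -> pd.DataFrame:
    """Gene x species matrix with values LOST / INTACT / NA, sorted both ways."""
    genes = sorted({c.gene_id for c in calls})
    species = sorted({c.species for c in calls})
    matrix = pd.DataFrame("NA", index=genes, columns=species)
    for call in calls:
        value = "NA" if call.verdict is LossVerdict.NO_DATA else call.verdict.value
        matrix.loc[call.gene_id, call.species] = value
    matrix.index.name = "gene"
    return matrix
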