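"""Detection of gene-inactivating mutations in per-exon pairwise alignments.

Five mutation classes are recognised: premature stop codons, frameshifting
insertions and deletions (gap runs whose length is not a multiple of 3),
splice-site disruptions (query donor dinucleotide outside GT/GC, acceptor
outside AG), deleted exons, and whole-gene deletions.  Unaligned exons
whose query interval is an assembly gap (a run of Ns) are treated as
missing data and never yield a mutation.

Framing convention after frameshifts: codons are always read in the
REFERENCE frame.  Alignment columns where the reference is gapped
(insertions) are excised before codon reading, and any codon whose query
side contains a gap or an N is skipped for stop calling, so a frameshift
and the stop codons it would create in the shifted query frame are never
conflated — each event is reported once, independently.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional, Sequence

from .models import (
    ExonAlignment,
    ExonStatus,
    GeneModel,
    InactivatingMutation,
    MutationKind,
    Thresholds,
)

_STOPS = {"TAA", "TAG", "TGA"}
_DONOR_OK = {"gt", "gc"}


def _gap_runs(text: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' as (start_column, length)."""
    return [(m.start(), m.end() - m.start()) for m in re.finditer(r"-+", text)]


def detect_frameshifts(
    alignments: Sequence[ExonAlignment], model: GeneModel
) -> list[InactivatingMutation]:
    """Frameshifting indels: per-row maximal gap runs with length % 3 != 0.

    A gap run in the query row is a deletion, in the reference row an
    insertion.  Adjacent insertion+deletion columns form two separate
    runs.  The reported codon is the reference codon overlapping the run
    start (for insertions, the codon of the reference base immediately
    5' of the inserted columns).
    """
    offsets = model.exon_cds_offsets()
    out: list[InactivatingMutation] = []
    for aln in alignments:
        if aln.status is not ExonStatus.ALIGNED:
            continue
        exon_off = offsets[aln.exon_index]
        # reference CDS offset reached *before* each column
        ref_off_before = []
        off = exon_off
        for ch in aln.ref_aln:
            ref_off_before.append(off)
            if ch != "-":
                off += 1
        for col, length in _gap_runs(aln.query_aln):
            if length % 3 == 0:
                continue
            start_off = ref_off_before[col]
            codon = start_off // 3 + 1
            out.append(
                InactivatingMutation(
                    kind=MutationKind.FRAMESHIFT_DEL,
                    exon_index=aln.exon_index,
                    codon_position=codon,
                    ref_allele=aln.ref_aln[col : col + length].upper(),
                    query_allele="",
                    indel_length=length,
                    codon_first=codon,
                    codon_last=(start_off + length - 1) // 3 + 1,
                )
            )
        for col, length in _gap_runs(aln.ref_aln):
            if length % 3 == 0:
                continue
            anchor = max(ref_off_before[col] - 1, 0)
            codon = anchor // 3 + 1
            out.append(
                InactivatingMutation(
                    kind=MutationKind.FRAMESHIFT_INS,
                    exon_index=aln.exon_index,
                    codon_position=codon,
                    ref_allele="",
                    query_allele=aln.query_aln[col : col + length].upper(),
                    indel_length=length,
                    codon_first=codon,
                    codon_last=codon,
                )
            )
    return out


def _spliced_query(alignments: Sequence[ExonAlignment], model: GeneModel):
    """Per-reference-CDS-position query and reference characters.

    Positions covered by non-ALIGNED exons hold None.  Columns where the
    reference is gapped (insertions) are excised, implementing the
    reference-frame reading convention.
    """
    offsets = model.exon_cds_offsets()
    q: list[Optional[str]] = [None] * model.cds_length
    r: list[Optional[str]] = [None] * model.cds_length
    for aln in alignments:
        if aln.status is not ExonStatus.ALIGNED:
            continue
        off = offsets[aln.exon_index]
        for rc, qc in zip(aln.ref_aln, aln.query_aln):
            if rc == "-":
                continue
            r[off] = rc.upper()
            q[off] = qc.upper()
            off += 1
    return r, q


def detect_premature_stops(
    alignments: Sequence[ExonAlignment], model: GeneModel
) -> list[InactivatingMutation]:
    """In-frame TAA/TAG/TGA in the query, excluding the natural terminal stop.

    Codons are read across exon junctions on the spliced CDS; codons with
    a query-side gap or N (or covered by an unaligned exon) are skipped.
    """
    ref_chars, qry_chars = _spliced_query(alignments, model)
    offsets = model.exon_cds_offsets()
    lengths = model.exon_lengths
    out: list[InactivatingMutation] = []
    n_codons = model.n_codons
    for c in range(n_codons - 1):  # terminal stop never reported
        triplet = qry_chars[3 * c : 3 * c + 3]
        if any(ch is None or ch == "-" or ch == "N" for ch in triplet):
            continue
        codon = "".join(triplet)
        if codon in _STOPS:
            ref_codon = "".join(ch or "?" for ch in ref_chars[3 * c : 3 * c + 3])
            if ref_codon == codon:
                continue  # reference itself encodes this stop; not a query event
            exon_index = next(
                i
                for i in range(model.n_exons)
                if offsets[i] <= 3 * c < offsets[i] + lengths[i]
            )
            out.append(
                InactivatingMutation(
                    kind=MutationKind.PREMATURE_STOP,
                    exon_index=exon_index,
                    codon_position=c + 1,
                    ref_allele=ref_codon,
                    query_allele=codon,
                    codon_first=c + 1,
                    codon_last=c + 1,
                )
            )
    return out


def detect_splice_mutations(
    alignments: Sequence[ExonAlignment], model: GeneModel
) -> list[InactivatingMutation]:
    """Donor dinucleotides outside {GT, GC} and acceptors != AG.

    Dinucleotides containing N are treated as missing data.  The mutation
    is anchored at the codon of the adjacent exon-boundary base.
    """
    if model.n_exons == 1:
        return []
    offsets = model.exon_cds_offsets()
    lengths = model.exon_lengths
    last = model.n_exons - 1
    out: list[InactivatingMutation] = []
    for aln in alignments:
        if aln.status is not ExonStatus.ALIGNED:
            continue
        i = aln.exon_index
        donor = aln.query_donor_dinuc
        if i < last and donor is not None and "n" not in donor.lower():
            if donor.lower() not in _DONOR_OK:
                codon = (offsets[i] + lengths[i] - 1) // 3 + 1
                out.append(
                    InactivatingMutation(
                        kind=MutationKind.SPLICE_DONOR,
                        exon_index=i,
                        codon_position=codon,
                        ref_allele="gt",
                        query_allele=donor.lower(),
                        codon_first=codon,
                        codon_last=codon,
                    )
                )
        acceptor = aln.query_acceptor_dinuc
        if i > 0 and acceptor is not None and "n" not in acceptor.lower():
            if acceptor.lower() != "ag":
                codon = offsets[i] // 3 + 1
                out.append(
                    InactivatingMutation(
                        kind=MutationKind.SPLICE_ACCEPTOR,
                        exon_index=i,
                        codon_position=codon,
                        ref_allele="ag",
                        query_allele=acceptor.lower(),
                        codon_first=codon,
                        codon_last=codon,
                    )
                )
    return out


def classify_exon_status(
    model: GeneModel,
    exon_index: int,
    query_context: Optional[str],
    min_gap_run: int,
) -> ExonStatus:
    """DELETED vs MISSING for an exon with no alignment.

    The query interval spanning the syntenic position of the exon decides:
    an N-run of at least ``min_gap_run`` means the assembly has a gap
    there (missing data), a gap-free interval means the exon is really
    deleted.  An unresolvable interval is conservatively missing.
    """
    if query_context is None:
        return ExonStatus.MISSING
    if re.search(rf"[Nn]{{{min_gap_run},}}", query_context):
        return ExonStatus.MISSING
    return ExonStatus.DELETED


def scan_gene(
    model: GeneModel,
    alignments: Iterable[ExonAlignment],
    contexts: Optional[dict[tuple[str, int], Optional[str]]] = None,
    thresholds: Thresholds = Thresholds(),
) -> tuple[list[InactivatingMutation], list[ExonStatus]]:
    """Full mutation scan of one transcript in one species.

    Returns the sorted mutation list and the per-exon status vector.
    Exons absent from ``alignments`` are resolved through ``contexts``
    (assembly gap vs real deletion); if every exon is deleted a single
    whole-gene deletion is reported instead of per-exon events.
    """
    alignments = [a for a in alignments if a.transcript_id == model.transcript_id]
    by_exon = {a.exon_index: a for a in alignments}
    contexts = contexts or {}

    status: list[ExonStatus] = []
    for i in range(model.n_exons):
        aln = by_exon.get(i)
        if aln is not None and aln.status is ExonStatus.ALIGNED:
            status.append(ExonStatus.ALIGNED)
        else:
            ctx = aln.query_context if aln is not None else contexts.get(
                (model.transcript_id, i)
            )
            status.append(
                classify_exon_status(model, i, ctx, thresholds.min_gap_run)
            )

    aligned = [a for a in alignments if a.status is ExonStatus.ALIGNED]
    mutations = (
        detect_premature_stops(aligned, model)
        + detect_frameshifts(aligned, model)
        + detect_splice_mutations(aligned, model)
    )

    if all(s is ExonStatus.DELETED for s in status):
        mutations = [
            InactivatingMutation(
                kind=MutationKind.GENE_DELETED,
                exon_index=None,
                codon_position=None,
                codon_first=1,
                codon_last=model.n_codons,
            )
        ]
    else:
        for i, s in enumerate(status):
            if s is ExonStatus.DELETED:
                first, last = model.exon_codon_span(i)
                mutations.append(
                    InactivatingMutation(
                        kind=MutationKind.EXON_DELETED,
                        exon_index=i,
                        codon_position=None,
                        codon_first=first,
                        codon_last=last,
                    )
                )
    return sorted(mutations), status
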