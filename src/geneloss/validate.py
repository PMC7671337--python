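"""Validation of candidate inactivating mutations against unassembled reads.

For each mutation the 50 bp of query assembly sequence on either side is
extracted twice: once around the assembly (mutant) allele, and once with
the ancestral non-inactivating allele substituted in.  Every read is
assigned to the context it aligns to strictly better (banded gap-aware
alignment; the read must span the variant position), and a mutation is
confirmed only when at least five reads support the mutant allele while
none supports the ancestral one.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
from Bio import SeqIO
from Bio.Seq import Seq

from .models import (
    ExonAlignment,
    GeneModel,
    InactivatingMutation,
    MutationKind,
    Thresholds,
)


class ValidationStatus(str, enum.Enum):
    CONFIRMED = "CONFIRMED"
    UNCONFIRMED = "UNCONFIRMED"
    NO_DATA = "NO_DATA"


@dataclass(frozen=True)
class ContextPair:
    """Mutant/ancestral flanked contexts with the variant span in each."""

    mutant: str
    ancestral: str
    mutant_var: tuple[int, int]     # 0-based half-open span within `mutant`
    ancestral_var: tuple[int, int]
    truncated: bool = False


@dataclass(frozen=True)
class ValidationVerdict:
    n_supporting: int
    n_ancestral: int
    n_uninformative: int
    status: ValidationStatus


def _query_offsets(aln: ExonAlignment) -> tuple[list[int], list[int]]:
    """Per-column (ref offset within exon, query offset within exon segment)."""
    r_off, q_off = [], []
    r = q = 0
    for rc, qc in zip(aln.ref_aln, aln.query_aln):
        r_off.append(r)
        q_off.append(q)
        if rc != "-":
            r += 1
        if qc != "-":
            q += 1
    return r_off, q_off


def _variant_query_span(
    mutation: InactivatingMutation,
    aln: ExonAlignment,
    model: GeneModel,
) -> tuple[int, int, str]:
    """Query-contig span of the mutant allele and the ancestral allele string."""
    assert aln.query_start is not None
    exon_off = model.exon_cds_offsets()[mutation.exon_index]
    r_off, q_off = _query_offsets(aln)
    q_len = len(aln.query_aln.replace("-", ""))
    kind = mutation.kind
    if kind is MutationKind.SPLICE_DONOR:
        start = aln.query_start + q_len
        return start, start + 2, mutation.ref_allele
    if kind is MutationKind.SPLICE_ACCEPTOR:
        start = aln.query_start - 2
        return start, start + 2, mutation.ref_allele
    if kind is MutationKind.PREMATURE_STOP:
        lo = 3 * (mutation.codon_position - 1) - exon_off
        hi = lo + 3
        cols = [
            i
            for i, (rc, ro) in enumerate(zip(aln.ref_aln, r_off))
            if rc != "-" and lo <= ro < hi
        ]
        q_start = q_off[cols[0]]
        last = cols[-1]
        q_end = q_off[last] + (0 if aln.query_aln[last] == "-" else 1)
        return aln.query_start + q_start, aln.query_start + q_end, mutation.ref_allele
    if kind in (MutationKind.FRAMESHIFT_DEL, MutationKind.FRAMESHIFT_INS):
        row = aln.query_aln if kind is MutationKind.FRAMESHIFT_DEL else aln.ref_aln
        col = 0
        while col < len(row):
            if row[col] != "-":
                col += 1
                continue
            run_start = col
            while col < len(row) and row[col] == "-":
                col += 1
            length = col - run_start
            codon = (
                (exon_off + r_off[run_start]) // 3 + 1
                if kind is MutationKind.FRAMESHIFT_DEL
                else max(exon_off + r_off[run_start] - 1, 0) // 3 + 1
            )
            if length == mutation.indel_length and codon == mutation.codon_position:
                q_start = q_off[run_start]
                if kind is MutationKind.FRAMESHIFT_DEL:
                    # deletion: empty mutant span at the junction
                    return (
                        aln.query_start + q_start,
                        aln.query_start + q_start,
                        mutation.ref_allele,
                    )
                return (
                    aln.query_start + q_start,
                    aln.query_start + q_start + length,
                    "",
                )
        raise ValueError("mutation's gap run not found in its alignment")
    raise ValueError(f"read validation does not apply to {kind.value}")


def extract_context(
    mutation: InactivatingMutation,
    aln: ExonAlignment,
    model: GeneModel,
    query_genome: dict[str, str],
    flank_bp: int = 50,
) -> ContextPair:
    """Mutant and ancestral contexts: assembly allele +- ``flank_bp``.

    Flanks truncated by a contig edge are shortened and flagged.
    """
    contig = query_genome[aln.query_chrom].upper()
    var_start, var_end, ancestral_allele = _variant_query_span(mutation, aln, model)
    left = max(var_start - flank_bp, 0)
    right = min(var_end + flank_bp, len(contig))
    truncated = (var_start - flank_bp) < 0 or (var_end + flank_bp) > len(contig)
    mutant = contig[left:right]
    ancestral = (
        contig[left:var_start] + ancestral_allele.upper() + contig[var_end:right]
    )
    m_var = (var_start - left, var_end - left)
    a_var = (var_start - left, var_start - left + len(ancestral_allele))
    return ContextPair(
        mutant=mutant,
        ancestral=ancestral,
        mutant_var=m_var,
        ancestral_var=a_var,
        truncated=truncated,
    )


def _best_alignment(read: str, context: str) -> tuple[int, list[tuple[int, int]]]:
    res = edlib.align(read, context, mode="HW", task="locations")
    return res["editDistance"], [tuple(loc) for loc in res["locations"]]


def _assign(
    read: str,
    context: str,
    var: tuple[int, int],
    max_edits: int,
) -> Optional[int]:
    """Edit distance of the read against one context, or None if it fails
    the identity threshold or does not span the variant position."""
    best: Optional[int] = None
    for seq in (read, str(Seq(read).reverse_complement())):
        dist, locations = _best_alignment(seq, context)
        if dist < 0 or dist > max_edits:
            continue
        lo_need = max(var[0] - 1, 0)
        hi_need = min(var[1], len(context) - 1)
        if any(start <= lo_need and end >= hi_need for start, end in locations):
            best = dist if best is None else min(best, dist)
    return best


def tally_support(
    contexts: ContextPair,
    reads: Iterable[str],
    thresholds: Thresholds = Thresholds(),
    max_edits_per_100: float = 2.0,
) -> ValidationVerdict:
    """Assign each read to the mutant or ancestral haplotype and rule.

    A read counts for the context it matches with strictly fewer
    mismatches+gaps (both orientations tried); equal scores, failed
    identity, or not spanning the variant make it uninformative.
    Confirmation requires >= ``min_supporting_reads`` mutant reads and no
    ancestral read; zero informative reads give NO_DATA.
    """
    n_sup = n_anc = n_unk = 0
    for read in reads:
        read = read.upper()
        max_edits = math.ceil(max_edits_per_100 * len(read) / 100.0)
        d_mut = _assign(read, contexts.mutant, contexts.mutant_var, max_edits)
        d_anc = _assign(read, contexts.ancestral, contexts.ancestral_var, max_edits)
        if d_mut is None and d_anc is None:
            n_unk += 1
        elif d_anc is None or (d_mut is not None and d_mut < d_anc):
            n_sup += 1
        elif d_mut is None or d_anc < d_mut:
            n_anc += 1
        else:
            n_unk += 1
    if n_sup + n_anc == 0:
        status = ValidationStatus.NO_DATA
    elif n_sup >= thresholds.min_supporting_reads and n_anc == 0:
        status = ValidationStatus.CONFIRMED
    else:
        status = ValidationStatus.UNCONFIRMED
    return ValidationVerdict(n_sup, n_anc, n_unk, status)


def load_reads(path: str) -> list[str]:
    """Read sequences from FASTA or FASTQ (by extension)."""
    fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(path, fmt)]


def write_reads_fastq(reads: Sequence[str], path: str) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")
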