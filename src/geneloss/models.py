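"""Core domain types shared by every stage of the gene-loss pipeline.

Coordinate convention: all genomic intervals are 0-based half-open (BED
convention).  Exons of a :class:`GeneModel` are stored in *transcription*
order, i.e. reversed relative to genomic sort for minus-strand genes, and
every downstream module works in transcription orientation; sequences are
reverse-complemented once, at ingestion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class ExonStatus(str, enum.Enum):
    ALIGNED = "ALIGNED"
    DELETED = "DELETED"
    MISSING = "MISSING"


class MutationKind(str, enum.Enum):
    PREMATURE_STOP = "PREMATURE_STOP"
    FRAMESHIFT_INS = "FRAMESHIFT_INS"
    FRAMESHIFT_DEL = "FRAMESHIFT_DEL"
    SPLICE_DONOR = "SPLICE_DONOR"
    SPLICE_ACCEPTOR = "SPLICE_ACCEPTOR"
    EXON_DELETED = "EXON_DELETED"
    GENE_DELETED = "GENE_DELETED"


#: sort rank used for the deterministic output ordering of mutation lists
_KIND_RANK = {k: i for i, k in enumerate(MutationKind)}


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding transcript: ordered coding exons of a gene.

    ``exons`` holds the coding portion only, as (start, end) 0-based
    half-open genomic intervals sorted in transcription order.  The CDS is
    taken to include the terminal stop codon, so the concatenated exon
    length must be divisible by 3.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    is_principal: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no coding exons")
        genomic = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(genomic, genomic[1:]):
            if e0 > s1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
        expect = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expect:
            raise ValueError(
                f"{self.transcript_id}: exons not in transcription order"
            )
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    @property
    def phase_per_exon(self) -> tuple[int, ...]:
        """Phase of each exon: cumulative coding length of preceding exons mod 3."""
        phases, cum = [], 0
        for ln in self.exon_lengths:
            phases.append(cum % 3)
            cum += ln
        return tuple(phases)

    def exon_cds_offsets(self) -> tuple[int, ...]:
        """0-based CDS offset of the first base of each exon."""
        offs, cum = [], 0
        for ln in self.exon_lengths:
            offs.append(cum)
            cum += ln
        return tuple(offs)

    def exon_codon_span(self, exon_index: int) -> tuple[int, int]:
        """1-based (first, last) codon overlapping the given exon."""
        off = self.exon_cds_offsets()[exon_index]
        ln = self.exon_lengths[exon_index]
        return off // 3 + 1, (off + ln - 1) // 3 + 1


@dataclass
class ExonAlignment:
    """Pairwise alignment of one reference coding exon to one query species.

    ``ref_aln``/``query_aln`` are same-length gapped strings when
    ``status == ALIGNED``; the ungapped ``ref_aln`` equals the reference
    exon sequence in transcription orientation.  ``query_donor_dinuc`` /
    ``query_acceptor_dinuc`` hold the query's intronic boundary
    dinucleotides and are ``None`` exactly where the exon is terminal on
    that side.  ``query_start`` is the 0-based offset of the aligned query
    segment on ``query_chrom`` (transcription orientation), used to place
    mutations on the query assembly for read validation.
    """

    gene_id: str
    transcript_id: str
    exon_index: int
    species: str
    status: ExonStatus
    ref_aln: str = ""
    query_aln: str = ""
    query_donor_dinuc: Optional[str] = None
    query_acceptor_dinuc: Optional[str] = None
    query_chrom: Optional[str] = None
    query_start: Optional[int] = None
    query_context: Optional[str] = None  # query interval of an unaligned exon

    def __post_init__(self) -> None:
        if self.status is ExonStatus.ALIGNED:
            if len(self.ref_aln) != len(self.query_aln):
                raise ValueError(
                    f"{self.transcript_id} exon {self.exon_index} ({self.species}): "
                    "aligned rows differ in length"
                )
            if not self.ref_aln:
                raise ValueError("empty ALIGNED alignment")


@dataclass(frozen=True, order=True)
class InactivatingMutation:
    """A typed gene-inactivating event on one transcript in one species.

    ``codon_position`` is 1-based on the reference CDS codon axis; splice
    events carry the codon at the adjacent exon boundary, exon/gene
    deletions carry ``None`` and instead expose their damaged codon span
    through ``codon_span``.
    """

    sort_index: tuple = field(init=False, repr=False)
    kind: MutationKind = MutationKind.PREMATURE_STOP
    exon_index: Optional[int] = None
    codon_position: Optional[int] = None
    ref_allele: str = ""
    query_allele: str = ""
    indel_length: int = 0
    codon_first: Optional[int] = None  # first affected codon (1-based)
    codon_last: Optional[int] = None   # last affected codon (1-based)

    def __post_init__(self) -> None:
        if self.kind in (MutationKind.FRAMESHIFT_INS, MutationKind.FRAMESHIFT_DEL):
            if self.indel_length < 1 or self.indel_length % 3 == 0:
                raise ValueError("frameshift indel_length must be >=1 and not divisible by 3")
        object.__setattr__(
            self,
            "sort_index",
            (
                self.exon_index if self.exon_index is not None else -1,
                self.codon_position if self.codon_position is not None else
                (self.codon_first if self.codon_first is not None else 0),
                _KIND_RANK[self.kind],
            ),
        )

    @property
    def key(self) -> tuple:
        """Identity used when comparing detected vs injected mutations."""
        return (self.kind.value, self.exon_index, self.codon_position)


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds of the loss classifier and read validator."""

    max_intact_fraction: float = 0.60
    min_exon_fraction_hit: float = 0.20
    min_mutations_single_exon: int = 2
    min_supporting_reads: int = 5
    flank_bp: int = 50
    min_gap_run: int = 10

    def __post_init__(self) -> None:
        for name in (
            "max_intact_fraction",
            "min_exon_fraction_hit",
            "min_mutations_single_exon",
            "min_supporting_reads",
            "flank_bp",
            "min_gap_run",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


class LossVerdict(str, enum.Enum):
    LOST = "LOST"
    INTACT = "INTACT"
    NO_DATA = "NO_DATA"


class LossRationale(str, enum.Enum):
    FRAME_AND_EXON_RULE = "FRAME_AND_EXON_RULE"
    SINGLE_EXON_RULE = "SINGLE_EXON_RULE"
    GENE_DELETED = "GENE_DELETED"
    INTACT = "INTACT"
    NO_DATA = "NO_DATA"


@dataclass(frozen=True)
class LossCall:
    """Per gene x species verdict with the quantities behind it."""

    gene_id: str
    species: str
    verdict: LossVerdict
    best_intact_fraction: float = 1.0
    exon_fraction_hit: float = 0.0
    n_mutations: int = 0
    rationale: LossRationale = LossRationale.INTACT

    @property
    def lost(self) -> bool:
        return self.verdict is LossVerdict.LOST


@dataclass
class LossHistory:
    """Dollo-parsimony loss history of one gene on the species tree.

    ``event_branches`` holds the branches (named by their child clade: the
    leaf name, or the sorted comma-joined leaf names of the internal node)
    on which an inactivation event is placed.
    """

    gene_id: str
    leaf_states: dict[str, LossVerdict]
    event_branches: frozenset[str]

    @property
    def n_independent_lineages(self) -> int:
        return len(self.event_branches)
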