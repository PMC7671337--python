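"""Shared fixtures and hand-rolled helpers for building tiny test inputs."""

from __future__ import annotations

import numpy as np
import pytest

from geneloss.models import ExonAlignment, ExonStatus, GeneModel


def make_cds(n_codons: int, body_codon: str = "GAA", stop: str = "TAA") -> str:
    """ATG + repeated body codons + terminal stop; n_codons total."""
    return "ATG" + body_codon * (n_codons - 2) + stop


def single_exon_model(n_codons: int = 100, gene: str = "gX") -> GeneModel:
    return GeneModel(
        gene_id=gene,
        transcript_id=f"{gene}.t1",
        chrom="chr1",
        strand="+",
        exons=((100, 100 + 3 * n_codons),),
    )


def multi_exon_model(exon_lengths: list[int], gene: str = "gX") -> GeneModel:
    """Plus-strand model with the given exon lengths, introns of 50 bp."""
    exons, pos = [], 100
    for ln in exon_lengths:
        exons.append((pos, pos + ln))
        pos += ln + 50
    return GeneModel(
        gene_id=gene,
        transcript_id=f"{gene}.t1",
        chrom="chr1",
        strand="+",
        exons=tuple(exons),
    )


def split_cds(cds: str, exon_lengths: list[int]) -> list[str]:
    out, pos = [], 0
    for ln in exon_lengths:
        out.append(cds[pos : pos + ln])
        pos += ln
    return out


def aligned(
    model: GeneModel,
    exon_index: int,
    ref_aln: str,
    query_aln: str,
    species: str = "spA",
    donor: str | None = "gt",
    acceptor: str | None = "ag",
    query_start: int = 0,
    query_chrom: str = "qchr",
) -> ExonAlignment:
    last = model.n_exons - 1
    return ExonAlignment(
        gene_id=model.gene_id,
        transcript_id=model.transcript_id,
        exon_index=exon_index,
        species=species,
        status=ExonStatus.ALIGNED,
        ref_aln=ref_aln,
        query_aln=query_aln,
        query_donor_dinuc=donor if exon_index < last else None,
        query_acceptor_dinuc=acceptor if exon_index > 0 else None,
        query_chrom=query_chrom,
        query_start=query_start,
    )


def identity_alignments(
    model: GeneModel, cds: str, species: str = "spA"
) -> list[ExonAlignment]:
    """Perfect query == reference alignments for every exon."""
    parts = split_cds(cds, list(model.exon_lengths))
    return [
        aligned(model, i, seq, seq, species=species)
        for i, seq in enumerate(parts)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
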