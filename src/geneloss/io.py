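"""Readers and writers for gene models, sequences, trees and gene tables.

Formats: BED12 / GTF (CDS features) for gene models, FASTA for sequences,
Newick for the species tree, tab-separated tables (header row, ``#``
comments, UTF-8) for gene classes, phenotype annotations and ortholog
maps.  Everything is converted on read to the package-wide convention:
0-based half-open coordinates, exons in transcription order.
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable, Optional

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .models import GeneModel


class ParseError(ValueError):
    """Raised for malformed records in any supported input format."""


# ---------------------------------------------------------------------------
# gene models


def _model_from_blocks(
    gene_id: str,
    transcript_id: str,
    chrom: str,
    strand: str,
    blocks: list[tuple[int, int]],
    is_principal: bool,
    skipped: Optional[list],
) -> Optional[GeneModel]:
    blocks = sorted(blocks)
    if strand == "-":
        blocks = blocks[::-1]
    try:
        return GeneModel(
            gene_id=gene_id,
            transcript_id=transcript_id,
            chrom=chrom,
            strand=strand,
            exons=tuple(blocks),
            is_principal=is_principal,
        )
    except ValueError as exc:
        warnings.warn(f"skipping {transcript_id}: {exc}")
        if skipped is not None:
            skipped.append((transcript_id, str(exc)))
        return None


def _parse_bed12_line(line: str, lineno: int):
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ParseError(f"line {lineno}: BED12 needs 12 columns, got {len(fields)}")
    try:
        chrom = fields[0]
        start = int(fields[1])
        name = fields[3]
        strand = fields[5]
        thick_start, thick_end = int(fields[6]), int(fields[7])
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ParseError(f"line {lineno}: blockCount disagrees with block lists")
    # intersect each block with the thick (coding) region
    coding = []
    for off, size in zip(starts, sizes):
        s, e = start + off, start + off + size
        s, e = max(s, thick_start), min(e, thick_end)
        if e > s:
            coding.append((s, e))
    if "|" in name:
        gene_id, transcript_id = name.split("|", 1)
    else:
        gene_id = transcript_id = name
    return gene_id, transcript_id, chrom, strand, coding


def read_bed12(path: str, skipped: Optional[list] = None) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            gene_id, tx_id, chrom, strand, coding = _parse_bed12_line(line, lineno)
            if not coding:
                warnings.warn(f"skipping {tx_id}: no coding blocks")
                if skipped is not None:
                    skipped.append((tx_id, "no coding blocks"))
                continue
            model = _model_from_blocks(gene_id, tx_id, chrom, strand, coding, True, skipped)
            if model is not None:
                models.append(model)
    return models


def read_gtf(path: str, skipped: Optional[list] = None) -> list[GeneModel]:
    """Read CDS (plus stop_codon) features of a GTF file into gene models."""
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "stop_codon"):
            continue
        tx = feat.attributes.get("transcript_id", [feat.id])[0]
        gene = feat.attributes.get("gene_id", [tx])[0]
        tags = feat.attributes.get("tag", [])
        rec = per_tx.setdefault(
            tx,
            {"gene": gene, "chrom": feat.seqid, "strand": feat.strand,
             "blocks": [], "principal": False},
        )
        rec["blocks"].append((feat.start - 1, feat.end))  # GTF is 1-based inclusive
        rec["principal"] = rec["principal"] or any("appris_principal" in t for t in tags)
    models = []
    for tx, rec in sorted(per_tx.items()):
        # merge touching CDS/stop_codon intervals into exon blocks
        merged: list[list[int]] = []
        for s, e in sorted(rec["blocks"]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        principal = rec["principal"] or not any(r["principal"] for r in per_tx.values())
        model = _model_from_blocks(
            rec["gene"], tx, rec["chrom"], rec["strand"],
            [tuple(b) for b in merged], principal, skipped,
        )
        if model is not None:
            models.append(model)
    return models


def read_gene_models(path: str, skipped: Optional[list] = None) -> list[GeneModel]:
    """Read gene models from BED12 or GTF, dispatching on file extension."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".gtf", ".gff"):
        return read_gtf(path, skipped=skipped)
    return read_bed12(path, skipped=skipped)


def write_bed12(models: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for m in models:
            blocks = sorted(m.exons)
            start, end = blocks[0][0], blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in blocks)
            offsets = ",".join(str(s - start) for s, _ in blocks)
            fh.write(
                "\t".join(
                    [
                        m.chrom, str(start), str(end), f"{m.gene_id}|{m.transcript_id}",
                        "0", m.strand, str(start), str(end), "0",
                        str(len(blocks)), sizes, offsets,
                    ]
                )
                + "\n"
            )


def cds_sequence(model: GeneModel, genome: dict[str, str]) -> str:
    """Spliced CDS of a model in transcription orientation (uppercase)."""
    chrom_seq = genome[model.chrom]
    parts = []
    for s, e in model.exons:
        seq = chrom_seq[s:e]
        if model.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        parts.append(seq)
    return "".join(parts).upper()


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# trees


def read_newick(path: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=path, schema="newick", rooting="force-rooted")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ParseError("duplicate leaf labels in tree")
    return tree


def parse_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ParseError("duplicate leaf labels in tree")
    return tree


def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# tabular inputs


def read_table(path: str) -> pd.DataFrame:
    """Tab-separated table with a header row and '#' comment lines."""
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_class_table(path: str) -> dict[str, set[str]]:
    """gene -> set of class labels (DISEASE/ESSENTIAL/LETHAL/DISPENSABLE)."""
    df = read_table(path)
    out: dict[str, set[str]] = {}
    for gene, label in zip(df["gene"], df["class"]):
        out.setdefault(gene, set()).add(label)
    return out


def read_annotation_table(path: str) -> list[tuple[str, str, int]]:
    """Rows of (gene, phenotype term, genotype arity)."""
    df = read_table(path)
    return [
        (g, t, int(a))
        for g, t, a in zip(df["gene"], df["term"], df["genotype_arity"])
    ]


def read_ortholog_map(path: str) -> dict[str, str]:
    df = read_table(path)
    return dict(zip(df["source_gene"], df["target_gene"]))
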