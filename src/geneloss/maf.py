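"""Minimal MAF (multiple alignment format) block I/O for exon alignments.

Each block holds the reference row and exactly one query-species row; a
multi-species MAF is split by species on read.  Blocks produced by this
package carry a ``meta=`` key on the ``a`` line
(``tx:<transcript>;exon:<i>;donor:<nn|.>;acceptor:<nn|.>``) that pins the
block to a coding exon and records the query's intronic splice
dinucleotides, which plain MAF cannot express.  Blocks without the tag
are mapped to exons by coordinate intersection and trimmed to the exon
boundaries.

A sidecar "contexts" table (transcript, exon_index, query interval
sequence or ``.`` for unresolvable) describes the query sequence under
exons that did not align, so that downstream code can separate assembly
gaps from real deletions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io import ParseError
from .models import ExonAlignment, ExonStatus, GeneModel


@dataclass
class MafRow:
    src: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def chrom(self) -> str:
        return self.src.split(".", 1)[1] if "." in self.src else self.src

    def forward_interval(self) -> tuple[int, int]:
        """0-based half-open interval on the forward strand of the source."""
        if self.strand == "+":
            return self.start, self.start + self.size
        return self.src_size - self.start - self.size, self.src_size - self.start


@dataclass
class MafBlock:
    rows: list[MafRow]
    meta: dict = field(default_factory=dict)


def _format_meta(meta: dict) -> str:
    parts = [f"{k}:{meta[k]}" for k in ("tx", "exon", "donor", "acceptor") if k in meta]
    return ";".join(parts)


def _parse_meta(tag: str) -> dict:
    meta: dict = {}
    for part in tag.split(";"):
        if not part:
            continue
        key, _, val = part.partition(":")
        meta[key] = val
    if "exon" in meta:
        meta["exon"] = int(meta["exon"])
    return meta


def write_maf(blocks: Iterable[MafBlock], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        for block in blocks:
            a_line = "a score=0.0"
            if block.meta:
                a_line += f" meta={_format_meta(block.meta)}"
            fh.write(a_line + "\n")
            for row in block.rows:
                fh.write(
                    f"s {row.src} {row.start} {row.size} {row.strand} "
                    f"{row.src_size} {row.text}\n"
                )
            fh.write("\n")


def read_maf(path: str) -> list[MafBlock]:
    blocks: list[MafBlock] = []
    current: Optional[MafBlock] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("a"):
                current = MafBlock(rows=[])
                for token in line.split()[1:]:
                    key, _, val = token.partition("=")
                    if key == "meta":
                        current.meta = _parse_meta(val)
                blocks.append(current)
            elif line.startswith("s "):
                if current is None:
                    raise ParseError(f"line {lineno}: s line outside a block")
                fields = line.split()
                if len(fields) != 7:
                    raise ParseError(f"line {lineno}: s line needs 7 fields")
                row = MafRow(
                    src=fields[1],
                    start=int(fields[2]),
                    size=int(fields[3]),
                    strand=fields[4],
                    src_size=int(fields[5]),
                    text=fields[6],
                )
                if len(row.text.replace("-", "")) != row.size:
                    raise ParseError(
                        f"line {lineno}: ungapped length != size for {row.src}"
                    )
                current.rows.append(row)
    for block in blocks:
        lengths = {len(r.text) for r in block.rows}
        if len(lengths) > 1:
            raise ParseError("rows of one block differ in alignment length")
    return blocks


def _dinuc_or_none(value: Optional[str]) -> Optional[str]:
    if value in (None, "", "."):
        return None
    return value


def _locate_exon(models_by_chrom: dict, row: MafRow) -> Optional[tuple[GeneModel, int]]:
    start, end = row.forward_interval()
    for model in models_by_chrom.get(row.chrom, ()):
        for i, (es, ee) in enumerate(model.exons):
            if start < ee and es < end:
                return model, i
    return None


def _trim_to_exon(ref_row: MafRow, qry_row: MafRow, exon: tuple[int, int]) -> tuple[str, str]:
    """Keep alignment columns whose reference coordinate falls inside the exon.

    Only forward-strand reference rows are supported for untagged blocks.
    """
    if ref_row.strand != "+":
        raise ParseError("untagged minus-strand reference blocks are not supported")
    pos = ref_row.start
    ref_out, qry_out = [], []
    for rc, qc in zip(ref_row.text, qry_row.text):
        inside = exon[0] <= pos < exon[1]
        if rc != "-":
            if inside:
                ref_out.append(rc)
                qry_out.append(qc)
            pos += 1
        elif inside and pos > exon[0]:
            ref_out.append(rc)
            qry_out.append(qc)
    return "".join(ref_out), "".join(qry_out)


def read_exon_alignments(
    path: str,
    models: list[GeneModel],
    ref_name: str = "ref",
) -> list[ExonAlignment]:
    """Read a MAF file into per-(exon x species) alignment records."""
    by_tx = {m.transcript_id: m for m in models}
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)

    out: list[ExonAlignment] = []
    for block in read_maf(path):
        ref_rows = [r for r in block.rows if r.species == ref_name]
        qry_rows = [r for r in block.rows if r.species != ref_name]
        if not ref_rows or not qry_rows:
            raise ParseError("block lacks a reference or query row")
        ref_row = ref_rows[0]
        for qry_row in qry_rows:
            if "tx" in block.meta:
                model = by_tx.get(block.meta["tx"])
                if model is None:
                    raise ParseError(f"unknown transcript {block.meta['tx']} in MAF meta")
                exon_index = block.meta["exon"]
                ref_aln, qry_aln = ref_row.text, qry_row.text
            else:
                hit = _locate_exon(by_chrom, ref_row)
                if hit is None:
                    continue
                model, exon_index = hit
                ref_aln, qry_aln = _trim_to_exon(ref_row, qry_row, model.exons[exon_index])
                if not ref_aln:
                    continue
            last = model.n_exons - 1
            out.append(
                ExonAlignment(
                    gene_id=model.gene_id,
                    transcript_id=model.transcript_id,
                    exon_index=exon_index,
                    species=qry_row.species,
                    status=ExonStatus.ALIGNED,
                    ref_aln=ref_aln,
                    query_aln=qry_aln,
                    query_donor_dinuc=(
                        _dinuc_or_none(block.meta.get("donor")) if exon_index < last else None
                    ),
                    query_acceptor_dinuc=(
                        _dinuc_or_none(block.meta.get("acceptor")) if exon_index > 0 else None
                    ),
                    query_chrom=qry_row.chrom,
                    query_start=qry_row.forward_interval()[0],
                )
            )
    return out


# ---------------------------------------------------------------------------
# sidecar contexts for unaligned exons


def write_contexts(contexts: dict[tuple[str, int], Optional[str]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\texon_index\tquery_interval\n")
        for (tx, exon_index), seq in sorted(contexts.items()):
            fh.write(f"{tx}\t{exon_index}\t{seq if seq is not None else '.'}\n")


def read_contexts(path: str) -> dict[tuple[str, int], Optional[str]]:
    out: dict[tuple[str, int], Optional[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("transcript_id"):
            raise ParseError("contexts table must start with its header row")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            tx, idx, seq = line.rstrip("\n").split("\t")
            out[(tx, int(idx))] = None if seq == "." else seq
    return out
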