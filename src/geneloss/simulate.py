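"""Ledgered synthetic cohorts: genomes, alignments, ontology, classes, reads.

The generator emulates the study design the analysis assumes: a species
tree on which genes are lost on branches (Dollo-consistent, optionally
convergently), reference gene models whose query alignments carry
injected inactivating mutations (enough to satisfy the loss rule) plus
neutral edits, assembly gaps and missing genomes at configurable rates,
a phenotype ontology with per-gene annotation counts drawn from
different distributions for lost and retained genes, gene-class labels
drawn with configurable class-by-loss odds ratios, and reads sampled
from mutant/ancestral haplotypes.  A TruthLedger records every drawn
quantity so each downstream module can be checked exactly.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimConfig.seed``; identical configs give bit-identical cohorts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import dendropy
import networkx as nx
import numpy as np

from .io import write_bed12, write_fasta, write_newick, parse_newick
from .maf import MafBlock, MafRow, write_contexts, write_maf
from .models import ExonAlignment, ExonStatus, GeneModel, MutationKind
from .ontology import OntologyDAG, write_obo
from .phenotypes import NO_ABNORMAL_PHENOTYPE, NORMAL_PHENOTYPE, PRENATAL_LETHALITY
from .validate import ContextPair

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_BAD_DONORS = ("aa", "ga", "tt", "ca")
_BAD_ACCEPTORS = ("gg", "ta", "cc")

_CODON_TO_AA: dict[str, str] = {}
_SYNONYMS: dict[str, list[str]] = {}


def _codon_tables() -> None:
    if _CODON_TO_AA:
        return
    from Bio.Seq import Seq

    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    for codon in codons:
        _CODON_TO_AA[codon] = str(Seq(codon).translate())
    for codon, aa in _CODON_TO_AA.items():
        if aa == "*":
            continue
        _SYNONYMS[codon] = [
            c for c, a in _CODON_TO_AA.items() if a == aa and c != codon
        ]


@dataclass
class SimConfig:
    """Study conditions of a synthetic cohort.

    Defaults are the package's standing conditions: 8 query species, a
    per-branch loss probability of 0.018 with convergent re-loss
    probability 0.25 (about a fifth of genes lost somewhere, slightly
    over half of them in more than one independent lineage), CDS of
    300-3000 bp over 1-20 exons, lost genes drawing fewer knockout
    phenotypes than retained ones, and class-by-loss odds ratios
    depleting disease / essential / lethal genes among losses while
    enriching dispensable ones.
    """

    seed: int = 0
    n_genes: int = 200
    n_species: int = 8
    newick: Optional[str] = None
    p_loss: float = 0.018
    p_convergent: float = 0.25
    mutation_mix: dict = field(
        default_factory=lambda: {
            "PREMATURE_STOP": 0.35,
            "FRAMESHIFT_DEL": 0.20,
            "FRAMESHIFT_INS": 0.10,
            "SPLICE": 0.20,
            "EXON_DELETED": 0.15,
        }
    )
    neutral_sub_rate: float = 0.01      # per eligible codon, intact pairs
    neutral_indel_rate: float = 0.02    # per exon, intact pairs
    assembly_gap_rate: float = 0.02     # per exon x species
    na_rate: float = 0.02               # per gene x species (genome hole)
    minus_strand_fraction: float = 0.3
    min_exons: int = 1
    max_exons: int = 20
    min_cds_bp: int = 300
    max_cds_bp: int = 3000
    # pleiotropy: counts = base + Poisson(lam), per loss status
    pleio_base_retained: int = 1
    pleio_lam_retained: float = 3.0
    pleio_base_lost: int = 1
    pleio_lam_lost: float = 1.5
    # gene classes
    class_base_rates: dict = field(
        default_factory=lambda: {
            "DISEASE": 0.15,
            "ESSENTIAL": 0.09,
            "LETHAL": 0.15,
            "DISPENSABLE": 0.10,
        }
    )
    class_loss_or: dict = field(
        default_factory=lambda: {
            "DISEASE": 0.4,
            "ESSENTIAL": 0.3,
            "LETHAL": 0.4,
            "DISPENSABLE": 2.5,
        }
    )
    digenic_noise_rows: int = 20
    # ontology shape: number of terms at levels 2..5
    terms_per_level: tuple = (8, 20, 60, 20)
    p_extra_parent: float = 0.15
    # reads
    read_length: int = 80
    read_coverage: float = 10.0
    read_error_rate: float = 0.0
    ancestral_read_fraction: float = 0.0

    def validate(self) -> None:
        for name in ("p_loss", "p_convergent", "assembly_gap_rate", "na_rate",
                     "minus_strand_fraction", "neutral_sub_rate",
                     "neutral_indel_rate", "read_error_rate",
                     "ancestral_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GeneTruth:
    """Everything drawn for one gene."""

    gene_id: str
    transcript_id: str
    event_branches: list[str]
    n_independent_lineages: int
    species_states: dict[str, str]            # LOST / INTACT / NA
    mutations: dict[str, list[list]]          # species -> [kind, exon, codon]
    classes: list[str]
    direct_terms: list[str]
    pleio_count: int


@dataclass
class TruthLedger:
    genes: dict[str, GeneTruth]

    def summary(self) -> dict:
        n_lost = sum(1 for g in self.genes.values() if g.n_independent_lineages >= 1)
        n_multi = sum(1 for g in self.genes.values() if g.n_independent_lineages >= 2)
        return {
            "n_genes": len(self.genes),
            "n_lost": n_lost,
            "n_single_lineage": n_lost - n_multi,
            "n_multi_lineage": n_multi,
        }

    def partition(self) -> dict[str, set[str]]:
        parts = {"no_loss": set(), "single_lineage": set(), "multi_lineage": set()}
        for gid, g in self.genes.items():
            n = g.n_independent_lineages
            key = "no_loss" if n == 0 else ("single_lineage" if n == 1 else "multi_lineage")
            parts[key].add(gid)
        return parts

    def to_json(self, path: str) -> None:
        payload = {gid: asdict(g) for gid, g in sorted(self.genes.items())}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "TruthLedger":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(genes={gid: GeneTruth(**g) for gid, g in payload.items()})


# ---------------------------------------------------------------------------
# tree and loss histories


def random_tree(rng: np.random.Generator, n_species: int) -> dendropy.Tree:
    """Random bifurcating topology by sequential random joins."""
    nodes = [f"sp{i + 1:02d}" for i in range(n_species)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return parse_newick(nodes[0] + ";")


def _branch_nodes(tree: dendropy.Tree) -> list[dendropy.Node]:
    """Candidate event branches, preorder, root excluded (the gene exists
    in the reference, so a root-branch loss cannot be ascertained)."""
    return [n for n in tree.preorder_node_iter() if n.parent_node is not None]


def _leaves_below(node: dendropy.Node) -> set[str]:
    return {leaf.taxon.label for leaf in node.leaf_iter()}


def simulate_loss_history(
    rng: np.random.Generator,
    tree: dendropy.Tree,
    p_loss: float,
    p_convergent: float,
) -> list[dendropy.Node]:
    """Dollo-consistent loss branches for one gene.

    Branches are visited in preorder; a branch not below an existing loss
    receives an event with probability ``p_loss`` (first event) or
    ``p_convergent`` (subsequent, independent lineages).  Descendants of
    an event never receive another.
    """
    events: list[dendropy.Node] = []
    lost_leaves: set[str] = set()
    for node in _branch_nodes(tree):
        leaves = _leaves_below(node)
        if leaves & lost_leaves:
            continue
        p = p_loss if not events else p_convergent
        if rng.random() < p:
            events.append(node)
            lost_leaves |= leaves
    return events


def _ledger_event_branches(tree: dendropy.Tree, states: dict[str, str]) -> list[str]:
    """Maximal all-LOST (NA-transparent) subtrees, by direct recursion.

    This is the generator's own bookkeeping of the expected Dollo
    events; the inference module is checked against a brute-force
    oracle separately.
    """
    from .dollo import clade_name  # label convention shared with inference

    events: list[str] = []

    def rec(node) -> tuple[bool, bool]:  # (has_lost, all_ok)
        if node.is_leaf():
            s = states.get(node.taxon.label, "NA")
            return s == "LOST", s != "INTACT"
        results = [rec(c) for c in node.child_nodes()]
        return any(h for h, _ in results), all(ok for _, ok in results)

    def collect(node, parent_ok: bool) -> None:
        has_lost, all_ok = rec(node)
        if has_lost and all_ok and not parent_ok:
            events.append(clade_name(node))
            return
        if not node.is_leaf():
            for c in node.child_nodes():
                collect(c, parent_ok=has_lost and all_ok)

    collect(tree.seed_node, parent_ok=False)
    return sorted(events)


# ---------------------------------------------------------------------------
# gene models and sequences


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random internal non-stop codons + a terminal stop codon."""
    _codon_tables()
    internal = [c for c in _CODON_TO_AA if _CODON_TO_AA[c] != "*" and c != "ATG"]
    idx = rng.integers(0, len(internal), n_codons - 2)
    body = "".join(internal[i] for i in idx)
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + body + stop


@dataclass
class _GeneLayout:
    model: GeneModel
    contig: str                  # reference contig sequence (forward strand)
    exon_seqs: list[str]         # transcription orientation, uppercase
    introns: list[str]           # introns between consecutive exons (txn orient)
    pad: int                     # flanking pad length


def _make_gene(
    rng: np.random.Generator, gene_no: int, config: SimConfig
) -> _GeneLayout:
    n_codons = int(rng.integers(config.min_cds_bp // 3, config.max_cds_bp // 3 + 1))
    cds = _random_cds(rng, n_codons)
    cds_len = 3 * n_codons
    max_exons = min(config.max_exons, max(config.min_exons, cds_len // 30))
    n_exons = int(rng.integers(config.min_exons, max_exons + 1))
    # split the CDS into exon lengths of at least 18 bp
    base = 18
    extra = cds_len - base * n_exons
    cuts = np.sort(rng.integers(0, extra + 1, n_exons - 1)) if n_exons > 1 else []
    shares = np.diff(np.concatenate([[0], cuts, [extra]])) if n_exons > 1 else [extra]
    lengths = [base + int(s) for s in shares]
    exon_seqs, pos = [], 0
    for ln in lengths:
        exon_seqs.append(cds[pos : pos + ln])
        pos += ln
    introns = [
        "gt" + _random_seq(rng, int(rng.integers(26, 60))).lower() + "ag"
        for _ in range(n_exons - 1)
    ]
    pad = 100
    parts = [_random_seq(rng, pad)]
    plus_exons = []
    offset = pad
    for i, seq in enumerate(exon_seqs):
        plus_exons.append((offset, offset + len(seq)))
        parts.append(seq)
        offset += len(seq)
        if i < n_exons - 1:
            parts.append(introns[i])
            offset += len(introns[i])
    parts.append(_random_seq(rng, pad))
    layout = "".join(parts)
    gene_id = f"g{gene_no:04d}"
    chrom = f"ctg_{gene_id}"
    strand = "-" if rng.random() < config.minus_strand_fraction else "+"
    if strand == "+":
        contig, exons = layout, plus_exons
    else:
        from Bio.Seq import Seq

        contig = str(Seq(layout).reverse_complement())
        total = len(layout)
        exons = [(total - e, total - s) for s, e in plus_exons]
    model = GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
    )
    return _GeneLayout(model=model, contig=contig, exon_seqs=exon_seqs,
                       introns=introns, pad=pad)


# ---------------------------------------------------------------------------
# mutation planning


@dataclass
class _ExonOps:
    subs: list = field(default_factory=list)      # (exon-rel offset, new bases)
    dels: list = field(default_factory=list)      # (exon-rel start, length)
    inss: list = field(default_factory=list)      # (exon-rel pos, bases)
    donor: Optional[str] = None
    acceptor: Optional[str] = None
    deleted: bool = False


@dataclass
class _Plan:
    ops: dict[int, _ExonOps]
    expected: list[tuple[str, Optional[int], Optional[int]]]  # (kind, exon, codon)


def _codon_candidates(model: GeneModel, exon: int) -> list[int]:
    """1-based codons lying fully inside the exon, excluding start and the
    two terminal codons (the natural stop is never an injection target)."""
    off = model.exon_cds_offsets()[exon]
    ln = model.exon_lengths[exon]
    first = off // 3 + 1 + (1 if off % 3 else 0)
    last = (off + ln) // 3
    return [c for c in range(max(first, 2), min(last, model.n_codons - 1) + 1)]


class _Collide:
    """Per-exon reference-interval registry with a safety margin, so
    injected events never merge into one alignment feature."""

    def __init__(self, margin: int = 4):
        self.margin = margin
        self.used: dict[int, list[tuple[int, int]]] = {}

    def ok(self, exon: int, start: int, end: int) -> bool:
        return all(
            end + self.margin <= s or e + self.margin <= start
            for s, e in self.used.get(exon, ())
        )

    def add(self, exon: int, start: int, end: int) -> None:
        self.used.setdefault(exon, []).append((start, end))


def _inject_one(
    rng: np.random.Generator,
    model: GeneModel,
    exon: int,
    kind: str,
    ops: dict[int, _ExonOps],
    collide: _Collide,
) -> Optional[tuple[str, Optional[int], Optional[int], tuple[int, int]]]:
    """Try to place one mutation of `kind` in `exon`; returns the expected
    (kind, exon, codon) key plus the affected codon span, or None."""
    off = model.exon_cds_offsets()[exon]
    ln = model.exon_lengths[exon]
    exon_ops = ops.setdefault(exon, _ExonOps())
    if kind == "EXON_DELETED":
        if exon_ops.subs or exon_ops.dels or exon_ops.inss or exon_ops.deleted:
            return None
        exon_ops.deleted = True
        first, last = model.exon_codon_span(exon)
        return "EXON_DELETED", exon, None, (first, last)
    if kind == "SPLICE":
        last_exon = model.n_exons - 1
        sides = []
        if exon < last_exon and exon_ops.donor is None:
            sides.append("donor")
        if exon > 0 and exon_ops.acceptor is None:
            sides.append("acceptor")
        if not sides:
            return None
        side = sides[int(rng.integers(0, len(sides)))]
        if side == "donor":
            exon_ops.donor = _BAD_DONORS[rng.integers(0, len(_BAD_DONORS))]
            codon = (off + ln - 1) // 3 + 1
            return "SPLICE_DONOR", exon, codon, (codon, codon)
        exon_ops.acceptor = _BAD_ACCEPTORS[rng.integers(0, len(_BAD_ACCEPTORS))]
        codon = off // 3 + 1
        return "SPLICE_ACCEPTOR", exon, codon, (codon, codon)
    if kind == "PREMATURE_STOP":
        candidates = [
            c
            for c in _codon_candidates(model, exon)
            if collide.ok(exon, 3 * (c - 1) - off, 3 * c - off)
        ]
        if not candidates:
            return None
        c = int(candidates[rng.integers(0, len(candidates))])
        s = 3 * (c - 1) - off
        exon_ops.subs.append((s, _STOPS[rng.integers(0, 3)]))
        collide.add(exon, s, s + 3)
        return "PREMATURE_STOP", exon, c, (c, c)
    if kind in ("FRAMESHIFT_DEL", "FRAMESHIFT_INS"):
        length = int(rng.choice([1, 2, 4], p=[0.45, 0.35, 0.20]))
        if kind == "FRAMESHIFT_INS":
            length = min(length, 2)
        lo, hi = 3, ln - 3 - length
        if hi <= lo:
            return None
        for _ in range(10):
            s = int(rng.integers(lo, hi + 1))
            if collide.ok(exon, s, s + max(length, 1)):
                break
        else:
            return None
        collide.add(exon, s, s + max(length, 1))
        if kind == "FRAMESHIFT_DEL":
            exon_ops.dels.append((s, length))
            codon = (off + s) // 3 + 1
            last_codon = (off + s + length - 1) // 3 + 1
            return kind, exon, codon, (codon, last_codon)
        exon_ops.inss.append((s, _random_seq(rng, length)))
        codon = (off + s - 1) // 3 + 1
        return kind, exon, codon, (codon, codon)
    raise ValueError(kind)


def _plan_loss_mutations(
    rng: np.random.Generator, model: GeneModel, config: SimConfig
) -> _Plan:
    """Mutation set satisfying the loss rule for one lineage of one gene.

    Placement is rejection-sampled: exons and positions are drawn until
    <60% of the codon axis is intact and >=20% of exons are hit (>=2
    events for single-exon genes).
    """
    mix = dict(config.mutation_mix)
    L = model.n_codons
    E = model.n_exons
    for attempt in range(300):
        ops: dict[int, _ExonOps] = {}
        collide = _Collide()
        expected = []
        spans = []
        if E == 1:
            kinds = ["PREMATURE_STOP", "FRAMESHIFT_DEL", "FRAMESHIFT_INS"]
            weights = np.array([mix.get(k, 0.1) for k in kinds], dtype=float)
            weights /= weights.sum()
            n_mut = 2 + (1 if rng.random() < 0.2 else 0)
            for _ in range(n_mut):
                kind = str(rng.choice(kinds, p=weights))
                placed = _inject_one(rng, model, 0, kind, ops, collide)
                if placed is None:
                    continue
                expected.append(placed[:3])
                spans.append(placed[3])
            if len(expected) >= 2:  # single-exon rule needs no intact check
                return _Plan(ops=ops, expected=sorted(expected, key=_expected_key))
            continue
        else:
            n_hit = min(E, max(2, math.ceil(0.2 * E)))
            hit = sorted(rng.choice(E, size=n_hit, replace=False).tolist())
            kinds = list(mix)
            weights = np.array([mix[k] for k in kinds], dtype=float)
            weights /= weights.sum()
            for exon in hit:
                kind = str(rng.choice(kinds, p=weights))
                placed = _inject_one(rng, model, exon, kind, ops, collide)
                if placed is None:  # fall back to a stop in this exon
                    placed = _inject_one(
                        rng, model, exon, "PREMATURE_STOP", ops, collide
                    )
                if placed is None:
                    break
                expected.append(placed[:3])
                spans.append(placed[3])
            if len(expected) < n_hit:
                continue
            if all(o.deleted for o in ops.values()) and len(ops) == E:
                expected = [("GENE_DELETED", None, None)]
                return _Plan(ops=ops, expected=expected)
        f = min(s for s, _ in spans)
        l = max(e for _, e in spans)
        # strict <60% intact on exact integers: 5*max(f-1, L-l) < 3*L
        if 5 * max(f - 1, L - l) < 3 * L:
            return _Plan(ops=ops, expected=sorted(expected, key=_expected_key))
    # deterministic fallback: stops bracketing the codon axis
    ops, collide, expected, spans = {}, _Collide(), [], []
    targets = [max(2, int(0.3 * L)), min(L - 1, int(0.7 * L))]
    offsets = model.exon_cds_offsets()
    for c in targets:
        exon = next(
            i for i in range(E) if offsets[i] <= 3 * (c - 1) < offsets[i] + model.exon_lengths[i]
        )
        cands = _codon_candidates(model, exon)
        c_use = min(cands, key=lambda x: abs(x - c)) if cands else None
        if c_use is None:
            continue
        off = offsets[exon]
        s = 3 * (c_use - 1) - off
        if not collide.ok(exon, s, s + 3):
            continue
        ops.setdefault(exon, _ExonOps()).subs.append((s, _STOPS[0]))
        collide.add(exon, s, s + 3)
        expected.append(("PREMATURE_STOP", exon, c_use))
        spans.append((c_use, c_use))
    needed = min(E, max(2, math.ceil(0.2 * E))) if E > 1 else 2
    for exon in range(E):
        if len({e[1] for e in expected}) >= needed and len(expected) >= 2:
            break
        if exon in {e[1] for e in expected}:
            continue
        placed = _inject_one(rng, model, exon, "PREMATURE_STOP", ops, collide)
        if placed is not None:
            expected.append(placed[:3])
            spans.append(placed[3])
    return _Plan(ops=ops, expected=sorted(expected, key=_expected_key))


def _expected_key(item) -> tuple:
    kind, exon, codon = item
    rank = {k.value: i for i, k in enumerate(MutationKind)}
    return (
        exon if exon is not None else -1,
        codon if codon is not None else 0,
        rank[kind],
    )


def _neutral_ops(
    rng: np.random.Generator, model: GeneModel, config: SimConfig
) -> dict[int, _ExonOps]:
    """Synonymous substitutions and length-3 indels; never inactivating."""
    _codon_tables()
    ops: dict[int, _ExonOps] = {}
    offsets = model.exon_cds_offsets()
    for exon in range(model.n_exons):
        exon_ops = _ExonOps()
        off, ln = offsets[exon], model.exon_lengths[exon]
        cands = _codon_candidates(model, exon)
        if cands and config.neutral_sub_rate > 0:
            n_sub = rng.binomial(len(cands), config.neutral_sub_rate)
            for c in rng.choice(cands, size=min(n_sub, len(cands)), replace=False):
                exon_ops.subs.append((3 * (int(c) - 1) - off, None))  # resolved later
        if config.neutral_indel_rate > 0 and ln > 30 and rng.random() < config.neutral_indel_rate:
            s = int(rng.integers(6, ln - 9))
            if rng.random() < 0.5:
                exon_ops.dels.append((s, 3))
            else:
                exon_ops.inss.append((s, _random_seq(rng, 3)))
        if exon_ops.subs or exon_ops.dels or exon_ops.inss:
            ops[exon] = exon_ops
    return ops


def _merge_neutral(
    rng: np.random.Generator,
    plan_ops: dict[int, _ExonOps],
    neutral: dict[int, _ExonOps],
    exon_seqs: list[str],
) -> dict[int, _ExonOps]:
    """Overlay neutral edits onto a (possibly empty) mutation plan,
    resolving synonymous substitutions and discarding clashes."""
    merged: dict[int, _ExonOps] = {}
    for exon, eops in plan_ops.items():
        merged[exon] = eops
    for exon, nops in neutral.items():
        base = merged.setdefault(exon, _ExonOps())
        if base.deleted:
            continue
        occupied = [(s, s + len(b)) for s, b in base.subs]
        occupied += [(s, s + k) for s, k in base.dels]
        occupied += [(s, s + 1) for s, _ in base.inss]

        def clashes(s: int, e: int) -> bool:
            return any(s < oe + 4 and os_ < e + 4 for os_, oe in occupied)

        for s, _ in nops.subs:
            if s < 0 or s + 3 > len(exon_seqs[exon]) or clashes(s, s + 3):
                continue
            codon = exon_seqs[exon][s : s + 3].upper()
            syns = _SYNONYMS.get(codon)
            if not syns:
                continue
            base.subs.append((s, syns[int(rng.integers(0, len(syns)))]))
            occupied.append((s, s + 3))
        for s, k in nops.dels:
            if not clashes(s, s + k):
                base.dels.append((s, k))
                occupied.append((s, s + k))
        for s, b in nops.inss:
            if not clashes(s, s + 1):
                base.inss.append((s, b))
                occupied.append((s, s + 1))
    return merged


# ---------------------------------------------------------------------------
# alignment emission


def _apply_ops(ref_seq: str, eops: _ExonOps) -> tuple[str, str]:
    """Build the (ref_aln, query_aln) strings for one exon."""
    events: list[tuple[int, str, object]] = []
    for s, bases in eops.subs:
        events.append((s, "sub", bases))
    for s, k in eops.dels:
        events.append((s, "del", k))
    for s, b in eops.inss:
        events.append((s, "ins", b))
    events.sort(key=lambda e: (e[0], e[1]))
    ref_out, qry_out = [], []
    pos = 0
    for s, kind, payload in events:
        ref_out.append(ref_seq[pos:s])
        qry_out.append(ref_seq[pos:s])
        if kind == "sub":
            bases = payload
            ref_out.append(ref_seq[s : s + len(bases)])
            qry_out.append(bases)
            pos = s + len(bases)
        elif kind == "del":
            k = payload
            ref_out.append(ref_seq[s : s + k])
            qry_out.append("-" * k)
            pos = s + k
        else:
            ref_out.append("-" * len(payload))
            qry_out.append(payload)
            pos = s
    ref_out.append(ref_seq[pos:])
    qry_out.append(ref_seq[pos:])
    return "".join(ref_out), "".join(qry_out)


@dataclass
class _SpeciesGene:
    alignments: list[ExonAlignment]
    contexts: dict[tuple[str, int], Optional[str]]
    query_contig: str
    query_chrom: str


def _emit_species_gene(
    layout: _GeneLayout,
    species: str,
    ops: dict[int, _ExonOps],
    missing_exons: set[int],
    all_missing: bool,
) -> _SpeciesGene:
    """Materialise query contig, exon alignments and unaligned-exon
    contexts for one gene in one species."""
    model = layout.model
    qchrom = f"q_{model.chrom}"
    # pads are copied in transcription orientation; content is irrelevant
    parts: list[str] = [_rc_if_minus(layout, slice(0, layout.pad))]
    offset = layout.pad
    alignments: list[ExonAlignment] = []
    contexts: dict[tuple[str, int], Optional[str]] = {}
    seg_spans: list[tuple[int, int, str]] = []  # (start, end, tag) per exon segment
    donors: list[Optional[str]] = []
    acceptors: list[Optional[str]] = []
    n = model.n_exons
    # build introns first so boundary dinucleotides are known
    introns = list(layout.introns)
    for i in range(n):
        eops = ops.get(i, _ExonOps())
        if i < n - 1 and eops.donor:
            introns[i] = eops.donor + introns[i][2:]
        if i > 0 and eops.acceptor:
            introns[i - 1] = introns[i - 1][:-2] + eops.acceptor
    for i in range(n):
        eops = ops.get(i, _ExonOps())
        ref_seq = layout.exon_seqs[i]
        if all_missing or i in missing_exons:
            seg = "N" * len(ref_seq)
            parts.append(seg)
            seg_spans.append((offset, offset + len(seg), "missing"))
            offset += len(seg)
            contexts[(model.transcript_id, i)] = seg
        elif eops.deleted:
            seg_spans.append((offset, offset, "deleted"))
            contexts[(model.transcript_id, i)] = None  # filled after contig built
        else:
            ref_aln, qry_aln = _apply_ops(ref_seq, eops)
            qseq = qry_aln.replace("-", "")
            donor = introns[i][:2] if i < n - 1 else None
            acceptor = introns[i - 1][-2:] if i > 0 else None
            alignments.append(
                ExonAlignment(
                    gene_id=model.gene_id,
                    transcript_id=model.transcript_id,
                    exon_index=i,
                    species=species,
                    status=ExonStatus.ALIGNED,
                    ref_aln=ref_aln,
                    query_aln=qry_aln,
                    query_donor_dinuc=donor,
                    query_acceptor_dinuc=acceptor,
                    query_chrom=qchrom,
                    query_start=offset,
                )
            )
            parts.append(qseq)
            seg_spans.append((offset, offset + len(qseq), "aligned"))
            offset += len(qseq)
        if i < n - 1:
            parts.append(introns[i])
            offset += len(introns[i])
    parts.append(_rc_if_minus(layout, slice(-layout.pad, None)))
    contig = "".join(parts)
    for i, (s, e, tag) in enumerate(seg_spans):
        if tag == "deleted":
            lo, hi = max(0, s - 20), min(len(contig), s + 20)
            contexts[(model.transcript_id, i)] = contig[lo:hi]
    return _SpeciesGene(
        alignments=alignments, contexts=contexts, query_contig=contig, query_chrom=qchrom
    )


def _rc_if_minus(layout: _GeneLayout, sl: slice) -> str:
    """Pad sequence in transcription orientation."""
    if layout.model.strand == "+":
        return layout.contig[sl]
    from Bio.Seq import Seq

    return str(Seq(layout.contig).reverse_complement())[sl]


def maf_blocks_for_species(
    cohort: "Cohort", species: str
) -> list[MafBlock]:
    blocks = []
    models = {m.transcript_id: m for m in cohort.models}
    for aln in cohort.alignments[species]:
        model = models[aln.transcript_id]
        s, e = model.exons[aln.exon_index]
        contig_len = len(cohort.ref_genome[model.chrom])
        ref_start = s if model.strand == "+" else contig_len - e
        qlen = len(aln.query_aln.replace("-", ""))
        blocks.append(
            MafBlock(
                meta={
                    "tx": aln.transcript_id,
                    "exon": aln.exon_index,
                    "donor": aln.query_donor_dinuc or ".",
                    "acceptor": aln.query_acceptor_dinuc or ".",
                },
                rows=[
                    MafRow(
                        src=f"ref.{model.chrom}",
                        start=ref_start,
                        size=e - s,
                        strand=model.strand,
                        src_size=contig_len,
                        text=aln.ref_aln,
                    ),
                    MafRow(
                        src=f"{species}.{aln.query_chrom}",
                        start=aln.query_start,
                        size=qlen,
                        strand="+",
                        src_size=len(cohort.query_genomes[species][aln.query_chrom]),
                        text=aln.query_aln,
                    ),
                ],
            )
        )
    return blocks


def uox_like_fixture(seed: int = 0) -> dict:
    """Preset scenario modelled on the urate-oxidase loss pattern.

    An 8-exon gene where two sister species share a premature stop in the
    third exon (index 2) while a third species carries a 4 bp deletion in
    the fourth exon (index 3) plus a stop in the fifth (index 4).
    Returns the model, per-species alignments, query genomes and the
    expected mutation keys.
    """
    rng = np.random.default_rng(seed)
    n_codons = 160
    cds = _random_cds(rng, n_codons)
    lengths = [60] * 8
    exon_seqs, pos = [], 0
    for ln in lengths:
        exon_seqs.append(cds[pos : pos + ln])
        pos += ln
    introns = ["gt" + _random_seq(rng, 40).lower() + "ag" for _ in range(7)]
    pad = 100
    parts, plus_exons, offset = [_random_seq(rng, pad)], [], pad
    for i, seq in enumerate(exon_seqs):
        plus_exons.append((offset, offset + len(seq)))
        parts.append(seq)
        offset += len(seq)
        if i < 7:
            parts.append(introns[i])
            offset += len(introns[i])
    parts.append(_random_seq(rng, pad))
    model = GeneModel(
        gene_id="gUOX", transcript_id="gUOX.t1", chrom="ctg_gUOX",
        strand="+", exons=tuple(plus_exons),
    )
    layout = _GeneLayout(
        model=model, contig="".join(parts), exon_seqs=exon_seqs,
        introns=introns, pad=pad,
    )
    shared = {2: _ExonOps(subs=[(27, "TGA")])}          # codon 50, exon index 2
    solo = {
        3: _ExonOps(dels=[(20, 4)]),                    # codon 67, exon index 3
        4: _ExonOps(subs=[(27, "TAA")]),                # codon 90, exon index 4
    }
    expected = {
        "spA": [("PREMATURE_STOP", 2, 50)],
        "spB": [("PREMATURE_STOP", 2, 50)],
        "spC": [("FRAMESHIFT_DEL", 3, 67), ("PREMATURE_STOP", 4, 90)],
    }
    alignments, query_genomes = {}, {}
    for sp, ops in (("spA", shared), ("spB", shared), ("spC", solo)):
        sg = _emit_species_gene(layout, sp, ops, set(), False)
        alignments[sp] = sg.alignments
        query_genomes[sp] = {sg.query_chrom: sg.query_contig}
    return {
        "model": model,
        "alignments": alignments,
        "query_genomes": query_genomes,
        "expected": expected,
    }


# ---------------------------------------------------------------------------
# ontology, annotations, classes


def build_ontology(rng: np.random.Generator, config: SimConfig) -> OntologyDAG:
    """Random is_a DAG with >=4 levels plus the fixed bookkeeping terms."""
    graph = nx.DiGraph()
    root = "MP:0000001"
    graph.add_node(root)
    names = {root: "mammalian phenotype"}
    n2, n3, n4, n5 = config.terms_per_level
    level_terms: dict[int, list[str]] = {1: [root]}
    counter = 1000000
    graph.add_edge(NORMAL_PHENOTYPE, root)
    names[NORMAL_PHENOTYPE] = "normal phenotype"
    graph.add_edge(NO_ABNORMAL_PHENOTYPE, NORMAL_PHENOTYPE)
    names[NO_ABNORMAL_PHENOTYPE] = "no abnormal phenotype detected"
    mortality = "MP:0010768"
    graph.add_edge(mortality, root)
    names[mortality] = "mortality/aging"
    graph.add_edge(PRENATAL_LETHALITY, mortality)
    names[PRENATAL_LETHALITY] = "prenatal lethality"
    level_terms[2] = [mortality]
    level_terms[3] = [PRENATAL_LETHALITY]
    for level, count in ((2, n2), (3, n3), (4, n4), (5, n5)):
        terms = level_terms.setdefault(level, [])
        for _ in range(count):
            term = f"MP:{counter:07d}"
            counter += 1
            # prenatal lethality is a class-defining term; random terms must
            # not descend from it or class derivation would be contaminated
            parents = [
                t for t in level_terms[level - 1] if t != PRENATAL_LETHALITY
            ] or level_terms[level - 1]
            parent = parents[int(rng.integers(0, len(parents)))]
            graph.add_edge(term, parent)
            names[term] = f"synthetic phenotype {term[-7:]}"
            if len(parents) > 1 and rng.random() < config.p_extra_parent:
                other = parents[int(rng.integers(0, len(parents)))]
                if other != parent:
                    graph.add_edge(term, other)
            terms.append(term)
    return OntologyDAG.from_graph(graph, names=names)


def draw_class_labels(
    rng: np.random.Generator,
    lost: bool,
    base_rates: dict[str, float],
    loss_or: dict[str, float],
) -> set[str]:
    """Class membership with loss-dependent odds.

    For a non-lost gene the membership probability is the base rate; for
    a lost gene the odds are multiplied by the configured odds ratio.
    """
    labels = set()
    for label, base in base_rates.items():
        odds = base / (1.0 - base)
        if lost:
            odds *= loss_or.get(label, 1.0)
        p = odds / (1.0 + odds)
        if rng.random() < p:
            labels.add(label)
    if "DISPENSABLE" in labels:
        labels.discard("LETHAL")  # contradictory annotations
    return labels


def draw_phenotype_count(
    rng: np.random.Generator, lost: bool, config: SimConfig
) -> int:
    if lost:
        return config.pleio_base_lost + int(rng.poisson(config.pleio_lam_lost))
    return config.pleio_base_retained + int(rng.poisson(config.pleio_lam_retained))


def emit_ontology_and_classes(
    rng: np.random.Generator,
    config: SimConfig,
    lost_by_gene: dict[str, bool],
) -> tuple[OntologyDAG, list[tuple[str, str, int]], dict[str, set[str]],
           dict[str, set[str]], dict[str, int]]:
    """Ontology + annotation rows + class table (+ drawn direct terms/counts).

    Dispensable genes are annotated only with 'no abnormal phenotype
    detected'; lethal genes additionally carry 'prenatal lethality'; all
    others draw their configured number of distinct level-4 terms.
    """
    dag = build_ontology(rng, config)
    level4 = sorted(t for t, lv in dag.levels.items() if lv == 4)
    rows: list[tuple[str, str, int]] = []
    classes: dict[str, set[str]] = {}
    direct: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    genes = sorted(lost_by_gene)
    for gene in genes:
        lost = lost_by_gene[gene]
        labels = draw_class_labels(rng, lost, config.class_base_rates, config.class_loss_or)
        classes[gene] = labels
        if "DISPENSABLE" in labels:
            terms = {NO_ABNORMAL_PHENOTYPE}
            counts[gene] = 0
        else:
            k = min(draw_phenotype_count(rng, lost, config), len(level4))
            idx = rng.choice(len(level4), size=k, replace=False)
            terms = {level4[int(i)] for i in idx}
            counts[gene] = k
            if "LETHAL" in labels:
                terms.add(PRENATAL_LETHALITY)
        direct[gene] = terms
        for term in sorted(terms):
            rows.append((gene, term, 1))
    all_terms = sorted(dag.terms - {dag.root})
    for _ in range(config.digenic_noise_rows if genes else 0):
        gene = genes[int(rng.integers(0, len(genes)))]
        term = all_terms[int(rng.integers(0, len(all_terms)))]
        rows.append((gene, term, 2))
    return dag, rows, classes, direct, counts


# ---------------------------------------------------------------------------
# reads


def emit_reads(
    rng: np.random.Generator,
    contexts: ContextPair,
    coverage: float = 10.0,
    read_length: int = 80,
    error_rate: float = 0.0,
    ancestral_fraction: float = 0.0,
) -> list[str]:
    """Reads sampled uniformly from the mutant and/or ancestral haplotype,
    both strands, with per-base errors."""
    from Bio.Seq import Seq

    n_reads = max(1, round(coverage * len(contexts.mutant) / read_length))
    reads = []
    for _ in range(n_reads):
        hap = (
            contexts.ancestral
            if rng.random() < ancestral_fraction
            else contexts.mutant
        )
        if len(hap) <= read_length:
            read = hap
        else:
            start = int(rng.integers(0, len(hap) - read_length + 1))
            read = hap[start : start + read_length]
        if error_rate > 0:
            chars = list(read)
            for i in range(len(chars)):
                if rng.random() < error_rate:
                    chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
            read = "".join(chars)
        if rng.random() < 0.5:
            read = str(Seq(read).reverse_complement())
        reads.append(read)
    return reads


# ---------------------------------------------------------------------------
# the cohort


@dataclass
class Cohort:
    config: SimConfig
    tree: dendropy.Tree
    species: list[str]
    models: list[GeneModel]
    ref_genome: dict[str, str]
    alignments: dict[str, list[ExonAlignment]]
    contexts: dict[str, dict[tuple[str, int], Optional[str]]]
    query_genomes: dict[str, dict[str, str]]
    dag: OntologyDAG
    annotation_rows: list[tuple[str, str, int]]
    class_table: dict[str, set[str]]
    ledger: TruthLedger


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a full synthetic cohort under the configured conditions."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = (
        parse_newick(config.newick)
        if config.newick
        else random_tree(rng, config.n_species)
    )
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())

    models: list[GeneModel] = []
    ref_genome: dict[str, str] = {}
    alignments: dict[str, list[ExonAlignment]] = {sp: [] for sp in species}
    contexts: dict[str, dict] = {sp: {} for sp in species}
    query_genomes: dict[str, dict[str, str]] = {sp: {} for sp in species}
    truths: dict[str, GeneTruth] = {}

    for gene_no in range(1, config.n_genes + 1):
        layout = _make_gene(rng, gene_no, config)
        model = layout.model
        models.append(model)
        ref_genome[model.chrom] = layout.contig

        events = simulate_loss_history(rng, tree, config.p_loss, config.p_convergent)
        plans = {id(node): _plan_loss_mutations(rng, model, config) for node in events}
        leaf_to_plan: dict[str, _Plan] = {}
        for node in events:
            for leaf in _leaves_below(node):
                leaf_to_plan[leaf] = plans[id(node)]

        states: dict[str, str] = {}
        mutations: dict[str, list[list]] = {}
        for sp in species:
            all_missing = rng.random() < config.na_rate
            plan = leaf_to_plan.get(sp)
            if all_missing:
                ops: dict[int, _ExonOps] = {}
                missing: set[int] = set(range(model.n_exons))
            elif plan is not None:
                ops = plan.ops
                hit = set(ops)
                eligible = [i for i in range(model.n_exons) if i not in hit]
                missing = {
                    i for i in eligible if rng.random() < config.assembly_gap_rate
                }
            else:
                neutral = _neutral_ops(rng, model, config)
                ops = _merge_neutral(rng, {}, neutral, layout.exon_seqs)
                missing = {
                    i
                    for i in range(model.n_exons)
                    if rng.random() < config.assembly_gap_rate
                }
                for i in missing:
                    ops.pop(i, None)
            sg = _emit_species_gene(layout, sp, ops, missing, all_missing)
            alignments[sp].extend(sg.alignments)
            contexts[sp].update(sg.contexts)
            query_genomes[sp][sg.query_chrom] = sg.query_contig
            if all_missing or len(missing) == model.n_exons:
                states[sp] = "NA"
                mutations[sp] = []
            elif plan is not None:
                states[sp] = "LOST"
                mutations[sp] = [list(e) for e in plan.expected]
            else:
                states[sp] = "INTACT"
                mutations[sp] = []
        event_branches = _ledger_event_branches(tree, states)
        truths[model.gene_id] = GeneTruth(
            gene_id=model.gene_id,
            transcript_id=model.transcript_id,
            event_branches=event_branches,
            n_independent_lineages=len(event_branches),
            species_states=states,
            mutations=mutations,
            classes=[],
            direct_terms=[],
            pleio_count=0,
        )

    lost_by_gene = {
        gid: t.n_independent_lineages >= 1 for gid, t in truths.items()
    }
    dag, rows, classes, direct, counts = emit_ontology_and_classes(
        rng, config, lost_by_gene
    )
    for gid, t in truths.items():
        t.classes = sorted(classes[gid])
        t.direct_terms = sorted(direct[gid])
        t.pleio_count = counts[gid]

    return Cohort(
        config=config,
        tree=tree,
        species=species,
        models=models,
        ref_genome=ref_genome,
        alignments=alignments,
        contexts=contexts,
        query_genomes=query_genomes,
        dag=dag,
        annotation_rows=rows,
        class_table=classes,
        ledger=TruthLedger(genes=truths),
    )


def write_cohort(cohort: Cohort, outdir: str) -> None:
    """Write every input file of the pipeline plus the truth ledger."""
    import os

    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "aln"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "query"), exist_ok=True)
    write_fasta(dict(sorted(cohort.ref_genome.items())), os.path.join(outdir, "genome.fa"))
    write_bed12(cohort.models, os.path.join(outdir, "genes.bed"))
    write_newick(cohort.tree, os.path.join(outdir, "tree.nwk"))
    for sp in cohort.species:
        write_maf(
            maf_blocks_for_species(cohort, sp),
            os.path.join(outdir, "aln", f"{sp}.maf"),
        )
        write_contexts(
            cohort.contexts[sp], os.path.join(outdir, "aln", f"{sp}.contexts.tsv")
        )
        write_fasta(
            dict(sorted(cohort.query_genomes[sp].items())),
            os.path.join(outdir, "query", f"{sp}.fa"),
        )
    write_obo(cohort.dag, os.path.join(outdir, "pheno.obo"))
    with open(os.path.join(outdir, "annotations.tsv"), "w") as fh:
        fh.write("gene\tterm\tgenotype_arity\n")
        for gene, term, arity in cohort.annotation_rows:
            fh.write(f"{gene}\t{term}\t{arity}\n")
    with open(os.path.join(outdir, "classes.tsv"), "w") as fh:
        fh.write("gene\tclass\n")
        for gene in sorted(cohort.class_table):
            for label in sorted(cohort.class_table[gene]):
                fh.write(f"{gene}\t{label}\n")
    cohort.ledger.to_json(os.path.join(outdir, "truth_ledger.json"))
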