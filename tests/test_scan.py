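"""Mutation-scan behaviour: stops, frameshifts, splice sites, deletions."""

import re

import numpy as np
import pytest

from geneloss.models import ExonStatus, MutationKind, Thresholds
from geneloss.scan import (
    classify_exon_status,
    detect_frameshifts,
    detect_premature_stops,
    detect_splice_mutations,
    scan_gene,
)
from geneloss.simulate import SimConfig, _make_gene, _neutral_ops, _merge_neutral, _emit_species_gene

from conftest import (
    aligned,
    identity_alignments,
    make_cds,
    multi_exon_model,
    single_exon_model,
    split_cds,
)


def translate_stops(query_cds: str) -> list[int]:
    """Oracle: 1-based positions of internal stop codons, read codon by codon."""
    stops = []
    for c in range(len(query_cds) // 3 - 1):
        if query_cds[3 * c : 3 * c + 3] in ("TAA", "TAG", "TGA"):
            stops.append(c + 1)
    return stops


class TestPrematureStops:
    def test_identical_query_terminal_stop_excluded(self):
        model = single_exon_model(100)
        cds = make_cds(100)
        alns = identity_alignments(model, cds)
        assert detect_premature_stops(alns, model) == []

    def test_stop_at_codon_ten_matches_translation_oracle(self):
        model = single_exon_model(100)
        cds = make_cds(100)  # codons 2..99 are GAA
        query = cds[:27] + "TAA" + cds[30:]  # codon 10 GAA -> TAA
        alns = [aligned(model, 0, cds, query)]
        muts = detect_premature_stops(alns, model)
        assert [m.codon_position for m in muts] == translate_stops(query) == [10]
        m = muts[0]
        assert m.kind is MutationKind.PREMATURE_STOP
        assert (m.ref_allele, m.query_allele) == ("GAA", "TAA")

    def test_stop_in_third_exon_uox_like(self):
        # mid-exon TGA in exon index 2, as in the elephant urate-oxidase loss
        lengths = [60, 60, 60, 60, 60]
        model = multi_exon_model(lengths)
        cds = make_cds(100)
        parts = split_cds(cds, lengths)
        codon = 45  # codon 45 spans CDS offsets 132..135, inside exon 2
        query_cds = cds[: 3 * (codon - 1)] + "TGA" + cds[3 * codon :]
        qparts = split_cds(query_cds, lengths)
        alns = [aligned(model, i, parts[i], qparts[i]) for i in range(5)]
        (m,) = detect_premature_stops(alns, model)
        assert (m.exon_index, m.codon_position) == (2, 45)

    def test_codon_spanning_exon_junction(self):
        # 61+59 split puts codon 21 across the junction
        lengths = [61, 119]
        model = multi_exon_model(lengths)
        cds = make_cds(60)
        query_cds = cds[:60] + "TAG" + cds[63:]  # codon 21
        parts, qparts = split_cds(cds, lengths), split_cds(query_cds, lengths)
        alns = [aligned(model, i, parts[i], qparts[i]) for i in range(2)]
        (m,) = detect_premature_stops(alns, model)
        assert m.codon_position == 21
        assert m.exon_index == 0  # codon's first base is in exon 0

    def test_codon_with_n_or_gap_skipped(self):
        model = single_exon_model(100)
        cds = make_cds(100)
        query = cds[:27] + "TNA" + cds[30:]
        assert detect_premature_stops([aligned(model, 0, cds, query)], model) == []


def gap_run_oracle(row: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end() - m.start()) for m in re.finditer(r"-+", row)]


class TestFrameshifts:
    def test_inframe_deletion_ignored(self):
        model = single_exon_model(100)
        cds = make_cds(100)
        query = cds[:30] + "---" + cds[33:]
        assert detect_frameshifts([aligned(model, 0, cds, query)], model) == []

    def test_four_bp_deletion_in_fourth_exon(self):
        # manatee-style: 4 bp deletion in exon index 3
        lengths = [60] * 5
        model = multi_exon_model(lengths)
        cds = make_cds(100)
        parts = split_cds(cds, lengths)
        qparts = list(parts)
        qparts[3] = parts[3][:20] + "----" + parts[3][24:]
        alns = [aligned(model, i, parts[i], qparts[i]) for i in range(5)]
        (m,) = detect_frameshifts(alns, model)
        assert m.kind is MutationKind.FRAMESHIFT_DEL
        assert m.exon_index == 3
        assert m.indel_length == 4
        assert m.codon_position == (180 + 20) // 3 + 1

    def test_two_separate_runs_both_reported(self):
        # 1 bp + 2 bp deletions 30 bp apart restore net frame but count twice
        model = single_exon_model(100)
        cds = make_cds(100)
        query = cds[:30] + "-" + cds[31:61] + "--" + cds[63:]
        muts = detect_frameshifts([aligned(model, 0, cds, query)], model)
        runs = [r for r in gap_run_oracle(query) if r[1] % 3]
        assert len(muts) == len(runs) == 2
        assert sorted(m.indel_length for m in muts) == [1, 2]

    def test_insertion_reported_with_anchor_codon(self):
        model = single_exon_model(100)
        cds = make_cds(100)
        ref = cds[:45] + "--" + cds[45:]
        query = cds[:45] + "CT" + cds[45:]
        (m,) = detect_frameshifts([aligned(model, 0, ref, query)], model)
        assert m.kind is MutationKind.FRAMESHIFT_INS
        assert m.indel_length == 2
        assert m.codon_position == (45 - 1) // 3 + 1


class TestSplice:
    @pytest.mark.parametrize(
        "donor,acceptor,expected_kinds",
        [
            ("gc", "ag", []),
            ("gt", "ag", []),
            ("gg", "ag", ["SPLICE_DONOR"]),
            ("gt", "aa", ["SPLICE_ACCEPTOR"]),
            ("ca", "tt", ["SPLICE_ACCEPTOR", "SPLICE_DONOR"]),
            ("nt", "ag", []),  # N = missing data
        ],
    )
    def test_dinucleotide_rules(self, donor, acceptor, expected_kinds):
        lengths = [60, 60, 60]
        model = multi_exon_model(lengths)
        cds = make_cds(60)
        parts = split_cds(cds, lengths)
        alns = [
            aligned(model, 0, parts[0], parts[0], donor="gt"),
            aligned(model, 1, parts[1], parts[1], donor=donor, acceptor=acceptor),
            aligned(model, 2, parts[2], parts[2], acceptor="ag"),
        ]
        muts = detect_splice_mutations(alns, model)
        assert sorted(m.kind.value for m in muts) == sorted(expected_kinds)

    def test_all_sixteen_dinucleotides_against_rule(self):
        # enumeration oracle: donors valid iff in {gt, gc}; acceptors iff ag
        lengths = [60, 60, 60]
        model = multi_exon_model(lengths)
        cds = make_cds(60)
        parts = split_cds(cds, lengths)
        dinucs = [a + b for a in "acgt" for b in "acgt"]
        for d in dinucs:
            alns = [aligned(model, 0, parts[0], parts[0], donor=d)]
            muts = detect_splice_mutations(alns, model)
            assert bool(muts) == (d not in ("gt", "gc"))
        for a in dinucs:
            alns = [aligned(model, 2, parts[2], parts[2], acceptor=a)]
            muts = detect_splice_mutations(alns, model)
            assert bool(muts) == (a != "ag")

    def test_single_exon_gene_never_splice(self):
        model = single_exon_model(100)
        cds = make_cds(100)
        assert detect_splice_mutations([aligned(model, 0, cds, cds)], model) == []

    def test_acceptor_on_last_exon(self):
        lengths = [60, 60, 60]
        model = multi_exon_model(lengths)
        cds = make_cds(60)
        parts = split_cds(cds, lengths)
        alns = [aligned(model, 2, parts[2], parts[2], acceptor="aa")]
        (m,) = detect_splice_mutations(alns, model)
        assert m.kind is MutationKind.SPLICE_ACCEPTOR
        assert m.codon_position == 120 // 3 + 1


class TestExonStatus:
    def test_n_run_is_missing(self):
        model = multi_exon_model([60, 60])
        ctx = "ACGT" + "N" * 30 + "ACGT"
        assert classify_exon_status(model, 0, ctx, 10) is ExonStatus.MISSING

    def test_clean_interval_is_deleted(self):
        model = multi_exon_model([60, 60])
        assert classify_exon_status(model, 0, "ACGTACGTACGT", 10) is ExonStatus.DELETED

    def test_unresolvable_is_missing(self):
        model = multi_exon_model([60, 60])
        assert classify_exon_status(model, 0, None, 10) is ExonStatus.MISSING

    def test_short_n_run_not_a_gap(self):
        model = multi_exon_model([60, 60])
        assert classify_exon_status(model, 0, "ACGNNNNNACG", 10) is ExonStatus.DELETED


class TestScanGene:
    def test_all_exons_deleted_is_gene_deletion(self):
        # complete deletion, as for thymidine phosphorylase in tenrec
        model = multi_exon_model([60, 60, 60])
        contexts = {(model.transcript_id, i): "ACGT" * 10 for i in range(3)}
        muts, status = scan_gene(model, [], contexts)
        assert [m.kind for m in muts] == [MutationKind.GENE_DELETED]
        assert all(s is ExonStatus.DELETED for s in status)

    def test_single_deleted_exon_event(self):
        lengths = [60, 60, 60]
        model = multi_exon_model(lengths)
        cds = make_cds(60)
        parts = split_cds(cds, lengths)
        alns = [aligned(model, i, parts[i], parts[i]) for i in (0, 2)]
        contexts = {(model.transcript_id, 1): "ACGT" * 10}
        muts, status = scan_gene(model, alns, contexts)
        (m,) = muts
        assert m.kind is MutationKind.EXON_DELETED
        assert m.exon_index == 1
        assert (m.codon_first, m.codon_last) == (21, 40)
        assert status == [ExonStatus.ALIGNED, ExonStatus.DELETED, ExonStatus.ALIGNED]

    def test_output_sorted_and_deterministic(self):
        model = single_exon_model(100)
        cds = make_cds(100)
        query = cds[:27] + "TAA" + cds[30:60] + "-" + cds[61:]
        muts1, _ = scan_gene(model, [aligned(model, 0, cds, cds[:27] + "TAA" + cds[30:60] + cds[60:])], {})
        alns = [aligned(model, 0, cds, query)]
        muts, _ = scan_gene(model, alns, {})
        assert muts == sorted(muts)
        muts2, _ = scan_gene(model, alns, {})
        assert muts == muts2


class TestNeutralRobustness:
    def test_synonymous_and_inframe_edits_never_inactivate(self):
        """Property: heavy neutral editing yields zero mutations."""
        config = SimConfig(seed=7, neutral_sub_rate=0.5, neutral_indel_rate=0.8)
        rng = np.random.default_rng(7)
        for gene_no in range(1, 31):
            layout = _make_gene(rng, gene_no, config)
            neutral = _neutral_ops(rng, layout.model, config)
            ops = _merge_neutral(rng, {}, neutral, layout.exon_seqs)
            sg = _emit_species_gene(layout, "spA", ops, set(), False)
            muts, _ = scan_gene(layout.model, sg.alignments, sg.contexts, Thresholds())
            assert muts == []
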