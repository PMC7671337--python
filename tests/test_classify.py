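"""Loss-classification rules: intact fraction, thresholds, isoform logic."""

import pytest

from geneloss.classify import (
    assess_isoform,
    build_loss_matrix,
    classify_gene,
    intact_fraction,
)
from geneloss.models import (
    ExonStatus,
    InactivatingMutation,
    LossCall,
    LossVerdict,
    MutationKind,
    Thresholds,
)

from conftest import multi_exon_model, single_exon_model


def stop_at(codon: int, exon: int = 0) -> InactivatingMutation:
    return InactivatingMutation(
        kind=MutationKind.PREMATURE_STOP,
        exon_index=exon,
        codon_position=codon,
        codon_first=codon,
        codon_last=codon,
    )


def intact_oracle(L: int, spans: list[tuple[int, int]]) -> float:
    """Direct counting: longest clean terminal segment of the codon axis."""
    damaged = set()
    for f, l in spans:
        damaged.update(range(f, l + 1))
    prefix = 0
    for c in range(1, L + 1):
        if c in damaged:
            break
        prefix += 1
    suffix = 0
    for c in range(L, 0, -1):
        if c in damaged:
            break
        suffix += 1
    return max(prefix, suffix) / L


class TestIntactFraction:
    def test_no_mutations_is_one(self):
        assert intact_fraction(single_exon_model(100), []) == 1.0

    def test_single_mid_mutation_both_flanks(self):
        model = single_exon_model(100)
        assert intact_fraction(model, [stop_at(51)]) == 0.50
        assert intact_fraction(model, [stop_at(51)]) == intact_oracle(100, [(51, 51)])

    def test_terminal_mutations_zero(self):
        model = single_exon_model(100)
        muts = [stop_at(1), stop_at(100)]
        assert intact_fraction(model, muts) == 0.0

    @pytest.mark.parametrize("codons", [[10], [10, 90], [33, 34], [2, 50, 99]])
    def test_matches_counting_oracle(self, codons):
        model = single_exon_model(100)
        muts = [stop_at(c) for c in codons]
        spans = [(c, c) for c in codons]
        assert intact_fraction(model, muts) == pytest.approx(
            intact_oracle(100, spans)
        )

    def test_exon_deletion_contributes_full_span(self):
        model = multi_exon_model([60, 60, 60])  # codons 1-20, 21-40, 41-60
        m = InactivatingMutation(
            kind=MutationKind.EXON_DELETED, exon_index=1,
            codon_position=None, codon_first=21, codon_last=40,
        )
        assert intact_fraction(model, [m]) == max(20, 20) / 60

    def test_max_stretch_alternative_rule(self):
        model = single_exon_model(100)
        muts = [stop_at(11), stop_at(90)]
        # terminal flanks: max(10, 10) = 0.10; inner stretch 12..89 = 78
        assert intact_fraction(model, muts) == 0.10
        assert intact_fraction(model, muts, rule="max_stretch") == 0.78

    def test_monotone_under_added_mutation(self):
        model = single_exon_model(100)
        base = [stop_at(30)]
        more = base + [stop_at(80)]
        assert intact_fraction(model, more) <= intact_fraction(model, base)


class TestLossRule:
    def test_threshold_boundaries_strict_as_printed(self):
        """<60% intact (strict) AND >=20% exons hit; >=2 for single-exon."""
        model = multi_exon_model([30] * 10)  # 100 codons, 10 exons
        thresholds = Thresholds()
        # intact exactly 0.60 (first damaged codon 61, suffix shorter)
        muts = [stop_at(61, exon=6), stop_at(95, exon=9)]
        a = assess_isoform(model, muts, [ExonStatus.ALIGNED] * 10, thresholds)
        assert a.intact_fraction == 0.60
        assert a.verdict is LossVerdict.INTACT
        # intact 0.59 with 2/10 exons -> lost
        muts = [stop_at(60, exon=5), stop_at(95, exon=9)]
        a = assess_isoform(model, muts, [ExonStatus.ALIGNED] * 10, thresholds)
        assert a.intact_fraction == 0.59
        assert a.verdict is LossVerdict.LOST

    def test_exon_fraction_boundary(self):
        model = multi_exon_model([30] * 10)
        # same exon twice: 1/10 exons -> not lost despite intact < 0.6
        muts = [stop_at(50, exon=4), stop_at(55, exon=4)]
        a = assess_isoform(model, muts, [ExonStatus.ALIGNED] * 10, Thresholds())
        assert a.exon_fraction_hit == 0.1
        assert a.verdict is LossVerdict.INTACT

    def test_single_exon_two_mutations_required(self):
        model = single_exon_model(100)
        one = [stop_at(50)]
        two = [stop_at(30), stop_at(70)]
        st = [ExonStatus.ALIGNED]
        assert assess_isoform(model, one, st).verdict is LossVerdict.INTACT
        assert assess_isoform(model, two, st).verdict is LossVerdict.LOST

    def test_missing_exons_excluded_from_denominator(self):
        model = multi_exon_model([30] * 10)
        status = [ExonStatus.MISSING] * 5 + [ExonStatus.ALIGNED] * 5
        muts = [stop_at(55, exon=5), stop_at(95, exon=9)]
        a = assess_isoform(model, muts, status)
        assert a.exon_fraction_hit == 2 / 5

    def test_all_missing_is_no_data(self):
        model = multi_exon_model([30, 30])
        a = assess_isoform(model, [], [ExonStatus.MISSING] * 2)
        assert a.verdict is LossVerdict.NO_DATA

    def test_gene_deleted_rationale(self):
        model = multi_exon_model([30, 30])
        m = InactivatingMutation(kind=MutationKind.GENE_DELETED, codon_first=1,
                                 codon_last=20)
        a = assess_isoform(model, [m], [ExonStatus.DELETED] * 2)
        assert a.verdict is LossVerdict.LOST
        assert a.intact_fraction == 0.0


class TestGeneAggregation:
    def _isoforms(self):
        m1 = single_exon_model(100, gene="gZ")
        m2 = multi_exon_model([150, 150], gene="gZ")
        m2 = type(m2)(
            gene_id="gZ", transcript_id="gZ.t2", chrom=m2.chrom,
            strand=m2.strand, exons=m2.exons,
        )
        return m1, m2

    def test_one_intact_isoform_rescues_gene(self):
        m1, m2 = self._isoforms()
        muts = {m1.transcript_id: [stop_at(30), stop_at(70)], m2.transcript_id: []}
        status = {
            m1.transcript_id: [ExonStatus.ALIGNED],
            m2.transcript_id: [ExonStatus.ALIGNED] * 2,
        }
        call = classify_gene([m1, m2], muts, status, "spA")
        assert call.verdict is LossVerdict.INTACT
        assert call.best_intact_fraction == 1.0

    def test_all_isoforms_lost_is_lost(self):
        m1, m2 = self._isoforms()
        muts = {
            m1.transcript_id: [stop_at(30), stop_at(70)],
            m2.transcript_id: [stop_at(30, exon=0), stop_at(70, exon=1)],
        }
        status = {
            m1.transcript_id: [ExonStatus.ALIGNED],
            m2.transcript_id: [ExonStatus.ALIGNED] * 2,
        }
        call = classify_gene([m1, m2], muts, status, "spA")
        assert call.verdict is LossVerdict.LOST

    def test_adding_mutation_never_unloses(self):
        model = multi_exon_model([30] * 10)
        muts = [stop_at(50, 4), stop_at(60, 5), stop_at(70, 6)]
        st = {"gX.t1": [ExonStatus.ALIGNED] * 10}
        before = classify_gene([model], {"gX.t1": muts}, st, "spA")
        after = classify_gene(
            [model], {"gX.t1": muts + [stop_at(20, 1)]}, st, "spA"
        )
        assert before.verdict is LossVerdict.LOST
        assert after.verdict is LossVerdict.LOST


class TestMatrix:
    def test_single_lost_cell(self):
        calls = [
            LossCall("g1", "spA", LossVerdict.LOST),
            LossCall("g1", "spB", LossVerdict.INTACT),
            LossCall("g2", "spA", LossVerdict.INTACT),
            LossCall("g2", "spB", LossVerdict.INTACT),
            LossCall("g3", "spA", LossVerdict.NO_DATA),
            LossCall("g3", "spB", LossVerdict.INTACT),
        ]
        mat = build_loss_matrix(calls)
        assert (mat.values == "LOST").sum() == 1
        assert mat.loc["g3", "spA"] == "NA"
        assert list(mat.index) == ["g1", "g2", "g3"]
        assert list(mat.columns) == ["spA", "spB"]
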