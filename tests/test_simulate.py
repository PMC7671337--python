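"""Generator contracts: Dollo-consistent histories, reproducibility,
ontology/class construction, and file round-trips."""

import hashlib
import math
import os

import numpy as np
import pytest

from geneloss.enrichment import derive_classes_from_annotations
from geneloss.io import parse_newick, read_bed12, read_fasta, read_newick
from geneloss.maf import read_contexts, read_exon_alignments
from geneloss.ontology import read_obo
from geneloss.phenotypes import direct_annotations, filter_single_gene_knockouts, propagate
from geneloss.simulate import (
    SimConfig,
    TruthLedger,
    simulate_cohort,
    simulate_loss_history,
    write_cohort,
)


class TestLossHistories:
    def test_zero_loss_probability_means_no_losses(self):
        cohort = simulate_cohort(SimConfig(seed=2, n_genes=30, p_loss=0.0))
        assert all(
            t.n_independent_lineages == 0 for t in cohort.ledger.genes.values()
        )

    def test_zero_convergence_means_single_lineage(self):
        cohort = simulate_cohort(
            SimConfig(seed=2, n_genes=60, p_loss=0.08, p_convergent=0.0)
        )
        lineages = {
            t.n_independent_lineages for t in cohort.ledger.genes.values()
        }
        assert lineages <= {0, 1}
        assert 1 in lineages  # at this rate some gene is lost

    def test_histories_are_dollo_consistent(self):
        cohort = simulate_cohort(
            SimConfig(seed=9, n_genes=80, p_loss=0.05, p_convergent=0.2)
        )
        leaves_by_branch = {}
        for t in cohort.ledger.genes.values():
            for branch in t.event_branches:
                leaves = set(branch.split(","))
                for sp in leaves:
                    assert t.species_states[sp] in ("LOST", "NA")

    def test_star_tree_matches_closed_form(self):
        """On a star tree every branch is independent, so the multi-lineage
        fraction has a closed form; simulated frequency must sit in a
        binomial CI around it."""
        newick = "(" + ",".join(f"sp{i:02d}" for i in range(1, 9)) + ");"
        tree = parse_newick(newick)
        p, q = 0.05, 0.10
        B = 8
        p_none = (1 - p) ** B
        # P(>=2 events): first event on branch i, then >=1 of the rest
        p_multi = sum(
            (1 - p) ** (i - 1) * p * (1 - (1 - q) ** (B - i)) for i in range(1, B + 1)
        )
        rng = np.random.default_rng(123)
        n = 4000
        events = [len(simulate_loss_history(rng, tree, p, q)) for _ in range(n)]
        frac_none = sum(e == 0 for e in events) / n
        frac_multi = sum(e >= 2 for e in events) / n
        for observed, expected in ((frac_none, p_none), (frac_multi, p_multi)):
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 4 * se


class TestReproducibility:
    def test_bit_identical_cohort_files(self, tmp_path):
        config = SimConfig(seed=77, n_genes=15, n_species=5,
                           assembly_gap_rate=0.05, na_rate=0.05)
        digests = []
        for name in ("a", "b"):
            out = tmp_path / name
            write_cohort(simulate_cohort(config), str(out))
            h = hashlib.sha256()
            for root, _, files in sorted(os.walk(out)):
                for f in sorted(files):
                    h.update(f.encode())
                    h.update(open(os.path.join(root, f), "rb").read())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimConfig(seed=1, n_genes=10))
        b = simulate_cohort(SimConfig(seed=2, n_genes=10))
        assert a.ref_genome != b.ref_genome


class TestOntologyAndClasses:
    def test_dag_has_at_least_four_levels(self):
        cohort = simulate_cohort(SimConfig(seed=4, n_genes=10))
        assert max(cohort.dag.levels.values()) >= 5

    def test_dispensable_and_lethal_derivation_matches_ledger(self):
        cohort = simulate_cohort(SimConfig(seed=4, n_genes=300))
        rows = filter_single_gene_knockouts(cohort.annotation_rows)
        closed = propagate(direct_annotations(rows), cohort.dag)
        derived = derive_classes_from_annotations(closed, cohort.dag)
        for gid, truth in cohort.ledger.genes.items():
            for label in ("DISPENSABLE", "LETHAL"):
                assert (label in truth.classes) == (
                    label in derived.get(gid, set())
                )

    def test_class_odds_ratio_recovered_roughly(self):
        config = SimConfig(seed=8, n_genes=4000, p_loss=0.04, p_convergent=0.1)
        cohort = simulate_cohort(config)
        lost = {g for g, t in cohort.ledger.genes.items() if t.n_independent_lineages}
        not_lost = set(cohort.ledger.genes) - lost
        member = {g for g, cls in cohort.class_table.items() if "ESSENTIAL" in cls}
        a = len(lost & member)
        b = len(lost - member)
        c = len(not_lost & member)
        d = len(not_lost - member)
        observed_or = (a * d) / (b * c)
        assert 0.15 < observed_or < 0.6  # configured 0.3


class TestRoundTrip:
    def test_written_cohort_reloads_identically(self, tmp_path):
        config = SimConfig(seed=6, n_genes=12, n_species=4,
                           assembly_gap_rate=0.05, na_rate=0.05)
        cohort = simulate_cohort(config)
        out = str(tmp_path / "cohort")
        write_cohort(cohort, out)

        models = read_bed12(os.path.join(out, "genes.bed"))
        assert models == cohort.models

        genome = read_fasta(os.path.join(out, "genome.fa"))
        assert genome == cohort.ref_genome

        tree = read_newick(os.path.join(out, "tree.nwk"))
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == cohort.species

        sp = cohort.species[0]
        alns = read_exon_alignments(os.path.join(out, "aln", f"{sp}.maf"), models)
        want = {
            (a.transcript_id, a.exon_index): (a.ref_aln, a.query_aln,
                                              a.query_donor_dinuc,
                                              a.query_acceptor_dinuc,
                                              a.query_start)
            for a in cohort.alignments[sp]
        }
        got = {
            (a.transcript_id, a.exon_index): (a.ref_aln, a.query_aln,
                                              a.query_donor_dinuc,
                                              a.query_acceptor_dinuc,
                                              a.query_start)
            for a in alns
        }
        assert got == want
        assert read_contexts(os.path.join(out, "aln", f"{sp}.contexts.tsv")) == cohort.contexts[sp]

        dag = read_obo(os.path.join(out, "pheno.obo"))
        assert dag.levels == cohort.dag.levels

        ledger = TruthLedger.from_json(os.path.join(out, "truth_ledger.json"))
        assert ledger.summary() == cohort.ledger.summary()

    def test_reference_cds_is_translatable(self):
        from geneloss.io import cds_sequence

        cohort = simulate_cohort(SimConfig(seed=10, n_genes=20))
        for model in cohort.models:
            cds = cds_sequence(model, cohort.ref_genome)
            assert cds.startswith("ATG")
            assert cds[-3:] in ("TAA", "TAG", "TGA")
            assert len(cds) % 3 == 0
            internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
            assert not any(c in ("TAA", "TAG", "TGA") for c in internal)
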