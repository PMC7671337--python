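"""End-to-end orchestration: scan -> classify -> Dollo -> pleiotropy ->
enrichment (-> read validation), with deterministic tabular outputs.

Every stage is a pure function of its inputs; rerunning with the same
inputs and configuration produces byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import classify as _classify
from . import dollo as _dollo
from . import enrichment as _enrichment
from . import phenotypes as _phenotypes
from . import scan as _scan
from .io import (
    read_annotation_table,
    read_class_table,
    read_fasta,
    read_gene_models,
    read_newick,
    read_ortholog_map,
)
from .maf import read_contexts, read_exon_alignments
from .models import (
    ExonAlignment,
    GeneModel,
    InactivatingMutation,
    LossCall,
    MutationKind,
    Thresholds,
)
from .ontology import read_obo
from .validate import extract_context, load_reads, tally_support


@dataclass
class PipelineConfig:
    genes: str
    aln_dir: str
    tree: str
    obo: str
    annotations: str
    classes: str
    out_dir: str
    ortholog_map: Optional[str] = None
    reads_manifest: Optional[str] = None
    query_dir: Optional[str] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    intact_rule: str = "terminal_flanks"
    pooled_enrichment: bool = False

    def validate(self) -> None:
        for name in ("genes", "aln_dir", "tree", "obo", "annotations", "classes"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name}: {path}")


@dataclass
class AnalysisResult:
    mutations: pd.DataFrame
    calls: list[LossCall]
    matrix: pd.DataFrame
    dollo: pd.DataFrame
    partition: dict[str, set[str]]
    pheno_counts: pd.DataFrame
    pleiotropy_tests: pd.DataFrame
    enrichment: pd.DataFrame
    summary: dict


def scan_and_classify(
    models: list[GeneModel],
    alignments_by_species: dict[str, list[ExonAlignment]],
    contexts_by_species: dict[str, dict],
    thresholds: Thresholds,
    intact_rule: str = "terminal_flanks",
) -> tuple[pd.DataFrame, list[LossCall]]:
    """Run the mutation scan and the loss classifier over every
    gene x species pair; returns the mutation table and all loss calls."""
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    mutation_rows = []
    status_rows = []
    calls: list[LossCall] = []
    for species in sorted(alignments_by_species):
        alns = alignments_by_species[species]
        contexts = contexts_by_species.get(species, {})
        by_tx: dict[str, list[ExonAlignment]] = {}
        for a in alns:
            by_tx.setdefault(a.transcript_id, []).append(a)
        for gene_id in sorted(by_gene):
            isoforms = by_gene[gene_id]
            mutations_by_tx, status_by_tx = {}, {}
            for model in isoforms:
                muts, status = _scan.scan_gene(
                    model,
                    by_tx.get(model.transcript_id, []),
                    contexts,
                    thresholds,
                )
                mutations_by_tx[model.transcript_id] = muts
                status_by_tx[model.transcript_id] = status
                for i, s in enumerate(status):
                    status_rows.append(
                        {
                            "gene": gene_id,
                            "transcript": model.transcript_id,
                            "species": species,
                            "exon_index": i,
                            "status": s.value,
                        }
                    )
                for m in muts:
                    mutation_rows.append(
                        {
                            "gene": gene_id,
                            "transcript": model.transcript_id,
                            "species": species,
                            "kind": m.kind.value,
                            "exon_index": m.exon_index,
                            "codon_position": m.codon_position,
                            "ref_allele": m.ref_allele,
                            "query_allele": m.query_allele,
                            "indel_length": m.indel_length,
                            "codon_first": m.codon_first,
                            "codon_last": m.codon_last,
                        }
                    )
            calls.append(
                _classify.classify_gene(
                    isoforms, mutations_by_tx, status_by_tx, species,
                    thresholds, intact_rule,
                )
            )
    mutations = pd.DataFrame(
        mutation_rows,
        columns=[
            "gene", "transcript", "species", "kind", "exon_index",
            "codon_position", "ref_allele", "query_allele", "indel_length",
            "codon_first", "codon_last",
        ],
    )
    status_df = pd.DataFrame(
        status_rows,
        columns=["gene", "transcript", "species", "exon_index", "status"],
    )
    return mutations, calls, status_df


def mutations_from_frame(df: pd.DataFrame) -> dict[tuple[str, str], list[InactivatingMutation]]:
    """Rebuild mutation objects from a mutations table, keyed by
    (species, transcript)."""
    out: dict[tuple[str, str], list[InactivatingMutation]] = {}

    def _opt(v):
        return None if pd.isna(v) else int(v)

    for rec in df.to_dict("records"):
        m = InactivatingMutation(
            kind=MutationKind(rec["kind"]),
            exon_index=_opt(rec["exon_index"]),
            codon_position=_opt(rec["codon_position"]),
            ref_allele="" if pd.isna(rec["ref_allele"]) else str(rec["ref_allele"]),
            query_allele="" if pd.isna(rec["query_allele"]) else str(rec["query_allele"]),
            indel_length=int(rec["indel_length"]),
            codon_first=_opt(rec.get("codon_first")),
            codon_last=_opt(rec.get("codon_last")),
        )
        out.setdefault((rec["species"], rec["transcript"]), []).append(m)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage from input files and write the report bundle."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    models = read_gene_models(config.genes)
    tree = read_newick(config.tree)
    species_files = sorted(
        f[:-4] for f in os.listdir(config.aln_dir) if f.endswith(".maf")
    )
    alignments_by_species, contexts_by_species = {}, {}
    for sp in species_files:
        alignments_by_species[sp] = read_exon_alignments(
            os.path.join(config.aln_dir, f"{sp}.maf"), models
        )
        ctx_path = os.path.join(config.aln_dir, f"{sp}.contexts.tsv")
        contexts_by_species[sp] = (
            read_contexts(ctx_path) if os.path.exists(ctx_path) else {}
        )

    mutations, calls, status_df = scan_and_classify(
        models, alignments_by_species, contexts_by_species,
        config.thresholds, config.intact_rule,
    )
    matrix = _classify.build_loss_matrix(calls)
    histories = _dollo.histories_from_matrix(tree, matrix)
    partition = _dollo.partition_by_lineage_count(histories)
    dollo_df = pd.DataFrame(
        [
            {
                "gene": h.gene_id,
                "n_independent_lineages": h.n_independent_lineages,
                "event_branches": ";".join(sorted(h.event_branches)),
            }
            for h in histories
        ],
        columns=["gene", "n_independent_lineages", "event_branches"],
    ).sort_values("gene").reset_index(drop=True)

    dag = read_obo(config.obo)
    annotation_rows = read_annotation_table(config.annotations)
    ortho = read_ortholog_map(config.ortholog_map) if config.ortholog_map else None
    counts = _phenotypes.gene_level_counts(annotation_rows, dag, ortholog_map=ortho)
    group_counts = {
        name: {
            lv: [int(counts.loc[g, f"level{lv}_count"]) for g in sorted(genes) if g in counts.index]
            for lv in (2, 3, 4)
        }
        for name, genes in partition.items()
    }
    pleio_rows = []
    for lv in (2, 3, 4):
        groups = {
            name: vals[lv] for name, vals in group_counts.items() if vals[lv]
        }
        if len(groups) >= 2:
            df = _phenotypes.pleiotropy_compare(groups)
            df.insert(0, "level", lv)
            pleio_rows.append(df)
    pleiotropy_tests = (
        pd.concat(pleio_rows, ignore_index=True) if pleio_rows else pd.DataFrame()
    )

    classes = read_class_table(config.classes)
    universe = set(matrix.index)
    enrich = _enrichment.class_enrichment(
        {
            "no_loss": partition["not_lost"],
            "single_lineage": partition["single_lineage"],
            "multi_lineage": partition["multi_lineage"],
        },
        classes,
        universe,
        pooled=config.pooled_enrichment,
    )

    validation_df = None
    if config.reads_manifest and config.query_dir:
        validation_df = _run_validation(
            config, models, alignments_by_species
        )

    summary = {
        "n_genes": int(len(matrix.index)),
        "n_species": int(len(matrix.columns)),
        "n_lost": int(len(partition["single_lineage"]) + len(partition["multi_lineage"])),
        "n_single_lineage": int(len(partition["single_lineage"])),
        "n_multi_lineage": int(len(partition["multi_lineage"])),
        "n_mutations": int(len(mutations)),
        "enrichment": [
            {
                "class": r["class"],
                "group": r["group"],
                "odds_ratio": None if pd.isna(r["odds_ratio"]) else float(r["odds_ratio"]),
                "p_value": float(r["p_value"]),
                "direction": r["direction"],
            }
            for r in enrich.to_dict("records")
        ],
        "pleiotropy": pleiotropy_tests.to_dict("records") if len(pleiotropy_tests) else [],
    }
    if validation_df is not None:
        summary["n_validated_confirmed"] = int(
            (validation_df["status"] == "CONFIRMED").sum()
        )
        summary["n_validated_total"] = int(len(validation_df))

    _write_outputs(
        config.out_dir, mutations, calls, matrix, dollo_df, counts,
        pleiotropy_tests, enrich, validation_df, summary,
    )
    status_df.to_csv(
        os.path.join(config.out_dir, "exon_status.tsv"),
        sep="\t", index=False,
    )
    return summary


def _run_validation(
    config: PipelineConfig,
    models: list[GeneModel],
    alignments_by_species: dict[str, list[ExonAlignment]],
) -> pd.DataFrame:
    manifest = pd.read_csv(config.reads_manifest, sep="\t", comment="#")
    by_tx = {m.transcript_id: m for m in models}
    aln_index = {
        (sp, a.transcript_id, a.exon_index): a
        for sp, alns in alignments_by_species.items()
        for a in alns
    }
    genomes: dict[str, dict[str, str]] = {}
    rows = []
    for rec in manifest.to_dict("records"):
        sp = rec["species"]
        if sp not in genomes:
            genomes[sp] = read_fasta(os.path.join(config.query_dir, f"{sp}.fa"))
        model = by_tx[rec["transcript"]]
        aln = aln_index[(sp, rec["transcript"], int(rec["exon_index"]))]
        mutation = InactivatingMutation(
            kind=MutationKind(rec["kind"]),
            exon_index=int(rec["exon_index"]),
            codon_position=int(rec["codon_position"]),
            ref_allele=str(rec["ref_allele"]) if not pd.isna(rec["ref_allele"]) else "",
            query_allele="",
            indel_length=int(rec.get("indel_length", 0) or 0),
        )
        pair = extract_context(
            mutation, aln, model, genomes[sp], config.thresholds.flank_bp
        )
        verdict = tally_support(
            pair, load_reads(rec["reads_path"]), config.thresholds
        )
        rows.append(
            {
                "gene": rec["gene"],
                "transcript": rec["transcript"],
                "species": sp,
                "kind": rec["kind"],
                "exon_index": int(rec["exon_index"]),
                "codon_position": int(rec["codon_position"]),
                "n_supporting": verdict.n_supporting,
                "n_ancestral": verdict.n_ancestral,
                "n_uninformative": verdict.n_uninformative,
                "status": verdict.status.value,
            }
        )
    return pd.DataFrame(rows)


def _write_outputs(
    out_dir, mutations, calls, matrix, dollo_df, counts,
    pleiotropy_tests, enrich, validation_df, summary,
) -> None:
    kw = dict(sep="\t", index=False, float_format="%.10g")
    mutations.to_csv(os.path.join(out_dir, "mutations.tsv"), **kw)
    pd.DataFrame(
        [
            {
                "gene": c.gene_id,
                "species": c.species,
                "verdict": c.verdict.value,
                "best_intact_fraction": round(c.best_intact_fraction, 10),
                "exon_fraction_hit": round(c.exon_fraction_hit, 10),
                "n_mutations": c.n_mutations,
                "rationale": c.rationale.value,
            }
            for c in calls
        ],
        columns=[
            "gene", "species", "verdict", "best_intact_fraction",
            "exon_fraction_hit", "n_mutations", "rationale",
        ],
    ).sort_values(["gene", "species"]).to_csv(
        os.path.join(out_dir, "loss_calls.tsv"), **kw
    )
    matrix.to_csv(os.path.join(out_dir, "loss_matrix.tsv"), sep="\t")
    dollo_df.to_csv(os.path.join(out_dir, "dollo.tsv"), **kw)
    counts.to_csv(os.path.join(out_dir, "pheno_counts.tsv"), sep="\t")
    pleiotropy_tests.to_csv(os.path.join(out_dir, "pleiotropy_tests.tsv"), **kw)
    enrich.to_csv(os.path.join(out_dir, "enrichment.tsv"), **kw)
    if validation_df is not None:
        validation_df.to_csv(os.path.join(out_dir, "validation.tsv"), **kw)
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump({"schema_version": 1, **summary}, fh, indent=1, sort_keys=True)
        fh.write("\n")
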