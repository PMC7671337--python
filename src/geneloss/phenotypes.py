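"""Knockout-phenotype propagation and pleiotropy scoring.

Each gene's directly annotated phenotype terms (from single-gene
knockouts only) are propagated up the is_a hierarchy; the number of
distinct terms at ontology levels 2, 3 and 4 is the per-gene pleiotropy
measure.  The bookkeeping level-3 term 'no abnormal phenotype detected'
is excluded from counting, as is the root.  Group comparisons use the
two-sided Wilcoxon rank-sum (Mann-Whitney U) test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .ontology import OntologyDAG

#: 'no abnormal phenotype detected' (MGI identifier), the level-3 child of
#: the 'normal phenotype' branch; never counted as a phenotype.
NO_ABNORMAL_PHENOTYPE = "MP:0002169"
#: 'normal phenotype', the level-2 term whose sole annotation marks a
#: dispensable gene.
NORMAL_PHENOTYPE = "MP:0002873"
#: 'prenatal lethality'
PRENATAL_LETHALITY = "MP:0002080"

#: the normal-phenotype bookkeeping branch is never counted as a phenotype:
#: both the level-3 'no abnormal phenotype detected' term and its level-2
#: 'normal phenotype' parent are excluded by default
DEFAULT_EXCLUDED = frozenset({NO_ABNORMAL_PHENOTYPE, NORMAL_PHENOTYPE})

AnnotationRow = tuple[str, str, int]  # (gene, term, genotype arity)


def filter_single_gene_knockouts(rows: Iterable[AnnotationRow]) -> list[AnnotationRow]:
    """Keep only annotations observed in single-gene (arity-1) knockouts."""
    return [r for r in rows if r[2] == 1]


def direct_annotations(rows: Iterable[AnnotationRow]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for gene, term, _ in rows:
        out.setdefault(gene, set()).add(term)
    return out


def propagate(
    annotations: Mapping[str, set[str]], dag: OntologyDAG
) -> dict[str, set[str]]:
    """Transitive is_a closure of each gene's terms; the root is dropped."""
    closed: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        acc: set[str] = set()
        for term in terms:
            if term not in dag.terms:
                raise KeyError(f"annotation term {term} absent from ontology")
            acc.add(term)
            acc |= dag.ancestors(term)
        acc.discard(dag.root)
        closed[gene] = acc
    return closed


def count_phenotypes(
    closed_terms: set[str],
    dag: OntologyDAG,
    level: int,
    excluded_terms: frozenset[str] = DEFAULT_EXCLUDED,
) -> int:
    """Distinct propagated terms at one level, minus the exclusion list."""
    return sum(
        1
        for t in closed_terms
        if dag.level(t) == level and t not in excluded_terms
    )


def gene_level_counts(
    rows: Iterable[AnnotationRow],
    dag: OntologyDAG,
    levels: Sequence[int] = (2, 3, 4),
    excluded_terms: frozenset[str] = DEFAULT_EXCLUDED,
    ortholog_map: Optional[Mapping[str, str]] = None,
    include_empty: bool = False,
) -> pd.DataFrame:
    """Per-gene phenotype counts at each requested level.

    ``ortholog_map`` translates annotation gene ids (e.g. mouse) to the
    analysis namespace (e.g. human); unmapped genes are dropped.  Genes
    with no surviving annotation are dropped unless ``include_empty``.
    """
    kept = filter_single_gene_knockouts(rows)
    direct = direct_annotations(kept)
    if ortholog_map is not None:
        direct = {
            ortholog_map[g]: t for g, t in direct.items() if g in ortholog_map
        }
    closed = propagate(direct, dag)
    records = []
    for gene in sorted(closed):
        counts = {
            f"level{lv}_count": count_phenotypes(closed[gene], dag, lv, excluded_terms)
            for lv in levels
        }
        if not include_empty and not closed[gene] - excluded_terms:
            continue
        records.append({"gene": gene, **counts})
    return pd.DataFrame(
        records, columns=["gene"] + [f"level{lv}_count" for lv in levels]
    ).set_index("gene")


# ---------------------------------------------------------------------------
# rank-sum comparison

#: exact Mann-Whitney distribution is used up to this group size when the
#: pooled sample has no ties; beyond it, normal approximation with
#: midranks and tie-corrected variance
EXACT_MAX_N = 25


@dataclass(frozen=True)
class RankSumResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    method: str
    rank_biserial: float  # >0: group_a tends to larger values


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], name_a: str = "a", name_b: str = "b"
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test with rank-biserial effect size."""
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = len(set(x) | set(y)) < n1 + n2
    method = "exact" if (not has_ties and min(n1, n2) <= EXACT_MAX_N) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    return RankSumResult(
        group_a=name_a,
        group_b=name_b,
        n_a=n1,
        n_b=n2,
        u_statistic=u1,
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        rank_biserial=2.0 * u1 / (n1 * n2) - 1.0,
    )


def rank_sum_normal_approx(x: Sequence[float], y: Sequence[float]) -> float:
    """Independent normal-approximation p (midranks, tie-corrected variance,
    continuity correction); used as a cross-check of the asymptotic path."""
    n1, n2 = len(x), len(y)
    pooled = list(x) + list(y)
    ranks = stats.rankdata(pooled)
    r1 = float(sum(ranks[:n1]))
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    tie_counts = pd.Series(pooled).value_counts().to_numpy()
    tie_term = float(sum(t**3 - t for t in tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return 1.0
    z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def pleiotropy_compare(
    group_counts: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """All pairwise two-sided rank-sum comparisons between gene groups."""
    names = list(group_counts)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = wilcoxon_rank_sum(group_counts[a], group_counts[b], a, b)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "n_a": r.n_a,
                    "n_b": r.n_b,
                    "u_statistic": r.u_statistic,
                    "p_value": r.p_value,
                    "method": r.method,
                    "rank_biserial": r.rank_biserial,
                }
            )
    return pd.DataFrame(rows)
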