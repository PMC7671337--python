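"""Depletion/enrichment of gene classes among lost genes.

Each loss group (single-lineage, multi-lineage, optionally pooled) is
compared against the no-loss background for membership in the disease /
essential / lethal / dispensable gene classes with a two-sided Fisher's
exact test.  The two-sided p-value follows the probability-mass rule:
the sum of hypergeometric probabilities of all tables (margins fixed)
whose probability does not exceed that of the observed table.  The test
is computed in exact rational arithmetic.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from .ontology import OntologyDAG
from .phenotypes import NORMAL_PHENOTYPE, PRENATAL_LETHALITY

CLASS_LABELS = ("DISEASE", "ESSENTIAL", "LETHAL", "DISPENSABLE")


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p)``.  The odds ratio is the sample value
    a*d/(b*c): ``inf`` when b*c == 0 with a*d > 0, and ``nan`` when both
    products vanish.  The p-value is exact (Fraction arithmetic).
    """
    (a, b), (c, d) = table
    for cell in (a, b, c, d):
        if not isinstance(cell, (int,)) or isinstance(cell, bool) or cell < 0:
            raise ValueError("table cells must be non-negative integers")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return float("nan"), 1.0
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = a * d / (b * c)
    if n > 2000:
        # big-integer enumeration gets slow; scipy implements the same
        # probability-mass rule in floating point
        from scipy.stats import fisher_exact as _scipy_fisher

        return odds, float(_scipy_fisher([[a, b], [c, d]]).pvalue)
    denom = math.comb(n, c1)

    def prob(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    p = sum((pk for k in range(lo, hi + 1) if (pk := prob(k)) <= p_obs), Fraction(0))
    return odds, float(min(p, Fraction(1)))


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (family-wise error control)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def class_enrichment(
    loss_partition: Mapping[str, set[str]],
    classes: Mapping[str, set[str]],
    universe: set[str],
    pooled: bool = False,
    holm: bool = False,
    class_labels: Sequence[str] = CLASS_LABELS,
) -> pd.DataFrame:
    """One Fisher comparison per (class x loss-group vs no-loss).

    ``loss_partition`` must carry ``no_loss`` / ``single_lineage`` /
    ``multi_lineage`` keys covering the universe.  With ``pooled`` the
    two loss groups are additionally tested as one ``any_loss`` group.
    Percentages per group are reported alongside the 2x2 cells.
    """
    covered = set().union(*loss_partition.values())
    if covered != universe:
        raise ValueError("loss partition does not cover the gene universe")
    background = loss_partition["no_loss"] & universe
    groups = {
        "single_lineage": loss_partition["single_lineage"] & universe,
        "multi_lineage": loss_partition["multi_lineage"] & universe,
    }
    if pooled:
        groups["any_loss"] = groups["single_lineage"] | groups["multi_lineage"]
    rows = []
    for label in class_labels:
        members = classes_to_members(classes, label) & universe
        for group_name, group in sorted(groups.items()):
            a = len(group & members)
            b = len(group) - a
            c = len(background & members)
            d = len(background) - c
            odds, p = fisher_exact_two_sided([[a, b], [c, d]])
            if math.isnan(odds) or odds == 1.0:
                direction = "NONE"
            else:
                direction = "DEPLETED" if odds < 1.0 else "ENRICHED"
            rows.append(
                {
                    "class": label,
                    "group": group_name,
                    "in_class_in_group": a,
                    "not_class_in_group": b,
                    "in_class_background": c,
                    "not_class_background": d,
                    "pct_group": 100.0 * a / len(group) if group else float("nan"),
                    "pct_background": (
                        100.0 * c / len(background) if background else float("nan")
                    ),
                    "odds_ratio": odds,
                    "p_value": p,
                    "direction": direction,
                }
            )
    result = pd.DataFrame(rows)
    if holm and len(result):
        result["p_holm"] = holm_adjust(list(result["p_value"]))
    return result


def classes_to_members(classes: Mapping[str, set[str]], label: str) -> set[str]:
    return {g for g, labels in classes.items() if label in labels}


def derive_classes_from_annotations(
    closed: Mapping[str, set[str]],
    dag: OntologyDAG,
) -> dict[str, set[str]]:
    """LETHAL / DISPENSABLE labels from propagated knockout annotations.

    Lethal: annotated (directly or by closure) with 'prenatal lethality'.
    Dispensable: only annotated within the level-2 'normal phenotype'
    branch, i.e. no abnormal phenotype at all.
    """
    normal_branch = {NORMAL_PHENOTYPE} | {
        t for t in dag.terms if NORMAL_PHENOTYPE in dag.ancestors(t)
    }
    out: dict[str, set[str]] = {}
    for gene, terms in closed.items():
        labels = set()
        if PRENATAL_LETHALITY in terms:
            labels.add("LETHAL")
        if terms and terms <= normal_branch:
            labels.add("DISPENSABLE")
        if labels:
            out[gene] = labels
    return out
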