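"""Dollo parsimony over per-gene loss states on the species tree.

An intact gene is a complex character that is never regained once lost,
so a loss shared by sister species is explained by a single event on the
branch to their common ancestor.  Event branches are the maximal
subtrees whose (non-missing) leaves are all lost; leaves without data
are transparent and never break an ancestral grouping.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Union

import dendropy

from .models import LossHistory, LossVerdict

State = Union[str, LossVerdict]


def _norm(state: State) -> str:
    value = state.value if isinstance(state, LossVerdict) else str(state)
    if value == "NO_DATA":
        value = "NA"
    if value not in ("LOST", "INTACT", "NA"):
        raise ValueError(f"leaf state must be LOST/INTACT/NA, got {value!r}")
    return value


def clade_name(node: dendropy.Node) -> str:
    """Branch label: its child clade's sorted comma-joined leaf names."""
    leaves = sorted(leaf.taxon.label for leaf in node.leaf_iter())
    return ",".join(leaves)


def infer_loss_events(
    tree: dendropy.Tree,
    leaf_states: Mapping[str, State],
    gene_id: str = "",
) -> LossHistory:
    """Place loss events on the minimal set of branches covering all lost leaves.

    A branch qualifies when every non-NA leaf below it is LOST and at
    least one leaf below is LOST; events sit on the maximal qualifying
    branches.  With no lost leaves the history is empty.
    """
    states = {label: _norm(s) for label, s in leaf_states.items()}
    qualifies: dict[int, bool] = {}
    events: list[dendropy.Node] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            state = states.get(label, "NA")
            has_lost = state == "LOST"
            all_ok = state != "INTACT"
        else:
            children = node.child_nodes()
            has_lost = any(qualifies[id(c)][0] for c in children)
            all_ok = all(qualifies[id(c)][1] for c in children)
        qualifies[id(node)] = (has_lost, all_ok)
    for node in tree.preorder_node_iter():
        has_lost, all_ok = qualifies[id(node)]
        if not (has_lost and all_ok):
            continue
        parent = node.parent_node
        if parent is None or not (
            qualifies[id(parent)][0] and qualifies[id(parent)][1]
        ):
            events.append(node)
    return LossHistory(
        gene_id=gene_id,
        leaf_states={
            k: LossVerdict("NO_DATA" if v == "NA" else v) for k, v in states.items()
        },
        event_branches=frozenset(clade_name(n) for n in events),
    )


def partition_by_lineage_count(
    histories: Iterable[LossHistory],
) -> dict[str, set[str]]:
    """Split genes into not_lost / single_lineage / multi_lineage sets."""
    parts: dict[str, set[str]] = {
        "not_lost": set(),
        "single_lineage": set(),
        "multi_lineage": set(),
    }
    for h in histories:
        n = h.n_independent_lineages
        key = "not_lost" if n == 0 else ("single_lineage" if n == 1 else "multi_lineage")
        parts[key].add(h.gene_id)
    return parts


def histories_from_matrix(tree: dendropy.Tree, matrix) -> list[LossHistory]:
    """One LossHistory per row of a gene x species LOST/INTACT/NA matrix."""
    out = []
    for gene, row in matrix.iterrows():
        out.append(infer_loss_events(tree, row.to_dict(), gene_id=gene))
    return out
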