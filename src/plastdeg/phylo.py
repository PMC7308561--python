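"""Mapping degradation events onto a rooted phylogeny.

Gene degradation is modelled as an ordered, irreversible process
F (functional) -> P (pseudogene) -> D (deleted): once a gene is pseudogenized
it never regains function, and once deleted it never returns (the Dollo
assumption for gene loss). Ancestral states are reconstructed per gene by
Sankoff dynamic programming over {F, P, D} with step costs F->P = 1,
P->D = 1, F->D = 2 and infinite cost for any reversal; the root is fixed to F
because the reference lineage is autotrophic. Equal-cost reconstructions are
resolved by DELTRAN: transformations are delayed toward the tips.

The tree is an input (Newick); tree inference is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

STATES = ("F", "P", "D")
# cost[parent][child]; degradation is irreversible
TRANSITION_COST = {
    "F": {"F": 0, "P": 1, "D": 2},
    "P": {"F": math.inf, "P": 0, "D": 1},
    "D": {"F": math.inf, "P": math.inf, "D": 0},
}


class TreeError(ValueError):
    """The input tree or its pairing with the matrix is invalid."""


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree, preserving labels and branch lengths.

    ``source`` may be a path or a Newick string. Duplicate tip labels and
    unbalanced parentheses raise :class:`TreeError`.
    """
    text = None
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        p = Path(source)
        is_pathlike = source.strip().endswith((".nwk", ".tre", ".newick", ".txt"))
        text = p.read_text() if (is_pathlike and p.exists()) else source
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise TreeError(f"invalid Newick input: {exc}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def branch_key(node: dendropy.Node) -> frozenset[str]:
    """Canonical identifier of the branch above ``node``: its tip set."""
    return frozenset(l.taxon.label for l in node.leaf_iter())


def branch_label(node: dendropy.Node) -> str:
    """Human-readable branch name for reports."""
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return "mrca(" + ",".join(sorted(l.taxon.label for l in node.leaf_iter())) + ")"


@dataclass
class EventMap:
    """Per-branch degradation events from an ancestral reconstruction.

    ``events`` maps the branch key (tip set of the child node) to a list of
    ``(gene, transition)`` pairs with transitions in {F->P, P->D, F->D}.
    ``node_states`` holds the full reconstruction per gene.
    """

    events: dict[frozenset[str], list[tuple[str, str]]]
    total_cost: int
    tie_break: str = "DELTRAN"
    node_states: dict[str, dict[frozenset[str], str]] = field(default_factory=dict)
    branch_labels: dict[frozenset[str], str] = field(default_factory=dict)

    def per_gene_cost(self) -> dict[str, int]:
        cost_of = {"F->P": 1, "P->D": 1, "F->D": 2}
        out: dict[str, int] = {}
        for evs in self.events.values():
            for gene, tr in evs:
                out[gene] = out.get(gene, 0) + cost_of[tr]
        return out

    def to_rows(self) -> list[dict]:
        rows = []
        for key in sorted(self.events, key=lambda k: (len(k), sorted(k))):
            for gene, tr in sorted(self.events[key]):
                rows.append(
                    {
                        "branch": self.branch_labels.get(key, ",".join(sorted(key))),
                        "gene": gene,
                        "transition": tr,
                    }
                )
        return rows


def _sankoff_gene(
    tree: dendropy.Tree, tip_states: dict[str, str]
) -> tuple[int, dict[dendropy.Node, str]]:
    """Minimum-cost irreversible assignment for one gene; DELTRAN on ties."""
    cost: dict[dendropy.Node, list[float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = tip_states[node.taxon.label]
            cost[node] = [0.0 if st == s else math.inf for st in STATES]
        else:
            vec = []
            for st in STATES:
                total = 0.0
                for child in node.child_nodes():
                    total += min(
                        TRANSITION_COST[st][cs] + cost[child][j]
                        for j, cs in enumerate(STATES)
                    )
                vec.append(total)
            cost[node] = vec
    root = tree.seed_node
    root_cost = cost[root][STATES.index("F")]
    if math.isinf(root_cost):
        raise TreeError("infeasible reconstruction with root fixed to F")
    # top-down assignment; among cost ties prefer the least-derived state
    # (F before P before D), which delays transformations toward the tips
    assign: dict[dendropy.Node, str] = {root: "F"}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        ps = assign[node.parent_node]
        options = [
            (TRANSITION_COST[ps][cs] + cost[node][j], j)
            for j, cs in enumerate(STATES)
        ]
        best = min(o[0] for o in options)
        j = min(j for c, j in options if c == best)  # F < P < D order
        assign[node] = STATES[j]
    return int(root_cost), assign


def reconstruct_events(
    tree: dendropy.Tree,
    matrix,
    root_state: str = "F",
) -> EventMap:
    """Reconstruct per-branch degradation events for every gene in a matrix.

    ``matrix`` is a :class:`~plastdeg.genestatus.DegradationMatrix` or a
    pandas DataFrame (index = species matching the tip labels, columns =
    genes, cells in {"F", "P", "D"}). The root is fixed functional for every
    gene of the panel. Genes are independent, so the total cost is the sum of
    per-gene minima.
    """
    if root_state != "F":
        raise TreeError("the root of an autotrophic reference lineage must be F")
    table = matrix.table if hasattr(matrix, "table") else matrix
    tips = tip_labels(tree)
    missing = [t for t in tips if t not in table.index]
    if missing:
        raise TreeError(f"tips missing from the matrix: {missing}")
    events: dict[frozenset[str], list[tuple[str, str]]] = {}
    node_states: dict[str, dict[frozenset[str], str]] = {}
    labels = {branch_key(n): branch_label(n) for n in tree.preorder_node_iter()}
    total = 0
    for gene in table.columns:
        tip_states = {t: str(table.at[t, gene]) for t in tips}
        bad = {s for s in tip_states.values() if s not in STATES}
        if bad:
            raise TreeError(f"gene {gene}: invalid states {sorted(bad)}")
        gcost, assign = _sankoff_gene(tree, tip_states)
        total += gcost
        node_states[gene] = {branch_key(n): s for n, s in assign.items()}
        for node, state in assign.items():
            parent = node.parent_node
            if parent is None:
                continue
            pstate = assign[parent]
            if pstate != state:
                events.setdefault(branch_key(node), []).append(
                    (gene, f"{pstate}->{state}")
                )
    return EventMap(
        events=events,
        total_cost=total,
        node_states=node_states,
        branch_labels=labels,
    )


def annotate_tree(tree: dendropy.Tree, event_map: EventMap) -> str:
    """Serialize the tree as Newick with per-branch event comments.

    Each branch carrying events gets a bracketed comment separating losses
    (transitions into D) from pseudogenizations (F->P), e.g.
    ``[&loss=ndhF,ndhI|pseudo=ccsA]``. A zero-event map yields plain Newick.
    """

    def comment(node) -> str:
        evs = event_map.events.get(branch_key(node), [])
        if not evs:
            return ""
        losses = sorted(g for g, tr in evs if tr.endswith("D"))
        pseudos = sorted(g for g, tr in evs if tr == "F->P")
        parts = []
        if losses:
            parts.append("loss=" + ",".join(losses))
        if pseudos:
            parts.append("pseudo=" + ",".join(pseudos))
        return "[&" + "|".join(parts) + "]"

    def render(node) -> str:
        if node.is_leaf():
            base = node.taxon.label
        else:
            base = (
                "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
                + (node.label or "")
            )
        blen = "" if node.edge.length is None else f":{node.edge.length:g}"
        return base + blen + comment(node)

    return render(tree.seed_node) + ";"
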