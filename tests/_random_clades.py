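"""Random synthetic clade specifications for property tests."""

from __future__ import annotations

import numpy as np

from plastdeg.model import GeneCategory
from plastdeg.simulate import EventSpec, GeneSpec, SynthSpec

P, T, R = GeneCategory.PROTEIN_CODING, GeneCategory.TRNA, GeneCategory.RRNA

_POOL = [
    ("rbcL", P, "LSC"), ("matK", P, "LSC"), ("infA", P, "LSC"),
    ("ndhC", P, "LSC"), ("ndhJ", P, "LSC"), ("trnV-UAC", T, "LSC"),
    ("trnG-UCC", T, "LSC"), ("ndhB", P, "IR"), ("rrn16", R, "IR"),
    ("trnN-GUU", T, "IR"), ("ndhF", P, "SSC"), ("ndhA", P, "SSC"),
    ("ccsA", P, "SSC"), ("trnL-UAG", T, "SSC"),
]
_REGION_BUDGET = {"LSC": 1300, "IR": 520, "SSC": 430}


def _random_tree(rng: np.random.Generator, n_tips: int) -> tuple[str, list[str]]:
    """Random rooted binary tree over sp1..spN with labeled internal nodes,
    plus the list of all branch labels (nodes below the root)."""
    counter = [0]

    def label():
        counter[0] += 1
        return f"n{counter[0]}"

    nodes = [f"sp{i+1}" for i in range(n_tips)]
    newicks = {n: n for n in nodes}
    branchable = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop higher index first
        nodes.pop(j)
        nodes.pop(i)
        lab = label()
        newicks[lab] = f"({newicks[a]},{newicks[b]}){lab}"
        nodes.append(lab)
        branchable.append(lab)
    ingroup = nodes[0]
    # the ingroup stem is a branch; the root itself is not
    tree = f"(REF,{newicks[ingroup]})root;"
    return tree, branchable


def random_spec(seed: int) -> SynthSpec:
    """A random small clade: 3-8 tips, 5-10 genes, up to 10 planted events."""
    rng = np.random.default_rng(seed)
    n_tips = int(rng.integers(3, 9))
    tree, branches = _random_tree(rng, n_tips)

    picks = rng.permutation(len(_POOL))[: int(rng.integers(5, 11))]
    used = {"LSC": 0, "IR": 0, "SSC": 0}
    panel: list[GeneSpec] = []
    for idx in picks:
        name, cat, region = _POOL[int(idx)]
        if cat is P:
            length = int(rng.integers(50, 150)) * 3
        else:
            length = int(rng.integers(60, 101))
        if used[region] + length + 20 > _REGION_BUDGET[region]:
            continue
        used[region] += length + 20
        strand = "+" if rng.random() < 0.5 else "-"
        panel.append(GeneSpec(name, cat, length, region, strand))
    if not panel:  # ensure a non-empty panel
        panel = [GeneSpec("rbcL", P, 300, "LSC", "+")]

    events: list[EventSpec] = []
    n_events = int(rng.integers(0, 11))
    gene_order = rng.permutation(len(panel))
    pseudogenized: list[tuple[str, str]] = []  # (gene, branch) for chaining
    for k in range(min(n_events, len(panel))):
        g = panel[int(gene_order[k])]
        branch = branches[int(rng.integers(len(branches)))]
        if g.category is P:
            kind = ["delete", "frameshift", "premature_stop"][int(rng.integers(3))]
        else:
            kind = "delete"
        if kind == "frameshift":
            ev = EventSpec(branch, g.name, "frameshift",
                           offset=int(rng.integers(3, g.length - 3)),
                           indel="del" if rng.random() < 0.5 else "ins")
            pseudogenized.append((g.name, branch))
        elif kind == "premature_stop":
            ev = EventSpec(branch, g.name, "premature_stop",
                           codon=int(rng.integers(1, g.length // 3 - 1)))
            pseudogenized.append((g.name, branch))
        else:
            ev = EventSpec(branch, g.name, "delete")
        events.append(ev)

    return SynthSpec(
        seed=int(rng.integers(0, 2**31 - 1)),
        lsc_len=int(rng.integers(2300, 3200)),
        ssc_len=int(rng.integers(550, 1000)),
        ir_len=int(rng.integers(650, 1000)),
        gene_panel=panel,
        tree=tree,
        events=events,
    )
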