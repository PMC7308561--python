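"""Synthetic annotated plastomes with planted ground truth.

The generator emulates the features of real plastomes that the pipeline
measures: a circular LSC + IRb + SSC + IRa layout with IRa the exact reverse
complement of IRb, a region-specific GC gradient (IR > LSC > SSC), a panel of
protein-coding/tRNA/rRNA genes on both strands — including genes duplicated
in the repeat and a gene spanning the LSC/IRb junction — and planted
degradation events: whole-gene deletions, 1-bp frameshifts, and in-frame
premature stop substitutions, placed on the branches of a supplied clade
tree. Everything is deterministic under a fixed seed, and the returned truth
object records exactly what the pipeline should recover.

Planted repeats are made *maximal* by construction: after assembly the bases
flanking each junction are adjusted so that no chance complementarity
extends the repeat pair past the planted boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from Bio.Seq import reverse_complement

from . import phylo
from .model import GeneCategory, GeneFeature, Lifeform, PlastomeRecord

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
STOPS = {"TAA", "TAG", "TGA"}


class SpecError(ValueError):
    """The synthetic specification is internally inconsistent."""


@dataclass(frozen=True)
class GeneSpec:
    """One gene of the synthetic panel.

    ``region`` places the gene in LSC, SSC, or IR (IR genes are implicitly
    duplicated: the mirror copy in IRa comes for free from reverse
    complementarity). ``cross_junction="JLB"`` instead plants the gene across
    the LSC/IRb boundary.
    """

    name: str
    category: GeneCategory
    length: int
    region: str = "LSC"  # LSC | SSC | IR
    strand: str = "+"
    cross_junction: str | None = None

    def __post_init__(self):
        if self.region not in ("LSC", "SSC", "IR"):
            raise SpecError(f"{self.name}: unknown region {self.region!r}")
        if self.cross_junction not in (None, "JLB"):
            raise SpecError(f"{self.name}: only JLB-crossing genes are supported")
        if self.category is GeneCategory.PROTEIN_CODING:
            if self.length % 3 or self.length < 9:
                raise SpecError(
                    f"{self.name}: protein-coding length must be a positive "
                    f"multiple of 3, got {self.length}"
                )
        elif self.length < 30:
            raise SpecError(f"{self.name}: RNA gene shorter than 30 bp")


@dataclass(frozen=True)
class EventSpec:
    """One planted degradation event on one branch of the clade tree.

    ``branch`` names the tree node (tip label or internal node label) whose
    parent edge carries the event. ``kind`` is ``delete``, ``frameshift``
    (1-bp indel at ``offset`` within the spliced gene; ``indel`` chooses
    insertion or deletion), or ``premature_stop`` (rewrite ``codon`` to TAA).
    """

    branch: str
    gene: str
    kind: str
    offset: int = 30
    codon: int = 10
    indel: str = "del"

    def __post_init__(self):
        if self.kind not in ("delete", "frameshift", "premature_stop"):
            raise SpecError(f"unknown event kind {self.kind!r}")
        if self.indel not in ("del", "ins"):
            raise SpecError(f"frameshift indel must be 'del' or 'ins'")


@dataclass
class SynthSpec:
    """Full specification of a synthetic clade."""

    seed: int = 0
    lsc_len: int = 84_000
    ssc_len: int = 15_000
    ir_len: int = 25_000
    gc: dict = field(default_factory=lambda: {"LSC": 36.0, "IR": 43.0, "SSC": 31.0})
    gene_panel: list[GeneSpec] = field(default_factory=list)
    tree: str = "(REF,(sp1,sp2));"
    events: list[EventSpec] = field(default_factory=list)
    reference_tip: str = "REF"

    def __post_init__(self):
        if min(self.lsc_len, self.ssc_len, self.ir_len) < 2:
            raise SpecError("region lengths must be at least 2 bp")
        if self.ssc_len > self.lsc_len:
            raise SpecError("SSC must not exceed LSC (definitional)")
        names = [g.name for g in self.gene_panel]
        if len(set(names)) != len(names):
            raise SpecError("duplicate gene names in panel")
        panel = set(names)
        for ev in self.events:
            if ev.gene not in panel:
                raise SpecError(f"event references unknown gene {ev.gene!r}")
        crossers = {g.name for g in self.gene_panel if g.cross_junction}
        for ev in self.events:
            if ev.gene in crossers:
                raise SpecError(
                    f"events on junction-spanning genes are not supported ({ev.gene})"
                )


@dataclass
class SynthTruth:
    """Ground truth for one generated clade."""

    region_lengths: dict[str, tuple[int, int, int]]  # species -> (lsc, ir, ssc)
    status: dict[str, dict[str, str]]  # species -> gene -> F/P/D
    branch_events: dict[frozenset, list[tuple[str, str]]]
    gene_panel: list[str] = field(default_factory=list)


# --- sequence helpers -------------------------------------------------------

def _background(rng: np.random.Generator, n: int, gc_pct: float) -> list[str]:
    g = gc_pct / 200.0
    a = (100.0 - gc_pct) / 200.0
    return list(rng.choice(_BASES, size=n, p=[a, g, g, a]))


def _sense_codons(rng: np.random.Generator, k: int) -> str:
    out = []
    while len(out) < k:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in STOPS:
            out.append(codon)
    return "".join(out)


def _gene_sequence(rng: np.random.Generator, spec: GeneSpec) -> str:
    if spec.category is GeneCategory.PROTEIN_CODING:
        return "ATG" + _sense_codons(rng, spec.length // 3 - 2) + "TAA"
    return "".join(rng.choice(_BASES, size=spec.length))


# --- reference genome -------------------------------------------------------

_PAD = 12  # gene-free bases kept at every region edge


def _layout(spec: SynthSpec) -> dict[str, list[tuple[GeneSpec, int]]]:
    """Assign region-local start coordinates to every panel gene."""
    by_region = {"LSC": [], "IR": [], "SSC": []}
    crosser = None
    for g in spec.gene_panel:
        if g.cross_junction == "JLB":
            if crosser is not None:
                raise SpecError("at most one JLB-crossing gene is supported")
            crosser = g
        else:
            by_region[g.region].append(g)
    region_len = {"LSC": spec.lsc_len, "IR": spec.ir_len, "SSC": spec.ssc_len}
    placed: dict[str, list[tuple[GeneSpec, int]]] = {"LSC": [], "IR": [], "SSC": []}
    # the crosser occupies the tail of LSC and the head of IRb
    lsc_tail = ir_head = 0
    if crosser is not None:
        in_lsc = max(3, 2 * crosser.length // 3)
        in_ir = crosser.length - in_lsc
        if in_ir < 1:
            raise SpecError(f"{crosser.name}: too short to span JLB")
        lsc_tail, ir_head = in_lsc, in_ir
    for region, genes in by_region.items():
        total = sum(g.length for g in genes)
        reserved = 2 * _PAD + (lsc_tail if region == "LSC" else 0) + (
            ir_head if region == "IR" else 0
        )
        free = region_len[region] - reserved - total
        if genes and free < 8 * len(genes):
            raise SpecError(f"gene panel overflows region {region}")
        gap = free // (len(genes) + 1) if genes else 0
        pos = _PAD + (ir_head if region == "IR" else 0)
        for g in genes:
            pos += gap
            placed[region].append((g, pos))
            pos += g.length
    if crosser is not None:
        placed["LSC"].append((crosser, spec.lsc_len - lsc_tail))
    return placed


def generate_reference(spec: SynthSpec) -> tuple[PlastomeRecord, SynthTruth]:
    """Build the autotrophic reference plastome and its ground truth.

    The sequence is LSC + IRb + SSC + revcomp(IRb); each protein-coding gene
    is a start codon, sense codons, and a stop codon, so the reference panel
    is frameshift- and premature-stop-free by construction. Deterministic
    under ``spec.seed``.
    """
    rng = np.random.default_rng([spec.seed, 0])
    l, r, s = spec.lsc_len, spec.ir_len, spec.ssc_len
    lsc = _background(rng, l, spec.gc.get("LSC", 36.0))
    irb = _background(rng, r, spec.gc.get("IR", 43.0))
    ssc = _background(rng, s, spec.gc.get("SSC", 31.0))
    regions = {"LSC": (lsc, 0), "IR": (irb, l), "SSC": (ssc, l + r)}

    placed = _layout(spec)
    features: list[GeneFeature] = []
    gene_seqs: dict[str, str] = {}
    for region, genes in placed.items():
        buf, offset = regions[region]
        for g, local in genes:
            seq = _gene_sequence(rng, g)
            gene_seqs[g.name] = seq
            written = seq if g.strand == "+" else reverse_complement(seq)
            if g.cross_junction == "JLB":
                # tail of LSC then head of IRb
                cut = l - local
                lsc[local:] = written[:cut]
                irb[: len(written) - cut] = written[cut:]
                features.append(
                    GeneFeature(g.name, g.category, g.strand,
                                ((local, local + g.length),))
                )
                continue
            buf[local : local + g.length] = written
            start = offset + local
            features.append(
                GeneFeature(g.name, g.category, g.strand, ((start, start + g.length),))
            )
            if region == "IR":
                # mirror copy in IRa, reverse-complemented in place
                ira_start = l + r + s
                ms = ira_start + (r - (local + g.length))
                features.append(
                    GeneFeature(
                        g.name, g.category, "+" if g.strand == "-" else "-",
                        ((ms, ms + g.length),),
                    )
                )

    seq = "".join(lsc) + "".join(irb) + "".join(ssc) + reverse_complement("".join(irb))
    seq = list(seq)
    n = l + s + 2 * r
    # block chance extension of the repeat pair past the planted junctions
    if seq[0] == _COMP[seq[l - 1]]:
        choices = [b for b in "ACGT" if b != _COMP[seq[l - 1]]]
        seq[0] = choices[int(rng.integers(len(choices)))]
    if seq[l + r] == _COMP[seq[l + r + s - 1]]:
        choices = [b for b in "ACGT" if b != _COMP[seq[l + r + s - 1]]]
        seq[l + r] = choices[int(rng.integers(len(choices)))]

    record = PlastomeRecord(
        record_id=spec.reference_tip,
        species=spec.reference_tip,
        lifeform=Lifeform.AUTOTROPH,
        sequence="".join(seq),
        circular=True,
        features=sorted(features, key=lambda f: (f.start, f.gene_name)),
    )
    truth = SynthTruth(
        region_lengths={spec.reference_tip: (l, r, s)},
        status={spec.reference_tip: {g.name: "F" for g in spec.gene_panel}},
        branch_events={},
        gene_panel=[g.name for g in spec.gene_panel],
    )
    return record, truth


# --- event application ------------------------------------------------------

def _mirror(pos: int, irb: tuple[int, int], ira: tuple[int, int]) -> int:
    """Map a position in IRb to its reverse-complement twin in IRa (and back)."""
    if irb[0] <= pos < irb[1]:
        return ira[0] + (irb[1] - 1 - pos)
    if ira[0] <= pos < ira[1]:
        return irb[0] + (ira[1] - 1 - pos)
    return pos


def _feature_copies(record: PlastomeRecord, gene: str) -> list[GeneFeature]:
    copies = [f for f in record.features if f.gene_name == gene]
    if not copies:
        raise SpecError(f"gene {gene} not present in reference record")
    return copies


def apply_events(
    record: PlastomeRecord,
    events: list[EventSpec],
    boundaries: tuple[int, int, int],
    rng: np.random.Generator,
) -> tuple[PlastomeRecord, tuple[int, int, int], dict[str, str]]:
    """Apply one species' degradation events to a copy of the reference.

    ``boundaries`` are the reference (lsc, ir, ssc) lengths. IR-resident
    genes are edited symmetrically in both repeat copies, so IRa remains the
    exact reverse complement of IRb. Returns the mutated record, the new
    region lengths, and the per-gene status implied by the events.

    Two events of conflicting type on the same gene raise :class:`SpecError`
    (a deleted gene cannot be further mutated).
    """
    l, r, s = boundaries
    n = len(record.sequence)
    irb_iv = (l, l + r)
    ira_iv = (l + r + s, n)
    seq = list(record.sequence)
    feats = {f.gene_name: _feature_copies(record, f.gene_name) for f in record.features}

    by_gene: dict[str, list[EventSpec]] = {}
    for ev in events:
        by_gene.setdefault(ev.gene, []).append(ev)
    status: dict[str, str] = {g: "F" for g in feats}
    edits: list[tuple] = []  # ("del", start, end) | ("ins", pos, base) | ("sub", pos, base)
    dropped_genes: set[str] = set()
    for gene, evs in by_gene.items():
        kinds = [e.kind for e in evs]
        pseudo_evs = [e for e in evs if e.kind in ("frameshift", "premature_stop")]
        if len(pseudo_evs) > 1 or kinds.count("delete") > 1:
            raise SpecError(f"conflicting events on gene {gene}")
        copies = _feature_copies(record, gene)
        if "delete" in kinds:
            status[gene] = "D"
            dropped_genes.add(gene)
            for f in copies:
                for a, b in f.intervals:
                    edits.append(("del", a, b))
        elif pseudo_evs:
            ev = pseudo_evs[0]
            status[gene] = "P"
            f = copies[0]
            cat = f.category
            if ev.kind == "frameshift":
                a, b = f.intervals[0]
                if not (0 < ev.offset < f.span_length - 1):
                    raise SpecError(f"{gene}: frameshift offset out of range")
                pos = a + ev.offset if f.strand == "+" else b - 1 - ev.offset
                if ev.indel == "del":
                    edits.append(("del", pos, pos + 1))
                    if len(copies) > 1:
                        m = _mirror(pos, irb_iv, ira_iv)
                        edits.append(("del", m, m + 1))
                else:
                    base = str(rng.choice(_BASES))
                    edits.append(("ins", pos, base))
                    if len(copies) > 1:
                        # revcomp symmetry: the twin base lands one past the
                        # mirror point, complemented
                        edits.append(
                            ("ins", _mirror(pos, irb_iv, ira_iv) + 1, _COMP[base])
                        )
            else:  # premature stop
                if cat is not GeneCategory.PROTEIN_CODING:
                    raise SpecError(f"{gene}: premature stop needs a reading frame")
                a, b = f.intervals[0]
                ncod = f.span_length // 3
                if not (0 < ev.codon < ncod - 1):
                    raise SpecError(f"{gene}: stop codon index out of range")
                if f.strand == "+":
                    p0 = a + 3 * ev.codon
                    repl = "TAA"
                else:
                    p0 = b - 3 * (ev.codon + 1)
                    repl = reverse_complement("TAA")
                positions = list(range(p0, p0 + 3))
                for i, p in enumerate(positions):
                    edits.append(("sub", p, repl[i]))
                if len(copies) > 1:
                    for i, p in enumerate(positions):
                        edits.append(("sub", _mirror(p, irb_iv, ira_iv), _COMP[repl[i]]))

    # apply substitutions first (no coordinate shifts), then indels high->low
    for kind, pos, val in [e for e in edits if e[0] == "sub"]:
        seq[pos] = val
    shifts = sorted(
        [e for e in edits if e[0] in ("del", "ins")], key=lambda e: -e[1]
    )
    bnd = [l, l + r, l + r + s, n]  # region end boundaries

    def map_del(x: int, s0: int, e0: int) -> int:
        if x <= s0:
            return x
        if x >= e0:
            return x - (e0 - s0)
        return s0

    surviving = [
        f for f in record.features if f.gene_name not in dropped_genes
    ]
    for ed in shifts:
        if ed[0] == "del":
            _, s0, e0 = ed
            del seq[s0:e0]
            bnd = [map_del(x, s0, e0) for x in bnd]
            surviving = [
                replace(
                    f,
                    intervals=tuple(
                        (map_del(a, s0, e0), map_del(b, s0, e0)) for a, b in f.intervals
                    ),
                )
                for f in surviving
            ]
        else:
            _, p, base = ed
            seq.insert(p, base)
            bnd = [x + 1 if x > p else x for x in bnd]
            surviving = [
                replace(
                    f,
                    intervals=tuple(
                        (a + 1 if a >= p else a, b + 1 if b > p else b)
                        for a, b in f.intervals
                    ),
                )
                for f in surviving
            ]

    new_l, new_r, new_s = bnd[0], bnd[1] - bnd[0], bnd[2] - bnd[1]
    mutated = PlastomeRecord(
        record_id=record.record_id,
        species=record.species,
        lifeform=Lifeform.UNKNOWN,
        sequence="".join(seq),
        circular=True,
        features=sorted(surviving, key=lambda f: (f.start, f.gene_name)),
    )
    return mutated, (new_l, new_r, new_s), status


# --- clade generation -------------------------------------------------------

@dataclass
class SynthClade:
    reference: PlastomeRecord
    records: dict[str, PlastomeRecord]  # tip label -> record (incl. reference tip)
    tree: dendropy.Tree
    newick: str
    truth: SynthTruth


def generate_clade(spec: SynthSpec) -> SynthClade:
    """Generate records for every tip of the spec tree plus full truth.

    Each tip carries the union of the events on its root-to-tip path. A gene
    may progress along a path (frameshift/stop on one branch, deletion on a
    descendant branch); regaining a lost gene, or conflicting events, raise
    :class:`SpecError`. Truth branch events record the implied transition
    (F->P, P->D, or F->D) keyed by the branch's descendant tip set.
    """
    reference, truth = generate_reference(spec)
    tree = phylo.read_newick(spec.tree)
    nodes_by_label: dict[str, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.is_leaf() else node.label
        if label:
            if label in nodes_by_label:
                raise SpecError(f"duplicate node label in tree: {label}")
            nodes_by_label[label] = node

    events_by_node: dict[dendropy.Node, list[EventSpec]] = {}
    for ev in spec.events:
        node = nodes_by_label.get(ev.branch)
        if node is None:
            raise SpecError(f"event branch {ev.branch!r} not found in tree")
        if node is tree.seed_node:
            raise SpecError("events cannot be placed above the root")
        events_by_node.setdefault(node, []).append(ev)

    # truth branch events, with path validation
    branch_events: dict[frozenset, list[tuple[str, str]]] = {}
    for node, evs in events_by_node.items():
        key = phylo.branch_key(node)
        for ev in evs:
            # state of the gene just above this branch
            anc_state = "F"
            anc = node.parent_node
            while anc is not None:
                for aev in events_by_node.get(anc, []):
                    if aev.gene == ev.gene:
                        anc_state = "D" if aev.kind == "delete" else "P"
                anc = anc.parent_node
            if anc_state == "D":
                raise SpecError(
                    f"gene {ev.gene}: event below a deletion on the same path"
                )
            if ev.kind == "delete":
                branch_events.setdefault(key, []).append(
                    (ev.gene, f"{anc_state}->D")
                )
            else:
                if anc_state == "P":
                    raise SpecError(f"gene {ev.gene}: double pseudogenization on path")
                branch_events.setdefault(key, []).append((ev.gene, "F->P"))

    records: dict[str, PlastomeRecord] = {}
    ref_boundaries = (spec.lsc_len, spec.ir_len, spec.ssc_len)
    for k, leaf in enumerate(tree.leaf_node_iter()):
        label = leaf.taxon.label
        path_events: list[EventSpec] = []
        node = leaf
        while node is not None:
            path_events = events_by_node.get(node, []) + path_events
            node = node.parent_node
        if label == spec.reference_tip:
            if path_events:
                raise SpecError("events on the reference lineage are not allowed")
            rec = replace_record_id(reference, label)
            records[label] = rec
            continue
        # a pseudogenizing event is subsumed by a later deletion of the gene
        final: dict[str, EventSpec] = {}
        for ev in path_events:
            prev = final.get(ev.gene)
            if prev is None or (prev.kind != "delete" and ev.kind == "delete"):
                final[ev.gene] = ev
        rng = np.random.default_rng([spec.seed, 1000 + k])
        rec, bounds, status = apply_events(
            replace_record_id(reference, label), list(final.values()),
            ref_boundaries, rng,
        )
        records[label] = rec
        truth.region_lengths[label] = bounds
        truth.status[label] = status
    truth.branch_events = branch_events
    return SynthClade(
        reference=reference,
        records=records,
        tree=tree,
        newick=spec.tree,
        truth=truth,
    )


def replace_record_id(record: PlastomeRecord, new_id: str) -> PlastomeRecord:
    return PlastomeRecord(
        record_id=new_id,
        species=new_id,
        lifeform=record.lifeform,
        sequence=record.sequence,
        circular=record.circular,
        features=list(record.features),
    )


def write_genbank(record: PlastomeRecord, path) -> None:
    """Write a synthetic record as a GenBank flat file.

    Each gene copy becomes one typed feature (CDS/tRNA/rRNA) with a ``gene``
    qualifier; pseudo flags become ``/pseudo``. Coordinates convert back to
    GenBank 1-based inclusive form via Biopython.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    type_of = {
        GeneCategory.PROTEIN_CODING: "CDS",
        GeneCategory.TRNA: "tRNA",
        GeneCategory.RRNA: "rRNA",
    }
    sr = SeqRecord(
        Seq(record.sequence),
        id=record.record_id,
        name=record.record_id[:16].replace(" ", "_"),
        description=f"{record.species} synthetic plastome",
    )
    sr.annotations["molecule_type"] = "DNA"
    sr.annotations["topology"] = "circular" if record.circular else "linear"
    sr.annotations["organism"] = record.species or record.record_id
    for f in record.features:
        strand = 1 if f.strand == "+" else -1
        parts = [SimpleLocation(s, e, strand) for s, e in f.intervals]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        quals = {"gene": [f.gene_name]}
        if f.pseudo_flag:
            quals["pseudo"] = [None]
        sr.features.append(SeqFeature(loc, type=type_of[f.category], qualifiers=quals))
    SeqIO.write(sr, str(path), "genbank")


# --- canonical specifications ----------------------------------------------

def default_panel() -> list[GeneSpec]:
    """A realistic plastid gene panel exercising every placement the pipeline
    must handle: both strands, IR duplication, a JLB-spanning gene, and the
    gene families whose degradation the pipeline tracks (ndh, infA, matK,
    ribosomal proteins, tRNAs with anticodon suffixes, the four rRNAs)."""
    P, T, R = GeneCategory.PROTEIN_CODING, GeneCategory.TRNA, GeneCategory.RRNA
    return [
        GeneSpec("psbA", P, 1062, "LSC", "-"),
        GeneSpec("matK", P, 1500, "LSC", "-"),
        GeneSpec("atpA", P, 1524, "LSC", "-"),
        GeneSpec("rbcL", P, 1428, "LSC", "+"),
        GeneSpec("infA", P, 234, "LSC", "-"),
        GeneSpec("rps16", P, 261, "LSC", "-"),
        GeneSpec("ndhC", P, 363, "LSC", "-"),
        GeneSpec("ndhJ", P, 477, "LSC", "-"),
        GeneSpec("ndhK", P, 678, "LSC", "-"),
        GeneSpec("trnV-UAC", T, 72, "LSC", "-"),
        GeneSpec("trnG-UCC", T, 71, "LSC", "+"),
        GeneSpec("trnH-GUG", T, 74, "LSC", "-"),
        GeneSpec("rps19", P, 279, "LSC", "-", cross_junction="JLB"),
        GeneSpec("ndhB", P, 1533, "IR", "-"),
        GeneSpec("rrn16", R, 1491, "IR", "+"),
        GeneSpec("rrn23", R, 2811, "IR", "+"),
        GeneSpec("rrn4.5", R, 103, "IR", "+"),
        GeneSpec("rrn5", R, 121, "IR", "+"),
        GeneSpec("trnR-ACG", T, 74, "IR", "+"),
        GeneSpec("trnN-GUU", T, 72, "IR", "-"),
        GeneSpec("ndhF", P, 2241, "SSC", "-"),
        GeneSpec("ndhA", P, 1092, "SSC", "-"),
        GeneSpec("ndhH", P, 1182, "SSC", "-"),
        GeneSpec("ndhI", P, 501, "SSC", "-"),
        GeneSpec("ndhG", P, 531, "SSC", "-"),
        GeneSpec("ndhE", P, 306, "SSC", "-"),
        GeneSpec("ccsA", P, 966, "SSC", "+"),
        GeneSpec("trnL-UAG", T, 80, "SSC", "-"),
    ]


DEFAULT_TREE = "(REF,(sp1,((sp2,sp3)clade23,(sp4,sp5)clade45)core)ingroup)root;"


def default_events() -> list[EventSpec]:
    """Degradation pattern echoing what hemiparasitic clades show: deep,
    shared ndh degradation, lineage-specific tRNA losses, late completion of
    a pseudogenization into a physical loss."""
    return [
        EventSpec("ingroup", "ndhC", "frameshift", offset=31),
        EventSpec("ingroup", "infA", "premature_stop", codon=20),
        EventSpec("clade45", "ndhF", "delete"),
        EventSpec("clade45", "ndhI", "delete"),
        EventSpec("clade45", "ccsA", "premature_stop", codon=100),
        EventSpec("clade23", "ndhB", "premature_stop", codon=200),
        EventSpec("sp1", "trnV-UAC", "delete"),
        EventSpec("sp2", "matK", "frameshift", offset=500, indel="ins"),
        EventSpec("sp5", "ndhC", "delete"),  # P -> D completion
    ]


def default_spec(seed: int = 0) -> SynthSpec:
    """Study-scale clade: ~149 kb genomes, full panel, six tips."""
    return SynthSpec(
        seed=seed,
        lsc_len=84_000,
        ssc_len=15_000,
        ir_len=25_000,
        gene_panel=default_panel(),
        tree=DEFAULT_TREE,
        events=default_events(),
    )


def toy_spec(seed: int = 0) -> SynthSpec:
    """Small clade (~6.4 kb genomes) with the same qualitative structure;
    convenient for fast tests and demonstrations."""
    P, T, R = GeneCategory.PROTEIN_CODING, GeneCategory.TRNA, GeneCategory.RRNA
    panel = [
        GeneSpec("rbcL", P, 390, "LSC", "+"),
        GeneSpec("matK", P, 300, "LSC", "-"),
        GeneSpec("infA", P, 150, "LSC", "-"),
        GeneSpec("ndhC", P, 240, "LSC", "-"),
        GeneSpec("trnV-UAC", T, 72, "LSC", "-"),
        GeneSpec("rps19", P, 120, "LSC", "-", cross_junction="JLB"),
        GeneSpec("rrn16", R, 360, "IR", "+"),
        GeneSpec("ndhB", P, 330, "IR", "-"),
        GeneSpec("trnN-GUU", T, 72, "IR", "-"),
        GeneSpec("ndhF", P, 420, "SSC", "-"),
        GeneSpec("ccsA", P, 300, "SSC", "+"),
        GeneSpec("trnL-UAG", T, 80, "SSC", "-"),
    ]
    return SynthSpec(
        seed=seed,
        lsc_len=3400,
        ssc_len=1100,
        ir_len=950,
        gene_panel=panel,
        tree=DEFAULT_TREE,
        events=[
            EventSpec("ingroup", "ndhC", "frameshift", offset=31),
            EventSpec("clade45", "ndhF", "delete"),
            EventSpec("clade45", "ccsA", "premature_stop", codon=40),
            EventSpec("clade23", "ndhB", "premature_stop", codon=50),
            EventSpec("sp1", "trnV-UAC", "delete"),
            EventSpec("sp2", "matK", "frameshift", offset=100, indel="ins"),
            EventSpec("sp5", "ndhC", "delete"),
        ],
    )
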