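"""Gene inventory and functional/pseudogene/deleted classification.

Every gene of the autotrophic reference is located in each target plastome by
local alignment (both strands). A gene whose best hit covers too little of
the reference, or at too low identity, is *deleted*; a protein-coding gene
whose located copy carries a net frame-disrupting indel or an in-frame stop
before the reference's final codon is a *pseudogene*; everything else is
*functional*. tRNA and rRNA genes have no reading frame and can only be
functional or deleted, unless the annotation itself flags them pseudo.

For large targets the quadratic local aligner is seeded with an edit-distance
infix search (edlib) that narrows the genome to candidate windows; scoring
and all reported evidence come from the Smith-Waterman refinement.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import edlib
import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .config import RunConfig
from .model import GeneCategory, GeneFeature, PlastomeRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}
MIN_QUERY_LENGTH = 12  # below this a local alignment seed is meaningless
_PRESCREEN_CELLS = 500_000  # run edlib first above this m*n product


class GeneState(str, enum.Enum):
    FUNCTIONAL = "F"
    PSEUDOGENE = "P"
    DELETED = "D"


@dataclass
class GeneStatusCall:
    """Per-gene verdict with its alignment evidence."""

    gene_name: str
    state: GeneState
    coverage_fraction: float
    identity_percent: float
    aligned_span: int = 0
    frameshift_positions: list[int] = field(default_factory=list)
    premature_stop_positions: list[int] = field(default_factory=list)
    strand: str = "+"
    score: float = 0.0
    evalue: float = 0.0
    annotation_pseudo: bool = False

    def validate(self, config: "RunConfig") -> None:
        if self.state is GeneState.PSEUDOGENE:
            if not (
                self.frameshift_positions
                or self.premature_stop_positions
                or self.annotation_pseudo
            ):
                raise ValueError(f"{self.gene_name}: pseudogene call without evidence")
        if self.state is GeneState.DELETED:
            if (
                self.coverage_fraction >= config.del_coverage
                and self.identity_percent >= config.min_identity
                and self.aligned_span >= config.min_hit_span
                and self.evalue <= config.evalue_max
            ):
                raise ValueError(f"{self.gene_name}: deleted call above thresholds")


def _aligner(config: RunConfig) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.match_score = config.match
    al.mismatch_score = config.mismatch
    al.open_gap_score = config.gap_open
    al.extend_gap_score = config.gap_extend
    return al


@dataclass
class _Hit:
    score: float
    coverage: float
    identity: float
    strand: str
    alignment: object | None  # Bio.Align.Alignment of (target_window, query)


def _alignment_stats(alignment, query_len: int) -> tuple[float, float]:
    tb, qb = alignment.aligned
    if len(qb) == 0:
        return 0.0, 0.0
    coverage = (qb[-1][1] - qb[0][0]) / query_len
    c = alignment.counts()
    cols = c.identities + c.mismatches + c.gaps
    identity = 100.0 * c.identities / cols if cols else 0.0
    return coverage, identity


def _windows(query: str, target: str, max_hits: int = 4) -> list[tuple[int, int]]:
    """Candidate target windows from an edit-distance infix search."""
    res = edlib.align(query, target, mode="HW", task="locations")
    pad = len(query) // 2 + 30
    wins: list[tuple[int, int]] = []
    for s, e in (res.get("locations") or [])[: max_hits * 8]:
        w = (max(0, (s or 0) - pad), min(len(target), e + 1 + pad))
        if not any(w[0] < b and a < w[1] for a, b in wins):
            wins.append(w)
        if len(wins) >= max_hits:
            break
    return wins or [(0, len(target))]


def _best_on_strand(query: str, target: str, strand: str, config: RunConfig) -> _Hit:
    al = _aligner(config)
    best = _Hit(score=0.0, coverage=0.0, identity=0.0, strand=strand, alignment=None)
    if len(query) * len(target) > _PRESCREEN_CELLS:
        windows = _windows(query, target)
    else:
        windows = [(0, len(target))]
    for ws, we in windows:
        sub = target[ws:we]
        alns = al.align(sub, query)
        if alns.score <= 0:
            continue
        if alns.score > best.score:
            a = alns[0]
            cov, ident = _alignment_stats(a, len(query))
            best = _Hit(alns.score, cov, ident, strand, a)
    return best


def locate_gene(query: str, target_record: PlastomeRecord, config: RunConfig) -> _Hit:
    """Best local hit of a reference gene in a target genome, both strands.

    On a circular target the forward search space is extended by a
    query-length prefix so hits spanning the origin are not missed. Minus
    strand hits are found by searching the reverse complement of the target,
    keeping the query (and its codon frame) forward throughout.
    """
    if len(query) < MIN_QUERY_LENGTH:
        raise ValueError(
            f"reference gene of length {len(query)} is below the "
            f"{MIN_QUERY_LENGTH} bp alignment seed length"
        )
    t = target_record.sequence
    ext = t[: min(len(t), len(query))] if target_record.circular else ""
    fwd = _best_on_strand(query, t + ext, "+", config)
    rc = reverse_complement(t)
    rev = _best_on_strand(query, rc + rc[: len(ext)], "-", config)
    return fwd if fwd.score >= rev.score else rev


def _frame_aligner(config: RunConfig) -> PairwiseAligner:
    """Infix aligner for frame analysis: the full reference CDS is aligned
    end-to-end (query global) against a free-end-gap target window, with the
    same scores as the local search so substitutions are preferred over
    spurious gap pairs."""
    al = PairwiseAligner()
    al.mode = "global"
    al.match_score = config.match
    al.mismatch_score = config.mismatch
    al.open_gap_score = config.gap_open
    al.extend_gap_score = config.gap_extend
    al.end_deletion_score = 0.0  # unaligned target ends are free (infix)
    al.end_insertion_score = -1_000_000.0  # the reference must align fully
    return al


def _indels_and_stops(
    hit: _Hit, query: str, config: RunConfig
) -> tuple[list[int], bool, list[int]]:
    """Indel reference positions and premature-stop codon indices of a hit.

    The local hit only locates the gene; mismatching gene ends get trimmed by
    local alignment, so frame analysis re-aligns the *full* reference CDS
    against the located window. Indels come off the aligned blocks; the
    located target segment is then translated in the reference frame from its
    start, so a frame-disrupting indel upstream surfaces downstream stops
    exactly as it would in vivo. Codon indices are 0-based on the reference;
    a stop strictly before the reference's terminal codon is premature.
    """
    window = str(hit.alignment.target)
    a = _frame_aligner(config).align(window, query)[0]
    tb, qb = a.aligned
    if len(qb) == 0:
        return [], False, []
    indel_positions: list[int] = []
    net = 0
    for k in range(1, len(qb)):
        dq = int(qb[k][0] - qb[k - 1][1])  # reference extra: deletion from target
        dt = int(tb[k][0] - tb[k - 1][1])  # target extra: insertion
        if dq:
            indel_positions.append(int(qb[k - 1][1]))
            net -= dq
        if dt:
            indel_positions.append(int(qb[k - 1][1]))
            net += dt

    segment = window[int(tb[0][0]) : int(tb[-1][1])]
    n_codons = len(query) // 3
    stops = [
        i
        for i in range(min(len(segment) // 3, n_codons - 1))
        if segment[3 * i : 3 * i + 3] in STOP_CODONS
    ]
    return indel_positions, (net % 3 != 0), stops


def call_gene_status(
    target_record: PlastomeRecord,
    reference_feature: GeneFeature,
    reference_sequence: str,
    config: RunConfig | None = None,
) -> GeneStatusCall:
    """Classify one reference gene as functional, pseudogene, or deleted in a
    target plastome.

    ``reference_sequence`` is the spliced (exon-concatenated, sense-strand)
    sequence of the reference gene. Frame analysis applies to protein-coding
    genes only and expects a length divisible by three.
    """
    config = config or RunConfig()
    hit = locate_gene(reference_sequence, target_record, config)
    name = reference_feature.gene_name
    anno_pseudo = _target_annotation_pseudo(target_record, name)
    if (
        hit.alignment is None
        or not _hit_is_homology(
            hit, reference_sequence, len(target_record.sequence), config
        )
        or hit.coverage < config.del_coverage
        or hit.identity < config.min_identity
    ):
        return GeneStatusCall(
            gene_name=name,
            state=GeneState.DELETED,
            coverage_fraction=hit.coverage,
            identity_percent=hit.identity,
            aligned_span=round(hit.coverage * len(reference_sequence)),
            strand=hit.strand,
            score=hit.score,
            evalue=hit_evalue(
                hit.score, len(reference_sequence), len(target_record.sequence)
            ),
            annotation_pseudo=anno_pseudo,
        )
    if reference_feature.category is not GeneCategory.PROTEIN_CODING:
        state = GeneState.PSEUDOGENE if anno_pseudo else GeneState.FUNCTIONAL
        return GeneStatusCall(
            gene_name=name,
            state=state,
            coverage_fraction=hit.coverage,
            identity_percent=hit.identity,
            aligned_span=round(hit.coverage * len(reference_sequence)),
            strand=hit.strand,
            score=hit.score,
            evalue=hit_evalue(
                hit.score, len(reference_sequence), len(target_record.sequence)
            ),
            annotation_pseudo=anno_pseudo,
        )
    indels, frameshifted, stops = _indels_and_stops(hit, reference_sequence, config)
    state = (
        GeneState.PSEUDOGENE
        if (frameshifted or stops or anno_pseudo)
        else GeneState.FUNCTIONAL
    )
    return GeneStatusCall(
        gene_name=name,
        state=state,
        coverage_fraction=hit.coverage,
        identity_percent=hit.identity,
        aligned_span=round(hit.coverage * len(reference_sequence)),
        frameshift_positions=indels,
        premature_stop_positions=stops,
        strand=hit.strand,
        score=hit.score,
        evalue=hit_evalue(
            hit.score, len(reference_sequence), len(target_record.sequence)
        ),
        annotation_pseudo=anno_pseudo,
    )


# Karlin-Altschul parameters for the default +2/-3 scoring with our affine
# gap costs (first gap base -5, each further base -2), calibrated on
# random-sequence simulations: chance best-hit scores grow as ln(m*n)/lambda.
_KA_LAMBDA = 0.42
_KA_K = 0.2


def hit_evalue(score: float, query_len: int, target_len: int) -> float:
    """Expected number of chance local hits scoring >= ``score`` when
    searching both strands of a ``target_len`` genome with a ``query_len``
    gene."""
    import math

    return _KA_K * query_len * (2 * target_len) * math.exp(-_KA_LAMBDA * score)


def _hit_is_homology(hit: _Hit, query: str, target_len: int, config: RunConfig) -> bool:
    """Chance-level filter: a hit must be statistically significant and span
    a minimum stretch of the reference before it counts as a remnant."""
    span = hit.coverage * len(query)
    if span < min(config.min_hit_span, len(query)):
        return False
    return hit_evalue(hit.score, len(query), target_len) <= config.evalue_max


def _target_annotation_pseudo(record: PlastomeRecord, gene_name: str) -> bool:
    """True iff the target annotates the gene and every copy is pseudo-flagged.

    One intact annotated copy suffices for function (the IR-duplication
    rule), so a single non-flagged copy vetoes the pseudo mark.
    """
    copies = [f for f in record.features if f.gene_name == gene_name]
    return bool(copies) and all(f.pseudo_flag for f in copies)


def verify_absence(
    reference_sequence: str,
    target_record: PlastomeRecord,
    config: RunConfig | None = None,
) -> tuple[bool, dict]:
    """Confirm a putative deletion by local search of the reference gene.

    Returns ``(present, best_hit)``: the gene is *present* iff its best local
    hit covers at least the deletion-coverage threshold of the reference
    length at at least the identity threshold. Every deleted call in the
    degradation matrix is backed by this check.
    """
    config = config or RunConfig()
    hit = locate_gene(reference_sequence, target_record, config)
    present = (
        hit.alignment is not None
        and _hit_is_homology(
            hit, reference_sequence, len(target_record.sequence), config
        )
        and hit.coverage >= config.del_coverage
        and hit.identity >= config.min_identity
    )
    return present, {
        "score": hit.score,
        "coverage_fraction": hit.coverage,
        "identity_percent": hit.identity,
        "strand": hit.strand,
    }


# --- inventory --------------------------------------------------------------

@dataclass(frozen=True)
class InventoryCounts:
    """Unique-gene counts for one annotated plastome.

    ``functional_genes`` decomposes into protein-coding + tRNA + rRNA, and
    ``total_genes`` = functional + pseudogenes. ``deleted`` is relative to a
    reference panel size and is 0 when none is given.
    """

    total_genes: int
    functional_genes: int
    protein_coding: int
    tRNA: int
    rRNA: int
    deleted: int
    pseudogenes: int

    def validate(self) -> None:
        if self.functional_genes != self.protein_coding + self.tRNA + self.rRNA:
            raise ValueError("functional != protein_coding + tRNA + rRNA")
        if self.total_genes != self.functional_genes + self.pseudogenes:
            raise ValueError("total != functional + pseudogenes")


def gene_inventory(
    record: PlastomeRecord, reference_total: int | None = None
) -> InventoryCounts:
    """Count unique genes of an annotated record (IR duplicates collapse).

    A gene is a pseudogene only if *every* annotated copy carries the pseudo
    flag; one intact copy suffices for function. ``reference_total`` (the
    unique gene count of the autotrophic reference) turns the difference into
    the deleted-gene count.
    """
    by_name: dict[str, list[GeneFeature]] = {}
    for f in record.features:
        if not isinstance(f.category, GeneCategory):
            raise ValueError(f"{f.gene_name}: unknown category {f.category!r}")
        by_name.setdefault(f.gene_name, []).append(f)
    total = len(by_name)
    pseudo = sum(1 for copies in by_name.values() if all(f.pseudo_flag for f in copies))
    cat_counts = {c: 0 for c in GeneCategory}
    for copies in by_name.values():
        if all(f.pseudo_flag for f in copies):
            continue
        intact = [f for f in copies if not f.pseudo_flag]
        cat_counts[intact[0].category] += 1
    counts = InventoryCounts(
        total_genes=total,
        functional_genes=total - pseudo,
        protein_coding=cat_counts[GeneCategory.PROTEIN_CODING],
        tRNA=cat_counts[GeneCategory.TRNA],
        rRNA=cat_counts[GeneCategory.RRNA],
        deleted=(reference_total - total) if reference_total is not None else 0,
        pseudogenes=pseudo,
    )
    counts.validate()
    return counts


# --- degradation matrix -----------------------------------------------------

@dataclass
class DegradationMatrix:
    """Species-by-gene table of F/P/D state codes with per-call evidence."""

    genes: list[str]
    species: list[str]
    table: pd.DataFrame  # index=species, columns=genes, values "F"/"P"/"D"
    calls: dict[tuple[str, str], GeneStatusCall]

    def state(self, species: str, gene: str) -> str:
        return self.table.at[species, gene]


def reference_gene_panel(reference: PlastomeRecord) -> list[GeneFeature]:
    """Unique functional genes of the reference, in genomic order.

    IR duplicates collapse to the first copy; pseudo-flagged reference genes
    are excluded from the panel (a degraded reference gene cannot anchor
    degradation calls in targets).
    """
    panel: dict[str, GeneFeature] = {}
    for f in sorted(reference.features, key=lambda f: (f.start, f.gene_name)):
        if f.pseudo_flag:
            continue
        panel.setdefault(f.gene_name, f)
    return list(panel.values())


def build_degradation_matrix(
    reference: PlastomeRecord,
    targets: list[PlastomeRecord],
    config: RunConfig | None = None,
) -> DegradationMatrix:
    """Call every reference gene in every target plastome.

    The reference species' own column is all-functional by construction.
    Raises on duplicate species identifiers.
    """
    config = config or RunConfig()
    panel = reference_gene_panel(reference)
    ids = [reference.record_id] + [t.record_id for t in targets]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate species identifiers: {dupes}")
    states: dict[str, dict[str, str]] = {}
    calls: dict[tuple[str, str], GeneStatusCall] = {}
    states[reference.record_id] = {}
    for feat in panel:
        states[reference.record_id][feat.gene_name] = GeneState.FUNCTIONAL.value
        calls[(reference.record_id, feat.gene_name)] = GeneStatusCall(
            gene_name=feat.gene_name,
            state=GeneState.FUNCTIONAL,
            coverage_fraction=1.0,
            identity_percent=100.0,
            aligned_span=feat.span_length,
        )
    for target in targets:
        row: dict[str, str] = {}
        for feat in panel:
            refseq = feat.spliced(reference.sequence)
            call = call_gene_status(target, feat, refseq, config)
            call.validate(config)
            row[feat.gene_name] = call.state.value
            calls[(target.record_id, feat.gene_name)] = call
        states[target.record_id] = row
    genes = [f.gene_name for f in panel]
    table = pd.DataFrame.from_dict(states, orient="index")[genes].reindex(ids)
    return DegradationMatrix(genes=genes, species=ids, table=table, calls=calls)
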