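"""Quadripartite structure: inverted-repeat detection, partitioning, metrics.

A canonical plastome is LSC + IRb + SSC + IRa on a circle, with IRa the exact
reverse complement of IRb. The detector finds the maximal pair of disjoint
circular intervals whose sequences are reverse complements of each other; the
partitioner assigns the longer inter-repeat arc to LSC and rotates the record
to the canonical LSC-first layout.

The detector uses a binary search over candidate repeat lengths with a double
64-bit rolling hash (existence of a valid disjoint pair is monotone in the
length: trimming one base preserves disjointness), and verifies the winning
pair by direct string comparison. Exact matching is the definition: the taxa
this pipeline targets have repeats of many kilobases, so boundary resolution
does not require a mismatch-tolerant mode.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import reverse_complement

from .model import GeneFeature, PlastomeRecord, UNAMBIGUOUS


class NoIRFound(Exception):
    """No reverse-complement repeat pair of the required length exists."""


class UndefinedGC(ValueError):
    """GC content is undefined: no unambiguous bases in the slice."""


# --- rolling hash machinery -------------------------------------------------

_MOD1 = (1 << 61) - 1
_MOD2 = (1 << 31) - 1
_BASE1 = 131
_BASE2 = 137


def _prefix_hashes(s: str):
    n = len(s)
    h1 = [0] * (n + 1)
    h2 = [0] * (n + 1)
    o = ord
    a1 = a2 = 0
    for i in range(n):
        c = o(s[i])
        a1 = (a1 * _BASE1 + c) % _MOD1
        a2 = (a2 * _BASE2 + c) % _MOD2
        h1[i + 1] = a1
        h2[i + 1] = a2
    return h1, h2


def _powers(n: int):
    p1 = [1] * (n + 1)
    p2 = [1] * (n + 1)
    for i in range(n):
        p1[i + 1] = (p1[i] * _BASE1) % _MOD1
        p2[i + 1] = (p2[i] * _BASE2) % _MOD2
    return p1, p2


def _circular_disjoint(a: int, b: int, length: int, n: int) -> bool:
    """Are circular intervals [a, a+length) and [b, b+length) disjoint?"""
    return (b - a) % n >= length and (a - b) % n >= length


def _slice_circular(s: str, start: int, length: int) -> str:
    n = len(s)
    start %= n
    if start + length <= n:
        return s[start : start + length]
    return s[start:] + s[: start + length - n]


class _IRSearch:
    """Shared state for the binary search over repeat lengths."""

    def __init__(self, sequence: str, circular: bool):
        self.n = len(sequence)
        self.seq = sequence
        self.circular = circular
        rc = reverse_complement(sequence)
        self.t = sequence + sequence if circular else sequence
        self.r = rc + rc if circular else rc
        self.th = _prefix_hashes(self.t)
        self.rh = _prefix_hashes(self.r)
        self.p = _powers(len(self.t))

    def _sub(self, pref, i, L):
        h1, h2 = pref
        p1, p2 = self.p
        v1 = (h1[i + L] - h1[i] * p1[L]) % _MOD1
        v2 = (h2[i + L] - h2[i] * p2[L]) % _MOD2
        return v1, v2

    def _positions(self, L):
        """Valid window start positions in the (possibly doubled) strings."""
        n = self.n
        if self.circular:
            return range(n)
        return range(n - L + 1)

    def pairs_at(self, L: int, collect: bool, cap: int = 4096):
        """Find disjoint pairs (a, b) of circular genome intervals of length
        L with seq[b:b+L] == revcomp(seq[a:a+L]).

        With ``collect`` false, returns a non-empty list as soon as one pair
        is found (existence test for the binary search).
        """
        n = self.n
        buckets: dict[tuple[int, int], list[int]] = {}
        for i in self._positions(L):
            buckets.setdefault(self._sub(self.th, i, L), []).append(i)
        found: list[tuple[int, int]] = []
        for j in self._positions(L):
            key = self._sub(self.rh, j, L)
            cand = buckets.get(key)
            if not cand:
                continue
            # position j in revcomp(seq) maps to genome interval start
            # (n - j - L) mod n
            b = (n - j - L) % n
            for a in cand:
                if _circular_disjoint(a, b, L, n):
                    found.append((a, b))
                    if not collect:
                        return found
                    if len(found) >= cap:
                        return found
        return found


def detect_inverted_repeats(
    sequence: str,
    min_ir_length: int = 1000,
    circular: bool = True,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Find the maximal inverted-repeat pair of a plastome sequence.

    Returns two intervals ``(start, end)`` ordered by start position; an
    interval with ``end > len(sequence)`` wraps around the circular origin.
    The two interval sequences are exact reverse complements of each other
    and circularly disjoint. Among maximal-length pairs, the pair whose two
    flanking single-copy arcs are most unequal in length wins (the canonical
    plastome has a long LSC and a short SSC); remaining ties break on the
    smallest start coordinate.

    Raises
    ------
    NoIRFound
        If no disjoint reverse-complement pair of length >= ``min_ir_length``
        exists.
    """
    n = len(sequence)
    if min_ir_length < 1:
        raise ValueError("min_ir_length must be >= 1")
    if n < 2 * min_ir_length + 2:
        raise ValueError(
            f"sequence length {n} too short for min_ir_length {min_ir_length}"
        )
    sequence = sequence.upper()
    search = _IRSearch(sequence, circular)

    lo, hi = min_ir_length, n // 2
    if not search.pairs_at(lo, collect=False):
        raise NoIRFound(f"no inverted repeat of length >= {min_ir_length}")
    # invariant: pairs exist at lo, none at hi+1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if search.pairs_at(mid, collect=False):
            lo = mid
        else:
            hi = mid - 1
    L = lo

    candidates = search.pairs_at(L, collect=True)
    verified = []
    seen = set()
    for a, b in candidates:
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        sa = _slice_circular(sequence, key[0], L)
        sb = _slice_circular(sequence, key[1], L)
        if sb == reverse_complement(sa):
            verified.append(key)
    if not verified:  # hash collision fallback: cannot happen in practice
        raise NoIRFound("candidate repeats failed verification")

    def arc_imbalance(pair):
        a, b = pair
        arc1 = (b - (a + L)) % n
        arc2 = (a - (b + L)) % n
        return abs(arc1 - arc2)

    a, b = max(verified, key=lambda p: (arc_imbalance(p), (-p[0], -p[1])))
    return (a, a + L), (b, b + L)


# --- partitioning -----------------------------------------------------------

@dataclass(frozen=True)
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa coordinates in the canonical (rotated) frame.

    ``linear_offset`` is the left rotation applied to the input linearization
    to reach the canonical LSC-first layout: canonical sequence =
    ``seq[linear_offset:] + seq[:linear_offset]``.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    ir_length: int
    linear_offset: int
    total_length: int

    def __post_init__(self):
        self.validate()

    @property
    def lsc_length(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_length(self) -> int:
        return self.ssc[1] - self.ssc[0]

    @property
    def junctions(self) -> dict[str, int]:
        """JLB/JSB/JSA/JLA positions in the canonical frame (JLA wraps to 0)."""
        return {
            "JLB": self.irb[0],
            "JSB": self.ssc[0],
            "JSA": self.ira[0],
            "JLA": self.ira[1] % self.total_length,
        }

    def validate(self) -> None:
        n = self.total_length
        if self.irb[1] - self.irb[0] != self.ir_length or self.ira[1] - self.ira[0] != self.ir_length:
            raise ValueError("IR interval lengths disagree with ir_length")
        if self.lsc_length + self.ssc_length + 2 * self.ir_length != n:
            raise ValueError("LSC + SSC + 2*IR does not equal the total length")
        if self.lsc_length < self.ssc_length:
            raise ValueError("LSC must be at least as long as SSC")
        order = (self.lsc, self.irb, self.ssc, self.ira)
        pos = 0
        for (s, e) in order:
            if s != pos:
                raise ValueError("regions are not contiguous in LSC,IRb,SSC,IRa order")
            pos = e
        if pos != n:
            raise ValueError("regions do not cover the full sequence")


def partition_quadripartite(
    record: PlastomeRecord,
    ir_pair: tuple[tuple[int, int], tuple[int, int]],
) -> QuadripartitePartition:
    """Partition a record into LSC/IRb/SSC/IRa given its detected IR pair.

    The longer inter-repeat arc becomes LSC and the repeat copy that follows
    it becomes IRb; the rotation needed to put LSC first is recorded as
    ``linear_offset``.
    """
    n = len(record.sequence)
    (a, ae), (b, be) = ir_pair
    L = ae - a
    if be - b != L:
        raise ValueError("IR intervals have unequal lengths")
    if not _circular_disjoint(a, b, L, n):
        raise ValueError("IR intervals overlap: detector contract violated")
    arc_ab = (b - (a + L)) % n  # arc after copy A, before copy B
    arc_ba = (a - (b + L)) % n  # arc after copy B, before copy A
    if arc_ab >= arc_ba:
        lsc_start, lsc_len, irb_start, ssc_len = (a + L) % n, arc_ab, b % n, arc_ba
    else:
        lsc_start, lsc_len, irb_start, ssc_len = (b + L) % n, arc_ba, a % n, arc_ab
    offset = lsc_start
    return QuadripartitePartition(
        lsc=(0, lsc_len),
        irb=(lsc_len, lsc_len + L),
        ssc=(lsc_len + L, lsc_len + L + ssc_len),
        ira=(lsc_len + L + ssc_len, n),
        ir_length=L,
        linear_offset=offset,
        total_length=n,
    )


# --- metrics ----------------------------------------------------------------

def gc_percent(sequence: str) -> float:
    """GC content in percent over unambiguous bases only.

    Ambiguity codes are excluded from both numerator and denominator.
    """
    if not sequence:
        raise UndefinedGC("empty slice")
    sequence = sequence.upper()
    gc = sequence.count("G") + sequence.count("C")
    at = sequence.count("A") + sequence.count("T")
    if gc + at == 0:
        raise UndefinedGC("no unambiguous bases in slice")
    return 100.0 * gc / (gc + at)


def _gc_count(sequence: str) -> int:
    return sequence.count("G") + sequence.count("C")


def _interval_union(intervals) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass(frozen=True)
class RegionMetrics:
    """Sizes (bp) and GC (%) per region, plus coding/non-coding split.

    ``ir`` is one repeat copy (both copies have identical GC by reverse
    complementarity), so ``lsc + ssc + 2*ir == whole``. The coding size is
    the length of the interval union of all non-pseudo features; with an
    unannotated record the coding/noncoding entries are absent.
    """

    sizes: dict[str, int]
    gc: dict[str, float]
    gc_counts: dict[str, int]

    def validate(self) -> None:
        s = self.sizes
        if s["lsc"] + s["ssc"] + 2 * s["ir"] != s["whole"]:
            raise ValueError("region sizes do not sum to the whole")
        if "coding" in s and s["coding"] + s["noncoding"] != s["whole"]:
            raise ValueError("coding + noncoding != whole")
        c = self.gc_counts
        if c and c["lsc"] + c["ssc"] + c["irb"] + c["ira"] != c["whole"]:
            raise ValueError("region GC counts do not sum to the whole")


def region_metrics(
    record: PlastomeRecord, partition: QuadripartitePartition
) -> RegionMetrics:
    """Compute per-region and coding/non-coding size and GC for one record."""
    rec = record.rotated(partition.linear_offset)
    seq = rec.sequence
    n = len(seq)
    sizes: dict[str, int] = {"whole": n}
    gc: dict[str, float] = {"whole": gc_percent(seq)}
    counts: dict[str, int] = {"whole": _gc_count(seq)}
    for name, (s, e) in (
        ("lsc", partition.lsc),
        ("ir", partition.irb),
        ("ssc", partition.ssc),
    ):
        sl = seq[s:e]
        sizes[name] = e - s
        gc[name] = gc_percent(sl) if sl else float("nan")
    counts["lsc"] = _gc_count(seq[slice(*partition.lsc)])
    counts["ssc"] = _gc_count(seq[slice(*partition.ssc)])
    counts["irb"] = _gc_count(seq[slice(*partition.irb)])
    counts["ira"] = _gc_count(seq[slice(*partition.ira)])
    if rec.features:
        union = _interval_union(
            iv for f in rec.features if not f.pseudo_flag for iv in f.intervals
        )
        coding_len = sum(e - s for s, e in union)
        coding_seq = "".join(seq[s:e] for s, e in union)
        # complement of the union
        noncoding_parts = []
        pos = 0
        for s, e in union:
            if pos < s:
                noncoding_parts.append(seq[pos:s])
            pos = e
        if pos < n:
            noncoding_parts.append(seq[pos:])
        noncoding_seq = "".join(noncoding_parts)
        sizes["coding"] = coding_len
        sizes["noncoding"] = n - coding_len
        gc["coding"] = gc_percent(coding_seq) if coding_seq else float("nan")
        gc["noncoding"] = gc_percent(noncoding_seq) if noncoding_seq else float("nan")
    metrics = RegionMetrics(sizes=sizes, gc=gc, gc_counts=counts)
    metrics.validate()
    return metrics


# --- junction gene context --------------------------------------------------

def junction_context(
    record: PlastomeRecord, partition: QuadripartitePartition
) -> dict[str, object]:
    """Report the gene context of the four region junctions.

    For each junction the context is the gene whose feature covers the bases
    on both sides of the boundary, or else the ordered pair (upstream gene,
    downstream gene) flanking the intergenic spacer the junction falls in.
    With no annotation every context is the string ``"unannotated"``.
    """
    rec = record.rotated(partition.linear_offset)
    n = len(rec.sequence)
    out: dict[str, object] = {}
    if not rec.features:
        return {j: "unannotated" for j in partition.junctions}

    # covered positions per feature, as sorted interval lists in canonical frame
    feats = sorted(rec.features, key=lambda f: (f.start, f.gene_name))

    def covers(f: GeneFeature, pos: int) -> bool:
        return any(s <= pos < e for s, e in f.intervals)

    for name, pos in partition.junctions.items():
        pos %= n
        left_base = (pos - 1) % n
        right_base = pos
        inside = [f for f in feats if covers(f, left_base) and covers(f, right_base)]
        if inside:
            inside.sort(key=lambda f: (f.start, f.gene_name))
            out[name] = inside[0].gene_name
            continue
        # spacer: nearest feature covering a base before / at-or-after the junction
        def best_flank(backward: bool):
            best_d, best_feats = None, []
            for f in feats:
                d = min(
                    ((left_base - (e - 1)) % n if backward else (s - right_base) % n)
                    if not (s <= (left_base if backward else right_base) < e)
                    else 0
                    for s, e in f.intervals
                )
                if best_d is None or d < best_d:
                    best_d, best_feats = d, [f]
                elif d == best_d:
                    best_feats.append(f)
            best_feats.sort(key=lambda f: (f.start, f.gene_name))
            return best_feats[0]

        up = best_flank(backward=True)
        down = best_flank(backward=False)
        out[name] = (up.gene_name, down.gene_name)
    return out
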