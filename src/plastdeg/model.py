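"""Core data model: annotated plastome records and gene features.

Coordinates are 0-based half-open on the record's linearization. A feature
that crosses the circular origin is stored as two or more intervals, so every
interval satisfies ``0 <= start < end <= len(sequence)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio.Seq import reverse_complement

# Unambiguous bases plus IUPAC ambiguity codes. Ambiguity codes are preserved
# as-is throughout the pipeline, never coerced to N.
IUPAC_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
UNAMBIGUOUS = frozenset("ACGT")


class Lifeform(str, enum.Enum):
    """Trophic lifestyle of the plant a plastome came from."""

    AUTOTROPH = "autotroph"
    FACULTATIVE_HEMIPARASITE = "facultative_hemiparasite"
    OBLIGATE_HEMIPARASITE = "obligate_hemiparasite"
    UNKNOWN = "unknown"

    @classmethod
    def from_code(cls, code: str) -> "Lifeform":
        """Map the survey-table shorthand (FH / OH / Autotroph) to the enum."""
        table = {
            "FH": cls.FACULTATIVE_HEMIPARASITE,
            "OH": cls.OBLIGATE_HEMIPARASITE,
            "AUTOTROPH": cls.AUTOTROPH,
        }
        return table.get(code.strip().upper(), cls.UNKNOWN)


class GeneCategory(str, enum.Enum):
    PROTEIN_CODING = "protein_coding"
    TRNA = "tRNA"
    RRNA = "rRNA"


class ValidationError(ValueError):
    """A record or feature violates the data-model invariants."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated copy of a gene.

    Genes duplicated by the inverted repeat appear as two separate
    ``GeneFeature`` objects under the same ``gene_name``; deduplication is the
    inventory's job, not the reader's. tRNA symbols keep their anticodon
    suffix (``trnV-UAC``) because losses are tracked at that resolution.
    """

    gene_name: str
    category: GeneCategory
    strand: str  # "+" or "-"
    intervals: tuple[tuple[int, int], ...]
    pseudo_flag: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_name}: strand must be '+' or '-'")
        if not self.intervals:
            raise ValidationError(f"{self.gene_name}: feature has no intervals")
        for s, e in self.intervals:
            if not (0 <= s < e):
                raise ValidationError(
                    f"{self.gene_name}: bad interval ({s}, {e}); need 0 <= start < end"
                )
        ivs = sorted(self.intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"{self.gene_name}: overlapping intervals ({s1},{e1}) and ({s2},{e2})"
                )

    @property
    def start(self) -> int:
        return min(s for s, _ in self.intervals)

    @property
    def end(self) -> int:
        return max(e for _, e in self.intervals)

    @property
    def span_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def spliced(self, sequence: str) -> str:
        """Concatenate the feature's intervals; reverse-complement on '-'.

        Intervals are taken in annotation order, which for an origin-spanning
        feature is biological order, not coordinate order.
        """
        s = "".join(sequence[a:b] for a, b in self.intervals)
        return reverse_complement(s) if self.strand == "-" else s

    def shifted(self, offset: int, n: int) -> "GeneFeature":
        """Return the feature re-addressed after rotating the record left by
        ``offset`` (new sequence = seq[offset:] + seq[:offset]).

        Intervals that come to cross the new origin are split.
        """
        new_ivs: list[tuple[int, int]] = []
        for a, b in self.intervals:
            na, nb = (a - offset) % n, (b - offset) % n
            if nb == 0:
                nb = n
            if na < nb:
                new_ivs.append((na, nb))
            else:  # wrapped: split at the origin
                new_ivs.append((na, n))
                new_ivs.append((0, nb))
        return replace(self, intervals=tuple(new_ivs))


@dataclass
class PlastomeRecord:
    """One annotated plastome: sequence, topology, features, lifeform tag."""

    record_id: str
    sequence: str
    species: str = ""
    lifeform: Lifeform = Lifeform.UNKNOWN
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("U", "T")
        self.validate()

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.record_id}: empty sequence")
        bad = set(self.sequence) - IUPAC_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.record_id}: non-IUPAC characters in sequence: {sorted(bad)}"
            )
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValidationError(
                    f"{self.record_id}: feature {f.gene_name} extends to {f.end} "
                    f"beyond sequence length {n}"
                )

    def rotated(self, offset: int) -> "PlastomeRecord":
        """Rotate the linearization left by ``offset`` bases (circular only)."""
        n = len(self.sequence)
        offset %= n
        if offset == 0:
            return self
        if not self.circular:
            raise ValidationError(f"{self.record_id}: cannot rotate a linear record")
        return PlastomeRecord(
            record_id=self.record_id,
            sequence=self.sequence[offset:] + self.sequence[:offset],
            species=self.species,
            lifeform=self.lifeform,
            circular=True,
            features=[f.shifted(offset, n) for f in self.features],
        )

    def reverse_complemented(self) -> "PlastomeRecord":
        """Return the record on the opposite strand (coordinates mirrored)."""
        n = len(self.sequence)
        feats = []
        for f in self.features:
            ivs = tuple(sorted((n - e, n - s) for s, e in f.intervals))
            feats.append(
                replace(f, intervals=ivs, strand="+" if f.strand == "-" else "-")
            )
        return PlastomeRecord(
            record_id=self.record_id,
            sequence=reverse_complement(self.sequence),
            species=self.species,
            lifeform=self.lifeform,
            circular=self.circular,
            features=feats,
        )


def check_unique_ids(records: Iterable[PlastomeRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.record_id in seen:
            raise ValidationError(f"duplicate record id: {r.record_id}")
        seen.add(r.record_id)
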