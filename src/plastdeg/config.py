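"""Run configuration: thresholds and alignment scoring, in one place.

Every threshold that shapes a biological call lives here so that calls are
reproducible from stated numbers rather than curator judgment.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


@dataclass
class RunConfig:
    """Tunable parameters for the degradation pipeline.

    min_ir_length
        Smallest repeat accepted as an inverted repeat (bp). Plastome IRs in
        the target clade are all >= 12 kb, so 1 kb leaves a wide margin while
        rejecting dispersed short repeats.
    del_coverage / min_identity
        A gene whose best local hit covers less than ``del_coverage`` of the
        reference length, or aligns below ``min_identity`` percent identity,
        is called deleted; otherwise a trackable remnant exists.
    min_hit_span
        Minimum aligned reference span (bp) for a local hit to count as
        homology at all; shorter hits are chance-level at plastome scale and
        are treated as no hit. Capped at the query length for very short
        genes.
    evalue_max
        Significance threshold for the best local hit, under Karlin-Altschul
        statistics with parameters calibrated for this scoring scheme on
        random-sequence simulations. Hits less significant than this are
        treated as absent — the gene-is-gone confirmation mirrors a local
        BLAST verification search.
    match/mismatch/gap_open/gap_extend
        BLAST-like local alignment scores. ``gap_open`` is the cost of the
        first base of a gap, ``gap_extend`` of each further base.
    tie_break
        Policy for equal-cost ancestral reconstructions; only ``DELTRAN``
        (delay transformations toward the tips) is implemented.
    """

    min_ir_length: int = 1000
    del_coverage: float = 0.30
    min_identity: float = 60.0
    min_hit_span: int = 30
    evalue_max: float = 1e-4
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    tie_break: str = "DELTRAN"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.del_coverage < 1.0):
            raise ValueError("del_coverage must lie in (0, 1)")
        if not (0.0 < self.min_identity <= 100.0):
            raise ValueError("min_identity must lie in (0, 100]")
        if self.min_ir_length < 1:
            raise ValueError("min_ir_length must be positive")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.tie_break != "DELTRAN":
            raise ValueError(f"unsupported tie-break policy: {self.tie_break!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a flat ``key = value`` file ('#' starts a comment)."""
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (x.strip() for x in line.split("=", 1))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            kwargs[key] = casts[types[key]](val)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")
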