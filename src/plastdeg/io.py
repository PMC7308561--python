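"""Readers and writers for external formats.

GenBank flat files and FASTA come in through Biopython and are normalized to
:class:`~plastdeg.model.PlastomeRecord`; tabular reports go out as TSV or
JSON and round-trip losslessly through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .model import (
    GeneCategory,
    GeneFeature,
    Lifeform,
    PlastomeRecord,
    ValidationError,
    check_unique_ids,
)

try:  # Python >= 3.9
    from importlib.resources import files as _resource_files
except ImportError:  # pragma: no cover
    _resource_files = None


class ParseError(ValueError):
    """The input file could not be parsed."""


_TYPED = {"CDS": GeneCategory.PROTEIN_CODING, "tRNA": GeneCategory.TRNA, "rRNA": GeneCategory.RRNA}


def _guess_category(name: str) -> GeneCategory:
    low = name.lower()
    if low.startswith("trn"):
        return GeneCategory.TRNA
    if low.startswith("rrn"):
        return GeneCategory.RRNA
    return GeneCategory.PROTEIN_CODING


def _feature_name(feat) -> str | None:
    q = feat.qualifiers
    for key in ("gene", "locus_tag", "product"):
        if key in q and q[key]:
            return str(q[key][0]).strip()
    return None


def _is_pseudo(feat) -> bool:
    return "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers


def _intervals_and_strand(feat) -> tuple[tuple[tuple[int, int], ...], str]:
    # Biopython already exposes GenBank locations 0-based half-open; join()
    # coordinates arrive as compound locations whose parts we keep in
    # annotation (biological) order.
    parts = list(feat.location.parts)
    ivs = tuple((int(p.start), int(p.end)) for p in parts)
    strand = "-" if (feat.location.strand or 1) < 0 else "+"
    return ivs, strand


def _merge_record_features(seqrec) -> list[GeneFeature]:
    """Merge gene/CDS/tRNA/rRNA annotation lines into GeneFeature objects.

    A typed feature (CDS/tRNA/rRNA) wins over its bare ``gene`` line; bare
    ``gene`` features survive only when no typed feature shares their symbol
    and span (common for pseudogenes annotated at the gene level only). IR
    duplicates under one symbol stay separate features.
    """
    typed: list[GeneFeature] = []
    typed_keys: set[tuple[str, int, int]] = set()
    gene_lines = []
    for feat in seqrec.features:
        name = _feature_name(feat)
        if name is None:
            continue
        if feat.type in _TYPED:
            ivs, strand = _intervals_and_strand(feat)
            typed.append(
                GeneFeature(
                    gene_name=name,
                    category=_TYPED[feat.type],
                    strand=strand,
                    intervals=ivs,
                    pseudo_flag=_is_pseudo(feat),
                )
            )
            lo = min(s for s, _ in ivs)
            hi = max(e for _, e in ivs)
            typed_keys.add((name, lo, hi))
        elif feat.type == "gene":
            gene_lines.append((name, feat))

    out = list(typed)
    for name, feat in gene_lines:
        ivs, strand = _intervals_and_strand(feat)
        lo = min(s for s, _ in ivs)
        hi = max(e for _, e in ivs)
        # a gene line is redundant if a typed feature with the same symbol
        # lies within its span
        covered = any(
            tname == name and lo <= tlo and thi <= hi for tname, tlo, thi in typed_keys
        )
        if not covered:
            out.append(
                GeneFeature(
                    gene_name=name,
                    category=_guess_category(name),
                    strand=strand,
                    intervals=ivs,
                    pseudo_flag=_is_pseudo(feat),
                )
            )
    out.sort(key=lambda f: (f.start, f.gene_name))
    return out


def read_genbank(
    path: str | Path,
    lifeforms: Mapping[str, str | Lifeform] | None = None,
) -> list[PlastomeRecord]:
    """Read one or more annotated plastomes from a GenBank flat file.

    Parameters
    ----------
    path
        GenBank flat file (may contain multiple entries).
    lifeforms
        Optional mapping from record id (or species name) to a
        :class:`Lifeform` or its survey shorthand (``FH``/``OH``/``Autotroph``);
        lifeform is not a GenBank concept, so it must be supplied externally.
    """
    path = Path(path)
    records: list[PlastomeRecord] = []
    try:
        seqrecs = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise ParseError(f"{path}: malformed GenBank file: {exc}") from exc
    if not seqrecs:
        raise ParseError(f"{path}: no GenBank records found")
    for sr in seqrecs:
        species = sr.annotations.get("organism", "") or ""
        lf = Lifeform.UNKNOWN
        if lifeforms:
            raw = lifeforms.get(sr.id) or lifeforms.get(species)
            if raw is not None:
                lf = raw if isinstance(raw, Lifeform) else Lifeform.from_code(str(raw))
        circular = str(sr.annotations.get("topology", "")).lower() == "circular"
        try:
            rec = PlastomeRecord(
                record_id=sr.id,
                sequence=str(sr.seq),
                species=species,
                lifeform=lf,
                circular=circular,
                features=_merge_record_features(sr),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: record {sr.id}: {exc}") from exc
        records.append(rec)
    check_unique_ids(records)
    return records


def read_fasta(path: str | Path) -> list[PlastomeRecord]:
    """Read plain FASTA into records with empty feature lists.

    Sequences are upper-cased; circular topology is assumed (plastomes are
    circular molecules) but carries no annotation weight without features.
    """
    path = Path(path)
    seqrecs = list(SeqIO.parse(str(path), "fasta"))
    if not seqrecs:
        raise ParseError(f"{path}: no FASTA records found")
    records = [
        PlastomeRecord(record_id=sr.id, sequence=str(sr.seq), species=sr.description)
        for sr in seqrecs
    ]
    check_unique_ids(records)
    return records


def write_report(table, path: str | Path, format: str = "tsv") -> None:
    """Write a tabular report as TSV or JSON (records orientation).

    ``table`` may be a pandas DataFrame or a list of dicts sharing a header.
    ``read_report(write_report(x)) == x`` cell-for-cell.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(list(table))
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        payload = {
            "columns": list(df.columns),
            "rows": json.loads(df.to_json(orient="records")),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown report format: {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        payload = json.loads(path.read_text())
        return pd.DataFrame(payload["rows"], columns=payload["columns"])
    raise ValueError(f"unknown report format: {format!r}")


# ---------------------------------------------------------------------------
# Bundled survey tables
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(_resource_files("plastdeg").joinpath("data", name)))


def load_survey_regions() -> pd.DataFrame:
    """Published region sizes and GC percentages for 31 Santalales plastomes.

    One row per species: whole-genome, LSC, IR (one copy), SSC, coding and
    non-coding sizes (bp) with their GC content (%), plus the lifeform code
    (FH = facultative hemiparasite, OH = obligate hemiparasite). These are the
    survey values our partition and metrics contracts are validated against.
    """
    return pd.read_csv(_data_path("santalales_regions.tsv"), sep="\t")


def load_survey_gene_content() -> pd.DataFrame:
    """Published plastid gene content for the same 31 Santalales species.

    Columns: total annotated genes, potentially functional genes and their
    protein-coding / tRNA / rRNA breakdown, deleted genes (relative to the
    113-gene autotrophic reference) and pseudogenes.
    """
    return pd.read_csv(_data_path("santalales_gene_content.tsv"), sep="\t")
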