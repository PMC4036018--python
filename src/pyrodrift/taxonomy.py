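"""Rank-annotated 16S rRNA reference collections.

A reference database is a set of sequences, each carrying a six-rank lineage
(domain, phylum, class, order, family, genus).  It is the single source of
truth for classifier training, chimera parent search and best-hit search.
Loading supports the two common dialects for lineage annotation: embedded in
the FASTA header after the id (semicolon-delimited, SILVA/RDP style), or in a
two-column sidecar TSV mapping id to lineage.
"""

from __future__ import annotations

import dataclasses
import io
import os
from collections.abc import Iterable, Mapping
from typing import Optional

from Bio import SeqIO

#: The six taxonomic ranks handled by the package, top-down.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

_RANK_POS: dict[str, int] = {r: i for i, r in enumerate(RANKS)}

# IUPAC nucleotide one-letter codes (uppercase); U is normalized to T at load.
IUPAC_CODES = set("ACGTRYSWKMBDHVN")


class TaxonomyError(ValueError):
    """Raised for malformed lineages, duplicate ids or unreadable references."""


@dataclasses.dataclass(frozen=True)
class RankedLineage:
    """A path through the six ranks; empty string means unassigned.

    An empty name at a rank forces empty names at every rank below it, so a
    lineage is always a prefix of a full six-rank path.
    """

    names: tuple[str, str, str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise TaxonomyError(f"lineage needs {len(RANKS)} names, got {len(self.names)}")
        seen_empty = False
        for name in self.names:
            if name == "":
                seen_empty = True
            elif seen_empty:
                raise TaxonomyError(
                    f"non-empty name below an unassigned rank in {self.names!r}"
                )

    @classmethod
    def from_names(cls, *names: str) -> "RankedLineage":
        """Build from up to six names, top-down; missing ranks are empty."""
        if len(names) > len(RANKS):
            names = names[: len(RANKS)]
        padded = tuple(names) + ("",) * (len(RANKS) - len(names))
        return cls(padded)  # type: ignore[arg-type]

    @classmethod
    def from_string(cls, text: str, sep: str = ";") -> "RankedLineage":
        """Parse a delimited lineage string; ranks beyond genus are ignored."""
        parts = [p.strip() for p in text.strip().split(sep)]
        return cls.from_names(*parts)

    @classmethod
    def empty(cls) -> "RankedLineage":
        return cls(("",) * 6)  # type: ignore[arg-type]

    def at(self, rank: str) -> str:
        """Name at `rank`, or empty string if unassigned there."""
        try:
            return self.names[_RANK_POS[rank]]
        except KeyError:
            raise TaxonomyError(f"unknown rank {rank!r}; expected one of {RANKS}") from None

    def to_string(self, sep: str = ";") -> str:
        return sep.join(self.names).rstrip(sep)

    def depth(self) -> int:
        """Number of assigned ranks (a prefix length in [0, 6])."""
        d = 0
        for name in self.names:
            if name == "":
                break
            d += 1
        return d

    def truncate(self, rank: str) -> "RankedLineage":
        """Copy keeping names down to `rank` inclusive, emptying the rest."""
        k = _RANK_POS[rank] + 1
        return RankedLineage(tuple(self.names[:k]) + ("",) * (len(RANKS) - k))  # type: ignore[arg-type]

    def prefix(self, depth: int) -> "RankedLineage":
        """Copy keeping the first `depth` ranks."""
        depth = max(0, min(depth, len(RANKS)))
        return RankedLineage(tuple(self.names[:depth]) + ("",) * (len(RANKS) - depth))  # type: ignore[arg-type]

    def is_prefix_of(self, other: "RankedLineage") -> bool:
        return all(a == "" or a == b for a, b in zip(self.names, other.names))


def lineage_at_rank(lineage: RankedLineage, rank: str) -> str:
    """Project a lineage onto one rank; unknown rank raises TaxonomyError."""
    return lineage.at(rank)


@dataclasses.dataclass(frozen=True)
class ReferenceSeq:
    """One reference sequence with its lineage and an optional source label."""

    id: str
    sequence: str
    lineage: RankedLineage
    source_label: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise TaxonomyError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_CODES
        if bad:
            raise TaxonomyError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )


class ReferenceDB:
    """An id-indexed collection of ReferenceSeq with a per-rank name index."""

    def __init__(self, records: Iterable[ReferenceSeq]):
        self.records: list[ReferenceSeq] = list(records)
        self._by_id: dict[str, ReferenceSeq] = {}
        for rec in self.records:
            if rec.id in self._by_id:
                raise TaxonomyError(f"duplicate reference id {rec.id!r}")
            self._by_id[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._by_id

    def get(self, rec_id: str) -> ReferenceSeq:
        return self._by_id[rec_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceDB):
            return NotImplemented
        return self.records == other.records

    @property
    def rank_index(self) -> dict[str, dict[str, list[str]]]:
        """rank -> taxon name -> sorted record ids; rebuilt from records."""
        index: dict[str, dict[str, list[str]]] = {r: {} for r in RANKS}
        for rec in self.records:
            for rank in RANKS:
                name = rec.lineage.at(rank)
                if name:
                    index[rank].setdefault(name, []).append(rec.id)
        for rank in RANKS:
            for name in index[rank]:
                index[rank][name].sort()
        return index

    def genera(self) -> list[str]:
        """Sorted genus names present in the database."""
        return sorted({r.lineage.at("genus") for r in self.records} - {""})

    def records_for_genus(self, genus: str) -> list[ReferenceSeq]:
        return [r for r in self.records if r.lineage.at("genus") == genus]

    def lineage_for_genus(self, genus: str) -> RankedLineage:
        for rec in self.records:
            if rec.lineage.at("genus") == genus:
                return rec.lineage
        raise TaxonomyError(f"genus {genus!r} not in database")

    def total_length(self) -> int:
        return sum(len(r.sequence) for r in self.records)


def _normalize_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


def load_reference(
    fasta_source,
    taxonomy_style: str = "header-embedded",
    sidecar_source=None,
) -> ReferenceDB:
    """Load a reference FASTA into a validated ReferenceDB.

    ``header-embedded`` expects headers like
    ``>id Bacteria;Proteobacteria;...;Bradyrhizobium``;
    ``sidecar-table`` expects plain ids plus a two-column TSV
    (``id<TAB>lineage``) given as `sidecar_source`.

    Sequences are uppercased and U is converted to T.  Records whose lineage
    cannot be parsed are counted and skipped (see the `skipped` attribute set
    on the returned database); an empty input or a duplicate id is fatal.
    """
    if taxonomy_style not in ("header-embedded", "sidecar-table"):
        raise TaxonomyError(f"unknown taxonomy_style {taxonomy_style!r}")

    sidecar: dict[str, str] = {}
    if taxonomy_style == "sidecar-table":
        if sidecar_source is None:
            raise TaxonomyError("sidecar-table style needs a sidecar_source")
        sidecar = _read_sidecar(sidecar_source)

    records: list[ReferenceSeq] = []
    seen: set[str] = set()
    skipped = 0
    for sr in SeqIO.parse(_as_handle(fasta_source), "fasta"):
        rec_id = sr.id
        if rec_id in seen:
            raise TaxonomyError(f"duplicate reference id {rec_id!r}")
        seen.add(rec_id)
        if taxonomy_style == "header-embedded":
            desc = sr.description[len(sr.id):].strip() if sr.description else ""
            lineage_text = desc
        else:
            lineage_text = sidecar.get(rec_id, "")
        try:
            if not lineage_text:
                raise TaxonomyError("missing lineage")
            lineage = RankedLineage.from_string(lineage_text)
            records.append(
                ReferenceSeq(rec_id, _normalize_sequence(str(sr.seq)), lineage)
            )
        except TaxonomyError:
            skipped += 1
    if not records and skipped == 0:
        raise TaxonomyError("empty reference input")
    db = ReferenceDB(records)
    db.skipped = skipped  # type: ignore[attr-defined]
    return db


def _as_handle(source):
    if hasattr(source, "read"):
        return source
    return os.fspath(source)


def _read_sidecar(source) -> dict[str, str]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) >= 2:
            mapping[parts[0]] = parts[1]
    return mapping


def write_reference(
    db: ReferenceDB,
    fasta_path,
    taxonomy_style: str = "header-embedded",
    sidecar_path=None,
) -> None:
    """Write a ReferenceDB back to FASTA (+ sidecar TSV when asked)."""
    with open(fasta_path, "w") as fh:
        for rec in db.records:
            if taxonomy_style == "header-embedded":
                fh.write(f">{rec.id} {rec.lineage.to_string()}\n")
            else:
                fh.write(f">{rec.id}\n")
            fh.write(rec.sequence + "\n")
    if taxonomy_style == "sidecar-table":
        if sidecar_path is None:
            raise TaxonomyError("sidecar-table style needs a sidecar_path")
        with open(sidecar_path, "w") as fh:
            for rec in db.records:
                fh.write(f"{rec.id}\t{rec.lineage.to_string()}\n")


def filter_reference(
    db: ReferenceDB, excluded_labels: Iterable[str]
) -> tuple[ReferenceDB, int]:
    """Drop records whose source label or any lineage name matches an excluded label.

    Matching is case-insensitive and exact per name.  Returns the filtered
    database and the number of removed records.  Mirrors the practice of
    excluding "environmental samples" and "unclassified" entries from a
    public rRNA reference before using it for assignment.
    """
    excluded = {lab.lower() for lab in excluded_labels}
    if not excluded:
        return ReferenceDB(db.records), 0
    kept: list[ReferenceSeq] = []
    removed = 0
    for rec in db.records:
        labels = {rec.source_label.lower()} | {n.lower() for n in rec.lineage.names if n}
        if labels & excluded:
            removed += 1
        else:
            kept.append(rec)
    return ReferenceDB(kept), removed
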