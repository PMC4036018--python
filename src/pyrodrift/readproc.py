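"""Demultiplexing, primer location and region extraction.

Reads arrive anti-sense from the 518R end: ``MID + 518R primer + insert``.
Processing assigns each read to its sample by exact MID prefix, anchors the
518R primer by IUPAC-aware semi-global edit distance, and builds the
simulated samples — either a fixed-length prefix of the insert ("the first N
bases past the 518R primer") or the region bounded by a far primer (27F or
109F, located at edit distance <= 2).  Extracted regions are re-oriented to
the 16S sense strand, then pass an average-quality and ambiguity filter.

Primer matching is semi-global Levenshtein (ends-free on the read side) with
IUPAC compatibility as the zero-cost predicate, computed by edlib with an
extended equality relation.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from typing import Optional

import edlib
import numpy as np

from .simulate import PrimerArchitecture, Read, revcomp

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: Symmetric pairs of distinct IUPAC codes whose base sets intersect,
#: handed to edlib as additional equalities.
IUPAC_EQUALITIES: list[tuple[str, str]] = [
    (a, b)
    for a in IUPAC_SETS
    for b in IUPAC_SETS
    if a < b and IUPAC_SETS[a] & IUPAC_SETS[b]
]


class ProcessingError(ValueError):
    pass


def iupac_match(base: str, code: str) -> bool:
    """True iff the IUPAC sets of `base` and `code` intersect."""
    try:
        return bool(IUPAC_SETS[base.upper()] & IUPAC_SETS[code.upper()])
    except KeyError as exc:
        raise ProcessingError(f"non-IUPAC character {exc.args[0]!r}") from None


def primer_edit_distance(window: str, primer: str) -> int:
    """Minimum edits to place `primer` anywhere inside `window`.

    Semi-global (infix) Levenshtein with unit costs and IUPAC-compatible
    characters matching at zero cost; 0 iff an IUPAC-exact occurrence exists.
    An empty window costs the full primer length.
    """
    if not primer:
        raise ProcessingError("empty primer")
    if not window:
        return len(primer)
    res = edlib.align(
        primer.upper(), window.upper(), mode="HW", task="distance",
        additionalEqualities=IUPAC_EQUALITIES,
    )
    return int(res["editDistance"])


def locate_primer(window: str, primer: str) -> tuple[int, list[tuple[int, int]]]:
    """(edit distance, list of (start, end-inclusive) optimal placements)."""
    if not window:
        return len(primer), []
    res = edlib.align(
        primer.upper(), window.upper(), mode="HW", task="locations",
        additionalEqualities=IUPAC_EQUALITIES,
    )
    locs = [(s if s is not None else 0, e) for s, e in res["locations"]]
    return int(res["editDistance"]), locs


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

def demultiplex(
    reads: Sequence[Read], mids: Sequence[str]
) -> dict[str, list[Read]]:
    """Assign reads to samples by exact MID prefix; trim the MID.

    Sample ids are "S1".."Sk" in MID order; reads matching no MID (including
    empty reads) land in the "unassigned" bin untouched.
    """
    if len(set(mids)) != len(mids):
        raise ProcessingError("duplicate MID sequences")
    bins: dict[str, list[Read]] = {f"S{i + 1}": [] for i in range(len(mids))}
    bins["unassigned"] = []
    for read in reads:
        hit: Optional[int] = None
        for i, mid in enumerate(mids):
            if read.sequence.startswith(mid):
                hit = i
                break
        if hit is None:
            bins["unassigned"].append(read)
        else:
            mid = mids[hit]
            trimmed = dataclasses.replace(
                read,
                sequence=read.sequence[len(mid):],
                qualities=read.qualities[len(mid):],
                mid=mid,
            )
            bins[f"S{hit + 1}"].append(trimmed)
    return bins


# ---------------------------------------------------------------------------
# truncation specs and extraction
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TruncationSpec:
    """One simulated sample: anchor at a primer, cut to a length or a far primer.

    Exactly one of `target_length` (fixed-length mode, e.g. P518R-250) and
    `far_primer` (between-primer mode, e.g. P518R-27F) must be set.
    `include_primer` keeps the anchor primer bases in the output instead of
    trimming them before counting the target length.
    """

    name: str
    anchor_primer: str = "518R"
    far_primer: Optional[str] = None
    target_length: Optional[int] = None
    max_edit_anchor: int = 0
    max_edit_far: int = 2
    include_primer: bool = False

    def __post_init__(self) -> None:
        if (self.far_primer is None) == (self.target_length is None):
            raise ProcessingError(
                f"spec {self.name!r}: set exactly one of far_primer/target_length"
            )
        if self.target_length is not None and self.target_length <= 0:
            raise ProcessingError(f"spec {self.name!r}: target_length must be positive")


def default_specs() -> list[TruncationSpec]:
    """The study grid: 250/300/350/400-base prefixes plus the two primer-bounded regions."""
    specs = [
        TruncationSpec(name=f"P518R-{n}", target_length=n) for n in (250, 300, 350, 400)
    ]
    specs.append(TruncationSpec(name="P518R-109F", far_primer="109F"))
    specs.append(TruncationSpec(name="P518R-27F", far_primer="27F"))
    return specs


@dataclasses.dataclass(frozen=True)
class QualityFilterParams:
    """Whole-region quality screen: mean Phred and ambiguous-base budget."""

    min_avg_quality: float = 25.0
    max_ambiguous: int = 0

    def __post_init__(self) -> None:
        if self.min_avg_quality < 0 or self.max_ambiguous < 0:
            raise ProcessingError("quality filter parameters must be >= 0")


REJECTION_REASONS = (
    "too_short", "low_quality", "ambiguous", "no_primer", "no_far_primer", "chimera",
)


@dataclasses.dataclass
class ProcessedRead:
    """An extracted, sense-oriented region with its audit trail."""

    read_id: str
    sequence: str
    qualities: np.ndarray
    sample_id: str = ""
    spec_name: str = ""
    rejection_reason: Optional[str] = None

    @property
    def accepted(self) -> bool:
        return self.rejection_reason is None

    def reject(self, reason: str) -> "ProcessedRead":
        if reason not in REJECTION_REASONS:
            raise ProcessingError(f"unknown rejection reason {reason!r}")
        return dataclasses.replace(self, rejection_reason=reason)


def extract_region(
    read: Read,
    spec: TruncationSpec,
    primers: PrimerArchitecture,
    sample_id: str = "",
) -> ProcessedRead:
    """Anchor, cut and re-orient one read according to a truncation spec.

    The anchor primer (as sequenced, 5'->3' at the read start) must occur in
    the first ``len(primer)+5`` bases within `max_edit_anchor` edits, else the
    read is rejected ``no_primer``.  Fixed-length mode keeps the first
    `target_length` bases after the anchor (``too_short`` if fewer remain);
    between-primer mode locates the reverse-complemented far primer within
    `max_edit_far` edits (``no_far_primer`` otherwise) and keeps the span
    between the two primer sites, both primers excluded.  The output is
    reverse-complemented into sense orientation.
    """
    anchor = primers.site(spec.anchor_primer)
    anchor_seq = anchor.sequence  # as sequenced from this end
    window = read.sequence[: len(anchor_seq) + 5]
    dist, locs = locate_primer(window, anchor_seq)
    out = ProcessedRead(
        read_id=read.id, sequence="", qualities=np.empty(0, dtype=np.int64),
        sample_id=sample_id, spec_name=spec.name,
    )
    if dist > spec.max_edit_anchor or not locs:
        return out.reject("no_primer")
    start, end = locs[0]  # leftmost optimal placement; anchors are terminal
    body_start = 0 if spec.include_primer else end + 1
    body = read.sequence[body_start:]
    quals = read.qualities[body_start:]

    if spec.target_length is not None:
        if len(body) < spec.target_length:
            return out.reject("too_short")
        seg = body[: spec.target_length]
        seg_q = quals[: spec.target_length]
    else:
        far = primers.site(spec.far_primer)
        far_as_read = revcomp(far.sequence)
        fdist, flocs = locate_primer(body, far_as_read)
        if fdist > spec.max_edit_far or not flocs:
            return out.reject("no_far_primer")
        fstart = flocs[-1][0]  # rightmost placement: the far site is terminal
        seg = body[:fstart]
        seg_q = quals[:fstart]
        if not seg:
            return out.reject("too_short")
    # sense orientation: the read runs anti-sense from the 518R end
    return dataclasses.replace(
        out, sequence=revcomp(seg), qualities=np.asarray(seg_q)[::-1].copy()
    )


def quality_filter(pr: ProcessedRead, params: QualityFilterParams) -> ProcessedRead:
    """Apply the mean-quality and ambiguity screens to an extracted region."""
    if not pr.accepted:
        return pr
    if len(pr.qualities) == 0 and params.min_avg_quality > 0:
        raise ProcessingError(f"read {pr.read_id}: no qualities to filter on")
    if float(np.mean(pr.qualities)) < params.min_avg_quality:
        return pr.reject("low_quality")
    if pr.sequence.count("N") > params.max_ambiguous:
        return pr.reject("ambiguous")
    return pr


def process_sample(
    reads: Sequence[Read],
    spec: TruncationSpec,
    primers: PrimerArchitecture,
    qparams: QualityFilterParams,
    sample_id: str = "",
) -> tuple[list[ProcessedRead], dict[str, int]]:
    """Extract + filter every read of one sample under one spec.

    Returns the full list of ProcessedRead (accepted and rejected) and an
    audit counter: input, accepted, and one count per rejection reason.
    Counts are conserved: accepted + rejections = input.
    """
    processed: list[ProcessedRead] = []
    audit = {"input": len(reads), "accepted": 0}
    audit.update({r: 0 for r in REJECTION_REASONS})
    for read in reads:
        pr = extract_region(read, spec, primers, sample_id=sample_id)
        pr = quality_filter(pr, qparams)
        processed.append(pr)
        if pr.accepted:
            audit["accepted"] += 1
        else:
            audit[pr.rejection_reason] += 1
    return processed, audit


def write_processed_fasta(reads: Sequence[ProcessedRead], path) -> None:
    with open(path, "w") as fh:
        for pr in reads:
            if pr.accepted:
                fh.write(f">{pr.read_id}\n{pr.sequence}\n")


def write_audit_table(audits: Mapping[tuple[str, str], Mapping[str, int]], path) -> None:
    """TSV audit: one row per (sample, spec) with per-reason counts."""
    cols = ["input", "accepted", *REJECTION_REASONS]
    with open(path, "w") as fh:
        fh.write("sample\tspec\t" + "\t".join(cols) + "\n")
        for (sample, spec) in sorted(audits):
            counts = audits[(sample, spec)]
            fh.write(
                f"{sample}\t{spec}\t" + "\t".join(str(counts.get(c, 0)) for c in cols) + "\n"
            )
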