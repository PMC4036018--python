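"""Reference-based two-parent chimera screening.

A read is flagged chimeric when splitting it at some breakpoint and
explaining the two sides with two different reference parents beats the best
single-parent explanation by a configurable improvement ratio.  Candidate
parents are found by shared k-mer counts against the left and right halves of
the query; per-side identities come from infix (semi-global) alignment of the
query segment against the parent, so breakpoint-local indels do not shift
coordinates.  The decision rule — candidate search, breakpoint scan,
improvement ratio over the best single parent with per-side identity floors —
is explicit and configurable.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from typing import Optional

import edlib

from .readproc import ProcessedRead
from .taxonomy import ReferenceDB


class ChimeraError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ChimeraParams:
    """Tunables of the two-parent screen.

    `min_improvement` is the ratio by which the length-weighted two-parent
    identity must exceed the best single-parent identity (default 1.007, the
    widely used divergence-ratio default); both sides must reach
    `min_side_identity` to their parents.
    """

    kmer: int = 8
    candidates_per_side: int = 3
    min_improvement: float = 1.007
    min_side_identity: float = 0.90
    breakpoint_step: int = 10

    def __post_init__(self) -> None:
        if self.min_improvement <= 1.0:
            raise ChimeraError("min_improvement must exceed 1")
        if not 0.0 <= self.min_side_identity <= 1.0:
            raise ChimeraError("min_side_identity must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class ChimeraVerdict:
    """Outcome of screening one read.

    `score` is the improvement ratio of the best two-parent identity over the
    best single-parent identity; the identity fields expose the underlying
    quantities for auditing.
    """

    read_id: str
    is_chimeric: bool
    best_parents: Optional[tuple[str, str]] = None
    breakpoint: Optional[int] = None
    score: float = 0.0
    combined_identity: float = 0.0
    left_identity: float = 0.0
    right_identity: float = 0.0

    def __post_init__(self) -> None:
        if self.is_chimeric and (self.best_parents is None or self.breakpoint is None):
            raise ChimeraError("chimeric verdict needs parents and a breakpoint")


def _kmer_set(seq: str, k: int) -> set[str]:
    return {
        seq[i:i + k]
        for i in range(len(seq) - k + 1)
        if "N" not in seq[i:i + k]
    }


def candidate_parents(
    query: str, db: ReferenceDB, params: ChimeraParams = ChimeraParams()
) -> tuple[list[str], list[str]]:
    """Top reference ids by shared k-mers with each half of the query."""
    if len(db) == 0:
        raise ChimeraError("empty reference database")
    if len(query) < 2 * params.kmer:
        raise ChimeraError("query shorter than two k-mers")
    half = len(query) // 2
    left_k = _kmer_set(query[:half], params.kmer)
    right_k = _kmer_set(query[half:], params.kmer)
    attr = f"_chimera_kmer_sets_{params.kmer}"
    ref_kmers = getattr(db, attr, None)
    if ref_kmers is None:
        ref_kmers = {rec.id: _kmer_set(rec.sequence, params.kmer) for rec in db}
        setattr(db, attr, ref_kmers)

    def top(kmers: set[str]) -> list[str]:
        scored = [
            (len(kmers & ref_kmers[rid]), rid)
            for rid in ref_kmers
            if kmers & ref_kmers[rid]
        ]
        scored.sort(key=lambda t: (-t[0], t[1]))
        return [rid for _, rid in scored[: params.candidates_per_side]]

    return top(left_k), top(right_k)


def _infix_identity(segment: str, ref: str) -> float:
    """1 - editdist/len(segment) with the segment placed anywhere in ref."""
    if not segment:
        return 0.0
    d = edlib.align(segment, ref, mode="HW", task="distance")["editDistance"]
    return max(0.0, 1.0 - d / len(segment))


def _locate_window(query: str, ref: str, pad: int = 200) -> tuple[float, str]:
    """Whole-query identity to `ref` plus the padded matching window.

    Side segments of the breakpoint scan are aligned against this window
    instead of the full reference — same placement, fewer cells.
    """
    res = edlib.align(query, ref, mode="HW", task="locations")
    d = res["editDistance"]
    identity = max(0.0, 1.0 - d / len(query)) if query else 0.0
    locs = res["locations"]
    if not locs:
        return identity, ref
    start = max(0, (locs[0][0] or 0) - pad)
    end = min(len(ref), locs[0][1] + 1 + pad)
    return identity, ref[start:end]


def _best_split(
    query: str, seq_a: str, seq_b: str, params: ChimeraParams
) -> tuple[Optional[int], float, float, float]:
    """Best breakpoint for A(left)+B(right): coarse scan, then refinement."""
    L = len(query)

    def two_parent(b: int) -> tuple[float, float, float]:
        left = _infix_identity(query[:b], seq_a)
        right = _infix_identity(query[b:], seq_b)
        return (b * left + (L - b) * right) / L, left, right

    step = max(1, params.breakpoint_step)
    best_b: Optional[int] = None
    best = (-1.0, 0.0, 0.0)
    for b in range(step, L, step):
        val = two_parent(b)
        if val[0] > best[0]:
            best_b, best = b, val
    if best_b is not None:
        for b in range(max(1, best_b - step), min(L, best_b + step + 1)):
            val = two_parent(b)
            if val[0] > best[0]:
                best_b, best = b, val
    return best_b, best[0], best[1], best[2]


def evaluate_chimera(
    query: str,
    parent_a: tuple[str, str],
    parent_b: tuple[str, str],
    params: ChimeraParams = ChimeraParams(),
) -> ChimeraVerdict:
    """Score the two-parent model A(left)+B(right) for one candidate pair.

    The verdict is chimeric iff the best length-weighted two-parent identity
    is at least ``min_improvement`` times the better of the two single-parent
    identities and both sides reach the per-side identity floor.  (The full
    screen in `remove_chimeras` additionally baselines against every
    candidate parent, not just this pair.)
    """
    (id_a, seq_a), (id_b, seq_b) = parent_a, parent_b
    if id_a == id_b:
        raise ChimeraError("parents must be distinct")
    ident_a, win_a = _locate_window(query, seq_a)
    ident_b, win_b = _locate_window(query, seq_b)
    single = max(ident_a, ident_b)
    best_b, combined, left_id, right_id = _best_split(query, win_a, win_b, params)
    ratio = combined / single if single > 0 else float("inf")
    chimeric = (
        best_b is not None
        and ratio >= params.min_improvement
        and left_id >= params.min_side_identity
        and right_id >= params.min_side_identity
    )
    return ChimeraVerdict(
        read_id="",
        is_chimeric=chimeric,
        best_parents=(id_a, id_b) if chimeric else None,
        breakpoint=best_b if chimeric else None,
        score=ratio,
        combined_identity=combined,
        left_identity=left_id,
        right_identity=right_id,
    )


@dataclasses.dataclass
class ChimeraScreenResult:
    clean: list[ProcessedRead]
    flagged: list[ProcessedRead]
    verdicts: list[ChimeraVerdict]


def remove_chimeras(
    reads: Sequence[ProcessedRead],
    db: ReferenceDB,
    params: ChimeraParams = ChimeraParams(),
) -> ChimeraScreenResult:
    """Partition accepted reads into clean and flagged-chimeric sets.

    For each read the best two-parent split over all left x right candidate
    pairs is compared against the best single-parent identity over *all*
    candidates, so a read fully explained by one reference can never be
    flagged.  Flagged reads carry rejection reason "chimera"; clean + flagged
    is exactly the input.  Reads already rejected upstream pass through to
    the clean set untouched.
    """
    clean: list[ProcessedRead] = []
    flagged: list[ProcessedRead] = []
    verdicts: list[ChimeraVerdict] = []
    for pr in reads:
        if not pr.accepted or len(pr.sequence) < 2 * params.kmer:
            clean.append(pr)
            continue
        left, right = candidate_parents(pr.sequence, db, params)
        all_cands = sorted(set(left) | set(right))
        if not all_cands:
            clean.append(pr)
            verdicts.append(ChimeraVerdict(read_id=pr.read_id, is_chimeric=False))
            continue
        located = {
            rid: _locate_window(pr.sequence, db.get(rid).sequence)
            for rid in all_cands
        }
        single_best = max(ident for ident, _ in located.values())
        best: Optional[tuple[int, float, float, float, str, str]] = None
        for la in left:
            for rb in right:
                if la == rb:
                    continue
                b, combined, lid, rid_ = _best_split(
                    pr.sequence, located[la][1], located[rb][1], params
                )
                if b is None:
                    continue
                if best is None or combined > best[1]:
                    best = (b, combined, lid, rid_, la, rb)
        if best is None:
            clean.append(pr)
            verdicts.append(ChimeraVerdict(read_id=pr.read_id, is_chimeric=False))
            continue
        b, combined, lid, rid_, la, rb = best
        ratio = combined / single_best if single_best > 0 else float("inf")
        chimeric = (
            ratio >= params.min_improvement
            and lid >= params.min_side_identity
            and rid_ >= params.min_side_identity
        )
        verdicts.append(ChimeraVerdict(
            read_id=pr.read_id,
            is_chimeric=chimeric,
            best_parents=(la, rb) if chimeric else None,
            breakpoint=b if chimeric else None,
            score=ratio,
            combined_identity=combined,
            left_identity=lid,
            right_identity=rid_,
        ))
        if chimeric:
            flagged.append(pr.reject("chimera"))
        else:
            clean.append(pr)
    return ChimeraScreenResult(clean, flagged, verdicts)


def write_verdict_table(verdicts: Sequence[ChimeraVerdict], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tflagged\tparents\tbreakpoint\tscore\n")
        for v in verdicts:
            parents = ",".join(v.best_parents) if v.best_parents else ""
            bp = "" if v.breakpoint is None else str(v.breakpoint)
            fh.write(f"{v.read_id}\t{int(v.is_chimeric)}\t{parents}\t{bp}\t{v.score:.6f}\n")
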