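"""Best-hit local-alignment taxonomy assignment.

Queries are aligned to every reference (optionally through a k-mer prefilter
that must not change the winner) with affine-gap Smith-Waterman; hits are
filtered by E-value, query coverage and identity, and the read inherits the
full lineage of the highest-scoring surviving hit.  E-values use the
Karlin-Altschul form ``E = K * m * n * exp(-lambda * S)`` with configurable
constants — the E-value acts purely as a filter threshold here, so lambda and
K are not fitted.

Scoring convention: a gap of length k costs ``gap_open + (k-1) * gap_extend``
(the first gap base pays the opening penalty).  The alignment kernel is a
numba-compiled Gotoh dynamic program; an independent pure-Python DP serves as
its oracle in the test suite.

Best hit is chosen by raw score, ties broken by higher identity then
lexicographic subject id; surviving hits within `ambiguity_margin` of the
best score that name a different genus mark the assignment ambiguous.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence
from typing import Optional, Union

import edlib
import numpy as np
from numba import njit

from .readproc import ProcessedRead
from .simulate import revcomp
from .taxonomy import RANKS, RankedLineage, ReferenceDB
from .nbayes import TaxAssignment


class AlignmentError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class AlignmentScoreParams:
    """Substitution/gap scores plus Karlin-Altschul constants."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    lam: float = 1.28
    K: float = 0.46

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise AlignmentError("need match > 0 > mismatch")
        if self.lam <= 0 or self.K <= 0:
            raise AlignmentError("lambda and K must be positive")


@dataclasses.dataclass(frozen=True)
class HitFilterParams:
    """The three hit filters plus the ambiguity margin on raw score."""

    max_evalue: float = 1.0e-30
    min_query_coverage: float = 0.90
    min_identity: float = 0.90
    ambiguity_margin: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.min_query_coverage <= 1.0:
            raise AlignmentError("min_query_coverage must be in (0, 1]")
        if not 0.0 <= self.min_identity <= 1.0:
            raise AlignmentError("min_identity must be in [0, 1]")


@dataclasses.dataclass
class Alignment:
    """A local alignment summary (one strand already chosen)."""

    query_id: str
    subject_id: str
    score: float
    aligned_length: int
    identities: int
    mismatches: int
    gaps: int
    query_start: int  # 0-based, on the query as given
    query_end: int    # exclusive
    subject_start: int
    subject_end: int
    query_length: int
    strand: str = "+"
    evalue: Optional[float] = None

    @property
    def identity(self) -> float:
        return self.identities / self.aligned_length if self.aligned_length else 0.0

    @property
    def coverage(self) -> float:
        return (self.query_end - self.query_start) / self.query_length


_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=True)
def _gotoh_score(q, s, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Score-only local Gotoh fill (no traceback matrices)."""
    nq, ns = q.shape[0], s.shape[0]
    NEG = -1.0e30
    h_prev = np.zeros(ns + 1)
    f_prev = np.full(ns + 1, NEG)
    best = 0.0
    for i in range(1, nq + 1):
        e = NEG
        h_diag = 0.0  # H[i-1][j-1]
        h_left = 0.0  # H[i][j-1]
        for j in range(1, ns + 1):
            e_open = h_left + gap_open
            e_ext = e + gap_extend
            e = e_open if e_open >= e_ext else e_ext
            f_open = h_prev[j] + gap_open
            f_ext = f_prev[j] + gap_extend
            f = f_open if f_open >= f_ext else f_ext
            sub = match if (q[i - 1] == s[j - 1] and q[i - 1] < 4) else mismatch
            h = h_diag + sub
            if h < 0.0:
                h = 0.0
            if e > h:
                h = e
            if f > h:
                h = f
            h_diag = h_prev[j]
            h_prev[j] = h
            h_left = h
            f_prev[j] = f
            if h > best:
                best = h
    return best


@njit(cache=True)
def _gotoh_fill(q, s, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    nq, ns = q.shape[0], s.shape[0]
    NEG = -1.0e30
    h_prev = np.zeros(ns + 1)
    h_cur = np.zeros(ns + 1)
    f_prev = np.full(ns + 1, NEG)
    f_cur = np.full(ns + 1, NEG)
    ptr_h = np.zeros((nq + 1, ns + 1), dtype=np.uint8)  # 0 stop,1 diag,2 E,3 F
    ptr_e = np.zeros((nq + 1, ns + 1), dtype=np.uint8)  # 1 open, 0 extend
    ptr_f = np.zeros((nq + 1, ns + 1), dtype=np.uint8)
    best = 0.0
    best_i = 0
    best_j = 0
    for i in range(1, nq + 1):
        e = NEG
        h_cur[0] = 0.0
        for j in range(1, ns + 1):
            # E: gap consuming subject char j (gap in query row)
            e_open = h_cur[j - 1] + gap_open
            e_ext = e + gap_extend
            if e_open >= e_ext:
                e = e_open
                ptr_e[i, j] = 1
            else:
                e = e_ext
                ptr_e[i, j] = 0
            # F: gap consuming query char i
            f_open = h_prev[j] + gap_open
            f_ext = f_prev[j] + gap_extend
            if f_open >= f_ext:
                f_cur[j] = f_open
                ptr_f[i, j] = 1
            else:
                f_cur[j] = f_ext
                ptr_f[i, j] = 0
            sub = match if (q[i - 1] == s[j - 1] and q[i - 1] < 4) else mismatch
            diag = h_prev[j - 1] + sub
            h = 0.0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if e > h:
                h = e
                p = 2
            if f_cur[j] > h:
                h = f_cur[j]
                p = 3
            h_cur[j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
                best_i = i
                best_j = j
        for j in range(ns + 1):
            h_prev[j] = h_cur[j]
            f_prev[j] = f_cur[j]
    return best, best_i, best_j, ptr_h, ptr_e, ptr_f


def _traceback(q, s, best_i, best_j, ptr_h, ptr_e, ptr_f):
    i, j = best_i, best_j
    identities = mismatches = gaps = 0
    state = "H"
    while True:
        if state == "H":
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    identities += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            gaps += 1
            opened = ptr_e[i, j]
            j -= 1
            if opened:
                state = "H"
        else:
            gaps += 1
            opened = ptr_f[i, j]
            i -= 1
            if opened:
                state = "H"
    return identities, mismatches, gaps, i, j


def local_align(
    query: str,
    subject: str,
    params: AlignmentScoreParams = AlignmentScoreParams(),
    query_id: str = "",
    subject_id: str = "",
    strands: str = "both",
) -> Alignment:
    """Optimal affine-gap local alignment; both strands tried, better kept.

    Identity and coverage are computed from the traceback; coordinates are on
    the query as given (reverse-strand spans are mapped back).
    """
    if not query or not subject:
        raise AlignmentError("sequences must be non-empty")
    s_enc = _encode(subject)
    tries = []
    if strands in ("both", "+"):
        tries.append(("+", query))
    if strands in ("both", "-"):
        tries.append(("-", revcomp(query)))
    best: Optional[Alignment] = None
    for strand, qseq in tries:
        q_enc = _encode(qseq)
        score, bi, bj, ph, pe, pf = _gotoh_fill(
            q_enc, s_enc, params.match, params.mismatch,
            params.gap_open, params.gap_extend,
        )
        idents, mism, gaps, qi, sj = _traceback(q_enc, s_enc, bi, bj, ph, pe, pf)
        qstart, qend = qi, bi
        if strand == "-":
            qstart, qend = len(query) - bi, len(query) - qi
        aln = Alignment(
            query_id=query_id, subject_id=subject_id, score=float(score),
            aligned_length=idents + mism + gaps, identities=idents,
            mismatches=mism, gaps=gaps,
            query_start=qstart, query_end=qend,
            subject_start=sj, subject_end=bj,
            query_length=len(query), strand=strand,
        )
        if best is None or aln.score > best.score:
            best = aln
    assert best is not None
    return best


def evalue(
    score: float, m: int, n: int, params: AlignmentScoreParams = AlignmentScoreParams()
) -> float:
    """Karlin-Altschul expected hit count: K * m * n * exp(-lambda * S)."""
    if score < 0:
        raise AlignmentError("score must be >= 0")
    return params.K * m * n * math.exp(-params.lam * score)


def _kmer_index(db: ReferenceDB, k: int) -> dict[str, list[str]]:
    """kmer -> reference ids, memoized on the database instance."""
    attr = f"_besthit_kmer_index_{k}"
    index = getattr(db, attr, None)
    if index is None:
        index = {}
        for rec in db:
            for i in range(len(rec.sequence) - k + 1):
                index.setdefault(rec.sequence[i:i + k], []).append(rec.id)
        setattr(db, attr, index)
    return index


def _kmer_candidates(
    query: str, db: ReferenceDB, top_k: int, k: int = 11
) -> list[str]:
    index = _kmer_index(db, k)
    qk = {query[i:i + k] for i in range(len(query) - k + 1)}
    qk |= {revcomp(w) for w in qk}
    counts: dict[str, int] = {}
    for word in qk:
        for rid in index.get(word, ()):
            counts[rid] = counts.get(rid, 0) + 1
    scored = sorted(((-c, rid) for rid, c in counts.items()))
    out = [rid for _, rid in scored[:top_k]]
    if len(out) < top_k:  # pad with arbitrary refs so weak queries still align
        for rec in db:
            if rec.id not in counts:
                out.append(rec.id)
                if len(out) == top_k:
                    break
    return out


def best_hit_assign(
    read: Union[ProcessedRead, tuple[str, str]],
    db: ReferenceDB,
    filters: HitFilterParams = HitFilterParams(),
    scores: AlignmentScoreParams = AlignmentScoreParams(),
    prefilter_k: Optional[int] = 8,
    strands: str = "both",
) -> tuple[TaxAssignment, list[Alignment]]:
    """Assign a read the lineage of its best surviving hit.

    Hits failing E-value, coverage or identity are discarded; with no
    survivor the read is unassigned at all ranks.  `prefilter_k` limits full
    alignment to the top-k references by shared 11-mers (None = exhaustive);
    the prefilter is an optimization only and is cross-checked against
    exhaustive search in the tests.  Returns the assignment and the surviving
    hits sorted best-first.
    """
    if len(db) == 0:
        raise AlignmentError("empty reference database")
    if isinstance(read, ProcessedRead):
        read_id, seq = read.read_id, read.sequence
    else:
        read_id, seq = read
    if prefilter_k is None or prefilter_k >= len(db):
        candidate_ids = [rec.id for rec in db]
    else:
        candidate_ids = _kmer_candidates(seq, db, prefilter_k)
    n_total = db.total_length()

    # Score-only pass over every candidate/strand, traceback lazily in score
    # order until no further hit can beat or tie the best surviving one.
    # Each candidate is first located with a fast edit-distance search and
    # the quadratic DP runs only on a padded subject window (a seeding
    # heuristic in the BLAST spirit; cross-checked against exhaustive
    # alignment in the tests).
    pad = 150
    strand_list = ["+", "-"] if strands == "both" else [strands]
    q_str = {"+": seq, "-": revcomp(seq)}
    q_enc = {st: _encode(q_str[st]) for st in strand_list}
    scored: list[tuple[float, str, str, int, int]] = []
    for rid in candidate_ids:
        ref = db.get(rid).sequence
        for strand in strand_list:
            locs = edlib.align(
                q_str[strand], ref, mode="HW", task="locations"
            )["locations"]
            if locs:
                wstart = max(0, (locs[0][0] or 0) - pad)
                wend = min(len(ref), locs[0][1] + 1 + pad)
            else:
                wstart, wend = 0, len(ref)
            sc = _gotoh_score(
                q_enc[strand], _encode(ref[wstart:wend]),
                scores.match, scores.mismatch, scores.gap_open, scores.gap_extend,
            )
            scored.append((float(sc), rid, strand, wstart, wend))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))

    surviving: list[Alignment] = []
    best_surv = None
    for sc, rid, strand, wstart, wend in scored:
        if best_surv is not None and sc < best_surv - filters.ambiguity_margin:
            break
        aln = local_align(
            seq, db.get(rid).sequence[wstart:wend], scores,
            query_id=read_id, subject_id=rid, strands=strand,
        )
        aln.subject_start += wstart
        aln.subject_end += wstart
        aln.evalue = evalue(max(aln.score, 0.0), len(seq), n_total, scores)
        if (
            aln.evalue <= filters.max_evalue
            and aln.coverage >= filters.min_query_coverage
            and aln.identity >= filters.min_identity
        ):
            surviving.append(aln)
            if best_surv is None or aln.score > best_surv:
                best_surv = aln.score

    surviving.sort(key=lambda a: (-a.score, -a.identity, a.subject_id))
    if not surviving:
        assignment = TaxAssignment(
            read_id=read_id,
            lineage=RankedLineage.empty(),
            confidences=(0.0,) * len(RANKS),
            method="best-hit",
        )
        return assignment, surviving

    top = surviving[0]
    lineage = db.get(top.subject_id).lineage
    ambiguous = any(
        a.score >= top.score - filters.ambiguity_margin
        and db.get(a.subject_id).lineage.at("genus") != lineage.at("genus")
        for a in surviving[1:]
    )
    assignment = TaxAssignment(
        read_id=read_id,
        lineage=lineage,
        confidences=(1.0,) * len(RANKS),
        method="best-hit",
        ambiguous=ambiguous,
    )
    return assignment, surviving


def write_hit_table(hits: Sequence[Alignment], path) -> None:
    """12-column tab-separated alignment summary (one row per hit)."""
    with open(path, "w") as fh:
        for a in hits:
            fh.write("\t".join([
                a.query_id, a.subject_id, f"{100 * a.identity:.2f}",
                str(a.aligned_length), str(a.mismatches), str(a.gaps),
                str(a.query_start + 1), str(a.query_end),
                str(a.subject_start + 1), str(a.subject_end),
                f"{a.evalue:.2e}" if a.evalue is not None else "",
                f"{a.score:g}",
            ]) + "\n")
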