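"""Word-based naive-Bayes taxonomic classifier with bootstrap confidence.

Training counts, for every overlapping word of size w (default 8) and every
genus G, the number of training sequences of G containing the word at least
once: m(word, G).  With M(G) training sequences in G, N in total and
n(word) = sum_G m(word, G), a query's genus score is

    P(word)   = (n(word) + 0.5) / (N + 1)
    P(word|G) = (m(word, G) + P(word)) / (M(G) + 1)
    score(G)  = sum over distinct query words of log P(word|G)

The reported genus is the argmax (ties broken by lexicographic genus name);
per-rank confidence is the fraction of bootstrap trials — each re-scoring a
with-replacement subsample of ceil(fraction * |words|) query words — whose
winning genus agrees with the best lineage at that rank.  A trial supports
every ancestor of its winner, so confidences never increase from domain to
genus.  Within a trial, exactly tied genera are resolved uniformly at random
from the seeded generator: an exact tie carries no signal, and resolving it
deterministically would fake unanimous support for one of the tied genera.

A minimum-support threshold then truncates the lineage to its deepest prefix
with confidence at or above the threshold at every rank.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from collections.abc import Iterable, Sequence
from typing import Optional, Union

import numpy as np

from .readproc import ProcessedRead
from .simulate import revcomp
from .taxonomy import RANKS, RankedLineage, ReferenceDB


class ClassifierError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class BootstrapParams:
    """Bootstrap settings: B trials over ceil(fraction * |words|) words each."""

    trials: int = 100
    fraction: float = 1.0 / 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ClassifierError("trials must be >= 1")
        if not 0.0 < self.fraction <= 1.0:
            raise ClassifierError("fraction must be in (0, 1]")


@dataclasses.dataclass
class TaxAssignment:
    """Per-read lineage with per-rank confidence and thresholded effective lineage."""

    read_id: str
    lineage: RankedLineage
    confidences: tuple[float, ...]  # aligned with RANKS
    method: str  # "naive-bayes" | "best-hit"
    effective: Optional[RankedLineage] = None
    tau: Optional[float] = None
    ambiguous: bool = False

    def confidence_at(self, rank: str) -> float:
        return self.confidences[RANKS.index(rank)]


class WordModel:
    """8-mer occurrence statistics per genus (presence/absence per sequence)."""

    def __init__(
        self,
        w: int,
        genera: list[str],
        lineages: dict[str, RankedLineage],
        word_index: dict[str, int],
        m: np.ndarray,
        M: np.ndarray,
    ):
        self.w = w
        self.genera = genera  # sorted; column order of m
        self.lineages = lineages
        self.word_index = word_index
        self.m = m  # (n_words, n_genera) presence counts
        self.M = M  # (n_genera,) training sequences per genus
        self.n = m.sum(axis=1)  # document frequency over all sequences
        self.N = int(M.sum())
        self._genus_pos = {g: i for i, g in enumerate(genera)}
        self._lineage_names = np.array(
            [[lineages[g].at(r) for r in RANKS] for g in genera], dtype=object
        )

    def genus_index(self, genus: str) -> int:
        try:
            return self._genus_pos[genus]
        except KeyError:
            raise ClassifierError(f"genus {genus!r} not in model") from None


def query_words(sequence: str, w: int) -> list[str]:
    """Distinct overlapping w-mers over {A,C,G,T}, in order of first occurrence."""
    seen: dict[str, None] = {}
    for i in range(len(sequence) - w + 1):
        word = sequence[i:i + w]
        if all(c in "ACGT" for c in word):
            seen.setdefault(word, None)
    return list(seen)


def build_word_model(db: ReferenceDB, w: int = 8) -> WordModel:
    """Count per-genus word presence over the training sequences.

    Every record must carry a genus and be at least w bases long; a genus maps
    to exactly one lineage.
    """
    missing = [rec.id for rec in db if rec.lineage.at("genus") == ""]
    if missing:
        raise ClassifierError(f"records lacking genus: {missing}")
    short = [rec.id for rec in db if len(rec.sequence) < w]
    if short:
        raise ClassifierError(f"records shorter than w={w}: {short}")

    genera = db.genera()
    lineages: dict[str, RankedLineage] = {}
    for rec in db:
        g = rec.lineage.at("genus")
        if g in lineages and lineages[g] != rec.lineage:
            raise ClassifierError(f"genus {g!r} maps to two different lineages")
        lineages[g] = rec.lineage

    gpos = {g: i for i, g in enumerate(genera)}
    word_index: dict[str, int] = {}
    rows: list[tuple[int, int]] = []  # (word row, genus col) increments
    for rec in db:
        col = gpos[rec.lineage.at("genus")]
        for word in query_words(rec.sequence, w):
            row = word_index.setdefault(word, len(word_index))
            rows.append((row, col))
    m = np.zeros((len(word_index), len(genera)), dtype=np.float64)
    for row, col in rows:
        m[row, col] += 1
    M = np.zeros(len(genera), dtype=np.float64)
    for rec in db:
        M[gpos[rec.lineage.at("genus")]] += 1
    return WordModel(w, genera, lineages, word_index, m, M)


def _log_conditional(model: WordModel, words: Sequence[str]) -> np.ndarray:
    """(len(words), n_genera) matrix of log P(word|G); unseen words included."""
    rows = np.array([model.word_index.get(wd, -1) for wd in words], dtype=np.int64)
    n_q = np.where(rows >= 0, model.n[rows.clip(min=0)], 0.0)
    m_q = np.where(
        (rows >= 0)[:, None],
        model.m[rows.clip(min=0), :],
        0.0,
    )
    prior = (n_q + 0.5) / (model.N + 1)
    return np.log(m_q + prior[:, None]) - np.log(model.M + 1.0)[None, :]


def genus_score(
    query: Union[Iterable[str], str], model: WordModel, genus: str
) -> float:
    """Sum of log P(word|G) over the distinct query words."""
    words = query_words(query, model.w) if isinstance(query, str) else list(query)
    if not words:
        raise ClassifierError("empty query word set")
    col = model.genus_index(genus)
    return float(_log_conditional(model, words)[:, col].sum())


def _read_seed(boot: BootstrapParams, read_id: str) -> list[int]:
    return [boot.seed, zlib.crc32(read_id.encode()) & 0x7FFFFFFF]


def nb_classify(
    read: Union[ProcessedRead, tuple[str, str]],
    model: WordModel,
    boot: BootstrapParams = BootstrapParams(),
    both_strands: bool = False,
) -> TaxAssignment:
    """Classify one read: argmax genus plus bootstrap per-rank confidence.

    `read` is a ProcessedRead or an ``(id, sequence)`` pair.  With
    `both_strands`, the strand whose full-word-set score is higher is used
    (for ingested sequences of unknown orientation; pipeline reads are
    sense-oriented upstream).  Deterministic given ``boot.seed``.
    """
    if isinstance(read, ProcessedRead):
        read_id, seq = read.read_id, read.sequence
    else:
        read_id, seq = read
    if len(seq) < model.w:
        raise ClassifierError(f"read {read_id}: shorter than w={model.w}")
    words = query_words(seq, model.w)
    if both_strands:
        words_rc = query_words(revcomp(seq), model.w)
        if words_rc:
            logp_f = _log_conditional(model, words) if words else None
            logp_r = _log_conditional(model, words_rc)
            if logp_f is None or logp_r.sum(axis=0).max() > logp_f.sum(axis=0).max():
                words = words_rc
    if not words:
        raise ClassifierError(f"read {read_id}: no scorable words")

    logp = _log_conditional(model, words)  # (W, G)
    totals = logp.sum(axis=0)
    best_idx = int(np.argmax(totals))  # genera sorted -> lexicographic tie-break
    best_lineage = model.lineages[model.genera[best_idx]]

    W = len(words)
    k = math.ceil(boot.fraction * W)
    rng = np.random.default_rng(_read_seed(boot, read_id))
    draws = rng.integers(0, W, size=(boot.trials, k))
    trial_scores = logp[draws].sum(axis=1)  # (B, G)
    winners = np.empty(boot.trials, dtype=np.int64)
    maxima = trial_scores.max(axis=1)
    for t in range(boot.trials):
        tied = np.flatnonzero(trial_scores[t] == maxima[t])
        winners[t] = tied[0] if len(tied) == 1 else int(rng.choice(tied))

    best_names = best_lineage.names
    winner_names = model._lineage_names[winners]  # (B, 6)
    confidences = tuple(
        float(np.mean(winner_names[:, r] == best_names[r])) for r in range(len(RANKS))
    )
    return TaxAssignment(
        read_id=read_id,
        lineage=best_lineage,
        confidences=confidences,
        method="naive-bayes",
    )


def apply_confidence_threshold(a: TaxAssignment, tau: float) -> TaxAssignment:
    """Truncate to the deepest lineage prefix supported at >= tau at every rank."""
    if not 0.0 < tau <= 1.0:
        raise ClassifierError("tau must be in (0, 1]")
    depth = 0
    for r in range(len(RANKS)):
        if a.lineage.names[r] == "" or a.confidences[r] < tau:
            break
        depth += 1
    return dataclasses.replace(a, effective=a.lineage.prefix(depth), tau=tau)


def classify_reads(
    reads: Sequence[ProcessedRead],
    model: WordModel,
    boot: BootstrapParams = BootstrapParams(),
    both_strands: bool = False,
) -> list[TaxAssignment]:
    """nb_classify over every accepted read."""
    return [
        nb_classify(pr, model, boot, both_strands=both_strands)
        for pr in reads
        if pr.accepted
    ]


# ---------------------------------------------------------------------------
# serialization (JSON bundle) and assignment TSV
# ---------------------------------------------------------------------------

def save_model(model: WordModel, path) -> None:
    bundle = {
        "w": model.w,
        "genera": model.genera,
        "lineages": {g: model.lineages[g].to_string() for g in model.genera},
        "words": list(model.word_index),
        "m": model.m.astype(int).tolist(),
        "M": model.M.astype(int).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(bundle, fh)


def load_model(path) -> WordModel:
    with open(path) as fh:
        bundle = json.load(fh)
    word_index = {wd: i for i, wd in enumerate(bundle["words"])}
    lineages = {
        g: RankedLineage.from_string(s) for g, s in bundle["lineages"].items()
    }
    return WordModel(
        w=bundle["w"],
        genera=list(bundle["genera"]),
        lineages=lineages,
        word_index=word_index,
        m=np.array(bundle["m"], dtype=np.float64),
        M=np.array(bundle["M"], dtype=np.float64),
    )


def write_assignment_table(assignments: Sequence[TaxAssignment], path) -> None:
    """TSV: read id, per-rank name and confidence, effective lineage, flags."""
    with open(path, "w") as fh:
        header = ["read_id", "method", "tau", "ambiguous"]
        for r in RANKS:
            header += [r, f"{r}_conf"]
        header.append("effective")
        fh.write("\t".join(header) + "\n")
        for a in assignments:
            row = [
                a.read_id, a.method,
                "" if a.tau is None else f"{a.tau:g}",
                str(int(a.ambiguous)),
            ]
            for r in range(len(RANKS)):
                row += [a.lineage.names[r], f"{a.confidences[r]:.3f}"]
            row.append(a.effective.to_string() if a.effective is not None else "")
            fh.write("\t".join(row) + "\n")
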