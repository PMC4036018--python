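"""Rank-wise composition tables, drift, length-sensitivity and stability.

The analysis layer turns per-read assignments into relative-abundance
vectors at a chosen rank, compares vectors across truncation lengths (L1
drift with per-taxon deltas), traces how often a single genus is recovered
as a function of read length, and reports replicate-to-replicate stability.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Callable, Sequence
from typing import Optional

import numpy as np
import pandas as pd

from .nbayes import TaxAssignment, apply_confidence_threshold
from .readproc import (
    ProcessedRead, QualityFilterParams, TruncationSpec, process_sample,
)
from .simulate import PrimerArchitecture, Read
from .taxonomy import RANKS

UNCLASSIFIED = "(unclassified)"


class CompositionError(ValueError):
    pass


@dataclasses.dataclass
class CompositionTable:
    """Relative abundances of one sample/spec/method/tau at one rank.

    Abundances plus the unclassified fraction sum to 1 over `total_reads`
    classified input reads.
    """

    sample_id: str
    spec_name: str
    rank: str
    abundances: dict[str, float]
    unclassified: float
    total_reads: int
    method: str = ""
    tau: Optional[float] = None

    def check(self) -> None:
        total = sum(self.abundances.values()) + self.unclassified
        if abs(total - 1.0) > 1e-9:
            raise CompositionError(f"abundances sum to {total}, not 1")


def composition_table(
    assignments: Sequence[TaxAssignment],
    rank: str,
    others_floor: float = 0.0,
    sample_id: str = "",
    spec_name: str = "",
    method: str = "",
    tau: Optional[float] = None,
) -> CompositionTable:
    """Relative abundance per taxon at `rank` from effective lineages.

    Reads whose effective lineage is empty at the rank count as unclassified;
    taxa below `others_floor` are pooled into "Others".
    """
    if rank not in RANKS:
        raise CompositionError(f"unknown rank {rank!r}")
    if not assignments:
        raise CompositionError("no assignments")
    counts: dict[str, int] = {}
    unclassified = 0
    for a in assignments:
        lineage = a.effective if a.effective is not None else a.lineage
        name = lineage.at(rank)
        if name == "":
            unclassified += 1
        else:
            counts[name] = counts.get(name, 0) + 1
    n = len(assignments)
    abundances = {t: c / n for t, c in counts.items()}
    if others_floor > 0:
        pooled = sum(v for v in abundances.values() if v < others_floor)
        abundances = {t: v for t, v in abundances.items() if v >= others_floor}
        if pooled > 0:
            abundances["Others"] = abundances.get("Others", 0.0) + pooled
    table = CompositionTable(
        sample_id=sample_id, spec_name=spec_name, rank=rank,
        abundances=abundances, unclassified=unclassified / n,
        total_reads=n, method=method, tau=tau,
    )
    table.check()
    return table


@dataclasses.dataclass
class DriftReport:
    """L1 distance between two composition tables plus signed per-taxon deltas."""

    rank: str
    l1: float
    deltas: list[tuple[str, float]]  # sorted by |delta| descending


def composition_drift(a: CompositionTable, b: CompositionTable) -> DriftReport:
    """L1 distance (total variation x 2) over the taxon union, incl. unclassified."""
    if a.rank != b.rank:
        raise CompositionError(f"rank mismatch: {a.rank} vs {b.rank}")
    taxa = sorted(set(a.abundances) | set(b.abundances))
    deltas = [(t, b.abundances.get(t, 0.0) - a.abundances.get(t, 0.0)) for t in taxa]
    deltas.append((UNCLASSIFIED, b.unclassified - a.unclassified))
    l1 = float(sum(abs(d) for _, d in deltas))
    deltas.sort(key=lambda td: (-abs(td[1]), td[0]))
    return DriftReport(rank=a.rank, l1=l1, deltas=deltas)


@dataclasses.dataclass
class SensitivityCurve:
    """Recovery of one taxon as a function of read length."""

    taxon: str
    points: list[tuple[int, float, float]]  # (length, genus recovery, family recovery)

    def genus_proportions(self) -> list[float]:
        return [p[1] for p in self.points]


def length_sensitivity(
    reads: Sequence[Read],
    lengths: Sequence[Optional[int]],
    classify: Callable[[ProcessedRead], TaxAssignment],
    tau: float,
    primers: PrimerArchitecture,
    far_primer: str = "27F",
    qparams: QualityFilterParams = QualityFilterParams(),
) -> SensitivityCurve:
    """Truncate, classify and threshold reads of one genus at each length.

    `lengths` entries are fixed prefix lengths; None means the full
    between-primer region bounded by `far_primer`.  All reads must share one
    truth genus; each point reports the fraction of accepted reads whose
    effective lineage names the truth genus, and the fraction naming the
    truth family.
    """
    genera = {r.truth_lineage.at("genus") for r in reads}
    if len(genera) != 1 or "" in genera:
        raise CompositionError("reads must share a single truth genus")
    truth = next(iter(reads)).truth_lineage
    points: list[tuple[int, float, float]] = []
    for length in lengths:
        if length is None:
            spec = TruncationSpec(name=f"518R-{far_primer}", far_primer=far_primer)
        else:
            spec = TruncationSpec(name=f"518R-{length}", target_length=length)
        processed, _ = process_sample(reads, spec, primers, qparams)
        accepted = [pr for pr in processed if pr.accepted]
        if not accepted:
            raise CompositionError(f"no reads accepted at length {length}")
        genus_hits = family_hits = 0
        region_lengths = []
        for pr in accepted:
            a = apply_confidence_threshold(classify(pr), tau)
            if a.effective.at("genus") == truth.at("genus"):
                genus_hits += 1
            if a.effective.at("family") == truth.at("family"):
                family_hits += 1
            region_lengths.append(len(pr.sequence))
        eff_len = length if length is not None else int(np.median(region_lengths))
        points.append((eff_len, genus_hits / len(accepted), family_hits / len(accepted)))
    points.sort(key=lambda p: p[0])
    if len({p[0] for p in points}) != len(points):
        raise CompositionError("lengths must be distinct")
    return SensitivityCurve(taxon=truth.at("genus"), points=points)


@dataclasses.dataclass
class StabilityRow:
    taxon: str
    values: list[float]  # percent, one per replicate
    range_points: float  # max - min, percentage points
    flagged: bool


@dataclasses.dataclass
class StabilityReport:
    rank: str
    flag_threshold: float  # percentage points
    rows: list[StabilityRow]

    def flagged_taxa(self) -> list[str]:
        return [r.taxon for r in self.rows if r.flagged]


def replicate_stability(
    tables: Sequence[CompositionTable], flag_threshold: float = 5.0
) -> StabilityReport:
    """Per-taxon min/max/range (percentage points) across replicate tables.

    Taxa whose range across replicates exceeds `flag_threshold` percentage
    points are flagged as markedly unstable.
    """
    if len(tables) < 2:
        raise CompositionError("need at least 2 replicate tables")
    rank = tables[0].rank
    spec = tables[0].spec_name
    for t in tables[1:]:
        if t.rank != rank or t.spec_name != spec:
            raise CompositionError("replicate tables must share rank and spec")
    taxa = sorted(set().union(*(t.abundances.keys() for t in tables)))
    rows = []
    for taxon in taxa:
        values = [100.0 * t.abundances.get(taxon, 0.0) for t in tables]
        rng = max(values) - min(values)
        rows.append(StabilityRow(
            taxon=taxon, values=values, range_points=rng,
            flagged=rng > flag_threshold,
        ))
    return StabilityReport(rank=rank, flag_threshold=flag_threshold, rows=rows)


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def tables_to_frame(tables: Sequence[CompositionTable]) -> pd.DataFrame:
    """Long-format frame: sample, spec, method, tau, rank, taxon, abundance."""
    rows = []
    for t in tables:
        entries = sorted(t.abundances.items())
        entries.append((UNCLASSIFIED, t.unclassified))
        for taxon, ab in entries:
            rows.append({
                "sample": t.sample_id, "spec": t.spec_name, "method": t.method,
                "tau": "" if t.tau is None else f"{t.tau:g}", "rank": t.rank,
                "taxon": taxon, "abundance": round(ab, 9),
                "total_reads": t.total_reads,
            })
    return pd.DataFrame(rows)


def plot_compositions(tables: Sequence[CompositionTable], path) -> None:
    """Stacked-bar export of composition tables (one bar per sample/spec)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    taxa = sorted(set().union(*(t.abundances.keys() for t in tables))) + [UNCLASSIFIED]
    labels = [f"{t.sample_id}:{t.spec_name}" for t in tables]
    bottoms = np.zeros(len(tables))
    fig, ax = plt.subplots(figsize=(max(6, len(tables) * 0.6), 4))
    for taxon in taxa:
        vals = np.array([
            t.unclassified if taxon == UNCLASSIFIED else t.abundances.get(taxon, 0.0)
            for t in tables
        ])
        ax.bar(labels, vals, bottom=bottoms, label=taxon)
        bottoms += vals
    ax.set_ylabel("relative abundance")
    ax.legend(fontsize=6, ncol=2)
    plt.xticks(rotation=90, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
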