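"""Synthetic 16S-like communities with ground truth.

Everything downstream of sequencing is testable without any download: this
module generates a ranked taxonomy, ~1.5 kb reference sequences that carry
the conserved primer architecture of the bacterial 16S gene (27F, 109F, 518R,
1525R) around variable inter-primer regions, and MID-barcoded amplicon reads
sequenced from the 518R end with substitution and homopolymer-indel errors,
decaying qualities, and an optional fraction of two-parent chimeras.

The generator can plant a "confusable pair": two genera of the same family
that are identical over a window adjacent to the 518R site but divergent near
27F.  Reads truncated to that window cannot be resolved to genus, while reads
reaching 27F can — the geometry that makes amplicon read length matter.

All randomness flows from integer seeds through numpy Generators; identical
parameters and seed give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import math
import os
from collections.abc import Mapping, Sequence
from typing import Optional

import numpy as np

from .taxonomy import RANKS, RankedLineage, ReferenceDB, ReferenceSeq

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)


def revcomp(seq: str) -> str:
    """Reverse complement with IUPAC support."""
    return seq.translate(_COMPLEMENT)[::-1]


_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class SimulationError(ValueError):
    """Raised for invalid community or simulation parameters."""


# ---------------------------------------------------------------------------
# primer architecture
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PrimerSite:
    """A conserved primer site on the sense strand of the template.

    `sequence` is the primer as synthesized (5'->3'); for reverse-strand
    primers the site on the sense strand is its reverse complement.
    `start` is the 0-based template coordinate of the site's first base.
    """

    name: str
    sequence: str
    strand: str  # "+" or "-"
    start: int

    @property
    def site_sequence(self) -> str:
        """IUPAC site as it reads on the sense strand."""
        return self.sequence if self.strand == "+" else revcomp(self.sequence)

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclasses.dataclass(frozen=True)
class PrimerArchitecture:
    """Ordered conserved primer sites along the 16S template."""

    sites: tuple[PrimerSite, ...]

    def __post_init__(self) -> None:
        starts = [s.start for s in self.sites]
        if starts != sorted(starts) or len(set(starts)) != len(starts):
            raise SimulationError("primer coordinates must strictly increase")

    def site(self, name: str) -> PrimerSite:
        for s in self.sites:
            if s.name == name:
                return s
        raise SimulationError(f"unknown primer {name!r}")

    def __iter__(self):
        return iter(self.sites)


def default_architecture() -> PrimerArchitecture:
    """27F / 109F / 518R / 1525R at their canonical 16S coordinates."""
    return PrimerArchitecture((
        PrimerSite("27F", "AGAGTTTGATCMTGGCTCAG", "+", 8),
        PrimerSite("109F", "ACGGGTGMGTAACRCGT", "+", 108),
        PrimerSite("518R", "TTACCGCGGCTGCTGG", "-", 502),
        PrimerSite("1525R", "AAGGAGGTGWTCCARCC", "-", 1508),
    ))


# ---------------------------------------------------------------------------
# community specification
# ---------------------------------------------------------------------------

DEFAULT_RANK_DIVERGENCE: dict[str, float] = {
    "phylum": 0.12,
    "class": 0.08,
    "order": 0.05,
    "family": 0.035,
    "genus": 0.02,
}


@dataclasses.dataclass(frozen=True)
class ConfusablePair:
    """Two same-family genera sharing the window next to the 518R site.

    `shared_window` bases immediately upstream of the 518R site are copied
    between the pair (Hamming distance 0); the window starting at the 27F
    site's end is mutated to at least `divergence` differences.  Genus names
    left as None are auto-picked as the first two genera sharing a family.
    """

    genus_a: Optional[str] = None
    genus_b: Optional[str] = None
    shared_window: int = 400
    divergence: float = 0.10


@dataclasses.dataclass(frozen=True)
class CommunitySpec:
    """Shape, divergence and abundances of a synthetic community.

    The taxonomy has `n_phyla` phyla under one domain and branches
    `n_genera_per_path` ways at every rank below phylum, so it holds
    ``n_phyla * n_genera_per_path**4`` genera.  `rank_divergence` gives the
    per-site substitution rate applied at each rank split when references
    evolve from the common ancestor, so sequence similarity respects
    taxonomic depth.
    """

    n_phyla: int = 2
    n_genera_per_path: int = 2
    rank_divergence: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_RANK_DIVERGENCE)
    )
    genome_length: int = 1550
    abundances: Optional[Mapping[str, float]] = None
    confusable_pair: Optional[ConfusablePair] = None
    refs_per_genus: int = 1
    within_genus_divergence: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phyla < 1 or self.n_genera_per_path < 1:
            raise SimulationError("taxonomy must contain at least one genus")
        for rank, rate in self.rank_divergence.items():
            if not 0.0 <= rate <= 0.75:
                raise SimulationError(f"divergence rate for {rank} outside [0, 0.75]")
        if self.abundances is not None:
            vals = np.array(list(self.abundances.values()), dtype=float)
            if (vals < 0).any():
                raise SimulationError("abundances must be non-negative")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise SimulationError("abundances must sum to 1 within 1e-9")

    @property
    def n_genera(self) -> int:
        return self.n_phyla * self.n_genera_per_path ** 4


# ---------------------------------------------------------------------------
# taxonomy generation
# ---------------------------------------------------------------------------

_SYLLABLES = [
    "ba", "ce", "di", "fo", "ga", "hi", "ju", "ko", "la", "mi",
    "no", "pe", "qui", "ra", "su", "ta", "ve", "xa", "yo", "zu",
    "bra", "chlo", "stre", "myco", "rhi", "metha", "nitro", "sulfo",
]

_RANK_SUFFIX = {
    "phylum": "ota",
    "class": "ia",
    "order": "ales",
    "family": "aceae",
    "genus": "us",
}


def _fresh_name(rng: np.random.Generator, rank: str, used: set[str]) -> str:
    for _ in range(10000):
        k = int(rng.integers(2, 4))
        stem = "".join(rng.choice(_SYLLABLES) for _ in range(k))
        name = stem.capitalize() + _RANK_SUFFIX[rank]
        if name not in used:
            used.add(name)
            return name
    raise SimulationError("name space exhausted")


def generate_taxonomy(spec: CommunitySpec) -> list[RankedLineage]:
    """Deterministically generate distinct genus-level lineages.

    Returns ``n_phyla * n_genera_per_path**4`` lineages under the domain
    "Bacteria", with globally unique names at every rank (so a genus name
    identifies exactly one path).
    """
    rng = np.random.default_rng([spec.seed, 101])
    used: set[str] = set()
    lineages: list[RankedLineage] = []

    def descend(prefix: tuple[str, ...], rank_idx: int) -> None:
        rank = RANKS[rank_idx]
        n = spec.n_phyla if rank == "phylum" else spec.n_genera_per_path
        for _ in range(n):
            name = _fresh_name(rng, rank, used)
            path = prefix + (name,)
            if rank == "genus":
                lineages.append(RankedLineage(path))  # type: ignore[arg-type]
            else:
                descend(path, rank_idx + 1)

    descend(("Bacteria",), 1)
    return lineages


# ---------------------------------------------------------------------------
# reference sequence generation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


def _mutate(
    seq: np.ndarray, rate: float, rng: np.random.Generator, mutable: np.ndarray
) -> np.ndarray:
    """Substitute bases at `rate` on positions where `mutable` is True."""
    out = seq.copy()
    hit = (rng.random(len(seq)) < rate) & mutable
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def _mutate_exact(
    seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = seq.copy()
    for i in positions:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def _instantiate_site(site: PrimerSite, rng: np.random.Generator) -> str:
    """Fix degenerate positions of the sense-strand site to concrete bases."""
    return "".join(
        b if b in "ACGT" else rng.choice(list(_IUPAC_CHOICES[b]))
        for b in site.site_sequence
    )


def generate_reference_sequences(
    taxonomy: Sequence[RankedLineage],
    arch: PrimerArchitecture,
    spec: CommunitySpec,
) -> ReferenceDB:
    """Evolve one or more references per genus from a common ancestor.

    Primer sites are stamped once (degenerate positions fixed to one concrete
    base for the whole database) and never mutated, so every record carries
    exactly conserved sites.  Inter-primer segments accumulate substitutions
    at the per-rank divergence rates along the taxonomy, and the optional
    confusable pair is planted last.
    """
    L = spec.genome_length
    sites = [s for s in arch if s.end <= L]
    dropped = [s.name for s in arch if s.end > L]
    if any(s.name in ("27F", "518R") for s in arch if s.end > L):
        raise SimulationError("genome length does not accommodate 27F..518R")
    rng = np.random.default_rng([spec.seed, 202])

    ancestor = _random_seq(rng, L)
    site_seqs = {s.name: _instantiate_site(s, rng) for s in sites}
    mutable = np.ones(L, dtype=bool)
    for s in sites:
        ancestor[s.start:s.end] = np.frombuffer(site_seqs[s.name].encode(), dtype="S1")
        mutable[s.start:s.end] = False

    # group lineages into a tree keyed by rank prefixes
    genus_seq: dict[str, np.ndarray] = {}

    def descend(node_seq: np.ndarray, lineages: list[RankedLineage], rank_idx: int):
        rank = RANKS[rank_idx]
        rate = float(spec.rank_divergence.get(rank, 0.0))
        groups: dict[str, list[RankedLineage]] = {}
        for lin in lineages:
            groups.setdefault(lin.at(rank), []).append(lin)
        for name in sorted(groups):
            child = _mutate(node_seq, rate, rng, mutable)
            if rank == "genus":
                genus_seq[name] = child
            else:
                descend(child, groups[name], rank_idx + 1)

    descend(ancestor, list(taxonomy), 1)

    pair = spec.confusable_pair
    if pair is not None:
        _plant_confusable_pair(genus_seq, taxonomy, arch, spec, rng)

    lineage_by_genus = {lin.at("genus"): lin for lin in taxonomy}
    records: list[ReferenceSeq] = []
    for genus in sorted(genus_seq):
        base = genus_seq[genus]
        for i in range(spec.refs_per_genus):
            seq = base if spec.refs_per_genus == 1 else _mutate(
                base, spec.within_genus_divergence, rng, mutable
            )
            records.append(
                ReferenceSeq(
                    id=f"{genus}_{i + 1}",
                    sequence=seq.tobytes().decode(),
                    lineage=lineage_by_genus[genus],
                )
            )
    db = ReferenceDB(records)
    db.site_sequences = site_seqs  # type: ignore[attr-defined]
    return db


def pick_confusable_genera(taxonomy: Sequence[RankedLineage]) -> tuple[str, str]:
    """First two genera (in generation order) that share a family."""
    by_family: dict[str, list[str]] = {}
    for lin in taxonomy:
        by_family.setdefault(lin.at("family"), []).append(lin.at("genus"))
    for family in by_family:
        if len(by_family[family]) >= 2:
            pair = sorted(by_family[family])[:2]
            return pair[0], pair[1]
    raise SimulationError("no family with two genera; cannot pick a confusable pair")


def _plant_confusable_pair(
    genus_seq: dict[str, np.ndarray],
    taxonomy: Sequence[RankedLineage],
    arch: PrimerArchitecture,
    spec: CommunitySpec,
    rng: np.random.Generator,
) -> None:
    pair = spec.confusable_pair
    assert pair is not None
    if pair.genus_a is None or pair.genus_b is None:
        a, b = pick_confusable_genera(taxonomy)
    else:
        a, b = pair.genus_a, pair.genus_b
    for g in (a, b):
        if g not in genus_seq:
            raise SimulationError(f"confusable genus {g!r} not in taxonomy")
    s518 = arch.site("518R").start
    e27 = arch.site("27F").end
    if pair.shared_window > s518:
        raise SimulationError("confusable shared window exceeds the template")
    share_lo = s518 - pair.shared_window
    if share_lo < e27:
        raise SimulationError(
            "confusable shared window reaches into the 27F site; shrink it"
        )
    # B becomes a copy of A, divergent only between 27F and the shared window.
    seq_b = genus_seq[a].copy()
    window = np.arange(e27, share_lo)
    # keep conserved primer sites (109F may fall in this span) untouched
    protected = np.zeros(len(seq_b), dtype=bool)
    for s in arch:
        if s.end <= len(seq_b):
            protected[s.start:s.end] = True
    window = window[~protected[window]]
    n_mut = math.ceil(pair.divergence * len(window))
    positions = rng.choice(window, size=n_mut, replace=False)
    genus_seq[b] = _mutate_exact(seq_b, positions, rng)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

DEFAULT_MIDS: tuple[str, ...] = ("ACGAGTGCGT", "ACGCTCGACA", "AGACGCACTC")


@dataclasses.dataclass(frozen=True)
class SimParams:
    """Sequencing-run parameters for the amplicon read simulator.

    Reads are synthesized anti-sense from the 518R end (the sequencing-primer
    geometry of a 454 run multiplexed with MID barcodes): each read is
    ``MID + 518R primer + reverse complement of the 27F..518R template span``,
    truncated to a sampled length.  Qualities follow
    ``Q(pos) = round(Qstart - decay*pos)`` clipped to [2, 45] with a per-read
    Qstart; substitution errors are i.i.d. per base and homopolymer runs of
    length >= 3 gain single-base indels with probability growing linearly in
    run length.
    """

    n_reads: int = 2000
    n_samples: int = 3
    length_mean: float = 520.0
    length_sd: float = 25.0
    length_floor: int = 80
    substitution_rate: float = 0.005
    homopolymer_rate: float = 0.002
    qstart_mean: float = 37.0
    qstart_sd: float = 3.0
    quality_decay: float = 0.02
    chimera_rate: float = 0.0
    mid_sequences: tuple[str, ...] = DEFAULT_MIDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.chimera_rate <= 1.0:
            raise SimulationError("chimera_rate must be in [0, 1]")
        for name in ("substitution_rate", "homopolymer_rate", "quality_decay"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if len(set(self.mid_sequences)) != len(self.mid_sequences):
            raise SimulationError("MID sequences must be pairwise distinct")


@dataclasses.dataclass
class Read:
    """A simulated (or ingested) read with ground-truth annotations."""

    id: str
    sequence: str
    qualities: np.ndarray  # integer Phred, same length as sequence
    mid: str = ""
    truth_lineage: RankedLineage = dataclasses.field(default_factory=RankedLineage.empty)
    is_chimera: bool = False
    truth_parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.qualities) != len(self.sequence):
            raise SimulationError(f"read {self.id}: quality/sequence length mismatch")
        if len(self.qualities) and (
            self.qualities.min() < 0 or self.qualities.max() > 45
        ):
            raise SimulationError(f"read {self.id}: qualities outside [0, 45]")
        if self.is_chimera and len(self.truth_parents) != 2:
            raise SimulationError(f"chimera {self.id} needs exactly 2 parents")


def _qualities(rng: np.random.Generator, n: int, sim: SimParams) -> np.ndarray:
    qstart = rng.normal(sim.qstart_mean, sim.qstart_sd)
    q = np.round(qstart - sim.quality_decay * np.arange(n))
    return np.clip(q, 2, 45).astype(np.int64)


def _apply_substitutions(
    seq: list[str], rate: float, rng: np.random.Generator
) -> None:
    if rate <= 0:
        return
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        alt = [b for b in "ACGT" if b != seq[i]]
        seq[i] = alt[int(rng.integers(3))]


def _apply_homopolymer_indels(
    seq: list[str], quals: list[int], rate: float, rng: np.random.Generator
) -> tuple[list[str], list[int]]:
    """Single-base indels at homopolymer runs, P(run) = rate * (len - 2)."""
    if rate <= 0:
        return seq, quals
    out_s: list[str] = []
    out_q: list[int] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = j - i
        out_s.extend(seq[i:j])
        out_q.extend(quals[i:j])
        if run >= 3 and rng.random() < rate * (run - 2):
            if rng.random() < 0.5:
                out_s.append(seq[i])  # insertion extends the run
                out_q.append(quals[j - 1])
            else:
                out_s.pop()
                out_q.pop()
        i = j
    return out_s, out_q


def _amplicon_core(template: str, arch: PrimerArchitecture) -> str:
    """Anti-sense strand of the 27F..518R product (starts with the 518R primer)."""
    s27 = arch.site("27F").start
    e518 = arch.site("518R").end
    return revcomp(template[s27:e518])


def simulate_amplicon_reads(
    db: ReferenceDB,
    arch: PrimerArchitecture,
    sim: SimParams,
    abundances: Optional[Mapping[str, float]] = None,
) -> list[Read]:
    """Draw `n_reads` per sample from the community and sequence them.

    Each read's genus is drawn from `abundances` (uniform over the database's
    genera when omitted); the template span between 27F and 518R is excised
    and read 5'->3' from the 518R end, prefixed with the sample's MID and the
    518R primer.  Fully deterministic given `sim.seed`.
    """
    if sim.n_reads <= 0:
        raise SimulationError("n_reads must be positive")
    genera = db.genera()
    if not genera:
        raise SimulationError("database has no genus-annotated records")
    if abundances is None:
        probs = {g: 1.0 / len(genera) for g in genera}
    else:
        missing = set(genera) - set(abundances)
        if missing:
            raise SimulationError(f"abundances missing genera: {sorted(missing)}")
        probs = {g: float(abundances[g]) for g in genera}
    names = sorted(probs)
    p = np.array([probs[g] for g in names], dtype=float)
    p = p / p.sum()

    refs_by_genus = {g: db.records_for_genus(g) for g in names}
    cores = {rec.id: _amplicon_core(rec.sequence, arch) for rec in db}

    reads: list[Read] = []
    for sample_idx in range(sim.n_samples):
        mid = sim.mid_sequences[sample_idx % len(sim.mid_sequences)]
        rng = np.random.default_rng([sim.seed, 303, sample_idx])
        genus_draws = rng.choice(len(names), size=sim.n_reads, p=p)
        for i in range(sim.n_reads):
            genus = names[int(genus_draws[i])]
            refs = refs_by_genus[genus]
            rec = refs[int(rng.integers(len(refs)))]
            full = mid + cores[rec.id]
            length = int(np.clip(
                round(rng.normal(sim.length_mean, sim.length_sd)),
                sim.length_floor, len(full),
            ))
            seq = list(full[:length])
            quals = list(_qualities(rng, length, sim))
            _apply_substitutions(seq, sim.substitution_rate, rng)
            seq, quals = _apply_homopolymer_indels(
                seq, quals, sim.homopolymer_rate, rng
            )
            reads.append(Read(
                id=f"S{sample_idx + 1}_R{i:06d}",
                sequence="".join(seq),
                qualities=np.array(quals, dtype=np.int64),
                mid=mid,
                truth_lineage=rec.lineage,
                is_chimera=False,
                truth_parents=(),
            ))
    return reads


def inject_chimeras(
    reads: Sequence[Read],
    db: ReferenceDB,
    arch: PrimerArchitecture,
    sim: SimParams,
) -> list[Read]:
    """Replace a `chimera_rate` fraction of reads by two-parent splices.

    The breakpoint is uniform in the middle 60% of the read body (after the
    MID); parents come from distinct genera.  Splices are perfect (no extra
    errors), emulating a PCR crossover between intact templates.
    """
    if sim.chimera_rate == 0.0:
        return list(reads)
    genera = db.genera()
    if len(genera) < 2:
        raise SimulationError("chimera injection needs at least 2 genera")
    rng = np.random.default_rng([sim.seed, 404])
    cores = {rec.id: _amplicon_core(rec.sequence, arch) for rec in db}
    refs_by_genus = {g: db.records_for_genus(g) for g in genera}

    out: list[Read] = []
    for read in reads:
        if rng.random() >= sim.chimera_rate:
            out.append(read)
            continue
        ga, gb = rng.choice(len(genera), size=2, replace=False)
        rec_a = refs_by_genus[genera[int(ga)]][0]
        rec_b = refs_by_genus[genera[int(gb)]][0]
        core_len = len(read.sequence) - len(read.mid)
        if core_len < 20:
            out.append(read)
            continue
        bp = int(rng.integers(int(0.2 * core_len), int(0.8 * core_len)))
        core = cores[rec_a.id][:bp] + cores[rec_b.id][bp:]
        seq = read.mid + core[:core_len]
        quals = _qualities(rng, len(seq), sim)
        out.append(Read(
            id=read.id,
            sequence=seq,
            qualities=quals,
            mid=read.mid,
            truth_lineage=RankedLineage.empty(),
            is_chimera=True,
            truth_parents=(rec_a.id, rec_b.id),
        ))
    return out


# ---------------------------------------------------------------------------
# plain-text IO
# ---------------------------------------------------------------------------

def write_fastq(reads: Sequence[Read], path) -> None:
    """Phred+33 FASTQ, byte-stable for determinism checks."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.qualities) + "\n")


def read_fastq(path) -> list[Read]:
    """Ingest external reads; truth fields are left empty."""
    from Bio import SeqIO

    reads = []
    for sr in SeqIO.parse(os.fspath(path) if not hasattr(path, "read") else path, "fastq"):
        reads.append(Read(
            id=sr.id,
            sequence=str(sr.seq).upper(),
            qualities=np.array(sr.letter_annotations["phred_quality"], dtype=np.int64),
        ))
    return reads


def write_truth_table(reads: Sequence[Read], path) -> None:
    """TSV: read id, MID, lineage, chimera flag, parents."""
    with open(path, "w") as fh:
        fh.write("read_id\tmid\tlineage\tis_chimera\tparents\n")
        for r in reads:
            fh.write(
                f"{r.id}\t{r.mid}\t{r.truth_lineage.to_string()}\t"
                f"{int(r.is_chimera)}\t{','.join(r.truth_parents)}\n"
            )
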