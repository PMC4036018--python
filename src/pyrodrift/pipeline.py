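"""Config-driven orchestration of the full read-length experiment.

One run simulates (or ingests) a multiplexed amplicon library, demultiplexes
it, builds every truncation spec per sample, screens chimeras, classifies
with each configured method, thresholds at each minimum support, and writes
composition, drift, sensitivity and stability tables plus a per-stage audit
count table and a machine-readable manifest.  One global seed drives every
stage through derived substreams; an identical config yields a byte-identical
output bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from collections.abc import Mapping, Sequence
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .besthit import AlignmentScoreParams, HitFilterParams, best_hit_assign
from .chimera import ChimeraParams, remove_chimeras, write_verdict_table
from .composition import (
    CompositionTable, composition_drift, composition_table, length_sensitivity,
    replicate_stability, tables_to_frame,
)
from .nbayes import (
    BootstrapParams, apply_confidence_threshold, build_word_model, nb_classify,
    write_assignment_table,
)
from .readproc import (
    QualityFilterParams, TruncationSpec, default_specs, demultiplex, process_sample,
    write_audit_table,
)
from .simulate import (
    CommunitySpec, ConfusablePair, PrimerArchitecture, SimParams,
    default_architecture, generate_reference_sequences, generate_taxonomy,
    inject_chimeras, pick_confusable_genera, simulate_amplicon_reads,
    write_fastq, write_truth_table,
)
from .taxonomy import ReferenceDB, load_reference, write_reference

log = logging.getLogger("pyrodrift")

RANKS_REPORTED = ("phylum", "class", "order", "family", "genus")


class ConfigError(ValueError):
    pass


def geometric_abundances(genera: Sequence[str], ratio: float = 0.75) -> dict[str, float]:
    """Skewed community: abundance proportional to ratio**i over sorted genera."""
    weights = np.array([ratio ** i for i in range(len(genera))])
    weights /= weights.sum()
    raw = {g: float(w) for g, w in zip(sorted(genera), weights)}
    # renormalize exactly to 1 against float round-off
    total = sum(raw.values())
    return {g: v / total for g, v in raw.items()}


@dataclasses.dataclass
class RunConfig:
    """Everything one experiment run needs; see `from_yaml` for the file format."""

    seed: int = 1
    replicates: int = 3
    n_reads: int = 400
    community: CommunitySpec = dataclasses.field(default_factory=CommunitySpec)
    abundance_profile: str = "geometric"  # "uniform" | "geometric"
    abundance_ratio: float = 0.75
    sim: SimParams = dataclasses.field(default_factory=SimParams)
    specs: list[TruncationSpec] = dataclasses.field(default_factory=default_specs)
    quality: QualityFilterParams = dataclasses.field(default_factory=QualityFilterParams)
    chimera_screen: bool = True
    chimera: ChimeraParams = dataclasses.field(default_factory=ChimeraParams)
    classifiers: list[str] = dataclasses.field(
        default_factory=lambda: ["naive-bayes", "best-hit"]
    )
    boot: BootstrapParams = dataclasses.field(default_factory=BootstrapParams)
    hit_filters: HitFilterParams = dataclasses.field(default_factory=HitFilterParams)
    align_scores: AlignmentScoreParams = dataclasses.field(
        default_factory=AlignmentScoreParams
    )
    taus: list[float] = dataclasses.field(default_factory=lambda: [0.8, 0.5])
    others_floor: float = 0.01
    stability_flag_threshold: float = 5.0
    reference_path: Optional[str] = None  # ingest an external reference FASTA
    reads_path: Optional[str] = None      # ingest external FASTQ reads

    def validate(self) -> None:
        if not self.specs:
            raise ConfigError("at least one truncation spec is required")
        if not self.classifiers:
            raise ConfigError("at least one classifier is required")
        bad = set(self.classifiers) - {"naive-bayes", "best-hit"}
        if bad:
            raise ConfigError(f"unknown classifiers: {sorted(bad)}")
        if not self.taus:
            raise ConfigError("at least one support threshold is required")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        cfg = cls()
        seed = int(raw.get("seed", cfg.seed))
        community = dict(raw.get("community", {}))
        confusable = community.pop("confusable_pair", None)
        if confusable:
            community["confusable_pair"] = ConfusablePair(**confusable)
        community.setdefault("seed", seed)
        sim = dict(raw.get("sim", {}))
        sim.setdefault("seed", seed + 1)
        specs = [TruncationSpec(**s) for s in raw["specs"]] if "specs" in raw else default_specs()
        boot = dict(raw.get("bootstrap", {}))
        boot.setdefault("seed", seed + 7)
        return cls(
            seed=seed,
            replicates=int(raw.get("replicates", cfg.replicates)),
            n_reads=int(raw.get("n_reads", cfg.n_reads)),
            community=CommunitySpec(**community),
            abundance_profile=raw.get("abundance_profile", cfg.abundance_profile),
            abundance_ratio=float(raw.get("abundance_ratio", cfg.abundance_ratio)),
            sim=SimParams(**sim),
            specs=specs,
            quality=QualityFilterParams(**raw.get("quality", {})),
            chimera_screen=bool(raw.get("chimera_screen", True)),
            chimera=ChimeraParams(**raw.get("chimera", {})),
            classifiers=list(raw.get("classifiers", cfg.classifiers)),
            boot=BootstrapParams(**boot),
            hit_filters=HitFilterParams(**raw.get("hit_filters", {})),
            align_scores=AlignmentScoreParams(**raw.get("align_scores", {})),
            taus=[float(t) for t in raw.get("taus", cfg.taus)],
            others_floor=float(raw.get("others_floor", cfg.others_floor)),
            stability_flag_threshold=float(
                raw.get("stability_flag_threshold", cfg.stability_flag_threshold)
            ),
            reference_path=raw.get("reference_path"),
            reads_path=raw.get("reads_path"),
        )

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Mapping):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj
        return {
            f.name: plain(getattr(self, f.name)) for f in dataclasses.fields(self)
        }


def demo_config(seed: int = 7) -> RunConfig:
    """The bundled end-to-end demonstration: small but exercises every stage."""
    community = CommunitySpec(
        n_phyla=2, n_genera_per_path=2,
        confusable_pair=ConfusablePair(),
        seed=seed,
    )
    sim = SimParams(
        n_reads=300, n_samples=3, length_mean=520.0, length_sd=25.0,
        substitution_rate=0.004, homopolymer_rate=0.002,
        chimera_rate=0.03, seed=seed + 1,
    )
    return RunConfig(seed=seed, replicates=3, n_reads=300, community=community, sim=sim)


@dataclasses.dataclass
class RunResult:
    outdir: pathlib.Path
    db: ReferenceDB
    compositions: list[CompositionTable]
    audits: dict[tuple[str, str], dict[str, int]]
    manifest: dict


def _build_inputs(config: RunConfig):
    """Reference database + pooled multiplexed reads, simulated or ingested."""
    if config.reference_path:
        db = load_reference(config.reference_path, "header-embedded")
        taxonomy = sorted(
            {rec.lineage for rec in db}, key=lambda lin: lin.names
        )
    else:
        taxonomy = generate_taxonomy(config.community)
        db = generate_reference_sequences(
            taxonomy, default_architecture(), config.community
        )
    if config.reads_path:
        from .simulate import read_fastq
        reads = read_fastq(config.reads_path)
    else:
        genera = db.genera()
        if config.community.abundances is not None:
            abundances = dict(config.community.abundances)
        elif config.abundance_profile == "geometric":
            abundances = geometric_abundances(genera, config.abundance_ratio)
        else:
            abundances = {g: 1.0 / len(genera) for g in genera}
        sim = dataclasses.replace(
            config.sim, n_reads=config.n_reads, n_samples=config.replicates
        )
        arch = default_architecture()
        reads = simulate_amplicon_reads(db, arch, sim, abundances)
        if sim.chimera_rate > 0:
            reads = inject_chimeras(reads, db, arch, sim)
    return db, taxonomy, reads


def run_experiment(
    config: RunConfig, outdir, skip_classification: bool = False
) -> RunResult:
    """Execute the full grid and write the output bundle under `outdir`.

    `skip_classification` stops after extraction, filtering and the chimera
    screen (the CLI's `process` subcommand); the audit table is still written.
    """
    config.validate()
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    arch = default_architecture()

    log.info("building inputs (seed=%d)", config.seed)
    db, taxonomy, reads = _build_inputs(config)
    write_reference(db, out / "reference.fasta")
    write_fastq(reads, out / "reads.fastq")
    write_truth_table(reads, out / "truth.tsv")

    bins = demultiplex(reads, list(config.sim.mid_sequences[: config.replicates]))
    samples = [s for s in sorted(bins) if s != "unassigned" and bins[s]]

    model = None
    if "naive-bayes" in config.classifiers and not skip_classification:
        model = build_word_model(db)

    audits: dict[tuple[str, str], dict[str, int]] = {}
    compositions: list[CompositionTable] = []
    all_verdicts = []
    assignments_dir = out / "assignments"
    assignments_dir.mkdir(exist_ok=True)

    for sample in samples:
        for spec in config.specs:
            processed, audit = process_sample(
                bins[sample], spec, arch, config.quality, sample_id=sample
            )
            accepted = [pr for pr in processed if pr.accepted]
            if config.chimera_screen:
                screen = remove_chimeras(accepted, db, config.chimera)
                audit["chimera"] = len(screen.flagged)
                audit["accepted"] -= len(screen.flagged)
                accepted = [pr for pr in screen.clean if pr.accepted]
                all_verdicts.extend(screen.verdicts)
            audits[(sample, spec.name)] = audit
            log.info(
                "%s %s: %d/%d accepted", sample, spec.name,
                audit["accepted"], audit["input"],
            )
            for method in ([] if skip_classification else config.classifiers):
                if method == "naive-bayes":
                    raw = [nb_classify(pr, model, config.boot) for pr in accepted]
                else:
                    raw = [
                        best_hit_assign(
                            pr, db, config.hit_filters, config.align_scores,
                            strands="+",
                        )[0]
                        for pr in accepted
                    ]
                for tau in config.taus:
                    assigned = [apply_confidence_threshold(a, tau) for a in raw]
                    write_assignment_table(
                        assigned,
                        assignments_dir / f"{sample}_{spec.name}_{method}_tau{tau:g}.tsv",
                    )
                    if not assigned:
                        continue
                    for rank in RANKS_REPORTED:
                        compositions.append(composition_table(
                            assigned, rank, others_floor=config.others_floor,
                            sample_id=sample, spec_name=spec.name,
                            method=method, tau=tau,
                        ))

    write_audit_table(audits, out / "audit.tsv")
    if config.chimera_screen:
        write_verdict_table(all_verdicts, out / "chimera_verdicts.tsv")
    if compositions:
        frame = tables_to_frame(compositions)
        frame.sort_values(list(frame.columns)[:6], inplace=True, kind="mergesort")
        frame.to_csv(out / "compositions.tsv", sep="\t", index=False)
        _write_drift(compositions, config, out)
        _write_stability(compositions, config, out)
        _write_sensitivity(config, db, reads, model, out)

    manifest = {
        "package": "pyrodrift",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_reads_total": len(reads),
        "n_references": len(db),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return RunResult(out, db, compositions, audits, manifest)


def _full_region_spec(config: RunConfig) -> Optional[str]:
    for spec in config.specs:
        if spec.far_primer == "27F":
            return spec.name
    return None


def _write_drift(compositions, config, out) -> None:
    """L1 drift of every spec against the full 518R-27F region, per stratum."""
    baseline_name = _full_region_spec(config)
    if baseline_name is None:
        return
    index = {
        (t.sample_id, t.spec_name, t.method, t.tau, t.rank): t for t in compositions
    }
    rows = []
    for (sample, spec, method, tau, rank), table in sorted(
        index.items(), key=lambda kv: str(kv[0])
    ):
        base = index.get((sample, baseline_name, method, tau, rank))
        if base is None or spec == baseline_name:
            continue
        drift = composition_drift(base, table)
        top_taxon, top_delta = drift.deltas[0] if drift.deltas else ("", 0.0)
        rows.append(
            f"{sample}\t{spec}\t{method}\t{tau:g}\t{rank}\t{drift.l1:.6f}"
            f"\t{top_taxon}\t{top_delta:.6f}"
        )
    with open(out / "drift.tsv", "w") as fh:
        fh.write("sample\tspec\tmethod\ttau\trank\tl1\ttop_taxon\ttop_delta\n")
        fh.write("\n".join(rows) + ("\n" if rows else ""))


def _write_stability(compositions, config, out) -> None:
    groups: dict[tuple, list[CompositionTable]] = {}
    for t in compositions:
        groups.setdefault((t.spec_name, t.method, t.tau, t.rank), []).append(t)
    rows = []
    for (spec, method, tau, rank), tables in sorted(groups.items(), key=str):
        if len(tables) < 2:
            continue
        report = replicate_stability(tables, config.stability_flag_threshold)
        for r in report.rows:
            vals = "\t".join(f"{v:.2f}" for v in r.values)
            rows.append(
                f"{spec}\t{method}\t{tau:g}\t{rank}\t{r.taxon}\t{vals}"
                f"\t{r.range_points:.2f}\t{int(r.flagged)}"
            )
    with open(out / "stability.tsv", "w") as fh:
        n = max((len(t) for t in groups.values()), default=0)
        reps = "\t".join(f"rep{i + 1}_pct" for i in range(n))
        fh.write(f"spec\tmethod\ttau\trank\ttaxon\t{reps}\trange\tflagged\n")
        fh.write("\n".join(rows) + ("\n" if rows else ""))


def _write_sensitivity(config, db, reads, model, out) -> None:
    """Genus-recovery-vs-length curve for the planted confusable genus.

    Uses a dedicated error-free read set drawn from that genus alone (the
    way a length-sensitivity analysis isolates reads of the taxon under
    study), so the curve does not depend on how many pool reads the genus
    happened to draw.
    """
    pair = config.community.confusable_pair
    if pair is None or model is None or config.reads_path:
        return
    taxonomy = sorted({rec.lineage for rec in db}, key=lambda lin: lin.names)
    if pair.genus_a is not None:
        genus = pair.genus_a
    else:
        genus, _ = pick_confusable_genera(taxonomy)
    arch = default_architecture()
    sens_sim = SimParams(
        n_reads=150, n_samples=1, length_mean=2000.0, length_sd=0.0,
        substitution_rate=0.0, homopolymer_rate=0.0,
        mid_sequences=("",), seed=config.seed + 11,
    )
    abundances = {g: (1.0 if g == genus else 0.0) for g in db.genera()}
    target = simulate_amplicon_reads(db, arch, sens_sim, abundances)
    curve = length_sensitivity(
        target, [250, 300, 350, 400, None],
        classify=lambda pr: nb_classify(pr, model, config.boot),
        tau=config.taus[0], primers=arch, far_primer="27F",
        qparams=config.quality,
    )
    with open(out / "sensitivity.tsv", "w") as fh:
        fh.write("taxon\tlength\tgenus_recovery\tfamily_recovery\n")
        for length, gp, fp in curve.points:
            fh.write(f"{curve.taxon}\t{length}\t{gp:.4f}\t{fp:.4f}\n")
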