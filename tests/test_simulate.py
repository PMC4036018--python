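import dataclasses

import numpy as np
import pytest

from pyrodrift import (
    CommunitySpec, ConfusablePair, SimParams, generate_reference_sequences,
    generate_taxonomy, inject_chimeras, pick_confusable_genera, revcomp,
    simulate_amplicon_reads,
)
from pyrodrift.simulate import (
    SimulationError, _amplicon_core, write_fastq,
)


class TestTaxonomy:
    def test_genus_count_is_product_of_branching(self):
        spec = CommunitySpec(n_phyla=2, n_genera_per_path=2, seed=1)
        assert len(generate_taxonomy(spec)) == 32  # 2 * 2**4

    def test_deterministic_given_seed(self):
        spec = CommunitySpec(seed=5)
        a = generate_taxonomy(spec)
        b = generate_taxonomy(spec)
        assert [x.names for x in a] == [y.names for y in b]

    def test_different_seed_different_names(self):
        a = {l.at("genus") for l in generate_taxonomy(CommunitySpec(seed=1))}
        b = {l.at("genus") for l in generate_taxonomy(CommunitySpec(seed=2))}
        assert a != b

    def test_genus_names_unique(self, taxonomy):
        genera = [l.at("genus") for l in taxonomy]
        assert len(genera) == len(set(genera))

    def test_invalid_spec_rejected(self):
        with pytest.raises(SimulationError):
            CommunitySpec(n_phyla=0)
        with pytest.raises(SimulationError):
            CommunitySpec(rank_divergence={"phylum": 0.9})
        with pytest.raises(SimulationError):
            CommunitySpec(abundances={"A": 0.5, "B": 0.6})


class TestReferences:
    def test_primer_sites_exactly_conserved(self, refdb, arch):
        site518 = arch.site("518R")
        for rec in refdb:
            window = rec.sequence[site518.start:site518.end]
            assert rec.sequence.count(window) >= 1
            # all records share the identical instantiated site
            assert window == refdb.records[0].sequence[site518.start:site518.end]

    def test_confusable_pair_shares_window_and_diverges_near_27F(
        self, refdb, taxonomy, arch, community_spec
    ):
        a, b = pick_confusable_genera(taxonomy)
        sa = refdb.records_for_genus(a)[0].sequence
        sb = refdb.records_for_genus(b)[0].sequence
        s518 = arch.site("518R").start
        window = community_spec.confusable_pair.shared_window
        shared_a = sa[s518 - window:s518]
        shared_b = sb[s518 - window:s518]
        assert shared_a == shared_b  # Hamming distance 0 on the shared window
        e27 = arch.site("27F").end
        near27 = [
            (x, y) for x, y in zip(sa[e27:s518 - window], sb[e27:s518 - window])
        ]
        diffs = sum(x != y for x, y in near27)
        assert diffs >= 0.10 * len(near27) * 0.9  # ~10% divergence planted

    def test_identity_respects_taxonomic_depth(self, refdb, taxonomy):
        # two genera in one family vs two genera in different phyla
        by_family, by_phylum = {}, {}
        for lin in taxonomy:
            by_family.setdefault(lin.at("family"), []).append(lin.at("genus"))
            by_phylum.setdefault(lin.at("phylum"), []).append(lin.at("genus"))
        fam = next(v for v in by_family.values() if len(v) >= 2)
        phyla = list(by_phylum.values())
        cross = (phyla[0][0], phyla[1][0])

        def identity(g1, g2):
            s1 = refdb.records_for_genus(g1)[0].sequence
            s2 = refdb.records_for_genus(g2)[0].sequence
            return np.mean([a == b for a, b in zip(s1, s2)])

        assert identity(fam[0], fam[1]) > identity(*cross)

    def test_window_exceeding_template_errors(self, taxonomy, arch):
        bad = CommunitySpec(
            confusable_pair=ConfusablePair(shared_window=5000), seed=11,
        )
        with pytest.raises(SimulationError):
            generate_reference_sequences(taxonomy, arch, bad)


class TestReadSimulation:
    def test_zero_error_read_is_revcomp_of_template_span(self, refdb, arch):
        sim = SimParams(
            n_reads=5, n_samples=1, length_mean=2000.0, length_sd=0.0,
            substitution_rate=0.0, homopolymer_rate=0.0, seed=9,
        )
        reads = simulate_amplicon_reads(refdb, arch, sim)
        genus_rec = {
            rec.lineage.at("genus"): rec for rec in refdb
        }
        for read in reads:
            rec = genus_rec[read.truth_lineage.at("genus")]
            expected = read.mid + _amplicon_core(rec.sequence, arch)
            assert read.sequence == expected
            # the 518R primer follows the MID exactly
            s518 = arch.site("518R")
            site = rec.sequence[s518.start:s518.end]
            assert read.sequence[len(read.mid):len(read.mid) + 16] == revcomp(site)

    def test_abundance_recovery_binomial(self, refdb, arch):
        genera = refdb.genera()
        p_a = 0.3
        rest = (1 - p_a) / (len(genera) - 1)
        ab = {g: (p_a if g == genera[0] else rest) for g in genera}
        total = sum(ab.values())
        ab = {g: v / total for g, v in ab.items()}
        sim = SimParams(n_reads=6000, n_samples=1, substitution_rate=0.0, seed=13)
        reads = simulate_amplicon_reads(refdb, arch, sim, ab)
        count = sum(r.truth_lineage.at("genus") == genera[0] for r in reads)
        sd = np.sqrt(6000 * p_a * (1 - p_a))
        assert abs(count - 6000 * p_a) <= 3 * sd

    def test_homopolymer_indels_concentrate_on_tracts(self, refdb, arch):
        # compare read lengths: with homopolymer errors on, length changes
        base = SimParams(
            n_reads=300, n_samples=1, length_mean=2000.0, length_sd=0.0,
            substitution_rate=0.0, homopolymer_rate=0.0, seed=17,
        )
        noisy = dataclasses.replace(base, homopolymer_rate=0.01)
        clean_lengths = [len(r.sequence) for r in simulate_amplicon_reads(refdb, arch, base)]
        noisy_lengths = [len(r.sequence) for r in simulate_amplicon_reads(refdb, arch, noisy)]
        assert clean_lengths != noisy_lengths
        changed = sum(a != b for a, b in zip(clean_lengths, noisy_lengths))
        assert changed > 30  # indels do occur at tracts

    def test_byte_identical_fastq_given_seed(self, refdb, arch, tmp_path):
        sim = SimParams(n_reads=40, n_samples=2, seed=23)
        for name in ("a", "b"):
            write_fastq(
                simulate_amplicon_reads(refdb, arch, sim), tmp_path / f"{name}.fastq"
            )
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_invalid_n_reads(self, refdb, arch):
        with pytest.raises(SimulationError):
            simulate_amplicon_reads(refdb, arch, SimParams(n_reads=0))


class TestChimeraInjection:
    def test_rate_zero_is_identity(self, refdb, arch, clean_reads):
        reads, sim = clean_reads
        out = inject_chimeras(reads, refdb, arch, sim)
        assert len(out) == len(reads)
        assert all(a is b for a, b in zip(out, reads))

    def test_chimera_count_binomial(self, refdb, arch):
        sim = SimParams(n_reads=5000, n_samples=1, chimera_rate=0.1, seed=31)
        reads = simulate_amplicon_reads(refdb, arch, sim)
        out = inject_chimeras(reads, refdb, arch, sim)
        n_chim = sum(r.is_chimera for r in out)
        sd = np.sqrt(5000 * 0.1 * 0.9)
        assert abs(n_chim - 500) <= 3 * sd
        for r in out:
            if r.is_chimera:
                assert len(r.truth_parents) == 2

    def test_chimera_prefix_and_suffix_match_their_parents(self, refdb, arch):
        import edlib
        sim = SimParams(
            n_reads=60, n_samples=1, chimera_rate=0.3, substitution_rate=0.0,
            homopolymer_rate=0.0, length_mean=600.0, length_sd=0.0, seed=37,
        )
        reads = inject_chimeras(
            simulate_amplicon_reads(refdb, arch, sim), refdb, arch, sim
        )
        chims = [r for r in reads if r.is_chimera][:10]
        assert chims

        def dist(seg, ref):
            return edlib.align(seg, ref, mode="HW", task="distance")["editDistance"]

        for r in chims:
            core = r.sequence[len(r.mid):]
            a = _amplicon_core(refdb.get(r.truth_parents[0]).sequence, arch)
            b = _amplicon_core(refdb.get(r.truth_parents[1]).sequence, arch)
            half = len(core) // 2
            # prefix belongs to parent A, suffix to parent B (strictly better)
            assert dist(core[:half // 2], a) <= dist(core[:half // 2], b)
            assert dist(core[-half // 2:], b) <= dist(core[-half // 2:], a)

    def test_single_genus_db_with_chimeras_errors(self, arch):
        spec = CommunitySpec(n_phyla=1, n_genera_per_path=1, seed=3)
        tax = generate_taxonomy(spec)
        db = generate_reference_sequences(tax, arch, spec)
        sim = SimParams(n_reads=10, n_samples=1, chimera_rate=0.5, seed=3)
        reads = simulate_amplicon_reads(db, arch, sim)
        with pytest.raises(SimulationError):
            inject_chimeras(reads, db, arch, sim)
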