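import numpy as np
import pytest

from pyrodrift import (
    BootstrapParams, CompositionTable, apply_confidence_threshold,
    composition_drift, composition_table, length_sensitivity, nb_classify,
    replicate_stability,
)
from pyrodrift.composition import CompositionError, UNCLASSIFIED, tables_to_frame
from pyrodrift.nbayes import TaxAssignment
from pyrodrift.taxonomy import RankedLineage


def _assignment(genus, rid="r"):
    if genus is None:
        lineage = RankedLineage.empty()
    else:
        lineage = RankedLineage.from_names("Bacteria", "P", "C", "O", "F", genus)
    a = TaxAssignment(rid, lineage, (1.0,) * 6, "naive-bayes")
    a.effective = lineage
    return a


class TestCompositionTable:
    def test_counting_with_unclassified(self):
        assignments = (
            [_assignment("GenA", f"a{i}") for i in range(3)]
            + [_assignment("GenB", f"b{i}") for i in range(2)]
            + [_assignment(None, f"u{i}") for i in range(5)]
        )
        t = composition_table(assignments, "genus")
        assert t.abundances == {"GenA": 0.3, "GenB": 0.2}
        assert t.unclassified == 0.5 and t.total_reads == 10

    def test_zero_floor_pools_nothing(self):
        assignments = [_assignment("GenA")] * 99 + [_assignment("GenB")]
        t = composition_table(assignments, "genus", others_floor=0.0)
        assert "Others" not in t.abundances and t.abundances["GenB"] == 0.01

    def test_floor_pools_rare_taxa_into_others(self):
        assignments = [_assignment("GenA")] * 99 + [_assignment("GenB")]
        t = composition_table(assignments, "genus", others_floor=0.05)
        assert t.abundances == {"GenA": 0.99, "Others": 0.01}

    def test_empty_input_errors(self):
        with pytest.raises(CompositionError):
            composition_table([], "genus")

    def test_normalization_invariant(self):
        rng = np.random.default_rng(0)
        assignments = [
            _assignment(rng.choice(["GenA", "GenB", "GenC", None]), str(i))
            for i in range(57)
        ]
        t = composition_table(assignments, "genus", others_floor=0.02)
        t.check()  # sums to 1 within 1e-9


class TestCompositionDrift:
    def _table(self, abundances, unclassified=0.0):
        return CompositionTable("S1", "spec", "genus", abundances, unclassified,
                                total_reads=100)

    def test_identical_tables_zero_drift(self):
        t = self._table({"A": 0.6, "B": 0.4})
        assert composition_drift(t, t).l1 == 0.0

    def test_disjoint_tables_maximal_drift(self):
        a = self._table({"A": 1.0})
        b = self._table({"B": 1.0})
        assert composition_drift(a, b).l1 == pytest.approx(2.0)

    def test_rank_mismatch_errors(self):
        a = self._table({"A": 1.0})
        b = CompositionTable("S1", "spec", "family", {"A": 1.0}, 0.0, 100)
        with pytest.raises(CompositionError):
            composition_drift(a, b)

    def test_deltas_sorted_by_magnitude(self):
        a = self._table({"A": 0.5, "B": 0.3, "C": 0.2})
        b = self._table({"A": 0.1, "B": 0.35, "C": 0.2}, unclassified=0.35)
        drift = composition_drift(a, b)
        mags = [abs(d) for _, d in drift.deltas]
        assert mags == sorted(mags, reverse=True)
        assert drift.deltas[0][0] == "A"


class TestReplicateStability:
    def _tables(self, per_rep):
        return [
            CompositionTable(f"S{i + 1}", "P518R-27F", "genus",
                             {t: v / 100 for t, v in rep.items()},
                             1 - sum(rep.values()) / 100, 1000)
            for i, rep in enumerate(per_rep)
        ]

    def test_identical_replicates_unflagged(self):
        tables = self._tables([{"A": 30.0}] * 3)
        report = replicate_stability(tables, 5.0)
        assert report.flagged_taxa() == [] and report.rows[0].range_points == 0.0

    def test_unstable_taxon_flagged(self):
        # the instability pattern seen for Burkholderia: 17.0 / 19.9 / 29.2 %
        tables = self._tables([{"A": 17.0}, {"A": 19.9}, {"A": 29.2}])
        report = replicate_stability(tables, 5.0)
        assert report.flagged_taxa() == ["A"]
        assert report.rows[0].range_points == pytest.approx(12.2)

    def test_stable_taxon_not_flagged_at_ten_points(self):
        # the stable pattern seen for Bradyrhizobium: 32.7 / 27.8 / 29.8 %
        tables = self._tables([{"A": 32.7}, {"A": 27.8}, {"A": 29.8}])
        report = replicate_stability(tables, 10.0)
        assert report.flagged_taxa() == []
        assert report.rows[0].range_points == pytest.approx(4.9)

    def test_fewer_than_two_tables_errors(self):
        with pytest.raises(CompositionError):
            replicate_stability(self._tables([{"A": 1.0}]))


class TestParameterRecovery:
    def test_known_abundances_recovered_from_clean_reads(
        self, refdb, arch, word_model, qparams
    ):
        from pyrodrift import (
            SimParams, TruncationSpec, demultiplex, process_sample,
            simulate_amplicon_reads,
        )
        genera = refdb.genera()
        p_a = 0.30
        rest = (1 - p_a) / (len(genera) - 1)
        ab = {g: (p_a if g == genera[0] else rest) for g in genera}
        total = sum(ab.values())
        ab = {g: v / total for g, v in ab.items()}
        n = 800
        sim = SimParams(
            n_reads=n, n_samples=1, length_mean=600.0, length_sd=0.0,
            substitution_rate=0.0, homopolymer_rate=0.0, seed=41,
        )
        reads = simulate_amplicon_reads(refdb, arch, sim, ab)
        sample = demultiplex(reads, list(sim.mid_sequences))["S1"]
        spec = TruncationSpec(name="full", far_primer="27F")
        processed, _ = process_sample(sample, spec, arch, qparams, "S1")
        boot = BootstrapParams(seed=43)
        assigned = [
            apply_confidence_threshold(nb_classify(pr, word_model, boot), 0.8)
            for pr in processed if pr.accepted
        ]
        t = composition_table(assigned, "genus")
        got = t.abundances.get(genera[0], 0.0)
        sd = np.sqrt(p_a * (1 - p_a) / n)
        assert abs(got - p_a) <= 3 * sd


class TestLengthSensitivity:
    def test_confusable_genus_recovers_only_at_full_length(
        self, refdb, taxonomy, arch, word_model, qparams
    ):
        from pyrodrift import SimParams, pick_confusable_genera, simulate_amplicon_reads
        genus_a, _ = pick_confusable_genera(taxonomy)
        ab = {g: (1.0 if g == genus_a else 0.0) for g in refdb.genera()}
        sim = SimParams(
            n_reads=80, n_samples=1, length_mean=600.0, length_sd=0.0,
            substitution_rate=0.0, homopolymer_rate=0.0, seed=47,
            mid_sequences=("",),
        )
        reads = simulate_amplicon_reads(refdb, arch, sim, ab)
        boot = BootstrapParams(seed=48)
        curve = length_sensitivity(
            reads, [250, 300, 350, 400, None],
            classify=lambda pr: nb_classify(pr, word_model, boot),
            tau=0.8, primers=arch,
        )
        props = curve.genus_proportions()
        assert all(x <= y + 1e-9 for x, y in zip(props, props[1:]))
        assert props[-1] >= 0.9 and props[0] <= 0.5
        # family recovery dominates genus recovery at every length
        for _, gp, fp in curve.points:
            assert fp >= gp

    def test_non_confusable_genus_recovered_at_all_lengths(
        self, refdb, taxonomy, arch, word_model, qparams
    ):
        from pyrodrift import SimParams, pick_confusable_genera, simulate_amplicon_reads
        confusable = set(pick_confusable_genera(taxonomy))
        genus = next(g for g in refdb.genera() if g not in confusable)
        ab = {g: (1.0 if g == genus else 0.0) for g in refdb.genera()}
        sim = SimParams(
            n_reads=40, n_samples=1, length_mean=600.0, length_sd=0.0,
            substitution_rate=0.0, homopolymer_rate=0.0, seed=49,
            mid_sequences=("",),
        )
        reads = simulate_amplicon_reads(refdb, arch, sim, ab)
        boot = BootstrapParams(seed=50)
        curve = length_sensitivity(
            reads, [250, 400, None],
            classify=lambda pr: nb_classify(pr, word_model, boot),
            tau=0.8, primers=arch,
        )
        assert all(gp == 1.0 for _, gp, _ in curve.points)

    def test_mixed_genera_rejected(self, clean_reads):
        reads, _ = clean_reads
        with pytest.raises(CompositionError):
            length_sensitivity(reads, [250], classify=None, tau=0.8, primers=None)


def test_tables_to_frame_long_format():
    t = CompositionTable("S1", "P518R-250", "genus", {"A": 0.7}, 0.3, 10,
                         method="naive-bayes", tau=0.8)
    frame = tables_to_frame([t])
    assert list(frame["taxon"]) == ["A", UNCLASSIFIED]
    assert frame["abundance"].sum() == pytest.approx(1.0)
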