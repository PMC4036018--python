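"""Build the simulated samples: fixed-length truncations and primer-bounded regions.

Each read is anchored at the 518R primer (edit distance 0), cut either to a
fixed number of bases or at a far primer (27F/109F, edit distance <= 2),
re-oriented to the sense strand, and passed through the average-quality and
ambiguity filters.  The audit table shows where reads are lost — note how the
518R-27F region keeps fewer reads (only reads long enough to span it survive).
"""

from pyrodrift import (
    CommunitySpec, QualityFilterParams, SimParams, demultiplex,
    generate_reference_sequences, generate_taxonomy, process_sample,
    simulate_amplicon_reads,
)
from pyrodrift.readproc import default_specs
from pyrodrift.simulate import default_architecture

spec = CommunitySpec(seed=42)
arch = default_architecture()
db = generate_reference_sequences(generate_taxonomy(spec), arch, spec)
sim = SimParams(n_reads=300, n_samples=1, substitution_rate=0.005, seed=43)
reads = demultiplex(simulate_amplicon_reads(db, arch, sim),
                    list(sim.mid_sequences))["S1"]

print(f"{'spec':<12}{'input':>6}{'accept':>7}{'no_prim':>8}{'short':>6}"
      f"{'no_far':>7}{'lowQ':>6}")
for tspec in default_specs():
    _, audit = process_sample(reads, tspec, arch, QualityFilterParams(), "S1")
    print(f"{tspec.name:<12}{audit['input']:>6}{audit['accepted']:>7}"
          f"{audit['no_primer']:>8}{audit['too_short']:>6}"
          f"{audit['no_far_primer']:>7}{audit['low_quality']:>6}")
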