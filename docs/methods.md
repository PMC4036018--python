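# Methods

`pyrodrift` studies a bioinformatic artifact: how the *length* of a 16S rRNA
amplicon read and the choice of assignment method change the community
composition a survey reports, independent of any biology in the sample.  The
package simulates the whole measurement process on a community whose
composition is known exactly, so every distortion the pipeline introduces is
measurable.  This note records the models, the parameters that matter, the
numerical choices, and what the simulations do and do not show about real
data.

## The sequencing geometry

The simulated amplicons follow the V1–V3 design of a multiplexed
pyrosequencing run: templates are amplified between the conserved 27F and
518R primer sites and sequenced **anti-sense from the 518R end**, so base 1
of every read sits just downstream of the 518R primer and the read walks
from V3 back toward V1.  Each read is

```
MID barcode + 518R primer + reverse complement of the 27F..518R template span
```

truncated to a sampled read length.  This geometry is what makes "the first
N bases past the 518R primer" a window that covers V3→V2 before it ever
reaches V1 — and it is why read length matters: taxa whose V2–V3 regions are
shared with a neighbor can only be separated by reads long enough to reach
the diagnostic V1-proximal bases.

The default primer architecture places 27F (`AGAGTTTGATCMTGGCTCAG`) at
template position 8, 109F (`ACGGGTGMGTAACRCGT`) at 108, the 518R site
(reverse complement of `TTACCGCGGCTGCTGG`) ending at 518 and 1525R
(`AAGGAGGTGWTCCARCC`) ending at 1525, on a 1550-base template (the template
default is sized so that all four canonical sites fit at their coordinates).
Degenerate primer positions are instantiated to concrete bases once per
database, so primer sites are strictly identical across all references —
reads must match them exactly when error-free, and the confusable pair's
shared window (which contains the 109F site) stays at Hamming distance 0.

## The synthetic community

A taxonomy of `n_phyla × n_genera_per_path⁴` genera is generated under one
domain with globally unique pseudo-Latin names, so a genus name identifies
exactly one lineage.  References evolve from a single random ancestor by
substitutions applied at each rank split, at per-rank rates (defaults:
phylum 0.12, class 0.08, order 0.05, family 0.035, genus 0.02 substitutions
per site, primer sites masked).  Two genera therefore grow more similar the
deeper their shared taxonomy — the property classifiers actually rely on.
These rates are this package's choice of a realistic 16S-like divergence
structure, not an estimate fitted to any particular dataset.

**The confusable pair.**  On request the generator plants the phenomenon
under study: two genera of the *same family* whose sequences are identical
over the `shared_window` (default 400) bases immediately upstream of the
518R site and ~10% divergent between the 27F site and that window.  Reads
that never leave the shared window carry literally zero bases distinguishing
the pair; reads reaching the 27F-proximal window are trivially separable.
The pair is constructed within one family deliberately: it makes family-level
assignment robust at every read length while genus-level assignment depends
entirely on length, which is the contrast of interest.

**Read simulation.**  Genus is drawn per read from the abundance vector;
read length from a normal distribution (mean 520, sd 25, floor 80) truncated
to the full amplicon; per-base qualities follow
`Q(pos) = round(Qstart − 0.02·pos)` clipped to [2, 45] with per-read
`Qstart ~ N(37, 3)`, so a realistic tail of reads fails the mean-Q ≥ 25
filter.  Substitution errors are i.i.d. per base (default 0.005, applied to
the MID and primer too, so demultiplexing and primer anchoring lose a
realistic few percent of reads).  Homopolymer runs of length r ≥ 3 receive a
single-base insertion or deletion with probability `rate · (r − 2)` — the
simplest signature of pyrosequencing's dominant error mode.  Error rates are
module parameters, not claims about any instrument.  Chimeras are perfect
two-parent splices: a configurable fraction of reads is replaced by
`parentA[..b] + parentB[b..]` with the breakpoint uniform in the middle 60%
of the read and parents from distinct genera.

Not modeled: flowgram-level signal, PCR amplification bias, chimeras with
errors or more than two parents, and Sanger chromatogram artifacts.  Passing
tests therefore demonstrate the *pipeline's* behavior under controlled
distortions, not instrument realism.

## Read processing

Demultiplexing requires an exact MID prefix (MIDs are short, equal-length
and pairwise distinct, so ties are impossible); mismatches go to an
`unassigned` bin.  Primer location uses semi-global (infix) Levenshtein
distance with IUPAC compatibility as the zero-cost match predicate, computed
by edlib with an extended equality relation and verified against a
brute-force DP in the tests.  The anchor (518R) must match at edit distance
0 within the first `len(primer)+5` bases; the far primer (27F/109F, reverse
complemented into read orientation) at edit distance ≤ 2 anywhere.

"The first N bases of the 518R primer" is interpreted as the first N bases
*after* trimming the anchor primer (primer bases carry no taxonomic signal);
a config switch (`include_primer`) restores the other reading.  Extracted
regions are reverse-complemented into sense orientation before
classification, making the word model and the aligner strand-uniform; reads
of unknown orientation (external FASTA) can still be scored on both strands.
The quality filter computes the arithmetic mean Phred over the extracted
region only (≥ 25, boundary inclusive) and tolerates no Ns by default.
Every read ends accepted or carrying exactly one rejection reason, and the
audit table conserves counts by construction.

## Naive-Bayes classifier

Training counts, for every 8-mer `word` and genus `G`, the number of
training sequences of `G` containing the word at least once, `m(word, G)`;
with `M(G)` sequences in `G` and `N` total, the scores are

    P(word)   = (n(word) + 0.5) / (N + 1)          n(word) = Σ_G m(word, G)
    P(word|G) = (m(word, G) + P(word)) / (M(G) + 1)
    score(G)  = Σ_{distinct query words} log P(word|G)

The reported genus is the argmax, ties broken by lexicographic genus name
for determinism.  Confidence comes from 100 bootstrap trials, each rescoring
`ceil(|words|/8)` words drawn with replacement; support at a rank is the
fraction of trials whose winner agrees with the best lineage there, so a
trial supports every ancestor of its winner and support never increases with
depth.  **Within a trial, exactly tied genera are resolved uniformly at
random from the seeded generator.**  This choice is load-bearing: for the
confusable pair at ≤ 400 bases, every trial ties exactly, and a
deterministic tie-break would manufacture 100% support for whichever genus
sorts first.  Random per-trial resolution yields the honest ~50% support
that the minimum-support threshold then correctly refuses to report.
Per-read RNG streams are derived from the bootstrap seed and a CRC of the
read id, so classification is deterministic and order-independent.

A minimum support threshold τ (the study grid uses 0.8 and 0.5) truncates
the lineage to its deepest prefix with support ≥ τ at every rank; lower
ranks count as unclassified.  Thresholding is monotone: the lineage at a
higher τ is always a prefix of the lineage at a lower τ.

## Best-hit assignment

The alternative assigner mimics a filtered best-hit search: affine-gap
Smith–Waterman (match +1, mismatch −2, gap open −5, gap extend −2; a gap of
length k costs `open + (k−1)·extend`), Karlin–Altschul E-value
`E = K·m·n·exp(−λS)` with fixed constants λ = 1.28, K = 0.46 (the E-value is
used only as a filter threshold, so the constants are configuration, not
fitted statistics), and three hit filters: E ≤ 1e−30, query coverage ≥ 90%,
identity ≥ 90%.  The read inherits the full lineage of the highest-scoring
surviving hit; ties break by higher identity, then lexicographic subject id,
and any surviving hit within a configurable score margin (default 0.5) that
names a different genus marks the assignment *ambiguous* — which is exactly
what happens to confusable-pair reads at 250 bases.

The alignment kernel is a numba-compiled Gotoh dynamic program (score-only
pass for candidate ranking, full traceback only for hits that can still win).
Candidates come from a shared-11-mer prefilter and each alignment runs on a
subject window located by a fast edit-distance search (±150 bases) — seeding
heuristics in the BLAST spirit that are cross-checked against exhaustive,
unwindowed alignment in the test suite.  An independent pure-Python DP is
the oracle for the kernel itself.

## Chimera screen

Reference-based and two-parent: candidate parents are the references sharing
the most 8-mers with the left and right halves of the query (3 per side);
for each parent pair the breakpoint is scanned at 10-base steps (then
refined ±1 step) and each side's identity is computed by infix alignment of
the query segment against the parent.  A read is flagged when the
length-weighted two-parent identity exceeds the best *single-parent* identity
over all candidates by the improvement ratio (default 1.007) and both sides
reach 90% identity to their parents.  Baselining against the best single
parent over all candidates (not just the evaluated pair) guarantees zero
false positives on reads fully explained by one reference.  Splices between
nearly identical parents (within-family pairs) are undetectable in
principle; sensitivity rises monotonically with parent divergence and
reaches 100% at ≥ 10% divergence in the tests.

## Composition analysis

Relative abundance at a rank is the fraction of classified reads whose
effective lineage names each taxon; unclassified mass is reported
explicitly and every table sums to one.  Rare taxa are pooled into "Others"
by a relative-abundance floor (default 1%) — an algorithmic stand-in for the
hand-curated taxon lists figures typically use.  Drift between two tables is
the L1 distance over the taxon union including the unclassified mass (twice
the total variation distance), with per-taxon signed deltas; replicate
stability reports each taxon's min/max/range in percentage points across
replicates and flags ranges above a threshold (default 5 points, an explicit
parameter because "markedly different" has no standard quantitative
definition).  The genus-recovery-versus-length curve truncates a read set of
one known genus at each length, classifies, thresholds, and reports the
fraction recovered at genus and family level; in the pipeline it runs on a
dedicated error-free read set of the confusable genus so the curve does not
depend on the community draw.

## Orchestration, seeding, determinism

`run_experiment` executes the factorial grid — replicates × truncation specs
× classifiers × thresholds — and writes compositions, drift, stability,
sensitivity, the per-stage audit table and a manifest.  One global seed
derives per-stage, per-sample substreams (`numpy` `default_rng` seeded with
integer sequences), so replicates are independent but the whole bundle is
byte-reproducible; no timestamps enter any output.  The bundled demo grid
uses 3 replicates × 300 reads × 6 specs × 2 classifiers × 2 thresholds —
sizes chosen so a complete run takes a couple of minutes on one core while
every stage still has enough reads to exercise its filters.  The acceptance
script scales the same analyses to 5,000 reads for parameter recovery and
500 reads per length for the recovery curve.

## Known limitations

- One reference per genus by default: within-genus diversity (and its
  blurring effect on bootstrap support) is available via `refs_per_genus`
  but not part of the default conditions.
- The classifier and the reference database are trained on the same
  simulated references the reads come from; real surveys classify against
  databases that do not contain the sampled strains, so absolute recovery
  rates here are upper bounds.
- The E-value constants are not calibrated to the score matrix; only the
  relative ordering and thresholding behavior is meaningful.
- The chimera screen assumes two parents and a single breakpoint.
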