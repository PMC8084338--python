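# Methods

## Model and procedure

`smartmap` treats the true origin of each paired-end read as a latent
variable. The observed data are the reported alignments of each read pair
(fragment intervals, derived from POS/TLEN of the leftmost proper-pair mate)
and their aligner scores. For read *i* with alignments *j = 1..k*, the weight
*w_{i,j}* is the probability that alignment *j* is the true origin; weights
of one read always sum to 1.

**Filtering.** Only SAM records with FLAG 99, 163, 355 or 419 are consumed
(paired, proper pair, mate reverse — the forward-placed mate of primary and
secondary alignments). This yields exactly one record per reported alignment
of a pair; the reverse mate is redundant and dropped. Reads that hit the
aligner's reporting cap (e.g. `-k 51` reporting exactly 51 alignments) are
excluded because their alignment set may be truncated; reads above the cap
are treated as input corruption and raise.

**Quality prior.** In scored mode the pair score *s = AS + YS* is compared
to the minimum reportable score *s_min = −0.6 − 0.6·(2·read_length)* (the
end-to-end minimum evaluated at the combined mate length; −60.6 at 50 bp).
The ratio *s/s_min ∈ [0,1]* is binned to a pseudo-MAPQ *z*:
[0, 0.2] → 42, (0.2, 0.3] → 40, (0.3, 0.4] → 24, (0.4, 0.5] → 23,
(0.5, 0.6] → 8, (0.6, 0.7] → 3, (0.7, 1] → 0 — the MAPQ values an
end-to-end aligner assigns to uniquely mapped reads. Quality is
*q = 1 − 10^(−z/10)*; unscored mode sets *q = 1*. The score bins are applied
to the mate-score **sum**, which reproduces the printed −60.6 threshold for
50 bp reads; applying them per mate would require a different minimum.

**Initialisation.** *w_{i,j} = q_{i,j} / Σ_j q_{i,j}*. Reads whose
qualities all vanish are discarded; zero-weight alignments are dropped;
*k = 1* reads are frozen at *w = 1* and never revisited. All surviving
weights are added to the genome weight field.

**Iteration.** Let *c_b* be the total weight at base *b* (all reads, all
alignments — including the read's own contribution; nothing is subtracted
out) and *C_{i,j}* the mean of *c_b* over alignment *j*'s interval. The
posterior is proportional to *C_{i,j} q_{i,j}*, damped by the learning rate
*r*:

    w'_{i,j} = r * C_{i,j} q_{i,j} / Σ_j C_{i,j} q_{i,j} + (1 − r) w_{i,j}

Defaults: one iteration, scored mode, *r = 1*. Reads are processed
sequentially in stable input order with the field updated immediately after
each read (*online*); a synchronous mode (all posteriors computed against
the iteration-start field) is available via `ReweightConfig(online=False)`
for sensitivity checks. The narration of the update ("the posterior weight
is treated as the prior for the next iteration") is compatible with either
schedule; online is the default because it needs no field snapshot and each
read always sees the freshest evidence. Both schedules are verified against
dense-array reference implementations.

**Degenerate denominator.** If Σ_j C_{i,j} q_{i,j} = 0 mid-iteration the
read's weights are kept unchanged and a warning is logged. This cannot occur
while the read's own weight is on the field (then C ≥ w/|g| > 0) except
through floating-point underflow, so the fallback is safe.

## The genome weight field

Each contig of length L is a pair of Fenwick trees with L+1 nodes
(`T1` over the per-base difference array, `T2` holding boundary
corrections), so that

    value_at(b)   = BITSum(T1, b)
    PointSum(i)   = BITSum(T1, i)·i − BITSum(T2, i)
    LocusSum(l,r) = PointSum(r−1) − PointSum(l−1)          # [l, r)

and a range increment on [l, r) is four point updates:
`T1: +v@l, −v@r; T2: +v(l−1)@l, −v(r−1)@r`. All operations are O(log L).
Strand-specific mode simply doubles the structure per contig. Memory is the
dominant cost: two float64 arrays of L+1 nodes per contig (four in strand
mode), i.e. ~16 bytes/bp. A single-tree variant would halve memory but turn
range sums into per-base loops, which is rejected for speed.

Coordinates are 1-based inclusive internally (the BIT arithmetic is written
over 1-based indices); conversion to 0-based half-open happens only at
BED/BEDGRAPH boundaries. BEDGRAPH export merges equal adjacent values,
rounds to 6 decimal places (lossless at the 1e-9 weight tolerance used
throughout) and omits zero runs.

## ICeChIP calibration

Spike-in barcodes are modelled as extra contigs. Per modification species,
barcode mean depths are **summed, then** the IP/Input ratio is taken (never
a mean of per-barcode ratios), giving enrichment *E_i*; the targeted
species' value is *E_t*. Then per base

    HMD(%) = IP / (E_t · Input) · 100        (Input = 0 ⇒ HMD = 0)
    Specificity_i(%) = E_i / E_t · 100

HMD capping at 100% is off by default and available as an option for
promoter-profile style summaries, where densities above 100% are
definitionally impossible.

## Synthetic validation data

The simulator replaces an aligner-plus-reference stack at desk scale, so the
whole pipeline is testable against an exact truth with no downloads.

* **Genome**: one 1 Mb contig of i.i.d. bases seeded with nine repeat
  families (unit lengths 300–3000 bp, copy numbers 2–100, per-copy
  divergence 0–2%; ~16% of the contig), emulating a young-repeat landscape:
  ~12% of read pairs become multireads and a 100-copy family mostly exceeds
  the default 51-alignment reporting cap, mirroring the "unanalyzable"
  multiread class real aligner settings produce.
* **Fragments**: 1200 target loci of 200 bp drawn uniformly; on-target
  fragments overlap their locus by ≥ 1 bp with insert length ~Normal(175,
  10) clamped to [50, 250]; fragment count set so nominal locus coverage is
  30× (~42k fragments); 2% of fragments are uniform off-target noise;
  per-base substitution errors at 1%. The realised mean locus depth (~20×)
  sits below nominal because fragments only partially overlap locus edges.
* **Mapper**: exact and exhaustive, not heuristic. A pigeonhole seed index
  (m+1 disjoint seeds per mate; any placement with ≤ m mismatches must match
  one seed exactly) proposes candidates, verified by direct comparison of
  both mates at the fragment's insert length. Scores are −6 per mismatch per
  mate (AS/YS), a free parameter since only the ratio *s/s_min* matters.
  Default budget m = 3 mismatches per mate.
* **Gold Standard**: the exact per-base coverage of the true fragment
  intervals, computed with plain array arithmetic (never through the
  Fenwick code). Target loci with nonzero gold depth are the "true origin"
  loci used by all error metrics.

Everything is deterministic per seed. What the simulator does **not**
emulate: indels and gapped/spliced alignments, base-quality strings, PCR
duplicates, GC bias, chimeric pairs, and a real genome's nonuniform base
composition. Passing tests therefore demonstrate correctness of the
allocation machinery and its qualitative behaviour on repeat structure, not
calibrated performance on any particular organism.

## Evaluation metrics

* Per-locus mean depth: arithmetic mean of per-base signal (absent bases
  count 0); overlapping loci are conceptually merged for the per-base
  partition but each input locus receives its own mean.
* MAE / mean error at true-origin loci, against the Gold Standard.
* Mappability: exact k-mer uniqueness (default k = 50, forward strand;
  reverse-complement pooling behind a flag), score(b) = unique covering
  k-mers / covering k-mers; loci binned at width 0.01.
* Overlap scores by final weight (bin width 0.05): unweighted = geometric
  mean of the two overlap proportions between alignment and true interval;
  weighted = weight × unweighted.
* Strategy comparison on identical input: uniread (k = 1 only), random
  one-alignment-per-read selection (uniform, seeded), prior-only
  (iteration 0), and N-iteration reweighting.
* Replicate agreement: per-locus log ratios of depth-normalised signal
  (normaliser = retained read count; natural log; optional pseudocount for
  zero-depth loci).

## Numerical choices

* Weights are float64 throughout; per-read normalisation is checked to
  1e-9, global mass conservation to 1e-6 × reads.
* Pseudo-MAPQ bin edges carry a 1e-9 guard so a score landing exactly on an
  edge (e.g. 0.7·s_min) bins by its mathematical value despite float
  round-off.
* Window tiling for high-signal counts: non-overlapping 200 bp tiles from
  base 1; a final partial tile is averaged over its true length.
* Strand inference for strand-specific preparation (convention not fixed by
  the upstream format): FLAG 99/355 → "+", 163/419 → "−", overridable.
* Duplicate identical intervals within a read are kept as reported.

## Problem sizes used in validation

The shipped validation fixture is one 1 Mb contig with ~42k fragments
(~158k alignments), chosen as the package's desk-scale study design; oracle
equivalence suites use ≤ 50 kb genomes with ≤ 700 reads per instance and
100 random instances. The full suite runs in about a minute on one CPU.

## Known limitations

* Online iteration order matters in principle (reads see earlier updates
  within a pass); results are bit-reproducible for a fixed input order but
  not invariant under reordering.
* Fragments are POS/TLEN intervals: gapped or spliced alignments spanning
  introns are averaged over the whole span and may be down-weighted
  unfairly; single-end data is out of scope.
* On the desk-scale fixture, additional full-rate iterations past the first
  keep reducing the error slightly rather than over-refining it; the
  over-refinement regime reported on mammalian-scale data evidently needs
  repeat structure richer than this fixture provides (see the acceptance
  test for the exact assertion).
* Memory, not CPU, bounds genome size (~16 bytes/bp/strand).
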