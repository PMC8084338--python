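# smartmap

Bayesian allocation of ambiguously mapped (multi-mapping) paired-end
sequencing reads over a Fenwick-tree genome track, with downstream ICeChIP
spike-in calibration and a built-in synthetic validation pipeline.

## The problem

Short-read pipelines for ChIP-seq, MNase-seq, ATAC-seq and similar assays
routinely discard read pairs that align to more than one genomic locus
("multireads"). In repeat-rich genomes that throws away 10–50% of usable
reads and blinds the analysis to repetitive regions entirely. `smartmap`
instead keeps every reported alignment of every read pair and estimates, for
each alignment, the probability that it is the pair's true origin.

## The model

Each read pair *r<sub>i</sub>* carries alignments *j = 1..k* with weights
*w<sub>i,j</sub>* = Pr(alignment *j* is the true origin), so Σ<sub>j</sub>
*w<sub>i,j</sub>* = 1. Weights are initialised from alignment quality and
refined by iterating a Bayesian update against the genome-wide weight field:

- **Quality prior.** The pair score *s = AS + YS* is mapped through the
  ratio *s / s<sub>min</sub>*, with *s<sub>min</sub> = −0.6 − 0.6·(2·read
  length)* (−60.6 for 50 bp mates), onto a binned pseudo-MAPQ *z* ∈
  {42, 40, 24, 23, 8, 3, 0} — the values an end-to-end aligner assigns to
  unique reads — giving quality *q = 1 − 10<sup>−z/10</sup>*. Initial
  weights are *w<sub>i,j</sub> = q<sub>i,j</sub> / Σ<sub>j</sub>
  q<sub>i,j</sub>* ("unscored" mode sets every *q* = 1).
- **Posterior update.** With *C<sub>i,j</sub>* the mean total weight over
  alignment *j*'s fragment interval, one iteration at learning rate *r* sets

  *w′<sub>i,j</sub> = r · C<sub>i,j</sub>q<sub>i,j</sub> / Σ<sub>j</sub>
  C<sub>i,j</sub>q<sub>i,j</sub> + (1 − r) · w<sub>i,j</sub>*

  so *r* = 0 freezes the weights and *r* = 1 is the full Bayes posterior.
  The default is one iteration in scored mode at *r* = 1.
- **Genome track.** Per-base weight sums live in a pair of binary-indexed
  (Fenwick) trees per contig, giving O(log L) range increments (adding or
  moving a fragment's weight) and O(log L) range sums (computing
  *C<sub>i,j</sub>*), which is what makes whole-genome iteration cheap.

For ICeChIP data the calibrated histone modification density is
*HMD(%) = IP / (E<sub>t</sub> · Input) · 100*, with spike-in enrichments
*E<sub>i</sub>* computed per modification species from barcode contigs and
antibody specificity *E<sub>i</sub>/E<sub>t</sub> · 100%*.

## Worked example

Library use — a unique read pins down the shared locus, so the ambiguous
read's weight shifts toward it in one iteration:

```python
import smartmap as sm

records = [
    sm.AlignmentRecord("chr1", 11, 20, "unique"),
    sm.AlignmentRecord("chr1", 11, 20, "ambiguous"),
    sm.AlignmentRecord("chr1", 51, 60, "ambiguous"),
]
cfg = sm.ReweightConfig(iterations=1, scored=False)
result = sm.run_smartmap(sm.build_read_groups(records), {"chr1": 100}, cfg)
for g in result.groups:
    print(g.read_id, g.weights)
# unique [1.]
# ambiguous [0.75 0.25]
```

The ambiguous read starts at (0.5, 0.5); the shared interval has mean weight
1.5 (its own 0.5 plus the unique read's 1.0) against 0.5 at the alternative,
and 1.5/(1.5 + 0.5) = 0.75.

Command line — simulate a repetitive genome with a known truth, allocate
reads, and score the result against the exact (Gold Standard) coverage:

```console
$ smartmap simulate --seed 7 --prefix sim --genome-length 200000 --n-target-loci 300
simulated 10496 fragments, 15275 alignments -> sim.*

$ smartmap run sim.alignments.bed --chrom-sizes sim.chrom.sizes \
      --out sm.bedgraph --iterations 1 --k-cap 51
analysed 10458 reads (0 discarded); wrote sm.bedgraph

$ smartmap eval mae sim.gold.bedgraph sm.bedgraph \
      --chrom-sizes sim.chrom.sizes --loci sim.target_loci.bed
mean_error	-1.268553
mae	1.305311
```

The same run with `--iterations 0` (quality priors only, no reweighting)
gives MAE 1.577714, so one Bayesian iteration removes ~17% of the mean
absolute depth error at the sampled loci. `smartmap prep` converts SAM/BAM
output from a real aligner (Bowtie2-style AS/YS tags, proper-pair flags 99,
163, 355, 419) into the same extended-BED input, and `smartmap hmd`
produces calibrated modification-density tracks from IP/Input pairs.

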