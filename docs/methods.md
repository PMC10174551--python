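# Methods

This note documents the models, algorithms and design choices implemented in
`contiguard`, and what the synthetic experiments do and do not demonstrate.

## Problem

Metagenome assemblers produce chimeric contigs — relocations, inversions,
translocations and interspecies translocations — that corrupt downstream
analyses. With no reference genomes available for most communities, the only
usable evidence is how the sequencing reads align back onto the contigs:
coverage anomalies, single-nucleotide variant (SNV) pileups, broken read
pairing and shifted insert sizes all concentrate near misassembly junctions.
`contiguard` scores each contig with a residual convolutional network over
per-position alignment features and supports assembly-level quality control:
filtering high-scoring contigs and ranking assemblies by estimated error
rate.

## Synthetic data generator

The generator replaces an external simulation chain (community simulator,
read simulator, assemblers, reference-based misassembly caller) with an
in-process emulation whose every contig carries exact ground truth.

* **Parameter grid.** `SimGrid` spans community richness, lognormal
  abundance σ, replicates, read length, insert-size distribution, error
  profile, sequencing depth and assembler label. `enumerate_grid` takes the
  Cartesian product with optional per-insert-size restrictions; the default
  grid with its restrictions yields 4,560 combinations (1,440 per
  unrestricted insert size; 960 and 720 for the two restricted ones; 240
  for the held-out configuration).
* **Communities.** `sample_community` draws `richness` genomes without
  replacement and sets relative abundances proportional to
  Lognormal(μ, σ) draws (μ = 10 by default; only ratios matter after
  normalization, so μ is exposed but inert).
* **Genomes.** I.i.d. random sequences at a configurable GC fraction stand
  in for reference genomes; `mutate_strain` derives strains by i.i.d.
  substitutions (no indels), providing intra-species diversity that
  surfaces as SNV background in pileups.
* **Misassemblies.** `inject_misassembly` builds a contig from explicit
  source segments: a clean window (`none`), an internal reverse-complemented
  segment (`inversion`), two non-adjacent windows of one genome
  (`relocation`), or windows of two genomes (`translocation` between
  strains of one species, `interspecies_translocation` across species).
  Breakpoints are defined as the junctions between source segments, so
  `label == 1` iff breakpoints exist, by construction.
* **Reads.** Paired-end fragments have Normal(mean, sd) lengths truncated to
  [read length, window length] by resampling and uniform start positions;
  mate 1 reads the fragment start forward, mate 2 the fragment end
  reverse-complemented. Substitution errors follow a per-cycle rate rising
  linearly from `rate_start` to `rate_end` (the default profile averages
  0.5%); indels and chimeric reads are out of scope.
* **Truth alignment.** Instead of running an aligner, reads are placed on
  the contig from their known source coordinates: a mate anchors to the
  source segment holding the majority of its bases and its mismatch set is
  the base-by-base difference against the contig. Reads crossing a junction
  therefore accumulate mismatches on the far side — the same signal a real
  aligner leaves around misassemblies. A pair is *proper* when both mates
  map in forward/reverse orientation with an insert within mean ± 3 sd;
  exactly one mapped mate gives an *orphan*; both mapped but not proper is
  *discordant*. Mapping quality is a surrogate (42, or 1 for reads from
  marked repeat regions) because a true mapq requires a full aligner;
  alignment score is −6 per mismatch, matching the scale of an end-to-end
  short-read aligner's penalty.

Coordinates are 0-based half-open everywhere; SAM output converts to
1-based at the writer.

## Per-position features

`compute_pileup` produces 23 channels per contig position: reference base;
coverage; aligned-base counts A/C/G/T; SNV count; discordant, proper and
orphan read counts; proper-pair SNV count; min/mean/stdev of mapping
quality and alignment score over covering reads; min/mean/stdev/max of
insert size over covering proper pairs; and 50 bp-window sequence entropy
and GC fraction. Interval-constant quantities use difference arrays plus a
cumulative sum (linear in reads + length); min/max statistics use per-read
slice updates. The standard deviation over a single covering read is 0, not
missing; numeric statistics at zero-coverage positions are missing (NaN)
until preprocessing.

Preprocessing follows the detector's training contract:

* reads are randomly subsampled (whole pairs at a time) to a mean coverage
  of at most 20, which also guards against out-of-distribution coverage at
  prediction time;
* count channels are divided by coverage, into [0, 1];
* numeric channels are standardized with mean/sd fitted on training
  contigs' covered positions (a zero-variance channel stores sd = 1 so it
  standardizes to 0);
* zero-coverage positions become all-zero rows — zero is the
  post-standardization mean.

The model consumes 14 of the 23 channels (base counts, SNV counts, pairing
counts, alignment-score statistics, mean mapping quality, coverage, minimum
insert size); the catalog is configuration, not code, so the selection can
be changed without touching the extractor.

A dataset-level applicability guard summarizes proper-pair insert sizes:
datasets whose 5%/95% quantiles fall outside the closed training envelope
[117, 493] bp are flagged, since detectors of this family generalize poorly
across insert-size distributions.

## Network

Input is a batch of feature windows, shape (B, M, 14), zero-padded to the
longest window in the batch, with a per-sample valid length. Topology:

1. input batch-norm over the 14 channels — its moving mean/variance double
   as the stored input-standardization constants, so checkpoints are
   self-contained;
2. an initial convolution, kernel 10, 16 filters, batch-normalized;
3. four residual groups of 2/5/5/2 blocks with 16/32/64/128 filters. A
   block is two batch-normalized valid (unpadded) convolutions of kernel
   K = 5 with ReLU; because convolutions are unpadded the identity skip is
   cropped by 2·(K−1) positions, and the first block of groups 2–4
   downsamples with stride 2 (its skip is a kernel-1, stride-2 convolution
   with bias and no batch norm);
4. masked global average pooling over valid positions only, giving a
   128-vector per contig regardless of length;
5. dense 128×50 (ReLU) and 50×1 (sigmoid).

With these choices the default configuration has 562,573 parameters, of
which 559,441 are trainable; the 3,132 non-trainable parameters are exactly
the moving statistics of the 1,566 batch-normalized channels
(14 input + 16 initial + 1,536 block channels). The kernel sizes are fixed
by this arithmetic: K = 5 in blocks and 10 in the initial convolution is
the unique integer solution consistent with the parameter totals.

The implementation is pure numpy: convolutions are computed as one dense
GEMM `(B·L, C) @ (C, K·F)` followed by K shifted slice-accumulations
(equivalent to im2col without the large gather, which dominated runtime),
and backward passes (including mask-aware batch norm) are explicit. A
numeric gradient check in float64 is part of the test suite.

Masking details: the valid length is threaded through every layer with the
same floor-division rules as the data path; positions computed from padding
are zeroed after every block, excluded from batch-norm statistics and from
the pooling mean. Batch-norm statistics over valid positions only is a
package choice (the masking could equally be applied only at pooling); in
inference mode moving statistics are used, so a contig's score is exactly
invariant to the amount of batch padding. Inputs shorter than the network's
receptive minimum (366 positions for the default configuration) are
zero-padded up to it and the padding counts as valid — relevant only for
contigs shorter than ~0.4 kb.

## Training protocol

Binary cross-entropy under Adam (initial learning rate 1e−4), batch size
200, gradients clipped element-wise to ±0.5 and then to global norm 1 (the
protocol names both limits but not an order; value-then-norm is the package
choice). Each epoch uses all misassembled contigs and a freshly drawn 10%
of the correct ones, so the realized positive fraction is
P / (P + round(0.1·N)). Contigs longer than 20 kb contribute one 20 kb
window per epoch: uniform over windows containing a uniformly chosen
breakpoint for positives (ambiguity for multi-breakpoint contigs resolved
by that two-stage draw), uniform for negatives. Validation contigs (10%)
use windows fixed once so AUPRC is comparable across epochs; AUPRC is
evaluated every second epoch, an improvement saves a checkpoint, and two
consecutive evaluations without improvement decay the learning rate by 0.8
(patience is configurable; the protocol says only "on plateau"). `fit()`
returns the checkpoint with the best validation AUPRC.

Normalization statistics are fitted on the training split only, after the
validation split is carved out, and are stored in the results object and
every checkpoint.

## Prediction and assembly-level use

Contigs longer than 20 kb are scored in 20 kb chunks overlapping by 500 bp
(read as overlap, not stride, keeping cost linear in length; the final
chunk is anchored at the contig end so coverage is complete) and the contig
score is the maximum chunk score. Evaluation uses AUPRC (random baseline =
prevalence) plus AUROC for cross-dataset comparison, both via
scikit-learn; an exhaustive threshold-enumeration oracle cross-checks them
in the tests. Filtering drops contigs scoring strictly above a threshold
(default 0.8) and reports N50, mean/median length, misassembly rate and
misassembled-bases fraction before and after; the estimated misassembly
rate of an assembly is the fraction of contigs above the threshold, and
assemblies are ranked by it (Spearman/Pearson against truth when
available).

## Desk-scale experiment and what it shows

The end-to-end tests train on 2,000 simulated contigs (25% misassembled,
mean coverage 10, 0.5% error, read length 100, insert 270 ± 50, lognormal
contig lengths with median ≈ 1.5 kb clipped to [0.6, 6] kb — the median
matches typical short-read metagenome assemblies), batch size 64, learning
rate 1e−3, 3 epochs — scaled-down settings chosen for a single-CPU run,
with the published-protocol defaults retained in `TrainConfig` for full
runs. Validation AUPRC reliably exceeds twice the prevalence, filtering at
0.8 reduces the true error rate of the kept set, and estimated rates rank
six assemblies with injected error fractions 0.01–0.30 concordantly with
the truth.

These experiments validate the *machinery* — features carry the junction
signal, the network can learn it, the protocol and metrics behave as
specified. They overstate real-world separability: truth-based alignment
has no mapping ambiguity, repeats, or indels; genomes are i.i.d. sequences
without shared k-mer structure; assembler consensus effects (e.g. coverage
chimeras without clean junctions) are absent. Published results at full
scale (tens of millions of contigs, GPU training) report AUPRC well below
1 on held-out data; desk-scale numbers here should not be read as
real-data performance.

## Numerical choices

* Batch-norm ε = 1e−3, moving-statistic decay 0.9.
* He-normal initialization for convolutions and dense layers; biases zero.
* Loss computed via the log-sum-exp-stable logit form; probabilities only
  at the output.
* Fragment-length truncation by resampling (avoids degenerate fragments at
  insert 190 ± 75 with 150 bp reads).
* The insert-size guard interval is closed (117 and 493 pass).
* Threshold comparisons are strict (score > t is flagged).
* N50: sort descending, accumulate until ≥ half the total bases.
* Replicates in the simulation grid differ only by the genome-subsampling
  seed; all generators are bit-reproducible given a seed.

## Known limitations

* The alignment surrogate cannot produce realistic mapping-quality
  variation; the mapq channels are near-constant in generated data and carry
  no signal there.
* Chunked prediction stores per-chunk scores but no breakpoint-position
  output.
* Training is single-threaded CPU numpy; it is adequate for datasets of
  thousands of contigs, not millions.
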