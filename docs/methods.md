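# Methods

This note documents the model, the choices behind its defaults, what the
synthetic data do and do not emulate, and the numerical conventions the
implementation fixes. It states no empirical result beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## Sequence encoding

An IUPAC string of length L becomes an `(L, 4)` matrix whose row *i* is
the uniform distribution over the canonical bases compatible with
character *i*. The column order is fixed as **(A, C, G, T)**; any fixed
order is equivalent up to a permutation of the kernel weights, so the
choice is purely a convention and is asserted throughout the package.
Lowercase input is accepted and upper-cased; `U` is treated as `T`.

Reads are shaped to the fixed model width (150 positions, the read
length of the targeted sequencers) by truncating longer inputs and
appending **all-zero** rows to shorter ones. Zero rows are deliberately
distinct from `N` (uniform 0.25): absent signal carries no probability
mass, so the network can separate "nothing was read here" from "a base
was read but is ambiguous". Padding is appended at the 3' end because
reads are left-anchored at the tag.

## Reference database and split sampling

A reference DB is a set of species-labelled, primer-free amplicons; the
species labels get dense class integers in lexicographic order, which
makes the index independent of record order and stable under JSON
round-trips. Exact duplicate (sequence, species) pairs are collapsed
with their multiplicity retained, so duplicates still weigh into class
balancing. Identical sequences shared across *different* species are
kept under both labels; no de-conflicting is attempted — the softmax
simply splits probability between the candidates, and such reads tend to
fall below the rejection threshold.

Hold-out evaluation uses random split sampling restricted to species
with at least two distinct sequences (uniqueness = distinct strings).
Exactly one randomly chosen unique sequence per species is held out by
default; the proportion is configurable (`holdout_per_species`). Both
partitions cover every eligible species, so the hold-out set never
contains an unseen class.

## Augmentation

Per epoch and per record, in this order:

1. **decoration** (optional): `N*10 + forward primer + amplicon +
   rc(reverse primer) + N*10`. The N blocks stand in for the 8 bp tag
   plus up to 2 attachment bases on each side, so the classifier stays
   tag-agnostic; the reverse primer is appended as its reverse complement
   because that is its orientation in a forward read.
2. **indels**: `k_ins ~ U{0..2}` uniform insertions then
   `k_del ~ U{0..2}` uniform deletions (capped so the sequence never
   empties). The order indel-then-substitute is a fixed convention.
3. **substitutions**: each position mutates independently with
   probability 5% (training) or 2% (evaluation). A mutated canonical
   base is replaced by one of the three *other* bases, so the observed
   change frequency equals the nominal rate — "mutation" is read as
   "change", not "resample". Mutated ambiguity codes become a uniform
   canonical base.
4. **reverse complements** (optional): each augmented sequence is also
   emitted reverse-complemented, doubling the batch, because sequencing
   reads either strand.

Class balancing happens once at the start of training: every species is
oversampled with replacement to the maximum per-species copy count.
Because augmentation is redrawn every epoch, oversampled duplicates
still yield distinct training inputs.

Evaluation mode (2% substitutions, single indels) reflects the
expectation that real PCR + sequencing noise is milder than the training
perturbation. Quality scores are ignored throughout.

## Network and training

The encoded read is treated as a `(width, 4)` single-channel image. The
first convolution uses a 7×4 kernel with no padding, spanning the full
base axis and collapsing it, so the feature map is 1-D over read
positions; deeper conv layers (up to three total, 4–16 filters each)
slide a 7-position kernel across all channels, optionally as a
depth-wise separable pair (7-tap depthwise + 1×1 pointwise). The
flattened features pass through 1–3 dense layers into a softmax over the
C species. Leaky-ReLU (slope 0.01) follows every hidden layer; dropout
(rate 0.2) follows every hidden dense layer. Stride is 1 everywhere.

The implementation is a self-contained numpy network: explicit forward
and backward passes per layer and an Adam optimiser. At the scale this
problem needs (~10^5 parameters, hundreds of training sequences) this
trains in seconds per run on a single CPU and keeps the dependency
surface minimal; predictions are deterministic, and checkpoints store
exact float64 weights so a reloaded model reproduces predictions
bit-identically.

Defaults chosen where the procedure leaves them open: Adam with learning
rate 1e-3, batch size 64, 50 epochs, categorical cross-entropy (implied
by softmax classification), He-normal initialisation. The default
architecture is 1 conv layer × 4 filters + 3 dense layers × 128 — the
smallest configuration in the search space that saturates the synthetic
benchmarks; `grid_search` trains any candidate list identically and
ranks by hold-out accuracy with ties broken toward fewer parameters.
One integer seed controls splitting, balancing, augmentation,
initialisation, dropout and shuffling. Exact argmax ties at prediction
time resolve to the lowest class index.

Degenerate cases are defined rather than forbidden: a single-species DB
trains and always predicts class 0; `epochs=0` returns the untrained
weights unchanged; a non-finite loss raises immediately with epoch/batch
diagnostics rather than continuing.

## Rejection threshold

`classify_with_threshold` accepts a read iff its top probability is
≥ t. For threshold selection, precision = correct accepted / accepted
and recall = correct accepted / **all** reads, micro-averaged, so
rejection costs recall — this matches the intent that discarding correct
reads is the price of suppressing wrong ones. The F-beta score with
beta = 0.3 is maximised over a 0.00–1.00 grid in steps of 0.05; ties
resolve toward the stricter threshold. The working default threshold is
0.9.

## Demultiplexing

Tags (and their reverse complements, for reverse-oriented reads) go into
one hash table; a read is probed at start offsets 0..4 (five look-ups,
covering up to 2 attachment bases plus slack) and the first exact hit
wins. There is deliberately **no** tag error correction: a single
substitution in the tag leaves the read unassigned. Read conservation
(assigned + unassigned = total) holds at every stage and is asserted in
tests. Only the 5' tag of the single-end read is used; paired-tag
verification is out of scope.

## Pipeline and tables

`run_raw` = demultiplex → thresholded classification → minimum-read
filter. The minimum-read filter (default 50) is applied **at the PCR
replicate level, before aggregation** — a species needs ≥ min_reads in a
replicate to be kept there. Tables carry the replicate → filter → river
hierarchy and aggregate by summation; rejected, skipped (invalid
characters) and unassigned read counts are recorded in the table
metadata for audit. Clean mode consumes already-demultiplexed per-sample
reads with the same classifier.

## Comparison statistics

Kendall tau-b (tie-corrected, via `scipy.stats.kendalltau`), Cohen's
kappa (2×2 marginals, via `scikit-learn`), and Bray–Curtis
(`1 − 2Σmin/(Σa+Σb)`, via `scipy.spatial.distance`) are computed per
sample over the **union of species detected anywhere in either table**,
with absences as zeros. A per-sample universe restricted to that
sample's detections would make kappa degenerate (chance agreement 1)
whenever the two methods detect the same species, so the global union is
used instead. Undefined statistics — all-tied vectors for tau-b, chance
agreement exactly 1 for kappa, two all-zero vectors for Bray–Curtis —
return NaN, are excluded from medians, and are counted in the report
rather than silently coerced to 0. Significance testing between
correlation distributions is intentionally not provided.

## Synthetic data

The generator produces the three artefacts needed to exercise every
stage: a reference DB, a tag manifest, and raw 150 bp reads with ground
truth.

* **Reference DB**: independent uniform random consensus sequences
  (default 60 bp) accepted under a pairwise-divergence floor (default
  10%), each species carrying 1–10 variants within half the floor of its
  consensus. Because the consensus draws are independent, typical
  pairwise divergence is far higher than between real congeners sharing
  a conserved marker — synthetic species are *easy* to separate. Tests
  passing on these data therefore demonstrate the correctness of the
  machinery (encoding, augmentation, training dynamics, thresholding,
  plumbing), not marker-level resolution on closely related taxa, which
  is limited by the barcode itself.
* **Tags**: random 8-mers accepted under multiplex-identifier design
  constraints — pairwise Hamming distance ≥ 3 among all table keys
  (tags and reverse complements) and no suffix/prefix overlap of length
  4–7 between any two keys. The overlap condition guarantees that the
  offset-scanning demultiplexer can never hit a spurious window inside a
  shifted read start; without it, random tags produce occasional false
  assignments.
* **Reads**: `attachment(0–2 random bases) + tag + forward primer +
  amplicon (+ substitution errors) + rc(reverse primer) + rc(tag) +
  attachment`, continued into a constant TruSeq-style adapter and cut at
  150 bp — i.e. short inserts read through into the adapter, as they do
  on a real instrument. A configurable fraction of reads is emitted in
  the mirror-image reverse orientation (reverse tag and primer first).
  Qualities are constant `I` since the method ignores them. The error
  model is substitution-only by default (matching the augmentation
  model); single indel errors sit behind a flag. PCR chimeras,
  tag-jumps and abundance biases are not modelled.

## Problem sizes

The shipped tests and examples use deliberately small instances chosen
as the package's own benchmark scale: 50-species databases with 3
variants per species for split-sample recovery, 10-species communities
with 5 tagged replicates and 10k–50k reads for the end-to-end chain, and
10,000-draw Monte-Carlo checks for the augmentation statistics. Each
complete run (simulate → train 50 epochs → classify → compare) takes on
the order of seconds on one CPU core.

## Known limitations

* The classifier is forced to the species level; conflicting or shared
  barcodes can only be handled by probability splitting plus rejection,
  not by assignment to a higher taxonomic rank.
* The rejection rate on raw reads can be substantial at t = 0.9 when
  training is short; accepted-read composition is robust (that is the
  design trade), but absolute read counts shrink accordingly.
* Backend determinism is within a fixed numpy/BLAS build; bit-identical
  results across different BLAS implementations are not guaranteed,
  though checkpoint round-trips are.
* An incomplete reference database yields confident-looking assignments
  only for species it contains; everything else must be caught by the
  rejection threshold.
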