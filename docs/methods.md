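# Methods

## Dataset construction

Positive sequences are filtered in order: exact-duplicate removal (first
occurrence kept), rejection of any sequence containing a letter outside
the 20 canonical amino acids, and a closed length window of 400–700
residues. Each record receives exactly one provenance verdict naming the
first failing rule.

Redundancy is removed by longest-first greedy incremental clustering: a
sequence joins the first existing cluster whose *seed* it matches at or
above the identity threshold (0.95 for positives, 0.90 for negatives),
otherwise it founds a new cluster. Identity is defined as the maximum
number of identically aligned positions under global alignment with
match = 1, mismatch = 0 and a linear gap penalty with zero coefficient,
divided by the shorter sequence's length. With that scoring the optimal
alignment score *equals* the match count, so the definition is free of
the usual ambiguity among co-optimal tracebacks; the implementation uses
`Bio.Align.PairwiseAligner` in global mode. The algorithm is exact
(every candidate is aligned against every seed), quadratic in the number
of clusters, and deterministic for a given input (length ties broken by
id). `build_dataset(neg_identity=None)` skips negative de-redundancy;
that is appropriate for backgrounds that are non-redundant by
construction, such as the synthetic generator's independent sequences,
and makes the pipeline linear in the number of negatives.

The three-way split is cluster-aware. Clusters of size ≥ 3 contribute
exactly 3 randomly chosen members, one per partition; the surplus is
discarded by default so no near-duplicate of a test sequence can reach
the training set (a `surplus_to_train` flag routes the remainder to
train instead). Size-2 clusters put one member in train and the other in
validation or test by fair coin. Singletons are pooled, shuffled, and cut
at 8:1:1 with rounded validation/test counts. All randomness flows from
one integer seed through `numpy.random.default_rng`.

Negative screening against the positive family defaults to an exact
shared-15-mer test: a negative is dropped iff it shares at least one
15-mer with any positive. At alphabet size 20 the chance of a collision
between unrelated sequences is about L² · 20⁻¹⁵ per pair — negligible —
so any shared word indicates genuine local similarity; an external mode
instead consumes a (query, subject, E-value) table from a real similarity
search with a 10⁻¹⁰ cutoff. Screening runs before negative clustering.

Artificial decoy negatives are the 400 ordered dipeptide repeats over the
canonical alphabet, each truncated to a uniformly drawn length in
[400, 700]; odd lengths end on the dipeptide's first letter.

## Encodings

One-hot: 700 × 20 binary matrix, columns in alphabetical one-letter
order, zero rows past the true length. Tokens: overlapping 3-mers at
stride 1 framed by `<CLS>` and `<EOS>`, right-padded with `<pad>` to
exactly 700 ids over a 8004-token vocabulary (4 specials + 20³ 3-mers);
a length-700 protein fills the budget exactly (698 content 3-mers + 2
specials). Both encodings are inverses of their decoders on filtered
sequences. A token-to-residue map (each residue is covered by ≤ 3
windows) lets token-level attributions be re-expressed per residue.

## Models

All models run on `famprobe.nn`, a ~400-line numpy reverse-mode autodiff
engine (float32, finite-difference-tested). Weights are Glorot-uniform
from the model seed, so constructors are bit-reproducible.

* **CNN classifier** (one-hot input): three convolutional hidden layers
  — widths (32, 32, 64), kernels (13, 7, 7), strides (1, 2, 2) — with a
  single-head scaled-dot-product self-attention block after the second
  layer. Padding is masked out of attention and pooling at every
  resolution. The readout max-pools *each* hidden layer over positions
  and sums per-layer dense terms into one sigmoid logit (equivalent to a
  dense head on the concatenated pooled vector). The multi-scale readout
  matters: with only the deepest layer pooled, the network reliably
  memorizes a few hundred training sequences before a first-layer motif
  detector can form, and test AUC stays near chance; giving layer-1
  filters a direct path to the output lets a planted 12-mer be learned
  within 300 steps. The wide (13) first kernel covers a motif-sized
  window; strides 2 downsample before attention so the quadratic
  attention cost is paid at length ≤ 350.
* **CNN autoencoder** (positives only): 5 encoder convolutions (width 32,
  kernel 7, attention after layer 1) → masked flatten → dense bottleneck
  of 200 → dense → 5 decoder convolutions (attention after decoder layer
  4) → per-position logits over the 20 letters. Reconstruction is argmax
  per position, truncated to the input's true length.
* **Transformer encoder** (token input): embedding dim 64 with sinusoidal
  positions, 2 pre-norm encoder blocks (4 heads, feed-forward width 128),
  key-padding masks everywhere. The *Extract* feature vector is the
  64-dim final-layer state at the `<CLS>` position; a dense sigmoid head
  on it gives the score. Attribution gradients are taken with respect to
  the embedded token vectors.

Width, kernel, stride, block and head counts are package defaults chosen
for single-core CPU training and are fully exposed through `ModelSpec`;
nothing is hard-coded. Checkpoints are saved as an `.npz` of named arrays
plus a JSON `ModelSpec`, and save→load round trips preserve outputs
bit-for-bit.

## Training and evaluation

Classifiers train with alternating homogeneous batches: all-positive,
all-negative, all-positive, …, each pool sampled without replacement
with a reshuffle whenever the queue empties (possibly mid-batch), so
class imbalance never tilts the gradient. One Adam step per batch
(lr 3 × 10⁻³, batch 32 by default; decoupled weight decay available) on
the binary cross-entropy computed stably from logits. Training is
seed-deterministic on CPU, and a non-finite loss aborts with the step
number.

The autoencoder trains on positives only with per-position cross-entropy
over the 20 letters, padding masked out. Its checkpoints record the mean
match rate and the count of sequences at match rate ≥ 0.9, where

    match rate = (positions at which reconstruction equals input) / input length,

compared positionwise up to the shorter length — the autoencoder is
position-preserving, so no alignment is involved, and a truncated output
is penalized through the input-length denominator.

Checkpoint selection: for classifiers, the checkpoint that maximizes
ACC, AUC, F1 and MCC simultaneously when one exists; otherwise the
highest mean rank across the four metrics (a simultaneous maximizer is
not guaranteed). For the autoencoder, lexicographic on (count ≥ 0.9,
mean match rate). Ties resolve to the latest step. ACC/F1/MCC come from
the thresholded (0.5) confusion counts by their closed forms; AUC is the
rank statistic with ties half-weighted; single-class label sets report
AUC as missing with a warning.

## Integrated gradients

The midpoint Riemann rule with m steps (default 64) approximates the
path integral from baseline to input; the whole interpolation path is
evaluated as one batch, so a track costs one forward/backward pass of
batch size m. Baselines: the all-zero one-hot matrix (the "no residue"
input — it also forces attributions beyond the true length to be exactly
zero, since x − b vanishes there), and for token models the embedding of
the all-`<pad>` sequence with `<CLS>`/`<EOS>` retained. Per-residue
values are |IG| summed over the 20 one-hot channels, or summed over the
≤ 3 covering 3-mer tokens after summing |IG| over embedding channels.
Feature-vector attribution treats every output coordinate as its own
scalar function and sums the absolute per-coordinate tracks (200
coordinates for the autoencoder, 64 for the transformer; a `coords`
argument restricts the sweep). Tracks are min–max normalized to [0, 1]
per sequence; constant tracks map to all zeros to avoid 0/0.

The correctness surface is the completeness axiom: on a trained CNN the
relative gap |Σ IG − (F(x) − F(b))| / |F(x) − F(b)| falls monotonically
through m ∈ {8, 32, 128, 512} and is below 10⁻² at m = 512 (measured
≈ 6 × 10⁻⁴); on a linear scorer IG equals w ⊙ (x − b) exactly for any m.

Conservation comparison: per-column conservation of an aligned FASTA is
the modal-residue frequency with gaps excluded, mapped to reference
residues by skipping reference gaps, and correlated (Pearson) with a
track; zero-variance inputs report a missing value.

## Clustering and representatives

Feature vectors are clustered with scikit-learn's k-means (k-means++
seeding, best of 10 initializations, fixed random state; k defaults
to 7). Each cluster is represented by the member with the smallest
Euclidean distance to its centroid, ties resolved by input order, empty
clusters skipped with a warning. Euclidean distance is used throughout
because it is the metric the k-means objective itself minimizes. The
distance report lists every sequence's distance to a chosen reference
vector and can join externally computed alignment bitscores by id
(bitscores are never computed internally), adding a Spearman rank
correlation when at least three joined rows exist. Feature vectors from
the autoencoder and the transformer are clustered separately, never
pooled — the two spaces have different dimensions and geometries.

## Synthetic study conditions

The generator plants a 12-residue motif (default `WYCHKWMFCYHP`) at a
uniform random interior position of otherwise uniform-composition random
sequences of length 400–700, mutating each motif position with
probability 0.1; negatives are pure background with the same length
distribution. Defaults are 150 positives / 600 negatives. Planted
intervals are recorded 1-based inclusive so attribution recovery is
checkable against ground truth. The expected number of spurious motif
occurrences in a background sequence is ~550/20¹² ≈ 10⁻¹³ per sequence.

What the generator does *not* emulate: phylogenetic correlation between
family members, realistic residue composition (an optional composition
table can be supplied), multi-motif architectures, and indels within the
motif. Passing tests on this fixture therefore demonstrate that the
machinery works end to end on separable data with a known answer — not
that any particular real family is learnable at these sample sizes.

## Problem sizes and numerical choices

The test-suite and acceptance script train the CNN for 300 steps at
batch 32 (five independent seeds), the demonstration autoencoder for 160
steps at width 16 on five sequences, and evaluate IG at m up to 512 —
sizes chosen so the whole study runs in minutes on one CPU core while
every claim stays measurable. Arithmetic is float32 throughout the
models (gradient checks compare against float64 finite differences);
softmaxes subtract the row maximum; the binary cross-entropy is computed
from logits via the softplus identity; attention masking adds −10⁹
before the softmax; min–max normalization and Pearson correlation guard
zero-variance inputs explicitly.

## Known limitations

Greedy identity clustering is exact but quadratic; for hundreds of
thousands of sequences a word-filtered tool should replace it upstream
(its output can be fed in as clusters). The transformer is the slowest
family on CPU (quadratic attention at length 700) and is best trained
for modest step counts. Feature-mode IG costs one IG pass per output
coordinate; with the default 200-dim bottleneck a full-track sweep is
~200× a score-mode track. The E-value screening mode trusts, and never
re-derives, the external hit table.
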