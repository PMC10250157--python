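# Methods

## Problem and model

`spliceconv` classifies fixed-length genomic sequence windows as true or
false splice sites, separately for acceptor (3' intron boundary, consensus
dinucleotide AG) and donor (5' boundary, consensus GT) sites.  Each window
is Z = 400 nt (region 0–399) with the first base of the site dinucleotide at
window offset 300, so the classifier sees ~300 nt of upstream and ~100 nt of
downstream context.  Windows are one-hot encoded as Z×4 matrices in column
order (A, C, G, T): A→(1,0,0,0), C→(0,1,0,0), G→(0,0,1,0), T→(0,0,0,1), and
the invalid/ambiguous letter N→(0,0,0,0).

The classifier family is a catalog of eleven 1-D convolutional
architectures.  Each is a stack of convolutional blocks — 50 filters of
size 9 with ReLU — optionally followed per block by size-2 stride-1 max or
average pooling, then a flatten (or, for the MEANPOOL13 variant, a global
average pool), a 100-unit ReLU dense layer, 30% dropout, and a 2-class
softmax head with class order (false_site, true_site).  Training uses Adam
at learning rate 1e-4 and 2-class cross-entropy, mini-batches of 32.

Two catalog entries are weight-averaged ensembles rather than trained
networks: MODEL4 is the elementwise mean of trained MODEL1 (3 blocks, max
pool) and MODEL2 (2 blocks, max pool); MODEL5 averages MODEL1 and MODEL3
(3 blocks, average pool).

### Padding and pooling conventions

Convolutions use length-preserving ("same") padding, and pooling uses
stride 1 with the final position pooling itself, so every variant keeps the
full 400-position axis through the conv stack.  This choice makes the
parameter shapes of coexisting layers identical across the 2- and 3-block
variants, which is what makes weight averaging well defined layerwise.
Averaging follows the rule: target = the deeper source architecture (the
first argument on a depth tie, so MODEL5 adopts MODEL1's max-pooling
topology); every tensor present with identical shape in both sources is
averaged; tensors only in the deeper source are copied unchanged.  The rule
applied is recorded in the weights' provenance string.  Whether the original
ensembles averaged weights or predictions is not recoverable from their
description; layerwise weight averaging is implemented because it is the
reading that makes the deeper/shallower pairing meaningful.

### Numerical engine

No deep-learning framework is used: `spliceconv.nn` is a compact float32
engine with manual backpropagation, written for exactly the layer vocabulary
above.  Convolution is computed as a single GEMM of the padded input against
a channel-major restack of the kernel ("tap stacking") followed by shifted
summation — algebraically identical to im2col but with far less memory
traffic, which matters on a single CPU.  All five grid-search optimizers
(sgd, adam, adagrad, rmsprop, nadam) are implemented in their standard
forms.  Every source of randomness — weight init, batch shuffling, dropout
masks, fold assignment, subsampling — derives from explicit
`numpy.random.Generator` streams, so a fixed master seed reproduces training
bit for bit on a given platform.  Non-finite losses or activations raise an
explicit divergence error.  Dropout is inverted (activations rescaled at
train time) and disabled at inference, so prediction is deterministic.

## Cross-validation and model selection

Model selection uses stratified 5-fold cross-validation
(`sklearn.model_selection.StratifiedKFold`, shuffled, seeded): folds
partition the dataset, sizes differ by at most one record, and each fold
preserves the global true:false ratio to within one record.  A balanced
10,000-record dataset therefore yields five folds of 1,000 true + 1,000
false windows; the 3:1 imbalanced dataset yields 1,500/500.  Each fold's
model trains on the other four folds; the fold's validation accuracy and
loss are reported per fold along with their arithmetic means.  Because the
best epoch and the final epoch can differ under early stopping, both
accuracies are reported (`fold_accuracies` at the restored
best-validation-loss epoch, `fold_final_accuracies` at the last epoch).

Epoch count and early stopping are not fixed by the architecture
description; the defaults are 30 epochs with patience-5 early stopping on
validation loss, both configurable.  Architectures are compared by mean CV
accuracy per organism, averaged across organisms, ranked descending with
lexicographic tie-breaks on the name — so selection is deterministic and
invariant to input order.  The hyperparameter grid (layers 1–5, filters
{50, 64, 100, 128, 150}, kernel {3, 5, 7, 9, 11}, stride {1, 3, 5}, four
activations, five learning rates, five optimizers) is searched under a
budget with deterministic seeded subsampling; exhaustive search is the
budget ≥ grid-size case.  The tuning dataset must be disjoint (by record id)
from the CV dataset; overlap is an error rather than a warning.

## Evaluation

With true_site as the positive class: recall = TP/(TP+FN), precision =
TP/(TP+FP), accuracy = (TP+TN)/(TP+TN+FP+FN), F1 = 2PR/(P+R).  Ratios with
a zero denominator are reported as undefined (`None`), never coerced to 0.
Metrics are computed in [0, 1] and rendered as percentages with two decimals
in reports.

Algorithms are compared across independent tests with the Friedman test:
within each test, accuracies become ranks (1 = best, ties averaged); the
chi-square statistic uses the standard rank-sum form with tie correction
and m−1 degrees of freedom, where m is the number of algorithms and k the
number of tests.  An all-tied table gives statistic 0 and p = 1.  The
implementation is verified in the test suite against both a brute-force
re-implementation written from the textbook definition and
`scipy.stats.friedmanchisquare`.

Cross-organism generalizability is a matrix evaluation: every organism's
trained model is scored on every organism's dataset; the diagonal is the
self-test.

## Attribution and motif reports

Two transparent attribution methods share one output contract (a Z×4 matrix
aligned with the one-hot input):

* **gradient × input** — the gradient of the true-site logit with respect to
  the input, times the input elementwise; zero input cells score exactly 0;
* **occlusion** — the drop in true-site probability when one position's row
  is zeroed (the N encoding serves as the neutral baseline); the
  per-position score is placed on the active cells.

Exact Shapley-value attribution is out of scope; these two methods are
chosen because they are deterministic, dependency-free, and directly
testable (a zero-weight head provably yields all-zero attributions).

A motif report samples n = 100 true windows (seeded, without replacement),
aggregates attributions, and summarizes the window 295–305 (inclusive) that
brackets the site dinucleotide at 300–301.  Position importance is the mean
absolute contribution summed over bases.  Two position frequency matrices
are built, since logo conventions differ: a plain base-frequency PFM of the
sampled subwindows, and a contribution-weighted PFM in which each observed
base is weighted by the positive part of its mean signed contribution (a
column with no positive signal falls back to the plain frequency so columns
always sum to 1).  Exports are a FASTA of the sampled subwindows and a
`pos/A/C/G/T` TSV — the inputs standard logo tools consume; no logo image is
rendered here.

## Synthetic data generator

Real splice-site corpora come from annotated genomes; the generator
reproduces their statistical structure so every stage is testable without
downloads.  A true window is i.i.d. background sequence (default uniform
base frequencies) with a 20-position PWM planted around the site: the
consensus dinucleotide itself (always emitted at offset 300–301 in true
windows) plus 18 flanking columns.  A false window is background sequence;
a configurable fraction (default 1.0) carries the bare consensus
dinucleotide at the site offset as a decoy, so the consensus alone cannot
separate the classes and a classifier must learn the flanking structure.
The `strength` parameter linearly interpolates the flank columns between
background (0) and the full PWM (1); at strength 0 with decoy fraction 1,
true and false windows are literally draws from the same distribution and
no classifier can beat chance.

Default PWMs model idealized canonical sites.  For acceptors: a faint
pyrimidine tract onset (positions −10..−6 of the site), a sharply T-dominant
tract segment adjacent to the site (A/C/G/T = 0.01/0.15/0.01/0.83 at
−5..−2), the canonical C at −1, then a G-dominant first exon base, an
A-leaning early exon, and background beyond +5.  For donors: a CAG-leaning
exon end, then GT, then sharply A/A/G/T-dominant intron positions +3..+6
(e.g. 0.72/0.06/0.14/0.08 at +3) and a purine-leaning tail — the
GT(A/G)AGT-style consensus.  Column sharpness follows the biological
gradient (strongest immediately adjacent to the dinucleotide, decaying
outward), which deliberately confines the discriminative signal to the
displayed 295–305 logo window so that attribution analyses have an
unambiguous in-window ground truth.  Sharpness was set by computing the
generative model's likelihood-ratio (Bayes-optimal) accuracy against the
decoy negatives — ~0.98 for the acceptor and ~0.95 for the donor model — so
that the synthetic task sits in the same attainable-accuracy regime
(mid-90s) that splice-site CNNs reach on real genomes.  A weaker plant
would make the published-scale accuracy targets unreachable by any
classifier; a near-1.0 optimum would make them trivial.

Record-level RNG streams are spawned from the master seed
(`SeedSequence.spawn`), so record i's sequence is independent of how many
records are generated around it, and identical configs serialize to
byte-identical files.

What the generator does **not** emulate: organism-specific intron/exon
length distributions, GC isochores and compositional long-range structure,
branch-point positioning variability, and noncanonical (non-GT/AG) sites.
Passing tests on this generator therefore demonstrate that the pipeline's
machinery — encoding, training, selection, evaluation, attribution — behaves
correctly on data with a planted, recoverable signal; they do not certify
accuracy levels on real genomes.

## Problem sizes and defaults used in checks

The study-scale checks use the generator's default conditions: 10,000
windows per dataset (5,000/5,000 balanced or 7,500/2,500 imbalanced),
window length 400, site offset 300, strength 1, all-decoy negatives,
uniform background.  Cross-validated training of the 3-block model runs 2
epochs per fold (early stopping patience 2) — on the separable-by-
construction data, validation accuracy is already ≈0.97 after the first
epoch, so additional epochs change little.  Smaller component checks (weight
averaging, attribution contracts, CLI round-trips) use subsets of a few
hundred windows and 1–2 epochs.  The acceptance script's Friedman comparison
trains three architectures on four synthetic "organisms" of 1,000 windows
each for 2 epochs; its purpose is to exercise the ranking machinery on real
trained-model accuracies, not to certify a model ordering.

## Known limitations

* The engine is CPU-only, single-threaded deterministic; bit-exact
  reproducibility across BLAS implementations is not guaranteed (means and
  convolutions are reassociated differently), though results agree
  numerically.
* Pool size is fixed at 2 (the only size the catalog uses).
* Weight averaging assumes the shape-agreement the padding convention
  provides; averaging models trained with different `input_len` fails with
  a shape error by design.
* The occlusion method recomputes one forward pass per masked position and
  is therefore ~L times the cost of gradient × input; for routine motif
  reports gradient × input is the default.
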