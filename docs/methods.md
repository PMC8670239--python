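# Methods

## The DDE descriptor

For a cleaned sequence over the 20 standard amino acids, the descriptor
compares each of the 400 dipeptide compositions `Dc(i) = n_i / N`
(`N = l − 1` overlapping windows) against the composition expected if
residues occurred in proportion to their codon degeneracy:
`TM(i) = (C₁/61)(C₂/61)` with `C_k ∈ {1,2,3,4,6}` the synonymous-codon count
and 61 the number of sense codons. The 400 theoretical means are computed
once, in exact rational arithmetic, and sum to exactly 1 because the
degeneracies sum to 61. The deviation is standardized by the binomial
standard deviation: `DDE(i) = (Dc(i) − TM(i)) / sqrt(TM(i)(1 − TM(i))/N)`.

Two deliberate choices:

* **Denominator.** The defining formula can be read as dividing by the
  variance `TV` itself rather than its square root. We standardize by
  `sqrt(TV)` — the canonical z-score form of the DDE descriptor, which keeps
  all 400 features on a common scale; the literal `raw` reading is available
  via `denominator="raw"` (and `--dde-denominator raw`) for comparison. The
  two differ per dipeptide only by the constant factor `sqrt(TV)`.
* **Ordering.** No canonical dipeptide order is mandated by the descriptor
  itself; we fix alphabetical one-letter order `ACDEFGHIKLMNPQRSTVWY`, first
  residue varying slowest, for every file header, vector and tensor layout.

An optional dataset-level z-scaling of the 400 columns after DDE
(`post_standardize`) is provided but off by default; the per-dipeptide
standardization inside DDE is usually sufficient and the dataset-level
variant makes features depend on the batch they were computed with.

Sequences must have length ≥ 2 after cleaning (otherwise no dipeptide
exists, and `TV > 0` requires `N ≥ 1`); shorter sequences raise an explicit
error rather than being dropped silently, so dataset sizes stay auditable.
Non-standard residues (B, J, O, U, X, Z, gaps, stop marks) are removed with
a warning by default (`skip_invalid`); a `strict` policy raises instead,
naming the character and position. Neither policy is claimed to match any
particular upstream curation.

## Network input layout

The 400-vector reshapes row-major to a 20×20 grid (row = first residue).
The network consumes it as a tensor of spatial extent 1×20 with 20
channels: channel = grid row, width = grid column. This layout is a
derivation, not an arbitrary choice: with a 3×3 same-padded kernel and 32
filters, only 20 input channels reproduce a first-layer parameter count of
32·(9·20 + 1) = 5,792, and only a 1-row spatial extent with width-halving
ceil-mode 1×2 pooling reproduces the width sequence 20 → 10 → 5 → 3 and the
384-element flatten.

## Architecture and training

Default stack (all defaults overridable via `ArchitectureSpec` /
`TrainingConfig` or CLI flags):

| setting | default | rationale |
|---|---|---|
| conv filters | 32, 64, 128 | three-block stack; 1- and 2-block variants configurable |
| kernel | 3×3, same padding | the only kernel size consistent with the per-layer parameter counts (18,496; 73,856) |
| pooling | 1×2, stride 1×2, ceil mode | ceil mode is forced by the 5 → 3 width step; floor would give 5 → 2 and a 256-element flatten |
| activation | leaky ReLU, slope 0.3 | plain ReLU selectable |
| dropout | 0.4 after each pool and after the dense activation | single shared rate |
| dense | 128 units, then 2-class softmax head | |
| optimizer | Adam, lr 0.001 (nadam, rmsprop, sgd, adadelta available) | |
| loss | categorical cross-entropy | |
| epochs / batch | 80 / 32 | batch size is a conventional choice |

Total trainable parameters of the default stack: 5,792 + 18,496 + 73,856 +
49,280 + 258 = 147,682, verified both analytically (`total_param_count`) and
by counting the realized weight arrays.

The implementation is plain numpy: im2col convolution (same padding, stride
1), explicit backward passes, inverted dropout, Glorot-uniform seeded
initialization, and hand-written optimizers. Correctness of the backward
pass is established by central-difference gradient checks in the test suite;
determinism follows from seeding a single `numpy.random.Generator` per model
for initialization and one per fit for shuffling and dropout masks. Softmax
is computed with max-subtraction; the cross-entropy adds 1e−12 inside the
log; a non-finite minibatch loss aborts training with an error naming the
epoch. Zero conv blocks are allowed (the dense head then sits on the raw
400 features), which is useful as a linear-ish baseline and for parameter
accounting tests.

## Evaluation protocol

Positive class = enzyme (label 1). Metrics are the standard confusion-matrix
forms; MCC returns 0 when any factor of its denominator vanishes, while
sensitivity/specificity/accuracy raise on an empty denominator rather than
return a misleading 0. ROC curves come from scikit-learn's threshold sweep;
AUC is the trapezoidal integral, equal to the pairwise concordance
probability with ties counted ½ (asserted against a brute-force oracle).
The default decision threshold is 0.5 on the softmax enzyme probability; a
Youden-J mode picks the ROC point maximizing sensitivity + specificity − 1.

Cross-validation is stratified k-fold (k = 5 default, scikit-learn's
`StratifiedKFold`, shuffled, seeded); each fold's model trains only on the
other folds (fold index added to the training seed so folds are not
weight-tied), and the pooled report is computed from the concatenated
out-of-fold predictions, which partition the set exactly. The independent
protocol holds out a stratified subset *before* cross-validation; per-class
hold-out fractions default to 129/652 positives and 249/1108 negatives so
the default benchmark reproduces an independent set of exactly 129 enzymes
and 249 non-enzymes. `independent_eval` refuses to score any id recorded in
the model's training set (leakage guard).

## Synthetic benchmark

The generator emulates a two-class enzyme/non-enzyme sequence collection of
652 positives and 1,108 negatives with lengths uniform on [50, 600].
Negatives are first-order Markov chains with uniform transitions (1/20
everywhere); positives multiply the transition probability into each of 20
fixed motif dipeptides (one per first-residue row:
AC, CD, DE, …, WY, YA) by `enrichment` (default 5.0) and renormalize the
row. A first-order Markov construction, rather than i.i.d. residues, puts
the class signal exactly in dipeptide-transition space — the space DDE
measures — so the enrichment factor is a clean, monotone dial on
separability, and `enrichment=1.0` makes the classes exchangeable by
construction (a null case the tests exploit). The motif set is fixed and
versioned so tests are stable.

What the generator does **not** emulate: real amino-acid background
frequencies, EC-class structure, domain architecture, homology clusters, or
length–class correlations. Passing tests on this benchmark therefore
demonstrate that the pipeline's plumbing, features, optimization and
evaluation are correct and that DDE+CNN detects dipeptide-level signal; they
do not certify accuracy on curated protein databases.

## Problem sizes used by the test suite

Tests run the real pipeline at sizes chosen to keep the default suite fast
while remaining statistically meaningful, as the package's own test-design
choice: the learnability check runs five-fold cross-validation on the full
default benchmark (1,760 sequences) at 15 epochs, reaching pooled accuracy
≈ 0.99 (threshold 0.90); the null-behaviour check averages pooled AUC over
five seeds of an 80-sequence enrichment-1.0 benchmark (band [0.4, 0.6]); the
enrichment-monotonicity property averages five seeds at each of
enrichment ∈ {1, 2, 5} on 80-sequence sets. Unit-level training tests use a
reduced architecture (one 8-filter block, 16 dense units, no dropout).

## Known limitations

* The numpy network targets this model family (stride-1 same-padded odd
  kernels, 1×2 ceil pooling); it is not a general deep-learning framework,
  and training large stacks would be slow.
* Even kernels and strided convolutions are rejected at spec validation.
* `post_standardize` statistics are not persisted with a trained model, so
  the flag is intended for feature-table export, not the train/predict
  round trip (the per-sequence DDE standardization, which is persisted
  implicitly via the `denominator` metadata, is the supported path).
* Real-data performance on curated enzyme collections is out of scope; no
  claim is made beyond the synthetic benchmark.
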