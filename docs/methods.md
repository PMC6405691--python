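# Methods

## Problem

A self-interacting protein (SIP) binds copies of itself, forming
homodimers, homotrimers or higher homo-oligomers. Detecting SIPs
experimentally is slow and expensive, so sipforest predicts them from
sequence-derived evolutionary profiles alone. The task is binary
classification: given a protein's position-specific scoring matrix
(PSSM), decide whether it self-interacts.

## Golden-standard construction

Benchmarks are built from per-protein annotation records merged across
interaction databases. Proteins shorter than 50 or longer than 5000
residues are discarded as likely fragments (the boundaries themselves
survive). A protein enters the positive set if it is annotated as a
homo-oligomer, has sufficient experimental support for its
self-interaction, or is reported by at least three publications. The
experimental-support clause is ambiguous in its common phrasing
("more than one small-scale experiment or two large-scale experiments"),
so both readings are exposed: the default `strict` variant requires at
least two small-scale or at least two large-scale experiments; the
`lenient` variant accepts a single small-scale experiment. The negative
set keeps only proteins with *no* interaction annotation of any kind —
including the looser "physical association" — no SIP annotation, and no
record satisfying a positive clause; the last condition is redundant for
consistently curated data but guarantees that the positive and negative
sets are disjoint for arbitrary inputs.

Building the sets from the live databases (UniProt, PDB, DIP, MINT,
InnateDB, IntAct, BioGRID, MatrixDB) is out of scope; the rules run on
pre-merged TSV annotation tables. How evidence counts are merged across
sources is the caller's responsibility.

## Features

**PSSM.** Each protein is represented by an H×20 profile (H = residue
count) over the standard amino-acid alphabet in NCBI column order. The
expected producer is PSI-BLAST (E-value 0.001, three iterations against a
large sequence database); the library reads the first 20-column log-odds
block of its ASCII output rather than invoking the search itself, which
needs an external database. Two database-free routes exist for testing
and exploration: substitution-weighted scores `C[a,b] = Σ_k p(a,k)q(b,k)`
from an observed frequency profile and the PAM250 mutation matrix
(biopython's table), and a seeded synthetic generator (below).

**Length collapse.** Profiles vary in length, so the H×20 matrix M is
collapsed to the 20×20 cross-product MᵀM — symmetric, positive
semidefinite, and equal to the sum of per-position outer products, i.e. a
co-conservation summary that no longer depends on H.

**Wavelet encoding.** One level of a 2-D orthonormal discrete wavelet
transform (Haar, periodization boundary) maps the 20×20 matrix to four
10×10 sub-bands — approximation, horizontal, vertical and diagonal
detail — concatenated row-major into exactly 400 coefficients. The
wavelet family, level, boundary rule and sub-band order are not forced by
the problem; Haar at level 1 with periodization is the unique simple
choice producing exactly 400 coefficients from a 20×20 input, and all
four settings are configuration keys. Orthonormality gives the Parseval
identity (Σ coefficients² = ‖input‖²_F, verified to 1e-8), so the
encoding is lossless up to the PCA step. An alternative encoder emitting
the 20 eigenvalues of MᵀM is available behind a flag but not the default.

**PCA.** Principal-component analysis reduces 400 to 300 dimensions
(requires ≥ 301 training vectors). By default the projection is fitted on
training folds only and applied to test folds; `pca_scope="global"`
reproduces whole-dataset fitting, which leaks test information into the
projection but matches how such pipelines are often run.

## Classifier: deep forest

The classifier is a from-scratch deep forest (cascade forest with
multi-grained scanning):

* **Scanning.** A window of length 100 with stride 1 slides over the
  300-dim feature vector, producing ⌊(d−window)/stride⌋+1 = 201
  sub-vectors per sample, each inheriting its sample's label. One Gini
  random forest and one complete-random tree forest train on the pooled
  window instances; at transform time each window's two-class probability
  vector from each forest is concatenated: 201 × 2 × 2 = 804 values.

* **Cascade.** Each level holds two Gini random forests and two
  complete-random tree forests, 500 trees each by default. A forest's
  per-sample class vector is estimated out-of-fold by stratified k-fold
  CV (k = 3 by default; the fold models are kept and averaged at test
  time). The level's class vectors are appended to the scan-augmented
  features to form the next level's input. A new level is retained only
  if its CV accuracy beats the best so far by more than `tolerance`
  percentage points (default 5.0); with that default cascades are
  typically one or two levels deep. Growth also stops at `max_levels`.

* **Trees.** Complete-random trees split each internal node on a
  uniformly random non-constant feature at a uniformly random cut between
  that feature's observed min and max, growing until leaves are
  class-pure or hold ≤ 10 instances; leaves store class-frequency
  vectors. They are implemented here directly (index-based iterative
  construction). Gini forests delegate to scikit-learn with the
  candidate-feature count pinned to ⌈√d⌉.

Prediction averages the final level's four class vectors; ties in the
argmax resolve toward class 0. All seeds flow from a single integer, so
fit and predict are bitwise reproducible.

A note on configuration: sample vectors here are 1-D, so the window and
stride are configured explicitly; a square "single-sample shape" setting
seen in some deep-forest configurations does not apply to 300-dim vectors
and is deliberately not exposed.

## Evaluation

Accuracy, specificity (TN/(TN+FP)), precision (TP/(TP+FP)), recall
(TP/(TP+FN)), F1 (= 2PR/(P+R) = 2TP/(2TP+FP+FN)) and Matthews correlation
are computed from the pooled and per-fold confusion counts; a printed
formula for recall with TP+TN in the denominator circulates in this
setting but contradicts the F1 identity and the universal definition, so
TP/(TP+FN) is used. Zero-denominator statistics return 0 with a warning
so degenerate folds do not abort a run. ROC curves use the standard axes
(x = FPR, y = TPR); the trapezoid AUC equals the Mann–Whitney pairwise
concordance probability with half-credit ties (asserted in tests).
The protocol is 5-fold: a seeded random partition into five
non-overlapping parts with sizes differing by at most one; four parts
train (including any PCA fit under `train_only` scope), the fifth is
scored. Per-fold and pooled statistics are both reported since either
summary convention may be wanted. The comparison baseline is an RBF-kernel
SVM with C = 0.3 and gamma = 1000.

## Synthetic data

Real golden-standard sets and PSI-BLAST profiles are not redistributable,
so the package ships two seeded generators that define its test
conditions:

* `synthesize_pssm(length, class_label, signal_strength, seed)` — rows
  i.i.d. standard Gaussian over 20 columns; class 1 shifts the mean of
  columns 0–4 by `signal_strength`. Defaults used in the CLI simulation:
  lengths uniform on [80, 160] (typical protein-domain scale),
  signal 2.0; the end-to-end smoke runs use signal 3.0, which the
  wavelet + deep-forest pipeline separates almost perfectly.
* `make_two_class_features(n_per_class, n_features=300, signal, n_signal=10,
  seed)` — unit-variance Gaussian feature vectors with class 1's mean
  shifted by `signal` on 10 evenly spaced features; signal 4.0 is
  effectively separable, signal 0 is exact chance.

These generators emulate the *geometry* the classifier must handle
(variable-length profiles, a class-dependent mean shift diluted across
many uninformative dimensions) but not the statistical structure of real
PSSMs: no positional autocorrelation, no amino-acid composition bias, no
class imbalance (real SIP benchmarks are ~1:10), and a literal linear
separation real data never has. Passing the synthetic benchmarks
therefore demonstrates that the machinery is correct and well-calibrated
(chance data stays at chance; separable data is recovered through the
full PSSM→wavelet→forest path), not that real-data accuracies are
reproduced.

## Numerical choices and problem sizes

* Symmetry tolerance for the 20×20 cross-product: 1e-9; PCA component
  orthonormality: 1e-8; probability-vector normalization: 1e-9.
* Complete-random trees: a numerically degenerate random cut (all
  instances on one side) falls back to the midpoint, then to another
  feature; a node whose features are all constant becomes a leaf.
* Benchmarks in the test-suite and acceptance script run the exact
  default architecture (window 100, stride 1, 2+2 forests per level,
  tolerance 5.0, k = 3) with 25 trees per forest, n = 300 samples of
  300 features — the package's desk-scale configuration; the tree count
  is the only dial changed from the 500-tree default, chosen so a full
  5-fold run completes in minutes on a single core.
* The 5-fold benchmark with these sizes reaches pooled accuracy and AUC
  of 1.0 on signal-4.0 data and stays inside [0.4, 0.6] on signal-0 data
  (99% binomial band); the numbers the acceptance script prints are
  recomputed at each run.

## Known limitations

* Multi-grained scanning uses a single window size; truly multi-grained
  (several window sizes) scanning is not implemented.
* No regression mode; two classes only (the cascade generalizes to more,
  but contracts are asserted for binary problems).
* PSI-BLAST is not wrapped; non-standard amino acids in upstream
  profiles are the parser caller's concern.
* The SVM baseline with gamma = 1000 collapses to near-majority voting on
  standardized synthetic features (kernel values vanish off-diagonal) —
  consistent with the very low recall such baselines show — so its
  synthetic-benchmark accuracy hovers near 50%.
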