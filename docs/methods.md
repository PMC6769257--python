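# Methods

## Model

The classifier is a sequence-labelling network over the first 200 residues
of a protein (the window covers the longest known transit peptides, which
reach ~160 residues).  Residues are encoded as rows of the BLOSUM62
substitution matrix in the fixed column order A R N D C Q E G H I L K M F P
S T W Y V; the unknown residue X — to which the ambiguity codes B, Z, J, U
and O are normalised — encodes as the zero vector, which is neutral under
the first linear layer.  Cleavage sites are stored 1-based as the index of
the *last* peptide residue; relative positions use −1 for the last peptide
residue and +1 for the first mature residue, with no position 0.

Layer sizes of the full configuration: 32 feature units, 256 LSTM units per
direction (512 concatenated), attention size 144, 13 attention heads,
256-unit summariser, 5-way softmax.  The reduced configuration used for the
desk-scale experiments throughout the tests and the acceptance script is
16/64/32/8; it exists purely because the full model is unnecessarily large
for the synthetic grammars.

Design choices where the architecture description is open:

* **Group conditioning.**  The plant/non-plant flag (plant = 1) enters as a
  learned linear projection to the initial hidden *and* cell states of both
  LSTM directions — the smallest mechanism that makes the flag trainable
  end to end.
* **CS read-out.**  The four CS position distributions are the first four
  attention rows taken as-is (identity read-out).  Supervising them
  directly is what forces those heads to localise the cleavage site and
  makes the attention maps interpretable; a per-head position-wise layer
  could be added but would decouple attention from the CS signal.
* **Activations.**  ReLU for the feature transform and summariser.
* **Summarisation.**  The 13 × 512 context matrix is flattened and passed
  through the 256-unit dense layer — the least-structured reading of
  "summarise into a vector".
* **Dropout** (default rate 0.25) after the feature transform, after the
  BiLSTM and after the summariser.
* **CS loss.**  Only the attention head matching a record's true class is
  supervised on its cleavage site — a record annotates exactly one CS, so
  the other heads have no target.  The total loss is the mean of the class
  cross-entropy and the CS cross-entropy (the latter averaged over records
  that have a CS); a batch of only noTP records yields the class term
  alone, and the test suite asserts that such a batch produces gradients
  identical to the classification term by itself.
* **Tie-breaking.**  All argmax decisions (class and CS) resolve ties
  toward the lower index.
* **Masking.**  Attention scores on padded positions receive −∞ before the
  softmax, so padded positions carry exactly zero probability mass and the
  forward pass is invariant to the amount of padding (asserted to 1e−5).
  The backward LSTM direction runs over each record's valid residues only,
  by reversing the valid prefix in place.

## Numerical engine

No GPU framework is used: `tpsort.nn` is a reverse-mode autodiff engine on
numpy arrays (float32 working precision, switchable to float64).  The LSTM
layer is a single fused graph node whose backward pass (BPTT, gate order
input/forget/cell/output, forget-gate bias initialised to 1) is written by
hand; all other operations are small composable nodes.  Every operation and
the full model graph are finite-difference checked in float64 in the test
suite.  Parameters are Glorot-uniform initialised from a seeded generator;
training uses Adam (lr 1e−3, β₁ 0.9, β₂ 0.999) with batch size 64,
length-bucketed batches (shuffled by batch each epoch), optional early
stopping on validation loss with patience 5, and is bitwise-reproducible on
CPU for a fixed seed.

## Cross-validation

Homology partitioning is a greedy single-linkage stand-in for profile-based
clustering: records are visited longest-first and join the first cluster
whose representative they match at ≥ 20% identity over ≥ 80% of the shorter
sequence (first 200 residues), using BLOSUM62 local alignment seeded by a
shared-3-mer prescreen; a precomputed cluster TSV can override it.  Whole
clusters are dealt largest-first to the currently smallest of five folds
(ties broken toward the fold with the fewest members of the cluster's
majority class), which bounds the fold-size spread by the largest cluster.
For each outer test fold the four remaining folds rotate as validation
sets: 20 models in total, test-fold predictions being the average of the
four inner models' class and attention probabilities.

## Synthetic data

The generator plants the sequence regularities each peptide class is known
for, at desk scale; it is a grammar, not a biophysical simulator.  Defaults
(chosen once as field-plausible values): every sequence starts with M;
mature regions of 30–80 residues are drawn from a uniform background (kept
uniform so the majority-class chance floor is analytic — 0.50 under the
default 50/20/15/10/5 class mix); noTP records are 50–160 residues.

* **SP** — n-region of 1–5 residues with K/R enriched (p ≈ 0.31 each),
  h-region of 7–15 residues drawn uniformly from {L, A, V, I, F}, c-region
  of 3–7 residues ending in the small-residue A-X-A pattern (alanine forced
  at −1 and −3).
* **mTP** — 15–60 residues enriched in R, L, S (p ≈ 0.15 each) and depleted
  of D/E; one arginine planted at −2, −3 or −10 from the CS with weights
  0.40/0.35/0.25 (the three mitochondrial peptidase signatures), and the 12
  residues upstream of the CS otherwise arginine-free so the planted
  position is the nearest upstream arginine — mirroring how the processing,
  Icp55 and intermediate peptidases define those offsets.
* **cTP** — 30–80 residues, alanine at position 2 with probability 0.65
  (about two-thirds of real cTPs/luTPs carry it), an S/T-enriched core
  (p ≈ 0.20 each) containing no acidic residues; assigned to the plant
  group.
* **luTP** — bipartite: a 20–40-residue cTP-like stretch followed by an
  SP-like stretch; only the second (thylakoidal-processing) cleavage is
  annotated, matching how such signals are annotated in practice.
* `generate_family` produces point-substituted homologues (per-site
  substitution by a uniform residue with rate r, expected identity
  (1 − r) + r/20) to exercise the clustering.

What the grammars deliberately lack: realistic residue backgrounds,
length–composition correlations, amphiphilic periodicity, and homology
between classes.  Passing the end-to-end tests therefore shows the
implementation learns and localises planted compositional signals — not
that it reaches any particular accuracy on real proteomes.

## Metrics and analyses

Confusion matrices are oriented rows = predicted, columns = observed.
Per-class precision, recall, F1 and MCC come from the one-vs-rest
reduction, with every zero-denominator case defined as 0.  Windowed CS
recall is computed only over correctly classified records, two-sided
(|predicted − true| ≤ w).  ROC curves are one-vs-rest threshold sweeps
(endpoints (0,0) and (1,1) included); tests verify the area against
pair-counting.  The count correction row-normalises the confusion matrix
into P(true | predicted) and redistributes predicted pools, corrected[c] =
Σₖ n[k]·P[k][c]; this orientation is the one under which total counts are
conserved exactly and the true per-class counts of the estimation set are
recovered exactly, which the tests assert on random labelled sets.

Interpretation: the attention profile of a prediction is the per-position
maximum over all heads (a per-head variant can be derived from the raw
attention matrix, which every `Prediction` carries).  LOGO matrices
aggregate residue frequencies or attention mass across records aligned at
the N-terminus or at the (true or predicted) CS; frequency columns sum to 1
where data exist, and uncovered offsets are flagged rather than filled.
Secondary-structure preference profiles report log2 of the mean
helix/sheet/turn propensity per offset using a bundled, editable
Chou–Fasman propensity table (results are scale-relative; any TSV with the
same columns may be substituted).

## Problem sizes

The end-to-end study conditions are 2,500 training and 500 test records
(class mix 50/20/15/10/5%), the reduced 16/64/32/8 configuration and at
most 15 epochs — sizes at which the full pipeline, including the baseline
and analyses, completes in a few minutes on one CPU.  The nested-CV
bookkeeping checks run on 150 records with a further-reduced configuration;
they exercise the partitioning and ensembling logic, not asymptotic
accuracy.

## Known limitations

* The synthetic grammars are far easier than real targeting peptides;
  reported synthetic metrics are upper bounds of a sort and say nothing
  quantitative about real data.
* The greedy clustering is a stand-in, not PSI-CD-HIT/BLAST; at very low
  identity thresholds its single-linkage behaviour depends on visiting
  order.
* The MLP baseline classifies only; it never predicts cleavage sites.
* float32 forward passes are deterministic per platform but may differ in
  the last bits across BLAS builds.
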