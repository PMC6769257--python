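# tpsort

Joint prediction of N-terminal **targeting peptides** and their **cleavage
sites** with a BiLSTM / multi-attention network, implemented in numpy,
together with the evaluation metrics, an MLP baseline, a confusion-matrix
count-correction procedure, attention/sequence interpretability analyses and
a synthetic-data generator that makes the whole pipeline testable end to end
without any database download.

## The problem

Many proteins carry an N-terminal presequence that routes them to a cellular
compartment and is cleaved off after import: signal peptides (**SP**,
secretory pathway), mitochondrial transit peptides (**mTP**), chloroplast
transit peptides (**cTP**) and the bipartite thylakoid luminal transit
peptides (**luTP**); proteins without such a signal are **noTP**.  Given a
protein sequence (and a plant / non-plant organism flag), the task is to
predict both the class and, for the four positive classes, the 1-based
position of the last peptide residue — the cleavage site (CS).

## The model

The first 200 residues are encoded as BLOSUM62 matrix rows *x*<sub>t</sub>
and processed by

1. a position-wise feature transform *c*<sub>t</sub> = relu(*W
   x*<sub>t</sub> + *b*) (32 units);
2. a BiLSTM (256 units per direction) whose initial hidden and cell states
   are a learned projection of the organism-group flag; hidden states are
   concatenated to *h*<sub>t</sub> ∈ ℝ<sup>512</sup>;
3. a multi-attention layer *A* = softmax(tanh(*H W*<sub>a</sub> +
   *b*<sub>a</sub>) *V*) with 13 heads (attention size 144), each row a
   probability distribution over sequence positions with exactly zero mass
   on padding;
4. rows 1–4 of *A* are read out directly as the CS position distributions
   for SP, mTP, cTP and luTP — CS supervision therefore shapes the attention
   itself, which is what makes the attention maps interpretable;
5. the context matrix *E* = *A H* (13 × 512) is flattened, summarised by a
   256-unit dense layer and classified by a 5-way softmax.

Training minimises the average of two cross-entropies (class, and the
true-class CS head) with Adam; records without a targeting peptide
contribute no CS error.  Model selection uses five-fold nested
cross-validation with homology-aware partitioning (greedy single-linkage
clustering at 20% identity over 80% coverage of the N-terminal window), so
similar sequences never straddle folds; 5 × 4 = 20 models are trained and
test folds are predicted by averaging the four inner models' probabilities.

Because no deep-learning framework is required, the network runs anywhere
numpy does: `tpsort.nn` is a small reverse-mode autodiff engine with a
fused, manually differentiated LSTM layer, finite-difference-checked in the
test suite.

## Worked example

Train the reduced configuration on synthetic proteins with planted
targeting-peptide grammars and evaluate out of sample:

```python
from tpsort.synthetic import SyntheticSpec, generate
from tpsort.model import ModelConfig
from tpsort.training import OptimiserSettings, train_model, predict_records
from tpsort.evaluation import classification_report, confusion, cs_recall

train = generate(SyntheticSpec(
    n_per_class={"noTP": 300, "SP": 120, "mTP": 90, "cTP": 60, "luTP": 30},
    seed=11))
test = generate(SyntheticSpec(
    n_per_class={"noTP": 100, "SP": 40, "mTP": 30, "cTP": 20, "luTP": 10},
    seed=12))

config = ModelConfig(feat_units=16, lstm_units=64, attn_units=32, n_attn=8,
                     seed=1)
model, history = train_model(train, None, config,
                             OptimiserSettings(max_epochs=10, seed=1))
preds = predict_records(model, test)

report = classification_report(
    confusion([p.pred_class for p in preds], [r.label for r in test]))
print(report.to_table())
by_id = {p.id: p for p in preds}
print("SP CS recall (+-2):", round(cs_recall(by_id, test, 2)["SP"], 3))
print("mTP CS recall (+-5):", round(cs_recall(by_id, test, 5)["mTP"], 3))
```

which prints:

```
 class precision  recall     F1    MCC
  noTP     0.942   0.970  0.956  0.910
    SP     0.851   1.000  0.920  0.902
   mTP     1.000   0.800  0.889  0.879
   cTP     1.000   1.000  1.000  1.000
  luTP     1.000   0.600  0.750  0.767
macro-F1 0.903
SP CS recall (+-2): 0.925
mTP CS recall (+-5): 0.667
```

Each row gives one-vs-rest precision, recall, F1 and Matthews correlation
for one class; the CS recalls are the fraction of correctly classified SP
(resp. mTP) test proteins whose predicted cleavage site lies within ±2
(resp. ±5) residues of the annotated one.  With the full 2,500-record
training set and 15 epochs (see below) macro-F1 reaches ≈ 0.99.

The same pipeline is available from the shell:

```bash
tpsort generate --out-dir data --seed 3
tpsort train --fasta data/synthetic.fasta --labels data/synthetic.labels.tsv \
             --out-dir run --seed 1          # nested CV: 20 models + metrics
tpsort predict --fasta data/synthetic.fasta \
               --checkpoint run/model_outer0_inner1.npz --out preds.tsv
tpsort interpret --fasta data/synthetic.fasta \
                 --labels data/synthetic.labels.tsv --out-dir interp
```

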