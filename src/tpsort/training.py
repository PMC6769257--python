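"""Homology-aware partitioning, nested cross-validation and optimisation.

Homology clustering is a greedy single-linkage stand-in for profile-based
clustering tools: records are visited by decreasing length and join the first
cluster whose representative they match at >= 20% identity over >= 80% of the
shorter sequence (first 200 residues, local alignment seeded by shared
3-mers).  A precomputed two-column TSV (id, cluster) may be supplied instead.

The cross-validation plan deals whole clusters to five outer folds; for each
outer test fold the remaining four folds rotate as validation sets, giving
5 x 4 = 20 train/validation/test triples and hence 20 trained models.  Each
test-fold prediction is the average of its four inner models' probability
outputs.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .model import ModelConfig, Prediction, TargetingModel
from .sequence_io import CLASS_INDEX, EncodedBatch, ProteinRecord, encode_batch, truncate_n_terminal


# ---------------------------------------------------------------------------
# Homology clustering (stand-in)
# ---------------------------------------------------------------------------

def _kmer_set(seq: str, k: int = 3) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _identity_coverage(a: str, b: str, aligner) -> Tuple[float, float]:
    """(identity over aligned columns, aligned fraction of the shorter seq)."""
    try:
        aln = aligner.align(a, b)[0]
    except (IndexError, ValueError):
        return 0.0, 0.0
    matches = 0
    columns = 0
    covered = 0
    shorter = min(len(a), len(b))
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        columns += ea - sa
        covered += ea - sa if len(a) <= len(b) else eb - sb
        matches += sum(1 for x, y in zip(a[sa:ea], b[sb:eb]) if x == y)
    if columns == 0:
        return 0.0, 0.0
    return matches / columns, covered / shorter


def cluster_greedy(records: Sequence[ProteinRecord], identity_threshold: float = 0.2,
                   coverage: float = 0.8, window: int = 200) -> Dict[str, str]:
    """Greedy single-linkage clustering of N-terminal windows.

    Returns a map record-id -> cluster-id (the representative's id).
    """
    if not records:
        raise ValueError("cluster_greedy: no records")
    aligner = _make_aligner()
    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: List[Tuple[str, str, set]] = []  # (cluster id, window seq, kmers)
    assignment: Dict[str, str] = {}
    for rec in order:
        seq = rec.sequence[:window].replace("X", "")
        kmers = _kmer_set(seq)
        placed = False
        for cid, rep_seq, rep_kmers in reps:
            if not (kmers & rep_kmers):
                continue  # no ungapped seed, no alignment attempted
            ident, cov = _identity_coverage(seq, rep_seq, aligner)
            if ident >= identity_threshold and cov >= coverage:
                assignment[rec.id] = cid
                placed = True
                break
        if not placed:
            reps.append((rec.id, seq, kmers))
            assignment[rec.id] = rec.id
    return assignment


def read_cluster_tsv(path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "cluster"], dtype=str)
    return dict(zip(df["id"], df["cluster"]))


# ---------------------------------------------------------------------------
# Cross-validation plan
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """Fold assignment plus the inner rotation bookkeeping."""

    outer_folds: int
    assignment: Dict[str, int]  # record id -> outer fold

    def triples(self) -> List[Tuple[int, int]]:
        """(outer test fold, inner validation fold) pairs — 5x4=20 by default."""
        return [(o, v) for o in range(self.outer_folds)
                for v in range(self.outer_folds) if v != o]

    def fold_members(self, fold: int) -> List[str]:
        return [rid for rid, f in self.assignment.items() if f == fold]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"outer_folds": self.outer_folds, "assignment": self.assignment},
                      fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CVPlan":
        with open(path) as fh:
            d = json.load(fh)
        return cls(outer_folds=d["outer_folds"], assignment=d["assignment"])


def make_cv_plan(records: Sequence[ProteinRecord], clusters: Dict[str, str],
                 n_outer: int = 5, seed: int = 0) -> CVPlan:
    """Deal whole homology clusters to folds, balancing per-class counts.

    Clusters are shuffled, then assigned largest-first: each cluster goes to
    the currently smallest fold, with ties broken toward the fold holding the
    fewest members of the cluster's majority class, then the lower fold
    index.  Largest-first dealing to the smallest fold bounds the spread of
    fold sizes by the largest cluster size.
    """
    by_cluster: Dict[str, List[ProteinRecord]] = defaultdict(list)
    for r in records:
        by_cluster[clusters[r.id]].append(r)
    if len(by_cluster) < n_outer:
        raise ValueError(f"only {len(by_cluster)} clusters for {n_outer} folds")
    rng = np.random.default_rng(seed)
    cids = sorted(by_cluster)
    rng.shuffle(cids)
    cids.sort(key=lambda c: -len(by_cluster[c]))  # stable: keeps shuffle for ties
    class_counts = np.zeros((n_outer, len(CLASS_INDEX)), dtype=int)
    fold_sizes = np.zeros(n_outer, dtype=int)
    assignment: Dict[str, int] = {}
    for cid in cids:
        members = by_cluster[cid]
        labels = [m.label for m in members if m.label is not None]
        maj = CLASS_INDEX[Counter(labels).most_common(1)[0][0]] if labels else 0
        order = sorted(range(n_outer),
                       key=lambda f: (fold_sizes[f], class_counts[f, maj], f))
        fold = order[0]
        for m in members:
            assignment[m.id] = fold
            if m.label is not None:
                class_counts[fold, CLASS_INDEX[m.label]] += 1
        fold_sizes[fold] += len(members)
    return CVPlan(outer_folds=n_outer, assignment=assignment)


# ---------------------------------------------------------------------------
# Optimisation loop
# ---------------------------------------------------------------------------

@dataclass
class OptimiserSettings:
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0


@dataclass
class TrainingHistory:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_csv(self, path) -> None:
        pd.DataFrame({"epoch": range(1, len(self.train_loss) + 1),
                      "train_loss": self.train_loss,
                      "val_loss": self.val_loss}).to_csv(path, index=False)


def _prepare(records: Sequence[ProteinRecord], max_len: int) -> List[ProteinRecord]:
    out = []
    for r in records:
        t = truncate_n_terminal(r, max_len)
        if t.valid_for_training:
            out.append(t)
    return out


def _length_batches(records: List[ProteinRecord], batch_size: int) -> List[List[int]]:
    """Batch indices bucketed by length so padding stays short."""
    order = sorted(range(len(records)), key=lambda i: (len(records[i]), i))
    return [order[i:i + batch_size] for i in range(0, len(order), batch_size)]


def evaluate_loss(model: TargetingModel, records: Sequence[ProteinRecord],
                  batch_size: int = 64) -> float:
    """Mean per-record loss without dropout."""
    recs = _prepare(records, model.config.max_len)
    batches = _length_batches(recs, batch_size)
    total, n = 0.0, 0
    for idx in batches:
        batch = encode_batch([recs[i] for i in idx], model.config.max_len)
        total += model.loss(batch) * len(idx)
        n += len(idx)
    return total / max(n, 1)


def train_model(train_records: Sequence[ProteinRecord],
                val_records: Optional[Sequence[ProteinRecord]],
                config: ModelConfig,
                settings: Optional[OptimiserSettings] = None,
                ) -> Tuple[TargetingModel, TrainingHistory]:
    """Adam training with early stopping on the validation loss.

    Returns the model restored to its best-validation checkpoint (the last
    epoch when no validation set is given) and the per-epoch history.
    """
    settings = settings or OptimiserSettings()
    train_ids = {r.id for r in train_records}
    if val_records and train_ids & {r.id for r in val_records}:
        raise ValueError("train and validation sets overlap")
    model = TargetingModel(config)
    opt = nn_adam(model, settings.lr)
    recs = _prepare(train_records, config.max_len)
    if not recs:
        raise ValueError("no trainable records after truncation")
    batches = _length_batches(recs, settings.batch_size)
    shuffle_rng = np.random.default_rng(settings.seed)
    drop_rng = np.random.default_rng(settings.seed + 1)
    history = TrainingHistory()
    best_state = model.get_state()
    best_val = np.inf
    since_best = 0
    for epoch in range(settings.max_epochs):
        order = shuffle_rng.permutation(len(batches))
        epoch_loss, n_seen = 0.0, 0
        for bi in order:
            idx = batches[bi]
            batch = encode_batch([recs[i] for i in idx], config.max_len)
            loss = model.loss_graph(batch, drop_rng if config.dropout > 0 else None)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch + 1}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            n_seen += len(idx)
        history.train_loss.append(epoch_loss / n_seen)
        if val_records:
            vloss = evaluate_loss(model, val_records, settings.batch_size)
            history.val_loss.append(vloss)
            if vloss < best_val:
                best_val = vloss
                best_state = model.get_state()
                history.best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best > settings.patience:
                    break
        else:
            history.val_loss.append(np.nan)
            history.best_epoch = epoch
            best_state = model.get_state()
    model.set_state(best_state)
    return model, history


def nn_adam(model: TargetingModel, lr: float):
    from .nn import Adam
    return Adam(model.params, lr=lr)


def predict_records(model: TargetingModel, records: Sequence[ProteinRecord],
                    batch_size: int = 64) -> List[Prediction]:
    """Inference in input order (internally length-bucketed)."""
    recs = [truncate_n_terminal(r, model.config.max_len) for r in records]
    batches = _length_batches(list(recs), batch_size)
    preds: Dict[int, Prediction] = {}
    for idx in batches:
        for i, p in zip(idx, model.forward(encode_batch([recs[i] for i in idx],
                                                        model.config.max_len))):
            preds[i] = p
    return [preds[i] for i in range(len(recs))]


def _average_predictions(per_model: List[List[Prediction]]) -> List[Prediction]:
    out = []
    for preds in zip(*per_model):
        cp = np.mean([p.class_probs for p in preds], axis=0)
        att = np.mean([p.attention for p in preds], axis=0)
        out.append(Prediction(id=preds[0].id, class_probs=cp,
                              cs_probs=att[0:4, :], attention=att))
    return out


def run_nested_cv(records: Sequence[ProteinRecord], plan: CVPlan,
                  config: ModelConfig,
                  settings: Optional[OptimiserSettings] = None,
                  ) -> Tuple[Dict[Tuple[int, int], TargetingModel],
                             Dict[str, Prediction]]:
    """Train the 20 nested-CV models and collect out-of-fold predictions.

    For each outer test fold, the four models trained on its inner rotations
    are ensembled by averaging class and attention probabilities; every record
    receives exactly one out-of-fold prediction.
    """
    settings = settings or OptimiserSettings()
    by_id = {r.id: r for r in records}
    models: Dict[Tuple[int, int], TargetingModel] = {}
    oof: Dict[str, Prediction] = {}
    for outer in range(plan.outer_folds):
        test_recs = [by_id[rid] for rid in plan.fold_members(outer) if rid in by_id]
        inner_preds = []
        for val in range(plan.outer_folds):
            if val == outer:
                continue
            train_recs = [r for r in records
                          if plan.assignment[r.id] not in (outer, val)]
            val_recs = [by_id[rid] for rid in plan.fold_members(val) if rid in by_id]
            cfg_seed = config.seed + 101 * outer + 13 * val
            cfg = ModelConfig(**{**config.__dict__, "seed": cfg_seed})
            model, _ = train_model(train_recs, val_recs, cfg, settings)
            models[(outer, val)] = model
            inner_preds.append(predict_records(model, test_recs,
                                               settings.batch_size))
        for p in _average_predictions(inner_preds):
            oof[p.id] = p
    return models, oof
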