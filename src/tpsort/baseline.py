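"""MLP baseline on one-hot encodings of the first XX residues.

A deliberately simple comparator for the recurrent model: the first
``n_residues`` amino acids (up to 20) are one-hot encoded, concatenated and
fed through a single hidden layer (optionally none) into a 5-way softmax.
It classifies only — no cleavage-site prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .nn import Adam, Tensor
from .nn import autograd as ag
from .sequence_io import CLASSES, CLASS_INDEX, RESIDUE_INDEX, ProteinRecord


@dataclass
class MLPConfig:
    n_residues: int = 20
    hidden_units: int = 64  # 0 = plain softmax regression
    n_classes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_residues <= 20):
            raise ValueError("n_residues must lie in [1, 20]")

    @property
    def input_dim(self) -> int:
        return 20 * self.n_residues


def mlp_encode(record: ProteinRecord, n_residues: int) -> np.ndarray:
    """Concatenated per-position one-hot vector, zero-padded; X -> zero block."""
    v = np.zeros(20 * n_residues, dtype=np.float32)
    for t, aa in enumerate(record.sequence[:n_residues]):
        j = RESIDUE_INDEX.get(aa)
        if j is not None:
            v[20 * t + j] = 1.0
    return v


class MLPBaseline:
    def __init__(self, config: MLPConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.params = {}

        def param(name, shape, zeros=False):
            if zeros:
                data = np.zeros(shape, dtype=np.float32)
            else:
                limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
                data = rng.uniform(-limit, limit, shape).astype(np.float32)
            self.params[name] = Tensor(data, requires_grad=True)

        if config.hidden_units > 0:
            param("W1", (config.input_dim, config.hidden_units))
            param("b1", (config.hidden_units,), zeros=True)
            param("W2", (config.hidden_units, config.n_classes))
        else:
            param("W2", (config.input_dim, config.n_classes))
        param("b2", (config.n_classes,), zeros=True)

    def _log_probs(self, X: np.ndarray) -> Tensor:
        h = Tensor(X)
        if self.config.hidden_units > 0:
            h = ag.relu(ag.add(ag.matmul(h, self.params["W1"]), self.params["b1"]))
        logits = ag.add(ag.matmul(h, self.params["W2"]), self.params["b2"])
        return ag.masked_log_softmax(logits, np.ones(logits.shape, dtype=bool))

    def predict_proba(self, records: Sequence[ProteinRecord]) -> np.ndarray:
        X = np.stack([mlp_encode(r, self.config.n_residues) for r in records])
        return np.exp(self._log_probs(X).data)

    def predict(self, records: Sequence[ProteinRecord]) -> List[str]:
        return [CLASSES[i] for i in np.argmax(self.predict_proba(records), axis=1)]


def train_mlp(train_records: Sequence[ProteinRecord],
              val_records: Optional[Sequence[ProteinRecord]],
              config: MLPConfig, lr: float = 1e-3, batch_size: int = 64,
              max_epochs: int = 50, patience: int = 5) -> MLPBaseline:
    """Cross-entropy / Adam training with early stopping on validation loss."""
    mlp = MLPBaseline(config)
    opt = Adam(mlp.params, lr=lr)
    X = np.stack([mlp_encode(r, config.n_residues) for r in train_records])
    y = np.array([CLASS_INDEX[r.label] for r in train_records])
    Xv = yv = None
    if val_records:
        Xv = np.stack([mlp_encode(r, config.n_residues) for r in val_records])
        yv = np.array([CLASS_INDEX[r.label] for r in val_records])
    rng = np.random.default_rng(config.seed)
    best_state = {k: p.data.copy() for k, p in mlp.params.items()}
    best_val = np.inf
    since_best = 0
    for _ in range(max_epochs):
        order = rng.permutation(len(X))
        for s in range(0, len(X), batch_size):
            idx = order[s:s + batch_size]
            logp = mlp._log_probs(X[idx])
            loss = ag.pick_mean_negative(logp, [(i, int(c)) for i, c in enumerate(y[idx])])
            opt.zero_grad()
            loss.backward()
            opt.step()
        if Xv is not None:
            logp = mlp._log_probs(Xv)
            vloss = float(ag.pick_mean_negative(
                logp, [(i, int(c)) for i, c in enumerate(yv)]).data)
            if vloss < best_val:
                best_val = vloss
                best_state = {k: p.data.copy() for k, p in mlp.params.items()}
                since_best = 0
            else:
                since_best += 1
                if since_best > patience:
                    break
        else:
            best_state = {k: p.data.copy() for k, p in mlp.params.items()}
    for k, p in mlp.params.items():
        p.data = best_state[k]
    return mlp
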