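"""The joint targeting-peptide / cleavage-site network.

Architecture (per-record, length L ≤ 200, BLOSUM62-encoded residues):

1. position-wise feature transform  c_t = relu(W x_t + b)            (32 units)
2. BiLSTM over c, 256 units per direction, both directions' initial
   hidden and cell states a learned linear map of the organism-group
   flag (plant = 1, nonplant = 0); states concatenated to 512 dims
3. multi-attention  A = softmax(tanh(H W_a + b_a) V) with 13 heads of
   attention size 144; masked positions receive zero mass exactly
4. rows 0-3 of A are the cleavage-site position distributions for
   SP, mTP, cTP and luTP respectively (the identity is used as the
   read-out on those rows, so CS supervision shapes the attention)
5. context E = A H (13 x 512), flattened, summarised by a 256-unit
   dense layer and classified by a 5-way softmax over
   (noTP, SP, mTP, cTP, luTP)

Training minimises the average of two cross-entropies: the class CE over the
batch, and the CS CE of the true-class attention head over the records that
have a cleavage site.  Records without a targeting peptide contribute no CS
error; a batch of only such records yields the class loss alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import nn
from .nn import Tensor
from .nn import autograd as ag
from .sequence_io import CLASSES, CS_CLASSES, EncodedBatch

CHECKPOINT_FORMAT = "tpsort-checkpoint-1"


@dataclass
class ModelConfig:
    """Hyper-parameters of the network (defaults are the full-size model)."""

    feat_units: int = 32
    lstm_units: int = 256
    attn_units: int = 144
    n_attn: int = 13
    summary_units: int = 256
    n_classes: int = 5
    dropout: float = 0.25
    seed: int = 0
    max_len: int = 200

    def __post_init__(self) -> None:
        if self.n_attn < 4:
            raise ValueError("n_attn must be >= 4: the first four attention "
                             "heads are the SP/mTP/cTP/luTP CS predictors")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")


#: reduced configuration used for desk-scale experiments and the test-suite
REDUCED_CONFIG = ModelConfig(feat_units=16, lstm_units=64, attn_units=32, n_attn=8)


@dataclass
class Prediction:
    """Model output for one record (padding removed)."""

    id: str
    class_probs: np.ndarray          # (5,)
    cs_probs: np.ndarray             # (4, L) rows: SP, mTP, cTP, luTP
    attention: np.ndarray            # (n_attn, L)
    pred_class: str = field(init=False)
    pred_cs: Optional[int] = field(init=False)

    def __post_init__(self) -> None:
        # np.argmax breaks ties toward the lower index, the documented rule
        k = int(np.argmax(self.class_probs))
        self.pred_class = CLASSES[k]
        if self.pred_class == "noTP":
            self.pred_cs = None
        else:
            self.pred_cs = int(np.argmax(self.cs_probs[k - 1])) + 1


class TargetingModel:
    """BiLSTM / multi-attention network over encoded batches."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: Dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(config.seed))

    # ----------------------------------------------------------------- init
    def _param(self, name: str, shape, rng, kind: str = "glorot") -> Tensor:
        if kind == "zeros":
            data = np.zeros(shape, dtype=np.float32)
        else:
            fan_in, fan_out = (shape[0], shape[-1]) if len(shape) > 1 else (shape[0], shape[0])
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            data = rng.uniform(-limit, limit, size=shape).astype(np.float32)
        t = Tensor(data, requires_grad=True)
        self.params[name] = t
        return t

    def _init_params(self, rng) -> None:
        c = self.config
        F, Hu, Au, K = c.feat_units, c.lstm_units, c.attn_units, c.n_attn
        self._param("W_feat", (20, F), rng)
        self._param("b_feat", (F,), rng, "zeros")
        for d in ("fwd", "bwd"):
            self._param(f"Wx_{d}", (F, 4 * Hu), rng)
            self._param(f"Wh_{d}", (Hu, 4 * Hu), rng)
            b = self._param(f"b_{d}", (4 * Hu,), rng, "zeros")
            b.data[Hu:2 * Hu] = 1.0  # forget-gate bias init
            self._param(f"Wg_h_{d}", (1, Hu), rng)
            self._param(f"Wg_c_{d}", (1, Hu), rng)
            self._param(f"bg_h_{d}", (Hu,), rng, "zeros")
            self._param(f"bg_c_{d}", (Hu,), rng, "zeros")
        self._param("W_attn", (2 * Hu, Au), rng)
        self._param("b_attn", (Au,), rng, "zeros")
        self._param("V_attn", (Au, K), rng)
        self._param("W_sum", (K * 2 * Hu, c.summary_units), rng)
        self._param("b_sum", (c.summary_units,), rng, "zeros")
        self._param("W_out", (c.summary_units, c.n_classes), rng)
        self._param("b_out", (c.n_classes,), rng, "zeros")

    # -------------------------------------------------------------- layers
    def feature_transform(self, x: Tensor, drop_rng=None) -> Tensor:
        """Position-wise dense transform of the BLOSUM62 rows (Eq-1 layer)."""
        c = ag.relu(ag.add(ag.matmul(x, self.params["W_feat"]), self.params["b_feat"]))
        if drop_rng is not None:
            c = ag.dropout(c, self.config.dropout, drop_rng)
        return c

    def _initial_state(self, group: Tensor, d: str) -> Tuple[Tensor, Tensor]:
        h0 = ag.add(ag.matmul(group, self.params[f"Wg_h_{d}"]), self.params[f"bg_h_{d}"])
        c0 = ag.add(ag.matmul(group, self.params[f"Wg_c_{d}"]), self.params[f"bg_c_{d}"])
        return h0, c0

    def bilstm_encode(self, c: Tensor, group: Tensor, lengths: np.ndarray,
                      drop_rng=None) -> Tensor:
        """Concatenated forward/backward LSTM states, (B, L, 2*lstm_units).

        The backward direction runs over each record's valid residues only
        (the padded suffix is left in place and is masked downstream).
        """
        T = c.shape[1]
        h0f, c0f = self._initial_state(group, "fwd")
        Hf = ag.lstm(c, self.params["Wx_fwd"], self.params["Wh_fwd"],
                     self.params["b_fwd"], h0f, c0f)
        perm = ag.reverse_perm(lengths, T)
        h0b, c0b = self._initial_state(group, "bwd")
        Hb_rev = ag.lstm(ag.permute_time(c, perm), self.params["Wx_bwd"],
                         self.params["Wh_bwd"], self.params["b_bwd"], h0b, c0b)
        Hb = ag.permute_time(Hb_rev, perm)
        H = ag.concat([Hf, Hb], axis=2)
        if drop_rng is not None:
            H = ag.dropout(H, self.config.dropout, drop_rng)
        return H

    def multi_attention(self, H: Tensor, mask: np.ndarray) -> Tuple[Tensor, Tensor]:
        """Attention log-probabilities and probabilities, both (B, n_attn, L)."""
        if not mask.any(axis=1).all():
            raise ValueError("multi_attention: a record has no valid positions")
        scores = ag.matmul(ag.tanh(ag.add(ag.matmul(H, self.params["W_attn"]),
                                          self.params["b_attn"])),
                           self.params["V_attn"])          # (B, L, K)
        scores = ag.swapaxes(scores, 1, 2)                 # (B, K, L)
        logA = ag.masked_log_softmax(scores, mask[:, None, :])
        return logA, ag.exp(logA)

    @staticmethod
    def predict_cs(A: np.ndarray) -> np.ndarray:
        """CS position distributions: rows 0-3 of the attention matrix
        (order SP, mTP, cTP, luTP); the read-out on these rows is the
        identity."""
        return A[..., 0:4, :]

    @staticmethod
    def encode_context(A: Tensor, H: Tensor) -> Tensor:
        """e_k = sum_t A[k, t] h_t — one context vector per attention head."""
        return ag.matmul(A, H)  # (B, K, 2H)

    def predict_type(self, e: Tensor, drop_rng=None) -> Tensor:
        """Class log-probabilities from the flattened context matrix."""
        B = e.shape[0]
        flat = ag.reshape(e, (B, -1))
        s = ag.relu(ag.add(ag.matmul(flat, self.params["W_sum"]), self.params["b_sum"]))
        if drop_rng is not None:
            s = ag.dropout(s, self.config.dropout, drop_rng)
        logits = ag.add(ag.matmul(s, self.params["W_out"]), self.params["b_out"])
        return ag.masked_log_softmax(logits, np.ones(logits.shape, dtype=bool))

    # ------------------------------------------------------------- forward
    def forward_graph(self, batch: EncodedBatch, drop_rng=None):
        """Build the full graph; returns (log-class-probs, log-attention,
        attention)."""
        x = Tensor(batch.features)
        group = Tensor(batch.group_vec)
        c = self.feature_transform(x, drop_rng)
        H = self.bilstm_encode(c, group, batch.lengths, drop_rng)
        logA, A = self.multi_attention(H, batch.mask)
        e = self.encode_context(A, H)
        logC = self.predict_type(e, drop_rng)
        return logC, logA, A

    def forward(self, batch: EncodedBatch) -> List[Prediction]:
        """Inference (no dropout); one Prediction per record, order kept."""
        logC, _, A = self.forward_graph(batch)
        probs = np.exp(logC.data)
        out = []
        for i, rid in enumerate(batch.ids):
            n = int(batch.lengths[i])
            att = A.data[i, :, :n]
            out.append(Prediction(id=rid, class_probs=probs[i],
                                  cs_probs=self.predict_cs(att), attention=att))
        return out

    # ---------------------------------------------------------------- loss
    def loss_graph(self, batch: EncodedBatch, drop_rng=None) -> Tensor:
        """Average of class CE and (true-class head) CS CE.

        Only the attention head matching a record's true class is supervised
        on its cleavage site; noTP records contribute no CS term.
        """
        if batch.class_targets is None:
            raise ValueError("loss requires class targets")
        logC, logA, _ = self.forward_graph(batch, drop_rng)
        class_idx = [(i, int(t)) for i, t in enumerate(batch.class_targets)]
        class_ce = ag.pick_mean_negative(logC, class_idx)
        cs_idx = []
        for i, t in enumerate(batch.cs_targets):
            if t < 0:
                continue
            if t >= batch.lengths[i]:
                raise ValueError(f"cs target {t} >= length {batch.lengths[i]}")
            head = int(batch.class_targets[i]) - 1  # class 1..4 -> head 0..3
            cs_idx.append((i, head, int(t)))
        if not cs_idx:
            return class_ce
        cs_ce = ag.pick_mean_negative(logA, cs_idx)
        return ag.mul(ag.add(class_ce, cs_ce), 0.5)

    def loss(self, batch: EncodedBatch) -> float:
        return float(self.loss_graph(batch).data)

    # ---------------------------------------------------------- parameters
    def get_state(self) -> Dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def set_state(self, state: Dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = state[k].astype(np.float32).copy()

    def save(self, path) -> None:
        meta = json.dumps({"format": CHECKPOINT_FORMAT, "config": asdict(self.config)})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **{k: p.data for k, p in self.params.items()})

    @classmethod
    def load(cls, path) -> "TargetingModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(f"unsupported checkpoint format: {meta.get('format')}")
            model = cls(ModelConfig(**meta["config"]))
            model.set_state({k: z[k] for k in z.files if k != "__meta__"})
        return model
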