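"""Architecture contracts of the joint classification / cleavage-site network."""

import numpy as np
import pytest

from tpsort import synthetic
from tpsort.model import ModelConfig, Prediction, TargetingModel
from tpsort.nn import autograd as ag
from tpsort.sequence_io import CLASSES, ProteinRecord, encode_batch


def small_batch(seed=5, **kw):
    spec = synthetic.SyntheticSpec(
        n_per_class=kw.pop("n_per_class",
                           {"noTP": 3, "SP": 3, "mTP": 2, "cTP": 2, "luTP": 2}),
        seed=seed, mature_len_range=(10, 20), notp_len_range=(20, 60), **kw)
    return encode_batch(synthetic.generate(spec))


@pytest.fixture(scope="module")
def tiny_model():
    return TargetingModel(ModelConfig(feat_units=8, lstm_units=16, attn_units=8,
                                      n_attn=5, dropout=0.0, seed=3))


class TestDefaultArchitectureShapes:
    """The published layer sizes: 32 feature units, 256 LSTM units per
    direction (512 concatenated), 13 attention heads, 512x13 context."""

    def test_layer_shapes(self):
        full_model = TargetingModel(ModelConfig(dropout=0.0, seed=0))
        batch = small_batch()
        c = full_model.feature_transform(ag.Tensor(batch.features))
        assert c.shape[-1] == 32
        H = full_model.bilstm_encode(c, ag.Tensor(batch.group_vec), batch.lengths)
        assert H.shape[-1] == 512
        _, A = full_model.multi_attention(H, batch.mask)
        assert A.shape[1] == 13
        e = full_model.encode_context(A, H)
        assert e.shape[1:] == (13, 512)
        logC = full_model.predict_type(e)
        assert logC.shape[-1] == 5

    def test_at_least_four_attention_heads_required(self):
        with pytest.raises(ValueError, match="n_attn"):
            ModelConfig(n_attn=3)


class TestForward:
    def test_probability_normalisation(self, tiny_model):
        batch = small_batch()
        preds = tiny_model.forward(batch)
        assert len(preds) == len(batch)
        for p in preds:
            assert abs(p.class_probs.sum() - 1.0) < 1e-6
            np.testing.assert_allclose(p.attention.sum(axis=1), 1.0, atol=1e-6)
            np.testing.assert_allclose(p.cs_probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_mass_on_padding(self, tiny_model):
        batch = small_batch()
        _, logA, A = tiny_model.forward_graph(batch)
        pad = ~batch.mask[:, None, :]
        assert (A.data[np.broadcast_to(pad, A.shape)] == 0.0).all()

    def test_cs_probs_are_first_four_attention_rows(self, tiny_model):
        batch = small_batch()
        for p in tiny_model.forward(batch):
            np.testing.assert_array_equal(p.cs_probs, p.attention[0:4])

    def test_notp_prediction_has_no_cs(self, tiny_model):
        batch = small_batch()
        for p in tiny_model.forward(batch):
            if p.pred_class == "noTP":
                assert p.pred_cs is None
            else:
                k = CLASSES.index(p.pred_class)
                assert p.pred_cs == int(np.argmax(p.cs_probs[k - 1])) + 1

    def test_determinism(self, tiny_model):
        batch = small_batch()
        p1 = tiny_model.forward(batch)
        p2 = tiny_model.forward(batch)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.class_probs, b.class_probs)
            np.testing.assert_array_equal(a.attention, b.attention)

    def test_same_seed_same_parameters(self):
        cfg = ModelConfig(feat_units=8, lstm_units=16, attn_units=8, n_attn=5, seed=9)
        m1, m2 = TargetingModel(cfg), TargetingModel(cfg)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k].data, m2.params[k].data)

    def test_group_flag_changes_output(self, tiny_model):
        r = ProteinRecord(id="x", sequence="MAGKLLYSTVIW" * 4)
        b_plant = encode_batch([ProteinRecord(id="x", sequence=r.sequence,
                                              group="plant")])
        b_non = encode_batch([r])
        p1 = tiny_model.forward(b_plant)[0]
        p2 = tiny_model.forward(b_non)[0]
        assert not np.allclose(p1.class_probs, p2.class_probs)

    def test_padding_invariance(self, tiny_model):
        """Class probabilities do not depend on how much padding a batch has."""
        seq = "MKRLLAVLAVAASAQA" + "GKTEW" * 10
        r = ProteinRecord(id="x", sequence=seq)
        alone = tiny_model.forward(encode_batch([r]))[0]
        long_mate = ProteinRecord(id="pad", sequence="M" + "A" * 199)
        padded = tiny_model.forward(encode_batch([r, long_mate]))[0]
        np.testing.assert_allclose(alone.class_probs, padded.class_probs, atol=1e-5)
        np.testing.assert_allclose(alone.attention,
                                   padded.attention[:, :len(seq)], atol=1e-5)

    def test_length_one_sequence(self, tiny_model):
        p = tiny_model.forward(encode_batch([ProteinRecord(id="m", sequence="M")]))[0]
        np.testing.assert_allclose(p.attention, 1.0, atol=1e-6)


class TestLoss:
    def test_loss_matches_independent_cross_entropy(self, tiny_model):
        """Hand-computed CE (log-sum-exp free, via normalised probabilities)
        on a small labelled batch."""
        batch = small_batch(seed=8)
        logC, logA, A = tiny_model.forward_graph(batch)
        probs = np.exp(np.asarray(logC.data, dtype=np.float64))
        class_ce = -np.mean([np.log(probs[i, t])
                             for i, t in enumerate(batch.class_targets)])
        cs_terms = [
            -np.log(np.asarray(A.data, dtype=np.float64)[i, t - 1, c])
            for i, (t, c) in enumerate(zip(batch.class_targets, batch.cs_targets))
            if c >= 0
        ]
        expected = 0.5 * (class_ce + np.mean(cs_terms))
        assert abs(tiny_model.loss(batch) - expected) < 1e-4

    def test_all_notp_batch_gives_class_loss_alone(self, tiny_model):
        batch = small_batch(seed=9, n_per_class={"noTP": 6})
        logC, _, _ = tiny_model.forward_graph(batch)
        class_ce = -np.mean([logC.data[i, 0] for i in range(len(batch))])
        assert abs(tiny_model.loss(batch) - class_ce) < 1e-6

    def test_no_cs_gradient_from_all_notp_batch(self, tiny_model):
        """Without cleavage sites there is no CS error to back-propagate:
        the loss gradients equal those of the classification term alone."""
        batch = small_batch(seed=9, n_per_class={"noTP": 6})
        loss = tiny_model.loss_graph(batch)
        loss.backward()
        grads_total = {k: p.grad.copy() for k, p in tiny_model.params.items()}
        logC, _, _ = tiny_model.forward_graph(batch)
        class_only = ag.pick_mean_negative(
            logC, [(i, 0) for i in range(len(batch))])
        class_only.backward()
        for k, p in tiny_model.params.items():
            np.testing.assert_array_equal(grads_total[k], p.grad)

    def test_cs_target_beyond_length_raises(self, tiny_model):
        batch = small_batch(seed=8)
        batch.cs_targets = batch.cs_targets.copy()
        pos = np.argmax(batch.cs_targets >= 0)
        batch.cs_targets[pos] = int(batch.lengths[pos]) + 5
        with pytest.raises(ValueError):
            tiny_model.loss(batch)


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        loaded = TargetingModel.load(path)
        assert loaded.config == tiny_model.config
        batch = small_batch()
        p1 = tiny_model.forward(batch)
        p2 = loaded.forward(batch)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.class_probs, b.class_probs)


def test_prediction_tie_break_lowest_index():
    probs = np.array([0.3, 0.3, 0.2, 0.1, 0.1])
    cs = np.full((4, 6), 1 / 6)
    p = Prediction(id="t", class_probs=probs, cs_probs=cs, attention=np.vstack([cs, cs[:1]]))
    assert p.pred_class == "noTP"  # index 0 wins the 0.3 tie
    probs2 = np.array([0.1, 0.3, 0.3, 0.2, 0.1])
    p2 = Prediction(id="t", class_probs=probs2, cs_probs=cs,
                    attention=np.vstack([cs, cs[:1]]))
    assert p2.pred_class == "SP" and p2.pred_cs == 1  # uniform cs row: pos 1
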