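"""Shared fixtures.

The expensive fixture is ``trained_synthetic``: the end-to-end training run
on the default synthetic study conditions (2,500 training and 500 test
records, class mix 50/20/15/10/5% over noTP/SP/mTP/cTP/luTP, reduced model,
at most 15 epochs).  It is session-scoped and shared by the evaluation and
interpretation checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from tpsort import synthetic
from tpsort.model import ModelConfig
from tpsort.training import OptimiserSettings, predict_records, train_model

CLASS_MIX = {"noTP": 0.50, "SP": 0.20, "mTP": 0.15, "cTP": 0.10, "luTP": 0.05}


def class_counts(n_total: int) -> dict:
    return {cls: int(round(n_total * frac)) for cls, frac in CLASS_MIX.items()}


def make_dataset(n_total: int, seed: int):
    return synthetic.generate(
        synthetic.SyntheticSpec(n_per_class=class_counts(n_total), seed=seed))


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(feat_units=8, lstm_units=16, attn_units=8, n_attn=5,
                       dropout=0.0, seed=0)


@pytest.fixture(scope="session")
def reduced_config():
    return ModelConfig(feat_units=16, lstm_units=64, attn_units=32, n_attn=8, seed=1)


@pytest.fixture()
def small_records():
    return make_dataset(60, seed=42)


@dataclass
class TrainedRun:
    model: object
    train_records: list
    test_records: list
    predictions: dict  # id -> Prediction on the test set


@pytest.fixture(scope="session")
def trained_synthetic(reduced_config) -> TrainedRun:
    train = make_dataset(2500, seed=1)
    test = make_dataset(500, seed=2)
    model, _ = train_model(train, None, reduced_config,
                           OptimiserSettings(max_epochs=15, seed=1))
    preds = {p.id: p for p in predict_records(model, test)}
    return TrainedRun(model=model, train_records=train, test_records=test,
                      predictions=preds)
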