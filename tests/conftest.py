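"""Shared fixtures: tiny architectures, synthetic datasets and window
factories used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import rtafnet as rt
from rtafnet.nn.model import ModelConfig
from rtafnet.preprocess import WINDOW_SAMPLES, Window

_ZEROS = np.zeros(WINDOW_SAMPLES)


def make_window(label="AF", fine=None, samples=None, record_id="rec0",
                start=0.0, augmented=False):
    """Cheap Window factory; defaults to an all-zero sample vector."""
    if fine is None:
        fine = "AF" if label == "AF" else "N"
    return Window(
        samples=_ZEROS if samples is None else samples,
        label=label, fine_rhythm=fine, record_id=record_id,
        start_time=start, is_augmented=augmented,
    )


@pytest.fixture(scope="session")
def tiny_model_config():
    """Minimal architecture for gradient checks and wiring tests."""
    return ModelConfig(
        stem_kernel=7, stem_stride=2, stem_channels=4,
        stages=((1, 4, 2), (1, 8, 2)),
        attention_stages=frozenset({2}), block_kernel=3,
        block_attention_heads=2,
        d_model=8, encoder_layers=1, num_heads=2, ffn_dim=16,
        dropout=0.0, classifier_hidden=6, input_length=32,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Six 2-minute records per class (NSR, AF), windowed and filtered."""
    specs = {k: v for k, v in rt.default_rhythm_specs().items() if k != "AFL"}
    records = rt.generate_dataset(6, specs, rt.SynthConfig(duration=120.0, seed=7))
    return records


@pytest.fixture(scope="session")
def small_windows(small_dataset):
    return rt.records_to_windows(small_dataset)


@pytest.fixture(scope="session")
def small_splits(small_windows):
    return rt.split_dataset(small_windows, level="record", seed=1)
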