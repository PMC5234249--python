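"""Shared fixtures: seeded synthetic datasets and trained classifiers.

Everything is generated programmatically; session scope keeps the cost of
LM training amortized across the suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hybridbci import classifier as clf
from hybridbci import controller as ctl
from hybridbci import dsp, synth

MENTAL_TASKS = (synth.TaskLabel.ARITHMETIC, synth.TaskLabel.ROTATION,
                synth.TaskLabel.LETTER)
SSVEP_TASKS = (synth.TaskLabel.SSVEP_6, synth.TaskLabel.SSVEP_13,
               synth.TaskLabel.SSVEP_16)


def make_feature_frame(tasks, n_sessions=6, base_seed=100, **synth_overrides):
    """37 windows x n_sessions per task, extracted with the 13 s / drop 3 s
    protocol; a ``session`` column supports session-blocked splitting."""
    frames = []
    for task in tasks:
        for s in range(n_sessions):
            cfg = synth.SynthConfig(seed=base_seed + s, **synth_overrides)
            rec = synth.generate_session(task, cfg)
            df = dsp.extract_features(rec, analysis_span=10.0, start=3.0)
            df.insert(0, "session", s)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def train_on_frame(df, seed=0, m=8, max_epochs=30):
    ds = clf.LabelledDataset.from_frame(df)
    tr, va, te = clf.split_dataset(ds, seed=seed,
                                   sessions=df["session"].to_numpy())
    model, hist = clf.train_lm(tr, va,
                               clf.TrainingConfig(seed=seed, max_epochs=max_epochs),
                               m=m)
    return model, hist, (tr, va, te)


@pytest.fixture(scope="session")
def mental_frame():
    return make_feature_frame(MENTAL_TASKS)


@pytest.fixture(scope="session")
def mental_model(mental_frame):
    model, hist, splits = train_on_frame(mental_frame)
    return model, hist, splits


@pytest.fixture(scope="session")
def ssvep_model():
    df = make_feature_frame(SSVEP_TASKS)
    model, hist, splits = train_on_frame(df)
    return model, hist, splits


@pytest.fixture(scope="session")
def eyes_model():
    df = make_feature_frame((synth.TaskLabel.BASELINE, synth.TaskLabel.EYES_CLOSED))
    model, hist, splits = train_on_frame(df, m=4)
    return model, hist, splits


@pytest.fixture(scope="session")
def calibrated_threshold():
    cfg = synth.SynthConfig(seed=1)
    baseline = synth.generate_session(synth.TaskLabel.BASELINE, cfg)
    closed = synth.generate_session(synth.TaskLabel.EYES_CLOSED, cfg)
    return ctl.calibrate_threshold(baseline, closed)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
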