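import numpy as np
import pandas as pd
import pytest

import riskcast as rc
from riskcast import preprocess


@pytest.fixture(scope="session")
def tiny_population():
    """A small deterministic population with planted coupling, shared by
    tests that only need *some* realistic records."""
    cfg = rc.signal_preset(2.0, n_subjects=4, n_days=200, seed=123)
    records, truth = rc.sample_population(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def tiny_matrices(tiny_population):
    _, records, truth = tiny_population
    top7 = rc.select_top_behaviors(records)
    mats = rc.build_daily_matrices(
        records, top7, truth.start_date, truth.n_days, truth.subject_ids
    )
    return mats, top7, truth


#: Channel layout of the planted-signal fixture; the trigger sits last.
TOY_CHANNELS = [
    "Agitation", "Impulsive Behavior", "Task Refusal", "Aggression",
    "Elopement", "Self-Injurious Behavior", "Disruptive Behavior",
]
TOY_TRIGGER_IDX = TOY_CHANNELS.index("Disruptive Behavior")


@pytest.fixture(scope="session")
def trained_toy_predictor():
    """One subject with a single planted coupling (disruptive behavior bouts
    drive next-day aggression), model trained on that subject's windows.
    The target's baseline is centered so the planted effect crosses the
    decision threshold and the model learns rather than memorizes.  Used by
    attribution and prediction-contract tests."""
    channels = rc.DEFAULT_CHANNELS
    c = len(channels)
    src = channels.index("Disruptive Behavior")
    dst = channels.index("Aggression")
    w = np.zeros((c, 3, c))
    w[src, :, dst] = 2.0
    w[src, 0, src] = 1.0
    means = {ch: -2.3 for ch in channels}
    means["Agitation"] = -0.3
    means["Disruptive Behavior"] = -1.2
    means["Aggression"] = -2.0
    cfg = rc.GeneratorConfig(
        n_subjects=1, n_days=1200, coupling=w, seed=31,
        baseline_logit_mean=[means[ch] for ch in channels],
        baseline_logit_sd=0.3,
    )
    records, truth = rc.sample_population(cfg)
    matrix = preprocess.aggregate_daily(
        records, TOY_CHANNELS, truth.start_date, truth.n_days, truth.subject_ids[0]
    )
    samples = preprocess.make_windows(matrix, 7, "Aggression")
    split = preprocess.temporal_split(samples)
    x_train, y_train = preprocess.samples_to_arrays(split.train)
    x_test, y_test = preprocess.samples_to_arrays(split.test)
    predictor = rc.build_model((7, 8), seed=3, epochs=30)
    rc.train(predictor, (x_train, y_train), seed=3)
    return predictor, x_test, y_test


def make_records(rows):
    """Episode table from (subject, date, shift, behavior, severe) tuples."""
    return pd.DataFrame(
        rows, columns=["subject_id", "date", "shift", "behavior", "severe"]
    )
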