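import numpy as np
import pandas as pd
import pytest

from skillcontext import behavior as bh
from skillcontext import synthetic as syn


def make_events(keys, trial=1, dt=0.25, t0=0.0):
    """Event frame from a key list with uniform transition times."""
    keys = list(keys)
    return pd.DataFrame(
        {
            "onset": t0 + dt * np.arange(len(keys)),
            "key": keys,
            "trial": trial,
        }
    )


def brute_force_label(keys, sequence):
    """Independent oracle: keypress i is correct iff some 5-window containing
    it equals some circular shift of the sequence (pure-python enumeration)."""
    n = len(sequence)
    shifts = [tuple(sequence[(s + j) % n] for j in range(n)) for s in range(n)]
    correct = [False] * len(keys)
    for start in range(len(keys) - n + 1):
        if tuple(keys[start : start + n]) in shifts:
            for j in range(start, start + n):
                correct[j] = True
    return correct


@pytest.fixture(scope="session")
def small_subject():
    """Full synthetic subject at desk scale (shared, read-only)."""
    bp = syn.BehaviorParams(n_trials=10, ktt_jitter_cv=0.05, error_rate=0.02, seed=11)
    np_ = syn.NeuralParams(
        n_voxels=120, n_parcels=12, noise_sigma=2.0, delta_ramp_trials=10, seed=11
    )
    return syn.generate_subject(bp, np_), bp, np_


@pytest.fixture(scope="session")
def clean_labeled_stream():
    """Error-free, jitter-free labeled stream with exact planted speeds."""
    bp = syn.BehaviorParams(ktt_jitter_cv=0.0, error_rate=0.0, seed=5)
    events, gt = syn.generate_behavior(bp)
    labeled = bh.sequence_iterations(bh.label_correct(events))
    return labeled, gt, bp
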