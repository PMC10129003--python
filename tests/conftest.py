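import numpy as np
import pytest

from odormix import AnalysisConfig, GeneratorConfig, generate_session
from odormix.core import EPOCH_WINDOW, SpikeTrainRecord
from odormix.synth import (
    NeuronSpec,
    TRIAL_PERIOD,
    rate_profile,
    sample_spikes,
)


@pytest.fixture
def fast_config():
    """Default analysis parameters with a reduced shuffle count for tests."""
    return AnalysisConfig(n_shuffles=200)


@pytest.fixture
def small_session():
    """A small but complete synthetic session with ground truth."""
    g = GeneratorConfig(n_trials=80, n_neurons=8, rng_seed=0)
    return generate_session(g, day_index=0, seed=0)


def make_planted_session(spec: NeuronSpec, seed: int, n_trials: int = 150):
    """One-neuron session whose spike train realizes *spec* exactly.

    Behavior and trial structure come from the standard generator; the single
    neuron is regenerated from the requested archetype so tests control its
    parameters precisely.
    """
    g = GeneratorConfig(n_trials=n_trials, n_neurons=1, selective_fraction=0.0)
    session, _ = generate_session(g, seed=seed)
    rng = np.random.default_rng(seed + 10_000)
    lo, hi = EPOCH_WINDOW
    times = []
    n = len(session.trials)
    for j, trial in enumerate(session.trials):
        profile = rate_profile(spec, trial)
        tile = (lo, hi if j == n - 1 else lo + TRIAL_PERIOD)
        times.append(sample_spikes(profile, tile, rng) + trial.odor_on_time)
    session.spikes = {
        "n000": SpikeTrainRecord("n000", np.sort(np.concatenate(times)))
    }
    return session
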