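"""Shared fixtures: one session-scoped synthetic corpus with its features."""

import numpy as np
import pandas as pd
import pytest

from vocaffect import acoustics, synthcorpus

CORPUS_SEED = 11
CORPUS_SR = 22050


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Full replicate-design corpus (155 WAVs) at a light sample rate."""
    out = tmp_path_factory.mktemp("corpus")
    stimuli = synthcorpus.generate_corpus(
        synthcorpus.paper_config(sample_rate=CORPUS_SR), CORPUS_SEED, out)
    return stimuli, out


@pytest.fixture(scope="session")
def corpus_features(corpus):
    """The 15 extracted acoustic parameters for every corpus stimulus."""
    stimuli, out = corpus
    return acoustics.extract_features_table(stimuli, out)


@pytest.fixture(scope="session")
def stimuli_meta():
    """Corpus metadata table without any audio (for listener simulations)."""
    rows, i = [], 0
    for p in synthcorpus.PAPER_CONTEXTS:
        for j in range(p.n_stimuli):
            i += 1
            rows.append({
                "stimulus_id": f"s{i:03d}",
                "caller_id": f"ch{(j % p.caller_pool) + 1:02d}",
                "context_id": p.context_id,
                "arousal": p.arousal_class,
                "valence": p.valence_class,
            })
    return pd.DataFrame(rows)


def tone(f0=300.0, duration=1.0, sr=44100, amplitude=1.0):
    t = np.arange(int(duration * sr)) / sr
    return amplitude * np.sin(2 * np.pi * f0 * t)
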