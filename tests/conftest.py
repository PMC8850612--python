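import numpy as np
import pandas as pd
import pytest

from neuroscore import (
    CVScheme,
    StimulusSet,
    canonical_embeddings,
    make_stimuli,
)


@pytest.fixture(scope="session")
def stimuli():
    """A 25-sentence stream: 5 blocks of 5, enough for 5-fold CV."""
    return make_stimuli(n_sentences=25, n_subjects=4, seed=7)


@pytest.fixture(scope="session")
def small_stimuli():
    """Short sentences for fast scoring loops."""
    return make_stimuli(
        n_sentences=25, words_per_sentence=(4, 6), n_subjects=3, seed=7
    )


@pytest.fixture(scope="session")
def embeddings(stimuli):
    return canonical_embeddings(stimuli, dim=8, seed=7)


@pytest.fixture(scope="session")
def cv():
    return CVScheme(n_folds=5, seed=7)


@pytest.fixture
def toy_words():
    """Two 5-word sentences in one block, hand-built timing."""
    rows = []
    t = 0.0
    wid = 0
    for s, words in enumerate(
        [["the", "cat", "is", "on", "mats"],
         ["dogs", "bark", "at", "the", "moon"]]
    ):
        for w in words:
            rows.append(dict(
                word_id=wid, token=w, onset=round(t, 3), duration=0.351,
                sentence_id=s, block_id=0, run_id=0, subject_ids="0,1",
            ))
            wid += 1
            t += 0.651
        t += 5.0
    return pd.DataFrame(rows)


@pytest.fixture
def toy_stimuli(toy_words):
    return StimulusSet(toy_words)


def assert_within_se(value, se, k=3, target=0.0):
    assert abs(value - target) <= k * se, (
        f"{value} deviates from {target} by more than {k}×SE ({se})"
    )
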