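import numpy as np
import pytest

from fatiguekit.stacking import corpus_to_arrays
from fatiguekit.synthetic import gen_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """40 synthetic clips with extracted facial/voice arrays."""
    clips, manifest = gen_corpus(40, class_balance=0.5, seed=11)
    facial, voice, labels, ids = corpus_to_arrays(clips)
    return {
        "clips": clips,
        "manifest": manifest,
        "facial": facial,
        "voice": voice,
        "labels": labels,
        "ids": ids,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
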