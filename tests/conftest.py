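"""Shared synthetic fixtures: a compact stimulus set with feature spaces,
tuned channels, and a fast response matrix, reused across test modules."""

import numpy as np
import pytest

import neurorsa as nr
from neurorsa.rdm import feature_rdm
from neurorsa.signal import ResponseMatrix


@pytest.fixture(scope="session")
def stimuli_and_spaces():
    stimuli0 = nr.make_stimulus_set(12, 5, seed=101)
    spaces, stimuli = nr.make_feature_spaces(
        stimuli0, dims=(16, 16, 8), cross_corr=(0.0, 0.0, 0.0), seed=102)
    return stimuli, spaces


@pytest.fixture(scope="session")
def stimuli(stimuli_and_spaces):
    return stimuli_and_spaces[0]


@pytest.fixture(scope="session")
def spaces(stimuli_and_spaces):
    return stimuli_and_spaces[1]


@pytest.fixture(scope="session")
def feature_rdms(spaces):
    return {a: feature_rdm(spaces[a]) for a in nr.ATTRIBUTES}


@pytest.fixture(scope="session")
def ground_truth(spaces):
    roster = [("VTC", "visual", 2.0, 3), ("MTL", "semantic", 2.0, 3),
              ("PFC", "memorability", 2.0, 3), ("STG", "none", 0.0, 3)]
    return nr.make_ground_truth(spaces, roster, seed=103)


@pytest.fixture(scope="session")
def response_matrix(stimuli, spaces, ground_truth):
    df = nr.make_response_matrix(stimuli, spaces, ground_truth, seed=104)
    return ResponseMatrix.from_frame(df)


@pytest.fixture(scope="session")
def small_recording(stimuli, spaces, ground_truth):
    rec = nr.make_recording(stimuli, spaces, ground_truth[:6], fs=1000.0,
                            seed=105)
    return rec
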