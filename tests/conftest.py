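import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from insolegait import (GaitEventSet, GaitProfile, analytic_reference_model,
                        detect_heel_strikes, detect_toe_offs, generate_recording,
                        segment_cycles)


@pytest.fixture(scope="session")
def model_15_10():
    """Analytic reference model with L = 1.5 m, T = 1.0 s."""
    return analytic_reference_model(1.5, 1.0)


@pytest.fixture(scope="session")
def clean_walk():
    """Noise-free 20-stride recording (L = 1.62 m, T = 1.0 s) with truth."""
    profile = GaitProfile.constant(20, stride_length=1.62, period=1.0, seed=11)
    recording, truth = generate_recording(profile)
    return recording, truth


@pytest.fixture(scope="session")
def clean_cycles(clean_walk):
    recording, _ = clean_walk
    toe_offs = detect_toe_offs(recording)
    heel_strikes = detect_heel_strikes(recording, toe_offs)
    return segment_cycles(recording, GaitEventSet(toe_offs, heel_strikes))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
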