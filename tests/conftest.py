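"""Shared fixtures: small synthetic recordings reused across test modules."""
from __future__ import annotations

import warnings

import numpy as np
import pytest

from scalphfo.montage import MONTAGE_ELECTRODES
from scalphfo.simulate import SimConfig, generate_background
from scalphfo.types import DataInterval, Recording

# induced sub-montage of 10 electrodes (10 bipolar pairs); keeps multi-channel
# detector tests fast while exercising homologue symmetry
SUBSET = ("Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2")

warnings.filterwarnings("ignore", message="only .* analysis interval")


@pytest.fixture(scope="session")
def fs() -> float:
    return 1024.0


@pytest.fixture(scope="session")
def background_60s() -> Recording:
    """60 s, full 19-electrode background at the default 1.5 uV band RMS."""
    return generate_background(SimConfig(duration_s=60.0, seed=5))


@pytest.fixture(scope="session")
def background_subset_60s() -> Recording:
    """60 s background restricted to the 10-electrode test subset."""
    return generate_background(SimConfig(labels=SUBSET, duration_s=60.0, seed=5))


@pytest.fixture(scope="session")
def interval_60s() -> list[DataInterval]:
    return [DataInterval(0.0, 60.0, stage="N3", index=0)]


@pytest.fixture(scope="session")
def silent_recording(fs) -> Recording:
    return Recording(
        np.zeros((len(MONTAGE_ELECTRODES), int(20 * fs))),
        fs,
        list(MONTAGE_ELECTRODES),
    )
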