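import numpy as np
import pytest

from motifnet.data import encode_sequences
from motifnet.motifs import PWM, MotifLibrary


def one_hot(seq: str) -> np.ndarray:
    """(4, L) one-hot array for a single sequence."""
    return encode_sequences({"s": seq}, L=len(seq)).onehot[0]


@pytest.fixture
def degenerate_library() -> MotifLibrary:
    """Three hard consensus motifs (rows are unit vectors)."""
    eye = np.eye(4)
    return MotifLibrary(
        [
            PWM("ACT", eye[[0, 1, 3]]),
            PWM("GGA", eye[[2, 2, 0]]),
            PWM("TAC", eye[[3, 0, 1]]),
        ]
    )


@pytest.fixture
def soft_library() -> MotifLibrary:
    """Two graded PWMs used where degenerate scores would hide bugs."""
    return MotifLibrary(
        [
            PWM("soft1", np.array([[0.7, 0.1, 0.1, 0.1],
                                   [0.1, 0.6, 0.2, 0.1],
                                   [0.25, 0.25, 0.25, 0.25]])),
            PWM("soft2", np.array([[0.4, 0.3, 0.2, 0.1],
                                   [0.1, 0.1, 0.2, 0.6]])),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
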