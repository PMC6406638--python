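import numpy as np
import pytest

from ntenet.channels import N_CHANNELS
from ntenet.datasets import CouplingSpec, SubjectProfile, simulate_subject
from ntenet.recording import Annotation, MultichannelRecording

NODE_LABELS_14 = tuple(f"n{i}" for i in range(14))


def make_recording(n_seconds=12.0, fs=128.0, seed=0, annotations=None):
    """A plain random recording with one annotation per state by default."""
    rng = np.random.default_rng(seed)
    n = int(n_seconds * fs)
    samples = rng.normal(size=(N_CHANNELS, n))
    if annotations is None:
        third = n // 3
        annotations = [
            Annotation("rest", 0, third),
            Annotation("drawing", third, 2 * third),
            Annotation("manipulation", 2 * third, n),
        ]
    return MultichannelRecording(samples, fs, annotations)


def random_digraph(n=14, p=0.3, seed=0, labels=None):
    from ntenet.graphs import BinaryDigraph

    rng = np.random.default_rng(seed)
    a = rng.random((n, n)) < p
    np.fill_diagonal(a, False)
    return BinaryDigraph(a, labels or tuple(f"n{i}" for i in range(n)))


@pytest.fixture(scope="session")
def novice_profile():
    return SubjectProfile(
        "S01", "novice",
        {"rest": 20.0, "drawing": 20.0, "manipulation": 20.0},
        {"rest": 0.35, "drawing": 0.7, "manipulation": 1.3},
        seed=42,
    )


@pytest.fixture(scope="session")
def single_pair_coupling():
    g = np.zeros((N_CHANNELS, N_CHANNELS))
    g[1, 0] = 0.8  # channel 0 drives channel 1
    return CouplingSpec(g)


@pytest.fixture(scope="session")
def coupled_recording(novice_profile, single_pair_coupling):
    return simulate_subject(novice_profile, single_pair_coupling)
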