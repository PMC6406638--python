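"""Window-level feature extraction for novice/expert classification.

Each 20-s task window becomes one sample. Its NTE matrix is computed,
binarized at the standard 0.001 threshold, and summarized into a fixed
43-entry vector:

    [1]      connectivity density
    [2-14]   3-node motif class counts (canonical class order)
    [15-28]  per-electrode directed clustering coefficients
    [29]     characteristic path length
    [30-43]  per-electrode mean information flow (outgoing NTE)

Channel-indexed blocks follow the canonical channel order. An undefined
path length (no reachable pair) is encoded as 0 and flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import graphs
from .channels import CHANNELS, N_CHANNELS
from .connectivity import NTEMatrix, nte_matrix
from .flows import mean_information_flow
from .recording import EpochSet, MultichannelRecording

logger = logging.getLogger(__name__)

N_FEATURES = 43
WINDOW_SECONDS = 20.0
WINDOW_STEP_SECONDS = 1.0
TASK_STATES = ("drawing", "manipulation")

FEATURE_NAMES: tuple[str, ...] = (
    ("connectivity_density",)
    + tuple(f"motif_class_{i + 1}" for i in range(graphs.N_MOTIF_CLASSES))
    + tuple(f"clustering_{c}" for c in CHANNELS)
    + ("characteristic_path_length",)
    + tuple(f"mean_if_{c}" for c in CHANNELS)
)
assert len(FEATURE_NAMES) == N_FEATURES


@dataclass
class Window:
    """One labelled 20-s sample cut from a task state."""

    samples: np.ndarray  # (14, win_len)
    state: str
    start: int           # sample index in the source recording
    fs: float
    label: str = ""      # subject expertise
    subject_id: str = ""


def sliding_windows(
    rec: MultichannelRecording,
    states: tuple[str, ...] = TASK_STATES,
    win_seconds: float = WINDOW_SECONDS,
    step_seconds: float = WINDOW_STEP_SECONDS,
    label: str = "",
    subject_id: str = "",
) -> list[Window]:
    """Cut overlapping windows from every annotated span of the given
    states; windows start every ``step_seconds`` and never cross a state
    boundary. Spans shorter than one window contribute nothing."""
    win = int(round(win_seconds * rec.fs))
    step = int(round(step_seconds * rec.fs))
    out: list[Window] = []
    for state in states:
        try:
            spans = rec.spans(state)
        except KeyError:
            continue
        for span in spans:
            start = span.start
            while start + win <= span.stop:
                out.append(Window(rec.samples[:, start:start + win], state,
                                  start, rec.fs, label, subject_id))
                start += step
    if not out:
        warnings.warn("no span long enough for a single window",
                      stacklevel=2)
    return out


def features_from_nte(
    m: NTEMatrix, threshold: float = graphs.DEFAULT_THRESHOLD
) -> tuple[np.ndarray, bool]:
    """Assemble the 43-entry feature vector from one NTE matrix.

    Returns the vector and a flag that is True when the path length was
    undefined (encoded as 0 in entry 29).
    """
    g = graphs.binarize(m, threshold)
    vec = np.empty(N_FEATURES)
    vec[0] = graphs.connectivity_density(g)
    vec[1:14] = graphs.motif_census(g).counts
    vec[14:28] = graphs.clustering_coefficients(g)
    pl = graphs.characteristic_path_length(g)
    vec[28] = pl.value if pl.defined else 0.0
    vec[29:43] = mean_information_flow(m)
    return vec, not pl.defined


def extract_features(
    window: Window | np.ndarray,
    fs: float | None = None,
    B: int = 4,
    n_shuffles: int = 20,
    seed: int = 0,
    threshold: float = graphs.DEFAULT_THRESHOLD,
) -> np.ndarray:
    """NTE matrix of one window (treated as a single segment) -> features."""
    if isinstance(window, Window):
        samples, fs = window.samples, window.fs
    else:
        samples = np.asarray(window)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    es = EpochSet(samples[None, :, :], state="window", fs=fs)
    m = nte_matrix(es, B=B, n_shuffles=n_shuffles, seed=seed)
    vec, flagged = features_from_nte(m, threshold)
    if flagged:
        logger.debug("window at fs=%g: undefined path length encoded as 0",
                     fs)
    return vec


class WindowFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping a list of :class:`Window` to the (n, 43)
    feature matrix. Stateless; ``fit`` records feature names only."""

    def __init__(self, B: int = 4, n_shuffles: int = 20, seed: int = 0,
                 threshold: float = graphs.DEFAULT_THRESHOLD):
        self.B = B
        self.n_shuffles = n_shuffles
        self.seed = seed
        self.threshold = threshold

    def fit(self, X, y=None):
        self.feature_names_out_ = list(FEATURE_NAMES)
        self.n_features_in_ = len(X)
        return self

    def transform(self, X) -> np.ndarray:
        return np.array([
            extract_features(w, B=self.B, n_shuffles=self.n_shuffles,
                             seed=self.seed, threshold=self.threshold)
            for w in X
        ])

    def get_feature_names_out(self, input_features=None):
        return np.array(FEATURE_NAMES)


def cohort_windows(cohort, states: tuple[str, ...] = TASK_STATES,
                   preprocess=None, win_seconds: float = WINDOW_SECONDS,
                   step_seconds: float = WINDOW_STEP_SECONDS) -> list[Window]:
    """Windows of every subject in a cohort, labelled with expertise."""
    out: list[Window] = []
    for rec, profile, _ in cohort:
        if preprocess is not None:
            rec = preprocess(rec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.extend(sliding_windows(rec, states, win_seconds,
                                       step_seconds,
                                       label=profile.expertise,
                                       subject_id=profile.subject_id))
    return out
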