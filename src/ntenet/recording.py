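"""In-memory containers for multichannel recordings and fixed-length epochs."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .channels import CHANNELS, N_CHANNELS

logger = logging.getLogger(__name__)


@dataclass
class Annotation:
    """A labelled, half-open sample span ``[start, stop)`` of one state."""

    state: str
    start: int
    stop: int

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


@dataclass
class MultichannelRecording:
    """A 14-channel recording with per-state annotations.

    Parameters
    ----------
    samples : ndarray, shape (14, n_samples)
        Signal in microvolt-like units, channels in canonical order.
    fs : float
        Sampling frequency in Hz.
    annotations : list of Annotation
        Non-overlapping state spans, within bounds.
    channel_labels : tuple of str
        Always the canonical order; kept explicit for serialization.
    """

    samples: np.ndarray
    fs: float
    annotations: list[Annotation] = field(default_factory=list)
    channel_labels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != N_CHANNELS:
            raise ValueError(
                f"expected {N_CHANNELS} channels, got array of shape "
                f"{self.samples.shape}"
            )
        if tuple(self.channel_labels) != CHANNELS:
            raise ValueError("channel_labels must be in canonical order; "
                             "use ntenet.io.read_recording to reorder")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        spans = sorted((a.start, a.stop) for a in self.annotations)
        n = self.samples.shape[1]
        for (s0, s1), nxt in zip(spans, spans[1:] + [(n, n)]):
            if not (0 <= s0 < s1 <= n):
                raise ValueError(f"annotation span ({s0}, {s1}) out of bounds")
            if s1 > nxt[0]:
                raise ValueError("annotation spans overlap")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def states(self) -> list[str]:
        return sorted({a.state for a in self.annotations})

    def spans(self, state: str) -> list[Annotation]:
        out = [a for a in self.annotations if a.state == state]
        if not out:
            raise KeyError(f"state {state!r} not present in annotations")
        return out

    def with_samples(self, samples: np.ndarray) -> "MultichannelRecording":
        return replace(self, samples=samples)


@dataclass
class EpochSet:
    """Fixed-length epochs cut from one state of a recording.

    ``epochs`` has shape (n_epochs, 14, epoch_len); ``starts`` holds the
    sample index of each epoch in the source recording.
    """

    epochs: np.ndarray
    state: str
    fs: float
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.size and (
            self.epochs.ndim != 3 or self.epochs.shape[1] != N_CHANNELS
        ):
            raise ValueError("epochs must have shape (n, 14, epoch_len)")
        self.starts = np.asarray(self.starts, dtype=int)

    def __len__(self) -> int:
        return 0 if self.epochs.size == 0 else self.epochs.shape[0]

    @property
    def epoch_len(self) -> int:
        return 0 if len(self) == 0 else self.epochs.shape[2]


def reject_bad_epochs(es: EpochSet, amplitude_limit: float) -> EpochSet:
    """Drop epochs whose peak absolute amplitude exceeds ``amplitude_limit``.

    An automated stand-in for manual rejection of noisy blocks; epochs
    containing large transients (blinks, motion) are removed wholesale.
    """
    if amplitude_limit <= 0:
        raise ValueError("amplitude_limit must be positive")
    if len(es) == 0:
        return es
    peak = np.abs(es.epochs).max(axis=(1, 2))
    keep = peak <= amplitude_limit
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("rejected %d/%d epochs above %.3g", n_drop, len(es),
                    amplitude_limit)
    if not keep.any():
        warnings.warn(
            f"all {len(es)} epochs exceeded the amplitude limit "
            f"{amplitude_limit:g}; returning an empty epoch set",
            stacklevel=2,
        )
        return EpochSet(np.empty((0, N_CHANNELS, es.epoch_len)), es.state,
                        es.fs, np.empty(0, dtype=int))
    return EpochSet(es.epochs[keep], es.state, es.fs, es.starts[keep])


def epoch_by_state(
    rec: MultichannelRecording,
    state: str,
    epoch_seconds: float = 2.0,
    step_seconds: float = 2.5,
) -> EpochSet:
    """Tile every annotated span of ``state`` with fixed-length epochs.

    Default geometry: 2-s epochs whose starts are 2.5 s apart (a 0.5-s gap
    between consecutive epochs). Partial trailing windows are discarded and
    no epoch crosses a state boundary.
    """
    spans = rec.spans(state)  # raises KeyError if absent
    epoch_len = int(round(epoch_seconds * rec.fs))
    step = int(round(step_seconds * rec.fs))
    if epoch_len < 2:
        raise ValueError("epoch too short for the sampling rate")
    chunks, starts = [], []
    for span in spans:
        start = span.start
        while start + epoch_len <= span.stop:
            chunks.append(rec.samples[:, start:start + epoch_len])
            starts.append(start)
            start += step
    if not chunks:
        return EpochSet(np.empty((0, N_CHANNELS, epoch_len)), state, rec.fs)
    return EpochSet(np.stack(chunks), state, rec.fs, np.array(starts))
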