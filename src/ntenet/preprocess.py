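"""Filtering chain applied to every recording before connectivity analysis.

Stages, in order: per-channel baseline (mean) removal, FIR low-pass at
45 Hz, FIR high-pass at 0.1 Hz, FIR notches at 50 and 60 Hz. Every filter
is a linear-phase FIR of order 300 (301 taps, Hamming window) applied
forward-backward, so the net chain has exactly zero phase and the output
length equals the input length. Notch stages at or above the Nyquist
frequency are skipped with a warning.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .recording import MultichannelRecording

logger = logging.getLogger(__name__)

FILTER_ORDER = 300
LOWPASS_HZ = 45.0
HIGHPASS_HZ = 0.1
NOTCH_HZ = (50.0, 60.0)
NOTCH_HALF_WIDTH_HZ = 2.0


def design_filters(
    fs: float,
    order: int = FILTER_ORDER,
    lowpass: float = LOWPASS_HZ,
    highpass: float = HIGHPASS_HZ,
    notches: tuple[float, ...] = NOTCH_HZ,
) -> list[np.ndarray]:
    """Return the FIR taps of each applicable stage for sampling rate fs."""
    ntaps = order + 1
    nyq = fs / 2.0
    taps = []
    if lowpass < nyq:
        taps.append(signal.firwin(ntaps, lowpass, fs=fs))
    if 0 < highpass < nyq:
        taps.append(signal.firwin(ntaps, highpass, fs=fs, pass_zero=False))
    for f0 in notches:
        lo, hi = f0 - NOTCH_HALF_WIDTH_HZ, f0 + NOTCH_HALF_WIDTH_HZ
        if hi >= nyq:
            logger.warning(
                "skipping %.0f Hz notch: band edge %.0f Hz is at or above "
                "Nyquist (%.1f Hz)", f0, hi, nyq)
            continue
        taps.append(signal.firwin(ntaps, [lo, hi], fs=fs, pass_zero="bandstop"))
    return taps


def filter_recording(
    rec: MultichannelRecording,
    order: int = FILTER_ORDER,
    lowpass: float = LOWPASS_HZ,
    highpass: float = HIGHPASS_HZ,
    notches: tuple[float, ...] = NOTCH_HZ,
) -> MultichannelRecording:
    """Apply baseline removal and the zero-phase FIR chain to a recording."""
    if rec.n_samples < 3 * order:
        raise ValueError(
            f"recording of {rec.n_samples} samples is too short to filter "
            f"with order-{order} FIR stages (needs at least {3 * order})"
        )
    x = rec.samples - rec.samples.mean(axis=1, keepdims=True)
    for taps in design_filters(rec.fs, order, lowpass, highpass, notches):
        x = signal.filtfilt(taps, [1.0], x, axis=1)
    return rec.with_samples(x)
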