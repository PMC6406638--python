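"""Transfer entropy and normalized transfer entropy between EEG channels.

Signals are first reduced to symbol sequences by equiprobable amplitude
binning. Transfer entropy from a source y to a target x (embedding
dimension 1, lag 1) is

    TE(y->x) = sum p(x_{n+1}, x_n, y_n)
               * log2[ p(x_{n+1}, x_n, y_n) p(x_n)
                       / (p(x_n, y_n) p(x_{n+1}, x_n)) ],

estimated with plug-in probabilities from joint counts. Finite data give
TE a positive bias, which is removed by subtracting the mean TE obtained
after randomly permuting the source symbols; dividing by the target's own
conditional entropy H(x_{n+1} | x_n) expresses the result as the fraction
of the target's information budget supplied by the source:

    NTE(y->x) = (TE(y->x) - <TE(y_shuffle->x)>) / H(x_{n+1} | x_n).

NTE lies in [0, 1]: 0 after clipping means no detectable transfer, 1 means
the source fully determines the target's next symbol. Entropies are in
bits; the log base cancels in NTE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .channels import CHANNELS, N_CHANNELS
from .recording import EpochSet

logger = logging.getLogger(__name__)

#: Default alphabet size. Two-second epochs at 128 Hz provide only 255
#: symbol triples; 4 bins (64 joint cells) keep the plug-in histograms
#: populated, where finer alphabets drown the estimate in small-sample
#: bias. Config-exposed for longer segments.
DEFAULT_BINS = 4
DEFAULT_SHUFFLES = 20


@dataclass
class SymbolSequence:
    """An integer sequence over the alphabet {0, ..., B-1}."""

    symbols: np.ndarray
    B: int

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.ndim != 1 or len(self.symbols) < 2:
            raise ValueError("symbols must be a 1-D sequence of length >= 2")
        if self.B < 2:
            raise ValueError("alphabet size B must be >= 2")
        if self.symbols.min() < 0 or self.symbols.max() >= self.B:
            raise ValueError("symbols must lie in [0, B)")

    def __len__(self) -> int:
        return len(self.symbols)


def quantize(x, B: int = DEFAULT_BINS) -> SymbolSequence:
    """Equiprobable (quantile-edge) binning of a real-valued sequence.

    Bin edges are the 1/B, ..., (B-1)/B quantiles of the sequence itself;
    values equal to an edge fall in the lower bin. Distinct values give a
    near-uniform symbol marginal. A constant sequence maps to all zeros
    (entropy 0).
    """
    x = np.asarray(x, dtype=float)
    if B < 2:
        raise ValueError("B must be >= 2")
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("signal must be 1-D with length >= 2")
    edges = np.quantile(x, np.arange(1, B) / B)
    symbols = np.searchsorted(edges, x, side="left")
    if x.min() == x.max():
        logger.debug("quantize: constant signal, all symbols 0")
    return SymbolSequence(symbols, B)


def _pair_counts(sx: SymbolSequence) -> np.ndarray:
    s = sx.symbols
    return np.bincount(s[1:] * sx.B + s[:-1],
                       minlength=sx.B * sx.B).astype(float)


def conditional_entropy(sx: SymbolSequence) -> float:
    """H(x_{n+1} | x_n) in bits, from plug-in pair counts."""
    B = sx.B
    n_pair = _pair_counts(sx).reshape(B, B)
    n = n_pair.sum()
    n_x0 = n_pair.sum(axis=0)
    nz = n_pair > 0
    # H = (1/N) [sum n_x0 log n_x0 - sum n_pair log n_pair]
    h = (np.sum(n_x0[n_x0 > 0] * np.log2(n_x0[n_x0 > 0]))
         - np.sum(n_pair[nz] * np.log2(n_pair[nz]))) / n
    return max(float(h), 0.0)


def transfer_entropy(
    x: SymbolSequence, y: SymbolSequence, require_same_alphabet: bool = True
) -> float:
    """Plug-in transfer entropy TE(y -> x) in bits (dimension 1, lag 1)."""
    if len(x) != len(y):
        raise ValueError(
            f"sequences differ in length: {len(x)} vs {len(y)}"
        )
    if require_same_alphabet and x.B != y.B:
        raise ValueError("sequences use different alphabets; pass "
                         "require_same_alphabet=False to allow")
    sx, sy = x.symbols, y.symbols
    Bx, By = x.B, y.B
    code = (sx[1:] * Bx + sx[:-1]) * By + sy[:-1]
    n3 = np.bincount(code, minlength=Bx * Bx * By).astype(float)
    n3 = n3.reshape(Bx, Bx, By)  # axes: x_{n+1}, x_n, y_n
    n = n3.sum()
    n_x0y0 = n3.sum(axis=0)
    n_x1x0 = n3.sum(axis=2)
    n_x0 = n3.sum(axis=(0, 2))

    def s(a):
        a = a[a > 0]
        return np.sum(a * np.log2(a))

    te = (s(n_x0) - s(n_x1x0) - s(n_x0y0) + s(n3)) / n
    return max(float(te), 0.0)


def normalized_te(
    x: SymbolSequence,
    y: SymbolSequence,
    n_shuffles: int = DEFAULT_SHUFFLES,
    rng_seed: int | np.random.Generator = 0,
) -> float:
    """Surrogate-corrected, entropy-normalized transfer entropy in [0, 1].

    Each surrogate permutes the full source sequence uniformly at random;
    the surrogate mean estimates the finite-sample bias of TE. A target
    with zero conditional entropy has no information budget, so NTE is 0
    by convention.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    h = conditional_entropy(x)
    if h == 0.0:
        return 0.0
    te_raw = transfer_entropy(x, y)
    surr = 0.0
    for _ in range(n_shuffles):
        perm = rng.permutation(len(y))
        surr += transfer_entropy(x, SymbolSequence(y.symbols[perm], y.B))
    nte = (te_raw - surr / n_shuffles) / h
    return max(float(nte), 0.0)


@dataclass
class NTEMatrix:
    """Directed connectivity weights; ``values[i, j]`` = NTE from channel j
    into channel i's information budget (target-major orientation)."""

    values: np.ndarray
    state: str = ""
    n_epochs_averaged: int = 0
    channel_labels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.channel_labels)
        if self.values.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got "
                             f"{self.values.shape}")
        if np.diagonal(self.values).any():
            raise ValueError("NTE diagonal must be exactly zero")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("NTE values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Rows = target channel, columns = source channel."""
        labels = list(self.channel_labels)
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, state: str = "",
                 n_epochs_averaged: int = 0) -> "NTEMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
        df = df.loc[list(CHANNELS), list(CHANNELS)]
        return cls(df.to_numpy(), state, n_epochs_averaged)


def nte_matrix(
    es: EpochSet,
    B: int = DEFAULT_BINS,
    n_shuffles: int = DEFAULT_SHUFFLES,
    seed: int = 0,
) -> NTEMatrix:
    """All-pairs NTE, computed per epoch and averaged across epochs.

    Channels are quantized per epoch (quantile edges within the epoch).
    Negative bias-corrected values are clipped to zero before averaging;
    the clip count is logged.
    """
    if len(es) == 0:
        raise ValueError("cannot compute an NTE matrix from an empty "
                         "epoch set")
    rng = np.random.default_rng(seed)
    total = np.zeros((N_CHANNELS, N_CHANNELS))
    n_clipped = 0
    for e in range(len(es)):
        epoch = es.epochs[e]
        L = epoch.shape[1]
        symbols = np.stack(
            [quantize(epoch[c], B).symbols for c in range(N_CHANNELS)]
        )
        perms = np.stack([rng.permutation(L) for _ in range(n_shuffles)])
        te, h = _kernels.epoch_te_all_pairs(symbols, B, perms)
        bias = te[1:].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            nte = np.where(h[:, None] > 0, (te[0] - bias) / h[:, None], 0.0)
        n_clipped += int((nte < 0).sum())
        nte = np.clip(nte, 0.0, 1.0)
        np.fill_diagonal(nte, 0.0)
        total += nte
    if n_clipped > 0:
        logger.debug("nte_matrix: clipped %d negative values to 0", n_clipped)
    return NTEMatrix(total / len(es), es.state, len(es))
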