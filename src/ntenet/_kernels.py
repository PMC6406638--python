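"""Fast all-pairs transfer-entropy kernel.

Entropies of plug-in (maximum-likelihood) histograms reduce to sums of
``n*log2(n)`` over integer bin counts, so the kernel counts symbol triples
per channel pair and reads entropy terms from a precomputed table. The
numba-compiled path is used when numba is importable; otherwise a slow
fallback loops over the reference per-pair functions.

Shuffle surrogates share one permutation per realization across all source
channels: each surrogate is still a uniformly random permutation of its
source sequence, and sharing keeps the work linear in the number of
channels instead of channel pairs.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


def nlogn_table(n_max: int) -> np.ndarray:
    """Table of n*log2(n) for integer n in [0, n_max]; 0*log0 := 0."""
    n = np.arange(n_max + 1, dtype=float)
    out = np.zeros(n_max + 1)
    out[1:] = n[1:] * np.log2(n[1:])
    return out


@njit(cache=True)
def _epoch_te_all_pairs(s, B, perms, nlog):  # pragma: no cover - numba
    C, L = s.shape
    M = L - 1
    K = perms.shape[0]

    xc = np.empty((C, M), dtype=np.int64)
    for i in range(C):
        for t in range(M):
            xc[i, t] = s[i, t + 1] * B + s[i, t]

    # Per-target own-history entropy terms.
    A0 = np.empty(C)
    A1 = np.empty(C)
    H = np.empty(C)
    cnt1 = np.zeros(B, dtype=np.int64)
    cnt2 = np.zeros(B * B, dtype=np.int64)
    for i in range(C):
        cnt1[:] = 0
        cnt2[:] = 0
        for t in range(M):
            cnt1[s[i, t]] += 1
            cnt2[xc[i, t]] += 1
        a0 = 0.0
        for b in range(B):
            a0 += nlog[cnt1[b]]
        a1 = 0.0
        for b in range(B * B):
            a1 += nlog[cnt2[b]]
        A0[i] = a0
        A1[i] = a1
        H[i] = (a0 - a1) / M

    te = np.zeros((K + 1, C, C))
    cnt3 = np.zeros(B * B * B, dtype=np.int64)
    cxy = np.zeros(B * B, dtype=np.int64)
    ybuf = np.empty(L, dtype=np.int64)
    for k in range(K + 1):
        for j in range(C):
            if k == 0:
                for t in range(L):
                    ybuf[t] = s[j, t]
            else:
                for t in range(L):
                    ybuf[t] = s[j, perms[k - 1, t]]
            for i in range(C):
                if i == j:
                    continue
                cnt3[:] = 0
                for t in range(M):
                    cnt3[xc[i, t] * B + ybuf[t]] += 1
                b1 = 0.0
                for c in range(B * B * B):
                    b1 += nlog[cnt3[c]]
                cxy[:] = 0
                for x1 in range(B):
                    base = x1 * B * B
                    for r in range(B * B):
                        cxy[r] += cnt3[base + r]
                b0 = 0.0
                for r in range(B * B):
                    b0 += nlog[cxy[r]]
                te[k, i, j] = (A0[i] - A1[i] - b0 + b1) / M
    return te, H


def epoch_te_all_pairs(
    symbols: np.ndarray, B: int, perms: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """TE of every directed channel pair, raw and per surrogate.

    Parameters
    ----------
    symbols : (C, L) int array of quantized channels
    B : alphabet size
    perms : (K, L) int array, one time permutation per surrogate

    Returns
    -------
    te : (K+1, C, C) array; ``te[0, i, j]`` is raw TE from channel j to
        channel i, ``te[k>0]`` the k-th shuffled-source surrogate.
    H : (C,) conditional entropy H(x_{n+1} | x_n) of each target, in bits.
    """
    s = np.ascontiguousarray(symbols, dtype=np.int64)
    p = np.ascontiguousarray(perms, dtype=np.int64).reshape(-1, s.shape[1])
    nlog = nlogn_table(s.shape[1])
    if HAVE_NUMBA:
        return _epoch_te_all_pairs(s, B, p, nlog)
    return _epoch_te_all_pairs_numpy(s, B, p, nlog)


def _epoch_te_all_pairs_numpy(s, B, perms, nlog):
    """Vectorized fallback mirroring the numba kernel."""
    C, L = s.shape
    M = L - 1
    K = perms.shape[0]
    xc = s[:, 1:] * B + s[:, :-1]

    A0 = np.array([nlog[np.bincount(row[:-1], minlength=B)].sum()
                   for row in s])
    A1 = np.array([nlog[np.bincount(row, minlength=B * B)].sum()
                   for row in xc])
    H = (A0 - A1) / M

    n3 = B ** 3
    pair_off = (np.arange(C * C) * n3).reshape(C, C, 1)
    te = np.zeros((K + 1, C, C))
    for k in range(K + 1):
        y = s if k == 0 else s[:, perms[k - 1]]
        code = xc[:, None, :] * B + y[None, :, :M] + pair_off
        cnt3 = np.bincount(code.ravel(), minlength=C * C * n3)
        cnt3 = cnt3.reshape(C, C, B, B * B)
        b1 = nlog[cnt3].sum(axis=(2, 3))
        b0 = nlog[cnt3.sum(axis=2)].sum(axis=2)
        te[k] = (A0[:, None] - A1[:, None] - b0 + b1) / M
    for k in range(K + 1):
        np.fill_diagonal(te[k], 0.0)
    return te, H
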