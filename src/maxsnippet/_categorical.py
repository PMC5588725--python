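"""Fused kernels for positional-categorical feature matrices.

All three encodings are positional-categorical: a snippet's feature vector
is the concatenation of one of S symbol vectors per position (Atchley rows,
or one-hot indicators).  The detector logit then decomposes per position,

    logit(snippet) = b0 + sum_p  T[p, symbol(snippet, p)]
    with T[p] = basis @ W[p-th block],

so the per-iteration forward pass over all restarts needs only k tiny
matmuls to build the (k, S, R) score tables plus one cached gather-sum per
snippet, instead of a dense (N x n_features) @ (n_features x R) matmul.
Kernels are JIT-compiled with numba when available; callers must fall back
to the dense path otherwise.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=True)
def _forward_max(codes, T, starts, ends, mx, amax):
    """Per-patient max and argmax of table-summed snippet logits.

    ``codes``: (N, k) uint8 symbol indices; ``T``: (k, S, R) float32 score
    tables; ``starts``/``ends``: per-patient snippet ranges.  Fills ``mx``
    (P, R) with the max logit (bias excluded) and ``amax`` (P, R) with the
    first-attaining global snippet index.
    """
    n_patients = starts.shape[0]
    k = codes.shape[1]
    R = T.shape[2]
    acc = np.empty(R, np.float32)
    for i in range(n_patients):
        for r in range(R):
            mx[i, r] = -np.inf
            amax[i, r] = starts[i]
        for n in range(starts[i], ends[i]):
            for r in range(R):
                acc[r] = T[0, codes[n, 0], r]
            for p in range(1, k):
                row = T[p, codes[n, p]]
                for r in range(R):
                    acc[r] += row[r]
            for r in range(R):
                if acc[r] > mx[i, r]:
                    mx[i, r] = acc[r]
                    amax[i, r] = n
    return mx, amax


@njit(cache=True)
def _grad_scatter(codes, amax, C, G):
    """Accumulate per-symbol gradient mass: G[p, sym, r] += C[i, r]."""
    n_patients, R = C.shape
    k = codes.shape[1]
    for i in range(n_patients):
        for r in range(R):
            n = amax[i, r]
            c = C[i, r]
            for p in range(k):
                G[p, codes[n, p], r] += c
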