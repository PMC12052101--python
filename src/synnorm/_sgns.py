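"""Numba kernel for skip-gram negative-sampling training.

Single-threaded on purpose: with a fixed seed the whole pass is
run-to-run deterministic, which the evaluation pipeline relies on (a null
replacement must yield bitwise-identical spaces). The RNG is an inline
xorshift64*, so no state escapes the kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MAX_EXP = 6.0


@njit(cache=True, fastmath=False)
def _rng_next(state: np.uint64) -> np.uint64:
    state ^= state >> np.uint64(12)
    state ^= state << np.uint64(25)
    state ^= state >> np.uint64(27)
    return state * np.uint64(2685821657736338717)


@njit(cache=True, fastmath=False)
def _rng_uniform(state: np.uint64) -> float:
    # top 53 bits -> double in [0, 1)
    return float(state >> np.uint64(11)) / 9007199254740992.0


@njit(cache=True, fastmath=False)
def train_sgns(
    tokens: np.ndarray,       # int32, all documents concatenated
    offsets: np.ndarray,      # int64, len n_docs+1, document boundaries
    syn0: np.ndarray,         # float32 (vocab, dim), modified in place
    syn1: np.ndarray,         # float32 (vocab, dim), modified in place
    neg_cdf: np.ndarray,      # float64 cumulative unigram^0.75 distribution
    keep_prob: np.ndarray,    # float64 per-word subsampling keep probability
    window: int,
    negative: int,
    alpha_start: float,
    alpha_min: float,
    epochs: int,
    seed: int,
) -> None:
    dim = syn0.shape[1]
    n_docs = offsets.shape[0] - 1
    total_words = np.int64(tokens.shape[0]) * np.int64(epochs)
    processed = np.int64(0)
    state = np.uint64(seed * np.uint64(2862933555777941757) + np.uint64(3037000493))
    state = _rng_next(state)

    kept = np.empty(tokens.shape[0], dtype=np.int32)
    neu1e = np.empty(dim, dtype=np.float32)

    for _epoch in range(epochs):
        for d in range(n_docs):
            start, stop = offsets[d], offsets[d + 1]
            # subsample frequent words, then train on the compacted document
            n_kept = 0
            for i in range(start, stop):
                w = tokens[i]
                processed += 1
                state = _rng_next(state)
                if _rng_uniform(state) < keep_prob[w]:
                    kept[n_kept] = w
                    n_kept += 1
            alpha = alpha_start * (1.0 - processed / (total_words + 1.0))
            if alpha < alpha_min:
                alpha = alpha_min
            for i in range(n_kept):
                center = kept[i]
                state = _rng_next(state)
                b = int(state % np.uint64(window))  # shrunk window, word2vec-style
                lo = i - window + b
                hi = i + window - b
                if lo < 0:
                    lo = 0
                if hi >= n_kept:
                    hi = n_kept - 1
                for j in range(lo, hi + 1):
                    if j == i:
                        continue
                    context = kept[j]
                    for k in range(dim):
                        neu1e[k] = 0.0
                    for neg in range(negative + 1):
                        if neg == 0:
                            target = center
                            label = 1.0
                        else:
                            state = _rng_next(state)
                            r = _rng_uniform(state)
                            target = np.searchsorted(neg_cdf, r)
                            if target == center:
                                continue
                            label = 0.0
                        f = 0.0
                        for k in range(dim):
                            f += syn0[context, k] * syn1[target, k]
                        if f > _MAX_EXP:
                            g = (label - 1.0) * alpha
                        elif f < -_MAX_EXP:
                            g = label * alpha
                        else:
                            g = (label - 1.0 / (1.0 + np.exp(-f))) * alpha
                        for k in range(dim):
                            neu1e[k] += g * syn1[target, k]
                        for k in range(dim):
                            syn1[target, k] += g * syn0[context, k]
                    for k in range(dim):
                        syn0[context, k] += neu1e[k]
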