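"""Skip-gram word embeddings over a tokenized corpus.

Trains 128-dimensional (by default) skip-gram vectors with negative
sampling: each (context, center) co-occurrence within a randomly shrunk
window pushes the pair's vectors together while `negative` sampled
unigram^0.75 noise words are pushed apart. High-frequency words are
probabilistically downsampled before windowing. The learning rate decays
linearly from ``alpha_start`` to ``alpha_min`` across all epochs.

Every token that occurs at least ``min_count`` times (default 1 — concept
identifiers are often rare and must not be dropped) receives a vector.
With a fixed seed training is run-to-run deterministic on a given
machine; bitwise reproducibility across platforms is not promised.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import numpy as np

from .corpus import Corpus, count_frequencies


@dataclass(frozen=True)
class EmbeddingParams:
    """Skip-gram hyperparameters.

    dim: vector length. window: max distance between center and context
    (the effective window is shrunk uniformly per position). min_count:
    vocabulary floor. negative: noise words per positive pair.
    sample_threshold: frequency downsampling knob (0 disables).
    """

    dim: int = 128
    window: int = 10
    min_count: int = 1
    negative: int = 5
    alpha_start: float = 0.03
    alpha_min: float = 0.0001
    sample_threshold: float = 1e-3
    epochs: int = 5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("dim must be positive")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.negative < 0:
            raise ValueError("negative must be >= 0")
        if not (self.alpha_start > self.alpha_min > 0):
            raise ValueError("need alpha_start > alpha_min > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def with_(self, **kwargs) -> "EmbeddingParams":
        return replace(self, **kwargs)


class EmbeddingSpace:
    """Token -> vector mapping backed by a dense (vocab, dim) matrix."""

    def __init__(self, tokens: list[str], matrix: np.ndarray, params: EmbeddingParams | None = None):
        if matrix.ndim != 2 or matrix.shape[0] != len(tokens):
            raise ValueError("matrix must be (len(tokens), dim)")
        self.tokens = list(tokens)
        self.matrix = np.asarray(matrix, dtype=np.float32)
        self.params = params
        self._index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    @property
    def vocab_size(self) -> int:
        return len(self.tokens)

    @property
    def vocab(self) -> set[str]:
        return set(self._index)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __getitem__(self, token: str) -> np.ndarray:
        return self.matrix[self._index[token]]

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)

    def index(self, token: str) -> int:
        return self._index[token]

    def submatrix(self, tokens: list[str]) -> np.ndarray:
        return self.matrix[[self._index[t] for t in tokens]]


def train_embeddings(corpus: Corpus, params: EmbeddingParams | None = None) -> EmbeddingSpace:
    """Train a skip-gram space over the corpus vocabulary.

    Raises on an empty corpus. The vocabulary is every distinct token with
    count >= min_count, ordered by descending frequency then token.
    """
    from ._sgns import train_sgns

    if params is None:
        params = EmbeddingParams()
    freq = count_frequencies(corpus)
    if freq.empty:
        raise ValueError("cannot train embeddings on an empty corpus")

    vocab_items = sorted(
        ((t, c) for t, c in freq.counts.items() if c >= params.min_count),
        key=lambda kv: (-kv[1], kv[0]),
    )
    if not vocab_items:
        raise ValueError("no token reaches min_count")
    tokens = [t for t, _ in vocab_items]
    counts = np.array([c for _, c in vocab_items], dtype=np.float64)
    index = {t: i for i, t in enumerate(tokens)}

    flat: list[int] = []
    offsets = [0]
    for doc in corpus.documents:
        ids = [index[t] for t in doc if t in index]
        flat.extend(ids)
        offsets.append(len(flat))
    token_arr = np.array(flat, dtype=np.int32)
    offset_arr = np.array(offsets, dtype=np.int64)

    # unigram^0.75 negative-sampling distribution as a CDF
    noise = counts ** 0.75
    neg_cdf = np.cumsum(noise / noise.sum())
    neg_cdf[-1] = 1.0

    total = counts.sum()
    if params.sample_threshold > 0:
        # word2vec downsampling: keep prob (sqrt(x)+1)*1/x with x = f/(t*T)
        ratio = counts / (params.sample_threshold * total)
        keep = (np.sqrt(ratio) + 1.0) / ratio
        keep_prob = np.minimum(keep, 1.0)
    else:
        keep_prob = np.ones_like(counts)

    rng = np.random.default_rng(params.seed)
    syn0 = ((rng.random((len(tokens), params.dim)) - 0.5) / params.dim).astype(np.float32)
    syn1 = np.zeros((len(tokens), params.dim), dtype=np.float32)

    train_sgns(
        token_arr,
        offset_arr,
        syn0,
        syn1,
        neg_cdf,
        keep_prob,
        params.window,
        params.negative,
        params.alpha_start,
        params.alpha_min,
        params.epochs,
        params.seed + 1,
    )
    return EmbeddingSpace(tokens, syn0, params)


def save_space(space: EmbeddingSpace, path: str | Path) -> None:
    """Write the standard word2vec text format: header ``vocab dim``, then
    one ``token v1 v2 ...`` line per token, full float32 precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{space.vocab_size} {space.dim}\n")
        for i, token in enumerate(space.tokens):
            values = " ".join(np.format_float_positional(v) for v in space.matrix[i])
            fh.write(f"{token} {values}\n")


def load_space(path: str | Path) -> EmbeddingSpace:
    """Read word2vec text format; raises ValueError on malformed files."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed header {header!r}")
        n, dim = int(header[0]), int(header[1])
        tokens: list[str] = []
        rows = np.empty((n, dim), dtype=np.float32)
        for i in range(n):
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated after {i} of {n} vectors")
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"{path}: line {i + 2} has {len(parts) - 1} values, expected {dim}")
            tokens.append(parts[0])
            rows[i] = np.array(parts[1:], dtype=np.float32)
    return EmbeddingSpace(tokens, rows)
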