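"""Word vectors: a compact CBOW / skip-gram trainer with negative
sampling, plus the word2vec text vector format and cosine similarity.

The trainer implements the standard word2vec objectives — predicting a
word from its window (CBOW) or the window from the word (skip-gram) —
with unigram^0.75 negative sampling, frequent-word subsampling, a
dynamic window (the effective radius is drawn uniformly from 1..window
per position) and linearly decaying learning rate. It is single-threaded
and fully deterministic given (corpus, params, seed): two trainings with
identical inputs produce identical vectors.

Skip-gram updates are batched per sentence (gradients within one
sentence are computed against a common snapshot and accumulated with
``np.add.at``); CBOW updates are applied per center word. At the corpus
sizes this package targets (10^4–10^6 tokens) this trains in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EmbeddingParams",
    "VectorSet",
    "PRESETS",
    "train_embeddings",
    "cosine",
    "save_vectors",
    "load_vectors",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Hyperparameters of the word-vector trainer.

    ``window`` is the number of surrounding words per side; ``sample``
    is the frequent-word subsampling threshold (0 disables).
    """

    algorithm: str = "cbow"  # "cbow" | "skipgram"
    window: int = 8
    dimension: int = 200
    min_count: int = 1
    epochs: int = 5
    seed: int = 1
    negative: int = 5
    alpha: float | None = None  # default 0.05 for CBOW, 0.025 for skip-gram
    sample: float = 1e-3

    def __post_init__(self) -> None:
        if self.algorithm not in {"cbow", "skipgram"}:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def initial_alpha(self) -> float:
        if self.alpha is not None:
            return self.alpha
        return 0.025 if self.algorithm == "skipgram" else 0.05

    def replace(self, **kwargs) -> "EmbeddingParams":
        return replace(self, **kwargs)


#: Named configurations: the generic default (CBOW, window 8, dim 200),
#: the tuned disease preset (skip-gram, window 5, dim 300), the plant
#: preset (CBOW, window 7, dim 200), and a small-corpus preset for
#: synthetic fixtures.
PRESETS: dict[str, EmbeddingParams] = {
    "default": EmbeddingParams(algorithm="cbow", window=8, dimension=200),
    "disease": EmbeddingParams(algorithm="skipgram", window=5, dimension=300),
    "plant": EmbeddingParams(algorithm="cbow", window=7, dimension=200),
    "fixture": EmbeddingParams(
        algorithm="skipgram", window=5, dimension=50, epochs=15, min_count=1
    ),
}


class VectorSet:
    """The learned token -> vector mapping V.

    The zero vector is reserved for out-of-vocabulary tokens; trained
    vectors are never exactly zero.
    """

    def __init__(
        self,
        tokens: Sequence[str],
        matrix: np.ndarray,
        params: EmbeddingParams | None = None,
        corpus_token_count: int = 0,
    ) -> None:
        matrix = np.asarray(matrix, dtype=np.float32)
        if matrix.ndim != 2 or matrix.shape[0] != len(tokens):
            raise ValueError("matrix shape does not match token count")
        self.tokens = list(tokens)
        self.matrix = matrix
        self.index = {tok: i for i, tok in enumerate(self.tokens)}
        if len(self.index) != len(self.tokens):
            raise ValueError("duplicate tokens in vector set")
        self.params = params
        self.corpus_token_count = corpus_token_count

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]

    def get(self, token: str) -> np.ndarray | None:
        i = self.index.get(token)
        return None if i is None else self.matrix[i]

    def __getitem__(self, token: str) -> np.ndarray:
        return self.matrix[self.index[token]]

    def neighbors(self, token: str, k: int = 10) -> list[tuple[str, float]]:
        """Top-k nearest tokens by cosine (excluding the probe),
        deterministically tie-broken by token string."""
        v = self[token]
        sims = _cosine_to_all(v, self.matrix)
        order = sorted(
            (i for i in range(len(self.tokens)) if self.tokens[i] != token),
            key=lambda i: (-sims[i], self.tokens[i]),
        )
        return [(self.tokens[i], float(sims[i])) for i in order[:k]]


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (|u| |v|); a zero-norm operand yields -inf so that
    zero (OOV) vectors always rank last."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return float("-inf")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def _cosine_to_all(v: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(matrix, axis=1)
    nv = np.linalg.norm(v)
    with np.errstate(divide="ignore", invalid="ignore"):
        sims = matrix @ v / (norms * nv)
    sims[~np.isfinite(sims)] = -np.inf
    return sims


# ---------------------------------------------------------------------------
# Training

def _as_token_lists(sentences: Iterable) -> list[list[str]]:
    out: list[list[str]] = []
    for sent in sentences:
        if isinstance(sent, str):
            toks = sent.split()
        elif hasattr(sent, "text"):  # corpus.Sentence
            toks = sent.text.split()
        else:
            toks = list(sent)
        if toks:
            out.append(toks)
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -8.0, 8.0)))


def train_embeddings(sentences: Iterable, params: EmbeddingParams) -> VectorSet:
    """Train a vector set on whitespace-tokenized sentences.

    Every token with frequency >= min_count receives a vector; training
    is reproducible given (corpus, params, seed).
    """
    token_lists = _as_token_lists(sentences)
    if not token_lists:
        raise ValueError("empty corpus: no sentences with tokens")

    counts: dict[str, int] = {}
    total = 0
    for toks in token_lists:
        for t in toks:
            counts[t] = counts.get(t, 0) + 1
            total += 1
    vocab = sorted(t for t, c in counts.items() if c >= params.min_count)
    if not vocab:
        raise ValueError(
            f"no token reaches min_count={params.min_count} "
            f"(corpus has {total} tokens)"
        )
    tok2id = {t: i for i, t in enumerate(vocab)}
    freqs = np.array([counts[t] for t in vocab], dtype=np.float64)

    rng = np.random.default_rng(params.seed)
    n, dim = len(vocab), params.dimension
    w_in = (rng.random((n, dim)) - 0.5) / dim  # input vectors (the result)
    w_out = np.zeros((n, dim))

    # unigram^0.75 negative-sampling table
    probs = freqs**0.75
    probs /= probs.sum()
    neg_cum = np.cumsum(probs)

    # frequent-word subsampling (word2vec keep probability)
    if params.sample > 0:
        ratio = params.sample / (freqs / total)
        keep = np.minimum(1.0, np.sqrt(ratio) + ratio)
    else:
        keep = np.ones(n)

    encoded = [
        np.array([tok2id[t] for t in toks if t in tok2id], dtype=np.intp)
        for toks in token_lists
    ]
    encoded = [e for e in encoded if e.size > 0]
    total_positions = sum(e.size for e in encoded) * params.epochs
    alpha0 = params.initial_alpha
    min_alpha = alpha0 * 1e-4
    processed = 0

    for _epoch in range(params.epochs):
        for ids in encoded:
            alpha = max(min_alpha, alpha0 * (1.0 - processed / total_positions))
            processed += ids.size
            kept = ids[rng.random(ids.size) < keep[ids]]
            if kept.size < 2:
                continue
            radii = rng.integers(1, params.window + 1, size=kept.size)
            if params.algorithm == "skipgram":
                _sgns_sentence(w_in, w_out, kept, radii, params.negative,
                               alpha, neg_cum, rng)
            else:
                _cbow_sentence(w_in, w_out, kept, radii, params.negative,
                               alpha, neg_cum, rng)

    # The zero vector is reserved for OOV: nudge any (pathological)
    # all-zero row off zero.
    zero_rows = np.flatnonzero(~w_in.any(axis=1))
    if zero_rows.size:
        w_in[zero_rows, 0] = 1e-8

    return VectorSet(vocab, w_in.astype(np.float32), params=params,
                     corpus_token_count=total)


def _draw_negatives(
    neg_cum: np.ndarray, shape: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    return np.searchsorted(neg_cum, rng.random(shape))


def _sgns_sentence(
    w_in: np.ndarray,
    w_out: np.ndarray,
    ids: np.ndarray,
    radii: np.ndarray,
    k: int,
    alpha: float,
    neg_cum: np.ndarray,
    rng: np.random.Generator,
) -> None:
    n = ids.size
    centers: list[int] = []
    contexts: list[int] = []
    for i in range(n):
        r = radii[i]
        lo, hi = max(0, i - r), min(n, i + r + 1)
        for j in range(lo, hi):
            if j != i:
                centers.append(ids[i])
                contexts.append(ids[j])
    if not centers:
        return
    c_idx = np.asarray(centers, dtype=np.intp)
    out_idx = np.empty((len(centers), 1 + k), dtype=np.intp)
    out_idx[:, 0] = contexts
    out_idx[:, 1:] = _draw_negatives(neg_cum, (len(centers), k), rng)

    wc = w_in[c_idx]  # (P, d)
    co = w_out[out_idx]  # (P, 1+k, d)
    score = np.einsum("pd,pkd->pk", wc, co)
    grad = -_sigmoid(score)
    grad[:, 0] += 1.0
    grad *= alpha
    d_center = np.einsum("pk,pkd->pd", grad, co)
    d_out = grad[:, :, None] * wc[:, None, :]
    np.add.at(w_in, c_idx, d_center)
    np.add.at(
        w_out.reshape(-1),
        (out_idx[:, :, None] * w_out.shape[1]
         + np.arange(w_out.shape[1])[None, None, :]).ravel(),
        d_out.ravel(),
    )


def _cbow_sentence(
    w_in: np.ndarray,
    w_out: np.ndarray,
    ids: np.ndarray,
    radii: np.ndarray,
    k: int,
    alpha: float,
    neg_cum: np.ndarray,
    rng: np.random.Generator,
) -> None:
    n = ids.size
    for i in range(n):
        r = radii[i]
        ctx = np.concatenate((ids[max(0, i - r):i], ids[i + 1:i + r + 1]))
        if ctx.size == 0:
            continue
        h = w_in[ctx].mean(axis=0)
        outs = np.empty(1 + k, dtype=np.intp)
        outs[0] = ids[i]
        outs[1:] = _draw_negatives(neg_cum, (k,), rng)
        co = w_out[outs]
        grad = -_sigmoid(co @ h)
        grad[0] += 1.0
        grad *= alpha
        dh = grad @ co
        np.add.at(w_out, outs, grad[:, None] * h[None, :])
        np.add.at(w_in, ctx, np.broadcast_to(dh / ctx.size, (ctx.size, len(dh))))


# ---------------------------------------------------------------------------
# word2vec text format

def save_vectors(vectors: VectorSet, path: str | Path) -> None:
    """Write the standard word2vec text format: a ``count dimension``
    header, then one ``token v1 ... vd`` line per token. Tokens with
    whitespace are rejected (underscore-joined tokens never have any)."""
    for tok in vectors.tokens:
        if any(ch.isspace() for ch in tok):
            raise ValueError(f"token contains whitespace: {tok!r}")
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"{len(vectors)} {vectors.dimension}\n")
        for tok, row in zip(vectors.tokens, vectors.matrix):
            values = " ".join(f"{x:.8f}" for x in row)
            handle.write(f"{tok} {values}\n")


def load_vectors(path: str | Path) -> VectorSet:
    """Load word2vec text format; the header must match the body."""
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed header {header!r}")
        count, dim = int(header[0]), int(header[1])
        tokens: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(handle, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {dim + 1} fields, got {len(parts)}"
                )
            tokens.append(parts[0])
            rows.append(np.array(parts[1:], dtype=np.float32))
    if len(tokens) != count:
        raise ValueError(
            f"{path}: header says {count} tokens but file has {len(tokens)}"
        )
    matrix = np.vstack(rows) if rows else np.zeros((0, dim), dtype=np.float32)
    return VectorSet(tokens, matrix)
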