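"""Small numpy skip-gram-negative-sampling (SGNS) engine.

Backs the word / subword / paragraph embedding schemes of
:mod:`thermoprot.string_features`.  Documents are token lists (k-mers);
training order is canonicalized (documents sorted by content) so the
result is invariant to input ordering, and all randomness flows from a
single integer seed.

This is a compact reference implementation tuned for the corpus sizes
this package trains on (hundreds of sequences); it is not a
large-corpus embedding trainer.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np


def _stable_hash(s: str, mod: int) -> int:
    return int.from_bytes(hashlib.blake2b(s.encode(), digest_size=8).digest(), "big") % mod


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


@dataclass
class SGNSModel:
    """Input/output embedding matrices plus the vocabulary."""

    vocab: dict[str, int]
    W_in: np.ndarray  # (V, dim) input (token) vectors
    W_out: np.ndarray  # (V, dim) output (context) vectors
    dim: int
    # subword extension: bucketed character n-gram vectors, token vector
    # = mean of its own row and its subword bucket rows
    subword_buckets: int = 0
    W_sub: np.ndarray | None = None
    subword_ngrams: tuple[int, ...] = (3, 4)

    def token_ngram_buckets(self, token: str) -> list[int]:
        padded = f"<{token}>"
        out = []
        for n in self.subword_ngrams:
            for i in range(len(padded) - n + 1):
                out.append(_stable_hash(padded[i : i + n], self.subword_buckets))
        return out

    def token_vector(self, token: str) -> np.ndarray | None:
        """Composed input vector; None for unseen tokens without subwords."""
        idx = self.vocab.get(token)
        if self.subword_buckets == 0:
            return None if idx is None else self.W_in[idx]
        buckets = self.token_ngram_buckets(token)
        parts = [self.W_sub[buckets].sum(axis=0)]
        count = len(buckets)
        if idx is not None:
            parts.append(self.W_in[idx])
            count += 1
        return sum(parts) / count

    def doc_mean(self, tokens: list[str]) -> np.ndarray:
        """Mean of token vectors; unseen tokens contribute zero."""
        acc = np.zeros(self.dim)
        if not tokens:
            return acc
        for t in tokens:
            v = self.token_vector(t)
            if v is not None:
                acc += v
        return acc / len(tokens)


def _canonical_order(docs: list[list[str]]) -> list[int]:
    return sorted(range(len(docs)), key=lambda i: (docs[i], i))


def build_vocab(docs: list[list[str]]) -> dict[str, int]:
    return {t: i for i, t in enumerate(sorted({t for d in docs for t in d}))}


def _negative_table(docs: list[list[str]], vocab: dict[str, int]) -> np.ndarray:
    """Unigram^0.75 sampling table (cumulative probabilities)."""
    counts = np.zeros(len(vocab))
    for d in docs:
        for t in d:
            counts[vocab[t]] += 1
    p = counts**0.75
    p /= p.sum()
    return np.cumsum(p)


def _sample_negatives(rng: np.random.Generator, cum: np.ndarray, size: int) -> np.ndarray:
    return np.searchsorted(cum, rng.random(size))


def train_sgns(
    docs: list[list[str]],
    dim: int = 100,
    window: int = 5,
    epochs: int = 5,
    negatives: int = 5,
    lr: float = 0.025,
    seed: int = 0,
    subword_buckets: int = 0,
) -> SGNSModel:
    """Train skip-gram with negative sampling on tokenized documents."""
    if not docs or all(not d for d in docs):
        raise ValueError("cannot train embeddings on an empty corpus")
    order = _canonical_order(docs)
    docs = [docs[i] for i in order]
    vocab = build_vocab(docs)
    V = len(vocab)
    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))
    W_sub = None
    sub_of: list[list[int]] | None = None
    if subword_buckets:
        W_sub = (rng.random((subword_buckets, dim)) - 0.5) / dim
        model_tmp = SGNSModel(vocab, W_in, W_out, dim, subword_buckets, W_sub)
        sub_of = [model_tmp.token_ngram_buckets(t) for t in sorted(vocab, key=vocab.get)]
    cum = _negative_table(docs, vocab)
    encoded = [np.array([vocab[t] for t in d], dtype=np.int64) for d in docs]
    total_steps = max(1, epochs * sum(len(d) for d in encoded))
    step = 0
    for _epoch in range(epochs):
        for doc in encoded:
            L = len(doc)
            for i in range(L):
                alpha = lr * max(1e-4, 1.0 - step / total_steps)
                step += 1
                w = int(doc[i])
                span = int(rng.integers(1, window + 1))
                ctx = np.concatenate([doc[max(0, i - span) : i], doc[i + 1 : i + 1 + span]])
                if ctx.size == 0:
                    continue
                if subword_buckets:
                    buckets = sub_of[w]
                    denom = len(buckets) + 1
                    v = (W_in[w] + W_sub[buckets].sum(axis=0)) / denom
                else:
                    v = W_in[w]
                for c in ctx:
                    targets = np.concatenate([[c], _sample_negatives(rng, cum, negatives)])
                    labels = np.zeros(targets.size)
                    labels[0] = 1.0
                    out = W_out[targets]
                    g = (labels - _sigmoid(out @ v)) * alpha
                    grad_v = g @ out
                    W_out[targets] += np.outer(g, v)
                    if subword_buckets:
                        gshare = grad_v / denom
                        W_in[w] += gshare
                        W_sub[buckets] += gshare
                    else:
                        W_in[w] += grad_v
    return SGNSModel(vocab, W_in, W_out, dim, subword_buckets, W_sub)


def train_pv_dbow(
    docs: list[list[str]],
    dim: int = 100,
    epochs: int = 5,
    negatives: int = 5,
    lr: float = 0.025,
    seed: int = 0,
) -> tuple[np.ndarray, SGNSModel, list[int]]:
    """Paragraph-vector (distributed bag of words) training.

    Returns (doc vectors in the *original* document order, model with
    output token matrix, canonical order used internally).
    """
    if not docs or all(not d for d in docs):
        raise ValueError("cannot train embeddings on an empty corpus")
    order = _canonical_order(docs)
    sorted_docs = [docs[i] for i in order]
    vocab = build_vocab(sorted_docs)
    V = len(vocab)
    rng = np.random.default_rng(seed)
    D = (rng.random((len(docs), dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))
    cum = _negative_table(sorted_docs, vocab)
    encoded = [np.array([vocab[t] for t in d], dtype=np.int64) for d in sorted_docs]
    total_steps = max(1, epochs * sum(len(d) for d in encoded))
    step = 0
    for _epoch in range(epochs):
        for di, doc in enumerate(encoded):
            for w in doc:
                alpha = lr * max(1e-4, 1.0 - step / total_steps)
                step += 1
                targets = np.concatenate([[w], _sample_negatives(rng, cum, negatives)])
                labels = np.zeros(targets.size)
                labels[0] = 1.0
                v = D[di]
                out = W_out[targets]
                g = (labels - _sigmoid(out @ v)) * alpha
                W_out[targets] += np.outer(g, v)
                D[di] += g @ out
    model = SGNSModel(vocab, np.zeros((V, dim)), W_out, dim)
    # undo the canonical sort so row i matches input doc i
    unsort = np.empty(len(docs), dtype=int)
    unsort[np.array(order)] = np.arange(len(docs))
    return D[unsort], model, order


def infer_pv_dbow(
    tokens: list[str],
    model: SGNSModel,
    epochs: int = 20,
    negatives: int = 5,
    lr: float = 0.025,
    seed: int = 0,
) -> np.ndarray:
    """Infer a paragraph vector for unseen tokens with frozen token matrix.

    The rng is seeded from (seed, token content) so inference is a pure
    function of the document.
    """
    content = _stable_hash("\x00".join(tokens), 2**31)
    rng = np.random.default_rng((seed, content))
    v = (rng.random(model.dim) - 0.5) / model.dim
    known = np.array([model.vocab[t] for t in tokens if t in model.vocab], dtype=np.int64)
    if known.size == 0:
        return np.zeros(model.dim)
    # uniform negative sampling at inference (the fitted table is not stored)
    V = model.W_out.shape[0]
    total = max(1, epochs * known.size)
    step = 0
    for _epoch in range(epochs):
        for w in known:
            alpha = lr * max(1e-4, 1.0 - step / total)
            step += 1
            targets = np.concatenate([[w], rng.integers(0, V, negatives)])
            labels = np.zeros(targets.size)
            labels[0] = 1.0
            out = model.W_out[targets]
            g = (labels - _sigmoid(out @ v)) * alpha
            v += g @ out
    return v
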