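"""Sequence-as-text feature schemes (the "str_feature" block).

Protein sequences are treated as character strings and encoded with
standard text feature extraction: character n-gram counts, signed
feature hashing, LSA/LDA/PCA decompositions of the n-gram count matrix,
t-SNE (train-only), and mean-pooled skip-gram / subword / paragraph
embeddings over overlapping 3-mer tokens.

The shipped end-to-end pipeline uses signed hashed character 1-3-grams
in D = 1024 buckets (see :func:`default_final_scheme`); the other
schemes are provided for model comparison.  Pretrained transformer
embeddings are not implemented; use ``kind="external"`` to read an
``id -> vector`` TSV produced by any external embedder.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA, LatentDirichletAllocation, TruncatedSVD
from sklearn.feature_extraction.text import CountVectorizer, HashingVectorizer
from sklearn.manifold import TSNE

from . import _embeddings
from .sequence_io import SequenceSet

SCHEME_KINDS = (
    "char_ngram_counts",
    "hashed_ngrams",
    "lsa",
    "lda",
    "pca",
    "tsne",
    "word_embedding_mean",
    "subword_embedding_mean",
    "paragraph_embedding",
)

#: schemes that reduce an n-gram count matrix
_DECOMPOSITIONS = {"lsa", "lda", "pca", "tsne"}
_EMBEDDINGS = {"word_embedding_mean", "subword_embedding_mean", "paragraph_embedding"}


def tokenize(sequence: str, k: int = 3) -> list[str]:
    """Overlapping k-mers, stride 1 (standard bio-NLP tokenization)."""
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


def _as_sequences(data: SequenceSet | Sequence[str]) -> list[str]:
    if isinstance(data, SequenceSet):
        return data.sequences
    return list(data)


class StringScheme(BaseEstimator, TransformerMixin):
    """One fitted string-feature scheme with a fixed output width.

    Parameters
    ----------
    kind:
        One of :data:`SCHEME_KINDS`.
    dim:
        Output dimension for ``hashed_ngrams`` (bucket count) and the
        embedding schemes (vector size).  Decompositions use
        ``n_components`` instead.
    ngram_range:
        Character n-gram range for count/hash based schemes.
    n_components:
        Component/topic count for lsa/lda/pca (t-SNE is fixed 2-D).
    token_k:
        k-mer size used as the embedding token.
    seed:
        Fixes every stochastic scheme.
    """

    def __init__(
        self,
        kind: str = "hashed_ngrams",
        dim: int = 1024,
        ngram_range: tuple[int, int] = (1, 3),
        n_components: Optional[int] = None,
        token_k: int = 3,
        window: int = 5,
        epochs: int = 5,
        seed: int = 0,
    ):
        self.kind = kind
        self.dim = dim
        self.ngram_range = ngram_range
        self.n_components = n_components
        self.token_k = token_k
        self.window = window
        self.epochs = epochs
        self.seed = seed

    # -- helpers ------------------------------------------------------------
    def _default_components(self) -> int:
        return {"lsa": 100, "lda": 50, "pca": 100, "tsne": 2}.get(self.kind, 0)

    def _count_vectorizer(self) -> CountVectorizer:
        return CountVectorizer(
            analyzer="char", ngram_range=tuple(self.ngram_range), lowercase=False
        )

    # -- sklearn API --------------------------------------------------------
    def fit(self, X: SequenceSet | Sequence[str], y=None) -> "StringScheme":
        seqs = _as_sequences(X)
        if not seqs:
            raise ValueError("cannot fit a string scheme on an empty set")
        if self.kind not in SCHEME_KINDS:
            raise ValueError(f"unknown scheme kind {self.kind!r}; choose from {SCHEME_KINDS}")
        if self.kind == "hashed_ngrams":
            self.vectorizer_ = HashingVectorizer(
                analyzer="char",
                ngram_range=tuple(self.ngram_range),
                n_features=self.dim,
                alternate_sign=True,
                norm=None,
                lowercase=False,
            )
            self.width_ = self.dim
            self.names_ = [f"feature_{i}" for i in range(self.dim)]
        elif self.kind == "char_ngram_counts":
            self.vectorizer_ = self._count_vectorizer().fit(seqs)
            vocab = self.vectorizer_.get_feature_names_out()
            self.width_ = len(vocab)
            self.names_ = [f"ngram_{g}" for g in vocab]
        elif self.kind in _DECOMPOSITIONS:
            k = self.n_components or self._default_components()
            if k > len(seqs):
                raise ValueError(
                    f"{self.kind} needs n_components <= n_sequences "
                    f"({k} > {len(seqs)})"
                )
            self.vectorizer_ = self._count_vectorizer().fit(seqs)
            counts = self.vectorizer_.transform(seqs)
            if self.kind == "lsa":
                if k >= counts.shape[1]:
                    raise ValueError(
                        f"lsa needs n_components < vocabulary size ({k} >= {counts.shape[1]})"
                    )
                self.reducer_ = TruncatedSVD(n_components=k, random_state=self.seed)
                self.reducer_.fit(counts)
            elif self.kind == "lda":
                self.reducer_ = LatentDirichletAllocation(
                    n_components=k, random_state=self.seed
                )
                self.reducer_.fit(counts)
            elif self.kind == "pca":
                self.reducer_ = PCA(n_components=k, random_state=self.seed)
                self.reducer_.fit(counts.toarray())
            else:  # tsne: transductive, train-only
                k = 2
                emb = TSNE(
                    n_components=2, random_state=self.seed, init="pca",
                    perplexity=min(30.0, max(2.0, len(seqs) / 4)),
                ).fit_transform(counts.toarray())
                self.train_sequences_ = list(seqs)
                self.train_embedding_ = emb
            self.width_ = k
            self.names_ = [f"{self.kind}_{i}" for i in range(k)]
        else:  # embedding schemes
            docs = [tokenize(s, self.token_k) for s in seqs]
            if self.kind == "paragraph_embedding":
                vecs, model, _ = _embeddings.train_pv_dbow(
                    docs, dim=self.dim, epochs=self.epochs, seed=self.seed
                )
                self.model_ = model
                # memoize training vectors by sequence content so a
                # re-transform of training data is bit-for-bit stable
                self.doc_vectors_ = {s: vecs[i] for i, s in enumerate(seqs)}
            else:
                buckets = 2000 if self.kind == "subword_embedding_mean" else 0
                self.model_ = _embeddings.train_sgns(
                    docs,
                    dim=self.dim,
                    window=self.window,
                    epochs=self.epochs,
                    seed=self.seed,
                    subword_buckets=buckets,
                )
            self.width_ = self.dim
            self.names_ = [f"{self.kind}_{i}" for i in range(self.dim)]
        return self

    def transform(self, X: SequenceSet | Sequence[str]) -> np.ndarray:
        if not hasattr(self, "width_"):
            raise RuntimeError("StringScheme must be fitted before transform")
        seqs = _as_sequences(X)
        if self.kind in ("hashed_ngrams", "char_ngram_counts"):
            return np.asarray(self.vectorizer_.transform(seqs).toarray(), dtype=float)
        if self.kind == "tsne":
            if seqs != self.train_sequences_:
                raise ValueError(
                    "t-SNE is transductive: it can only return the embedding of "
                    "the exact training set, not transform unseen data"
                )
            return np.asarray(self.train_embedding_, dtype=float)
        if self.kind in ("lsa", "lda", "pca"):
            counts = self.vectorizer_.transform(seqs)
            if self.kind == "pca":
                counts = counts.toarray()
            return np.asarray(self.reducer_.transform(counts), dtype=float)
        # embeddings
        rows = []
        for s in seqs:
            toks = tokenize(s, self.token_k)
            if self.kind == "paragraph_embedding":
                cached = self.doc_vectors_.get(s)
                rows.append(
                    cached
                    if cached is not None
                    else _embeddings.infer_pv_dbow(toks, self.model_, seed=self.seed)
                )
            else:
                rows.append(self.model_.doc_mean(toks))
        return np.vstack(rows) if rows else np.empty((0, self.width_))

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.names_, dtype=object)


def fit(scheme: StringScheme, train: SequenceSet | Sequence[str], seed: int) -> StringScheme:
    """Fit a scheme on training sequences only, under a fixed seed."""
    scheme.seed = seed
    return scheme.fit(train)


def transform(scheme: StringScheme, s: SequenceSet | Sequence[str]) -> np.ndarray:
    return scheme.transform(s)


def default_final_scheme() -> StringScheme:
    """The scheme used by the shipped end-to-end pipeline.

    Signed hashed character n-grams, n in {1, 2, 3}, 1024 buckets —
    the pairing that won the model-selection comparison with gradient
    boosting.
    """
    return StringScheme(kind="hashed_ngrams", dim=1024, ngram_range=(1, 3))


def read_external_embeddings(path, ids: Sequence[str]) -> np.ndarray:
    """Read an external ``id<TAB>v1<TAB>v2...`` TSV (e.g. transformer
    embeddings computed elsewhere) aligned to the given ids."""
    table: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            table[parts[0]] = np.asarray([float(x) for x in parts[1:]])
    missing = [i for i in ids if i not in table]
    if missing:
        raise KeyError(f"external embedding file lacks ids: {missing[:5]}")
    return np.vstack([table[i] for i in ids])
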