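"""Skip-gram gene embedding trained on a co-expression pair corpus.

Each co-expressed gene pair is a two-token sentence: with a window of 1,
skip-gram generates both prediction directions from it.  The model assigns
gene ``i`` a vector ``v_i`` (row i of the input matrix W) and defines

    Pr(g_i | g_j) = exp(v_i . v_j) / sum_j' exp(v_i . v_j')

The corpus loss is the negative log-likelihood of all pair occurrences under
this full softmax.  Training at scale uses the standard negative-sampling
surrogate (unigram^0.75 noise distribution, 5 negatives, linearly decaying
learning rate) with separate input/output matrices, exporting the input
matrix; a small-vocabulary exact mode performs full-batch gradient descent
on the tied-weight full-softmax objective directly, which is what the unit
oracles check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.special import expit, log_softmax

from .coexpr import CoexprCorpus

DEFAULT_MIN_FREQUENCY = 5


@dataclass
class GeneVocabulary:
    """Gene inventory with multiplicity-weighted occurrence counts.

    Genes are ordered by descending frequency, ties broken alphabetically,
    so the index <-> gene mapping is deterministic.
    """

    gene_ids: list[str]
    frequency: dict[str, int]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {g: i for i, g in enumerate(self.gene_ids)}
        if len(self.index) != len(self.gene_ids):
            raise ValueError("duplicate genes in vocabulary")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def from_corpus(
        cls, corpus: CoexprCorpus, min_frequency: int = DEFAULT_MIN_FREQUENCY
    ) -> "GeneVocabulary":
        freq = corpus.gene_frequencies()
        kept = {g: n for g, n in freq.items() if n >= min_frequency}
        order = sorted(kept, key=lambda g: (-kept[g], g))
        return cls(gene_ids=order, frequency=kept)


@dataclass
class TrainConfig:
    k: int = 200
    iterations: int = 9  # the grid-search winner at production scale
    min_frequency: int = DEFAULT_MIN_FREQUENCY
    negative_samples: int = 5
    learning_rate_initial: float = 0.025
    learning_rate_final: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.negative_samples < 1:
            raise ValueError("negative_samples must be >= 1")


@dataclass
class GeneEmbedding:
    """Vocabulary plus the d x k input-weight matrix; v_i = W[i]."""

    vocab: GeneVocabulary
    W: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape[0] != len(self.vocab):
            raise ValueError(
                f"W has {self.W.shape[0]} rows for a {len(self.vocab)}-gene vocabulary"
            )
        if not np.all(np.isfinite(self.W)):
            raise ValueError("non-finite embedding weights")

    @property
    def k(self) -> int:
        return self.W.shape[1]

    def vector(self, gene: str) -> np.ndarray:
        try:
            return self.W[self.vocab.index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in embedding vocabulary") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self.vocab.index


def random_embedding(gene_ids: list[str], k: int, seed: int) -> GeneEmbedding:
    """Seeded Gaussian embedding, the null baseline for clusteredness and GGIPNN."""
    rng = np.random.default_rng(seed)
    vocab = GeneVocabulary(gene_ids=list(gene_ids), frequency={g: 0 for g in gene_ids})
    return GeneEmbedding(vocab=vocab, W=rng.standard_normal((len(gene_ids), k)),
                         meta={"mode": "random", "seed": seed})


# ---------------------------------------------------------------------------
# the printed objective: full softmax over the vocabulary


def pair_probability(emb: GeneEmbedding, i: int, j: int) -> float:
    """Full-softmax Pr normalized over the second index: sums to 1 over j."""
    d = len(emb.vocab)
    if d == 0:
        raise ValueError("empty vocabulary")
    scores = emb.W @ emb.W[i]  # v_i . v_j' for all j'
    return float(np.exp(log_softmax(scores))[j])


def _corpus_indices(emb: GeneEmbedding, corpus: CoexprCorpus):
    idx = emb.vocab.index
    rows_a, rows_b, counts = [], [], []
    for (a, b), n in sorted(corpus.pairs.items()):
        if a not in idx:
            raise KeyError(f"gene {a!r} in corpus but not in vocabulary")
        if b not in idx:
            raise KeyError(f"gene {b!r} in corpus but not in vocabulary")
        rows_a.append(idx[a])
        rows_b.append(idx[b])
        counts.append(n)
    return np.array(rows_a, int), np.array(rows_b, int), np.array(counts, float)


def corpus_loss(emb: GeneEmbedding, corpus: CoexprCorpus) -> float:
    """Negative log-likelihood of the corpus under the full softmax.

    Pairs are unordered, so each occurrence contributes the mean of its two
    directional terms: -(log Pr(a|b) + log Pr(b|a)) / 2.  With a uniform
    embedding this reduces to N * log d.
    """
    if not corpus.pairs:
        return 0.0
    ia, ib, n = _corpus_indices(emb, corpus)
    ls = log_softmax(emb.W @ emb.W.T, axis=1)
    return float(-0.5 * np.sum(n * (ls[ia, ib] + ls[ib, ia])))


def corpus_loss_gradient(emb: GeneEmbedding, corpus: CoexprCorpus) -> np.ndarray:
    """Analytic gradient of corpus_loss w.r.t. the tied weight matrix W."""
    d = len(emb.vocab)
    ia, ib, n = _corpus_indices(emb, corpus)
    P = np.exp(log_softmax(emb.W @ emb.W.T, axis=1))
    # G = dL/dS for S = W W^T treated elementwise
    G = np.zeros((d, d))
    w = np.zeros(d)
    np.add.at(w, ia, 0.5 * n)
    np.add.at(w, ib, 0.5 * n)
    G += w[:, None] * P
    np.add.at(G, (ia, ib), -0.5 * n)
    np.add.at(G, (ib, ia), -0.5 * n)
    return G @ emb.W + G.T @ emb.W


# ---------------------------------------------------------------------------
# training


def _init_input_weights(rng: np.random.Generator, d: int, k: int) -> np.ndarray:
    # word2vec-style init: small uniform input weights
    return rng.uniform(-0.5 / k, 0.5 / k, size=(d, k))


def _filtered_events(
    corpus: CoexprCorpus, vocab: GeneVocabulary
) -> np.ndarray:
    """Occurrence-level (a, b) index array, one row per pair occurrence."""
    idx = vocab.index
    rows = []
    for (a, b), n in sorted(corpus.pairs.items()):
        if a in idx and b in idx:
            rows.extend([(idx[a], idx[b])] * n)
    return np.array(rows, dtype=np.int64).reshape(-1, 2)


def train_checkpoints(
    corpus: CoexprCorpus, cfg: TrainConfig
) -> Iterator[tuple[int, GeneEmbedding]]:
    """Negative-sampling skip-gram; yields the embedding after each epoch.

    Single-threaded and fully seeded: the same config reproduces the same
    weights bit for bit.  Every epoch re-shuffles the occurrence sequence
    (never the multiset), and the learning rate decays linearly over all
    scheduled occurrences.  Epoch 0 (the untrained initialization) is
    yielded first so callers can measure training progress against it.
    """
    vocab = GeneVocabulary.from_corpus(corpus, cfg.min_frequency)
    if not len(vocab):
        raise ValueError(
            f"no gene reaches min_frequency={cfg.min_frequency}; corpus too sparse"
        )
    events = _filtered_events(corpus, vocab)
    if events.size == 0:
        raise ValueError(
            f"no pair survives min_frequency={cfg.min_frequency} filtering"
        )
    d, k = len(vocab), cfg.k
    rng = np.random.default_rng(cfg.seed)
    W_in = _init_input_weights(rng, d, k)
    W_out = np.zeros((d, k))

    counts = np.array([vocab.frequency[g] for g in vocab.gene_ids], dtype=float)
    noise = counts**0.75
    noise /= noise.sum()

    def snapshot(epoch: int) -> GeneEmbedding:
        return GeneEmbedding(
            vocab=vocab,
            W=W_in.copy(),
            meta={
                "k": k,
                "iterations": epoch,
                "min_frequency": cfg.min_frequency,
                "negative_samples": cfg.negative_samples,
                "seed": cfg.seed,
                "objective": "skip-gram negative sampling",
            },
        )

    yield 0, snapshot(0)
    n_occ = events.shape[0]
    total = cfg.iterations * n_occ
    lr0, lr1 = cfg.learning_rate_initial, cfg.learning_rate_final
    processed = 0
    for epoch in range(1, cfg.iterations + 1):
        order = rng.permutation(n_occ)
        # negatives for both directions of every occurrence, drawn up front
        negs = rng.choice(d, size=(n_occ, 2, cfg.negative_samples), p=noise)
        for t, e in enumerate(order):
            lr = max(lr1, lr0 * (1.0 - processed / total))
            a, b = events[e]
            for direction, (center, context) in enumerate(((a, b), (b, a))):
                targets = np.concatenate(([context], negs[e, direction]))
                labels = np.zeros(targets.shape[0])
                labels[0] = 1.0
                # a sampled negative equal to the context is skipped
                keep = np.ones(targets.shape[0], bool)
                keep[1:] = targets[1:] != context
                targets, labels = targets[keep], labels[keep]
                v = W_in[center]
                U = W_out[targets]
                g = (labels - expit(U @ v)) * lr
                dv = g @ U
                np.add.at(W_out, targets, np.outer(g, v))
                W_in[center] += dv
            processed += 1
        yield epoch, snapshot(epoch)


def train(corpus: CoexprCorpus, cfg: TrainConfig) -> GeneEmbedding:
    """Train for cfg.iterations epochs and return the final embedding."""
    emb = None
    for _, emb in train_checkpoints(corpus, cfg):
        pass
    assert emb is not None
    return emb


def train_exact(
    corpus: CoexprCorpus,
    cfg: TrainConfig,
    *,
    steps: int = 300,
    step_size: float = 1.0,
) -> GeneEmbedding:
    """Gradient descent on the exact tied-weight full-softmax objective.

    Only sensible for small vocabularies (the softmax is O(d^2) per step).
    Uses backtracking on the mean per-occurrence loss so every accepted step
    decreases the objective.
    """
    vocab = GeneVocabulary.from_corpus(corpus, cfg.min_frequency)
    if not len(vocab):
        raise ValueError(
            f"no gene reaches min_frequency={cfg.min_frequency}; corpus too sparse"
        )
    filtered = CoexprCorpus()
    for (a, b), n in corpus.pairs.items():
        if a in vocab.index and b in vocab.index:
            filtered.pairs[(a, b)] = n
    n_occ = filtered.total_occurrences
    rng = np.random.default_rng(cfg.seed)
    W = _init_input_weights(rng, len(vocab), cfg.k)
    emb = GeneEmbedding(vocab=vocab, W=W, meta={"objective": "exact full softmax"})
    loss = corpus_loss(emb, filtered) / n_occ
    lr = step_size
    for _ in range(steps):
        grad = corpus_loss_gradient(emb, filtered) / n_occ
        while lr > 1e-8:
            trial = GeneEmbedding(vocab=vocab, W=emb.W - lr * grad, meta=emb.meta)
            trial_loss = corpus_loss(trial, filtered) / n_occ
            if trial_loss <= loss:
                emb, loss = trial, trial_loss
                lr *= 1.2  # cautious growth after an accepted step
                break
            lr *= 0.5
        else:
            break
    emb.meta.update({"k": cfg.k, "steps": steps, "seed": cfg.seed})
    return emb
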