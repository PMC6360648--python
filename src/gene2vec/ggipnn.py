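"""Gene-pair functional-interaction prediction (GGIPNN).

Positive pairs share an experimentally supported biological-process
annotation (evidence IDA/IMP/IPI/IGI/TAS, over-general terms and the first
three hierarchy levels excluded); negative pairs have disjoint
descendant-closed annotation sets.  Genes — not pairs — are split 7:1:2 into
train/validation/test, and a pair survives only if both endpoints share a
split, so the classifier can never score a gene it saw during training.

The classifier maps each gene of a pair to its embedding vector through a
shared lookup matrix, concatenates the two vectors, and passes them through
fully connected layers of width 100, 100 and 10 (ReLU throughout, dropout
0.5 on the first two), ending in a 2-unit softmax trained with mean
cross-entropy.  The embedding matrix may be pretrained or random, and frozen
or trainable; comparing those four regimes on gene-disjoint test pairs is
the point of the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple

import numpy as np
from scipy.stats import rankdata

from .coexpr import Pair, canonical_pair
from .embed import GeneEmbedding

logger = logging.getLogger(__name__)

DEFAULT_EVIDENCE_CODES = frozenset({"IDA", "IMP", "IPI", "IGI", "TAS"})
# highly over-represented process terms excluded from positive construction
DEFAULT_EXCLUDED_TERMS = frozenset(
    {"GO:0007165", "GO:0006468", "GO:0046777", "GO:0006470"}
)
DEFAULT_EXCLUDED_MAX_LEVEL = 3


class AnnotationRecord(NamedTuple):
    gene: str
    term: str
    evidence: str


@dataclass
class AnnotationTable:
    """Gene -> term annotations plus the term hierarchy.

    Term levels are minimum depth from the root (root = level 0) over all
    parent paths.  The hierarchy must be acyclic.
    """

    records: list[AnnotationRecord]
    edges: list[tuple[str, str]]  # (parent, child)
    root: str | None = None
    term_levels: dict[str, int] = field(init=False)
    children: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        self.records = [AnnotationRecord(*r) for r in self.records]
        self.children = {}
        parents: dict[str, set[str]] = {}
        terms = set()
        for parent, child in self.edges:
            self.children.setdefault(parent, set()).add(child)
            parents.setdefault(child, set()).add(parent)
            terms.update((parent, child))
        if self.root is None:
            roots = [t for t in terms if t not in parents]
            if len(roots) != 1:
                raise ValueError(
                    f"hierarchy has {len(roots)} roots; pass root= explicitly"
                )
            self.root = roots[0]
        self.term_levels = self._bfs_levels()

    def _bfs_levels(self) -> dict[str, int]:
        levels = {self.root: 0}
        frontier = [self.root]
        seen_edges = 0
        while frontier:
            nxt = []
            for t in frontier:
                for c in self.children.get(t, ()):
                    seen_edges += 1
                    if c not in levels:  # min depth: first BFS visit
                        levels[c] = levels[t] + 1
                        nxt.append(c)
            frontier = nxt
            if seen_edges > 4 * len(self.edges) + 4:
                raise ValueError("term hierarchy contains a cycle")
        # explicit cycle check: every edge's child must be reachable & deeper
        reachable = set(levels)
        self._assert_acyclic(reachable)
        return levels

    def _assert_acyclic(self, reachable: set[str]) -> None:
        state: dict[str, int] = {}

        def visit(t: str, stack: list[str]) -> None:
            state[t] = 1
            for c in self.children.get(t, ()):
                if state.get(c) == 1:
                    raise ValueError(f"term hierarchy contains a cycle through {c}")
                if c not in state:
                    visit(c, stack + [c])
            state[t] = 2

        for t in reachable:
            if t not in state:
                visit(t, [t])

    def descendants(self, term: str) -> frozenset[str]:
        """Descendant closure of a term, including the term itself."""
        out = {term}
        frontier = [term]
        while frontier:
            t = frontier.pop()
            for c in self.children.get(t, ()):
                if c not in out:
                    out.add(c)
                    frontier.append(c)
        return frozenset(out)

    def genes(self) -> list[str]:
        return sorted({r.gene for r in self.records})


@dataclass(frozen=True)
class PositiveFilters:
    evidence_codes: frozenset[str] = DEFAULT_EVIDENCE_CODES
    excluded_terms: frozenset[str] = DEFAULT_EXCLUDED_TERMS
    excluded_max_level: int = DEFAULT_EXCLUDED_MAX_LEVEL


def positive_pairs(
    ann: AnnotationTable, filters: PositiveFilters = PositiveFilters()
) -> set[Pair]:
    """Pairs of genes sharing a retained (specific, experimental) term."""
    orphans = sorted(
        {r.term for r in ann.records} - set(ann.term_levels)
    )
    if orphans:
        raise ValueError(
            f"annotation terms unreachable from root {ann.root!r} "
            f"(no level): {', '.join(orphans)}"
        )
    term_genes: dict[str, set[str]] = {}
    for gene, term, evidence in ann.records:
        if evidence not in filters.evidence_codes:
            continue
        if term in filters.excluded_terms:
            continue
        if ann.term_levels[term] <= filters.excluded_max_level:
            continue
        term_genes.setdefault(term, set()).add(gene)
    pairs: set[Pair] = set()
    for genes in term_genes.values():
        ordered = sorted(genes)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                pairs.add(canonical_pair(a, b))
    return pairs


def negative_pairs(ann: AnnotationTable) -> set[Pair]:
    """Pairs whose descendant-closed annotation sets are disjoint.

    All annotations count here, regardless of evidence or level: two genes
    are unrelated only if no term of one is a term — or a descendant of a
    term — of the other.
    """
    gene_closure: dict[str, frozenset[str]] = {}
    for gene, term, _ in ann.records:
        gene_closure[gene] = gene_closure.get(gene, frozenset()) | ann.descendants(term)
    genes = sorted(gene_closure)
    pairs: set[Pair] = set()
    for i, a in enumerate(genes):
        ca = gene_closure[a]
        for b in genes[i + 1 :]:
            if ca.isdisjoint(gene_closure[b]):
                pairs.add(canonical_pair(a, b))
    return pairs


SplitName = Literal["train", "val", "test"]
SPLITS: tuple[SplitName, ...] = ("train", "val", "test")


@dataclass
class PairDataset:
    """Labeled gene pairs with a gene-disjoint train/val/test partition."""

    pairs: list[tuple[str, str, int]]
    split: dict[str, SplitName]

    def pairs_in(self, name: SplitName) -> list[tuple[str, str, int]]:
        return [
            (a, b, y)
            for a, b, y in self.pairs
            if self.split.get(a) == name and self.split.get(b) == name
        ]

    def split_sizes(self) -> dict[SplitName, int]:
        return {name: len(self.pairs_in(name)) for name in SPLITS}

    def genes_in(self, name: SplitName) -> set[str]:
        return {g for g, s in self.split.items() if s == name}


def gene_disjoint_split(
    pairs: Iterable[tuple[str, str, int]],
    proportions: tuple[float, float, float] = (7, 1, 2),
    seed: int = 0,
) -> PairDataset:
    """Partition genes ~proportions; keep pairs with both endpoints co-resident.

    Split sizes use largest-remainder rounding, so 10 genes at 7:1:2 come out
    exactly 7/1/2.  Pairs spanning two splits are dropped — that is the
    device preventing the classifier from memorizing gene identities.
    """
    pairs = [(a, b, int(y)) for a, b, y in pairs]
    if any(p <= 0 for p in proportions):
        raise ValueError("proportions must be positive")
    genes = sorted({g for a, b, _ in pairs for g in (a, b)})
    rng = np.random.default_rng(seed)
    order = [genes[i] for i in rng.permutation(len(genes))]
    total = sum(proportions)
    n = len(genes)
    quota = [p * n / total for p in proportions]
    sizes = [int(q) for q in quota]
    remainders = sorted(
        range(3), key=lambda i: (quota[i] - sizes[i], -i), reverse=True
    )
    for i in remainders[: n - sum(sizes)]:
        sizes[i] += 1
    split: dict[str, SplitName] = {}
    start = 0
    for name, size in zip(SPLITS, sizes):
        for g in order[start : start + size]:
            split[g] = name
        start += size
    empties = [name for name, size in zip(SPLITS, sizes) if size == 0]
    if empties:
        raise ValueError(
            f"split(s) {empties} received no genes; supply more genes "
            f"or different proportions"
        )
    return PairDataset(pairs=pairs, split=split)


def build_pair_dataset(
    positives: set[Pair],
    negatives: set[Pair],
    *,
    proportions: tuple[float, float, float] = (7, 1, 2),
    seed: int = 0,
) -> PairDataset:
    """Balance by downsampling negatives to |positives|, then split genes."""
    if not positives:
        raise ValueError("no positive pairs")
    overlap = positives & negatives
    if overlap:
        raise ValueError(f"{len(overlap)} pairs are both positive and negative")
    rng = np.random.default_rng(seed)
    neg_sorted = sorted(negatives)
    if len(neg_sorted) > len(positives):
        chosen = rng.choice(len(neg_sorted), size=len(positives), replace=False)
        neg_sorted = [neg_sorted[i] for i in sorted(chosen)]
    labeled = [(a, b, 1) for a, b in sorted(positives)] + [
        (a, b, 0) for a, b in neg_sorted
    ]
    return gene_disjoint_split(labeled, proportions, seed=seed)


# ---------------------------------------------------------------------------
# the neural network


@dataclass
class GGIPNNConfig:
    hidden_dims: tuple[int, int, int] = (100, 100, 10)
    dropout: float = 0.5
    embedding_trainable: bool = False
    embedding_dim: int = 200  # used only when no pretrained embedding is given
    epochs: int = 20
    batch_size: int = 256
    learning_rate: float = 1e-3
    patience: int = 5
    seed: int = 0


class GGIPNN:
    """Feed-forward pair classifier over a shared gene-embedding lookup.

    Hand-rolled numpy implementation (Adam, inverted dropout, Glorot-uniform
    init) so that single-threaded runs are bit-reproducible under a seed and
    the frozen-embedding contract can be asserted exactly.
    """

    def __init__(self, gene_ids: list[str], k: int, cfg: GGIPNNConfig):
        self.cfg = cfg
        self.gene_index = {g: i for i, g in enumerate(gene_ids)}
        self.k = k
        rng = np.random.default_rng(cfg.seed)
        self.E = rng.uniform(-0.05, 0.05, size=(len(gene_ids), k))
        dims = [2 * k, *cfg.hidden_dims, 2]
        self.weights, self.biases = [], []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._rng = rng
        self._adam_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- plumbing

    def set_pretrained(self, emb: GeneEmbedding) -> None:
        missing = [g for g in self.gene_index if g not in emb]
        if missing:
            raise ValueError(
                f"gene(s) without an embedding row: {', '.join(sorted(missing)[:5])}"
                + ("..." if len(missing) > 5 else "")
            )
        for g, i in self.gene_index.items():
            self.E[i] = emb.vector(g)

    def _rows(self, pairs: list[tuple[str, str, int]]):
        try:
            ia = np.array([self.gene_index[a] for a, _, _ in pairs])
            ib = np.array([self.gene_index[b] for _, b, _ in pairs])
        except KeyError as exc:
            raise ValueError(f"gene without embedding row: {exc.args[0]!r}") from None
        y = np.array([lab for _, _, lab in pairs], dtype=int)
        return ia, ib, y

    def _forward(self, ia, ib, train: bool):
        X = np.concatenate([self.E[ia], self.E[ib]], axis=1)
        cache = {"X": X, "ia": ia, "ib": ib, "h": [], "mask": []}
        h = X
        n_hidden = len(self.cfg.hidden_dims)
        for layer in range(n_hidden):
            z = h @ self.weights[layer] + self.biases[layer]
            h = np.maximum(z, 0.0)
            if train and layer < 2 and self.cfg.dropout > 0:
                keep = 1.0 - self.cfg.dropout
                mask = (self._rng.random(h.shape) < keep) / keep
                h = h * mask
                cache["mask"].append(mask)
            else:
                cache["mask"].append(None)
            cache["h"].append(h)
        logits = h @ self.weights[-1] + self.biases[-1]
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        cache["p"] = p
        return p, cache

    def _adam(self, key: int, param: np.ndarray, grad: np.ndarray) -> None:
        b1, b2, eps = 0.9, 0.999, 1e-8
        m, v = self._adam_state.get(key, (np.zeros_like(param), np.zeros_like(param)))
        m = b1 * m + (1 - b1) * grad
        v = b2 * v + (1 - b2) * grad**2
        self._adam_state[key] = (m, v)
        mhat = m / (1 - b1**self._adam_t)
        vhat = v / (1 - b2**self._adam_t)
        param -= self.cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

    def _backward(self, cache, y) -> float:
        p = cache["p"]
        n = len(y)
        loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-12)))
        delta = p.copy()
        delta[np.arange(n), y] -= 1.0
        delta /= n
        self._adam_t += 1
        grads_w, grads_b = [], []
        hs = [cache["X"]] + cache["h"]
        for layer in reversed(range(len(self.weights))):
            h_in = hs[layer]
            grads_w.append(h_in.T @ delta)
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = delta @ self.weights[layer].T
                mask = cache["mask"][layer - 1]
                if mask is not None:
                    delta = delta * mask
                delta = delta * (hs[layer] > 0)
            else:
                delta_X = delta @ self.weights[0].T
        grads_w.reverse()
        grads_b.reverse()
        for layer, (gw, gb) in enumerate(zip(grads_w, grads_b)):
            self._adam(2 * layer, self.weights[layer], gw)
            self._adam(2 * layer + 1, self.biases[layer], gb)
        if self.cfg.embedding_trainable:
            gE = np.zeros_like(self.E)
            np.add.at(gE, cache["ia"], delta_X[:, : self.k])
            np.add.at(gE, cache["ib"], delta_X[:, self.k :])
            self._adam(-1, self.E, gE)
        return loss

    # -- public API

    def fit(self, ds: PairDataset) -> list[float]:
        """Train on the train split; early-stop on validation AUC.

        Returns the per-epoch mean training loss curve.
        """
        train_pairs = ds.pairs_in("train")
        val_pairs = ds.pairs_in("val")
        if not train_pairs:
            raise ValueError("empty training split")
        ia, ib, y = self._rows(train_pairs)
        n = len(y)
        losses: list[float] = []
        best_auc, best_state, stall = -np.inf, None, 0
        for _epoch in range(self.cfg.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.cfg.batch_size):
                sel = order[start : start + self.cfg.batch_size]
                _, cache = self._forward(ia[sel], ib[sel], train=True)
                epoch_loss += self._backward(cache, y[sel]) * len(sel)
            losses.append(epoch_loss / n)
            if val_pairs:
                labels = [lab for _, _, lab in val_pairs]
                if len(set(labels)) == 2:
                    auc = auc_score(labels, self.predict_scores(val_pairs))
                    if auc > best_auc:
                        best_auc, stall = auc, 0
                        best_state = self._snapshot()
                    else:
                        stall += 1
                        if stall >= self.cfg.patience:
                            break
        if best_state is not None:
            self._restore(best_state)
        return losses

    def _snapshot(self):
        return (
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.E.copy(),
        )

    def _restore(self, state) -> None:
        ws, bs, E = state
        self.weights = [w.copy() for w in ws]
        self.biases = [b.copy() for b in bs]
        self.E = E.copy()

    def predict_scores(self, pairs: list[tuple[str, str, int]]) -> np.ndarray:
        """Positive-class softmax probability for each pair."""
        ia, ib, _ = self._rows(pairs)
        p, _ = self._forward(ia, ib, train=False)
        return p[:, 1]


def train_ggipnn(
    ds: PairDataset,
    emb: GeneEmbedding | None,
    cfg: GGIPNNConfig = GGIPNNConfig(),
) -> GGIPNN:
    """Build and fit the pair classifier.

    emb=None draws a random embedding matrix (seeded) of cfg.embedding_dim;
    with cfg.embedding_trainable=False the lookup matrix is asserted to be
    bitwise unchanged by training.
    """
    genes = sorted(ds.split)
    k = emb.k if emb is not None else cfg.embedding_dim
    model = GGIPNN(genes, k, cfg)
    if emb is not None:
        model.set_pretrained(emb)
    before = model.E.copy()
    model.fit(ds)
    if not cfg.embedding_trainable:
        assert np.array_equal(model.E, before), "frozen embedding was modified"
    return model


def auc_score(labels: Iterable[int], scores: Iterable[float]) -> float:
    """Mann-Whitney AUC of the positive class, midranks for ties."""
    y = np.asarray(list(labels), dtype=int)
    s = np.asarray(list(scores), dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)  # midranks
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_auc(model: GGIPNN, ds: PairDataset, split: SplitName = "test") -> float:
    """AUC of the model's positive-class score on one split."""
    pairs = ds.pairs_in(split)
    if not pairs:
        raise ValueError(f"empty {split} split")
    return auc_score([y for _, _, y in pairs], model.predict_scores(pairs))
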