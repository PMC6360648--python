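"""From per-study expression matrices to a merged co-expression pair corpus.

Each study is preprocessed independently (log2 if needed, then quantile
normalization), probes are collapsed to genes by maximum variance, and every
unordered gene pair whose Pearson correlation meets the threshold (default
0.9, inclusive) is kept.  Pairs from all studies are merged into a multiset:
a pair's multiplicity is the number of studies in which it passed, and that
multiset is the training corpus for the embedding.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_PCC_THRESHOLD = 0.9
DEFAULT_MIN_SAMPLES = 30

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Unordered pair as a sorted tuple; self-pairs are a bug upstream."""
    if a == b:
        raise ValueError(f"self-pair for gene {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class ExpressionDataset:
    """One study's genes x samples matrix after preprocessing."""

    dataset_id: str
    gene_ids: list[str]
    values: np.ndarray  # shape (g, s), log2 scale

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")

    @property
    def sample_count(self) -> int:
        return self.values.shape[1]

    def check_min_samples(self, min_samples: int = DEFAULT_MIN_SAMPLES) -> None:
        if self.sample_count < min_samples:
            raise ValueError(
                f"dataset {self.dataset_id}: {self.sample_count} samples "
                f"< required minimum {min_samples}"
            )


@dataclass
class ProbeTable:
    """One probe's intensity profile, mapped to exactly one gene."""

    probe_id: str
    gene_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class CoexprCorpus:
    """Multiset of unordered co-expressed gene pairs, merged across datasets."""

    pairs: Counter[Pair] = field(default_factory=Counter)
    source_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_occurrences(self) -> int:
        return sum(self.pairs.values())

    def gene_frequencies(self) -> Counter[str]:
        """Multiplicity-weighted occurrence count per gene."""
        freq: Counter[str] = Counter()
        for (a, b), n in self.pairs.items():
            freq[a] += n
            freq[b] += n
        return freq


def preprocess(
    raw: np.ndarray, *, linear_scale: bool = True, dataset_id: str = "?"
) -> np.ndarray:
    """log2 (if linear-scale) then quantile-normalize a probes x samples matrix.

    Quantile normalization maps each column's sorted values onto the row means
    of the column-sorted matrix, so afterwards every column holds exactly the
    same value multiset. Ties within a column are broken by row order (stable
    sort), which keeps the multiset contract exact; tied inputs may therefore
    receive adjacent, not identical, normalized values.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a 2-D probes x samples matrix")
    if linear_scale:
        bad = np.argwhere(raw <= 0)
        if bad.size:
            p, s = bad[0]
            raise ValueError(
                f"dataset {dataset_id}: non-positive value {raw[p, s]!r} at "
                f"probe row {p}, sample column {s}; cannot log-transform "
                f"(pass linear_scale=False for data already on log scale)"
            )
        mat = np.log2(raw)
    else:
        mat = raw.copy()
    if mat.shape[1] == 1:
        return mat
    return quantile_normalize(mat)


def quantile_normalize(mat: np.ndarray) -> np.ndarray:
    """Standard quantile normalization over columns, stable-rank ties."""
    ref = np.sort(mat, axis=0).mean(axis=1)  # reference distribution
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        order = np.argsort(mat[:, j], kind="stable")
        out[order, j] = ref
    return out


def collapse_probes(probes: list[ProbeTable], dataset_id: str = "?") -> ExpressionDataset:
    """One row per gene: keep the probe with the largest sample variance.

    Ties broken by lexicographically smallest probe_id, so the result does not
    depend on input order.
    """
    by_gene: dict[str, ProbeTable] = {}
    for p in probes:
        if p.values.size < 2:
            raise ValueError(f"probe {p.probe_id}: need >= 2 samples")
        cur = by_gene.get(p.gene_id)
        if cur is None:
            by_gene[p.gene_id] = p
            continue
        v_new, v_cur = p.values.var(ddof=1), cur.values.var(ddof=1)
        if v_new > v_cur or (v_new == v_cur and p.probe_id < cur.probe_id):
            by_gene[p.gene_id] = p
    genes = sorted(by_gene)
    values = np.vstack([by_gene[g].values for g in genes]) if genes else np.empty((0, 0))
    return ExpressionDataset(dataset_id=dataset_id, gene_ids=genes, values=values)


def coexpr_pairs(
    ds: ExpressionDataset, threshold: float = DEFAULT_PCC_THRESHOLD
) -> set[Pair]:
    """All unordered gene pairs with Pearson correlation >= threshold.

    Zero-variance rows are excluded (their PCC is undefined) with a warning.
    """
    if not -1 < threshold <= 1:
        raise ValueError(f"threshold {threshold} outside (-1, 1]")
    if len(ds.gene_ids) < 2:
        raise ValueError("need at least 2 genes")
    variances = ds.values.var(axis=1, ddof=1)
    keep = variances > 0
    n_flat = int((~keep).sum())
    if n_flat:
        flat = [g for g, k in zip(ds.gene_ids, keep) if not k]
        logger.warning(
            "dataset %s: skipping %d zero-variance gene(s) (PCC undefined): %s%s",
            ds.dataset_id,
            n_flat,
            ", ".join(flat[:5]),
            "..." if n_flat > 5 else "",
        )
    genes = [g for g, k in zip(ds.gene_ids, keep) if k]
    if len(genes) < 2:
        return set()
    corr = np.corrcoef(ds.values[keep])
    ii, jj = np.nonzero(np.triu(corr >= threshold, k=1))
    return {canonical_pair(genes[i], genes[j]) for i, j in zip(ii, jj)}


def merge_corpora(per_dataset: dict[str, set[Pair]]) -> CoexprCorpus:
    """Merge per-dataset pair sets; multiplicity = number of contributing sets."""
    corpus = CoexprCorpus()
    for dataset_id, pairs in per_dataset.items():
        corpus.source_counts[dataset_id] = len(pairs)
        for pair in pairs:
            corpus.pairs[canonical_pair(*pair)] += 1
    return corpus


def build_corpus(
    datasets: list[ExpressionDataset],
    *,
    threshold: float = DEFAULT_PCC_THRESHOLD,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> CoexprCorpus:
    """Full pipeline from preprocessed datasets to merged corpus."""
    per_dataset = {}
    for ds in datasets:
        ds.check_min_samples(min_samples)
        per_dataset[ds.dataset_id] = coexpr_pairs(ds, threshold)
    return merge_corpora(per_dataset)
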