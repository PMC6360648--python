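"""2-D gene co-expression map and tissue-specificity overlays.

The map is produced by the usual two-stage pipeline: PCA down to 50
components (a plain rotation when the embedding dimension is already <= 50),
then Barnes-Hut t-SNE to two dimensions.  Tissue specificity is a per-gene
z-score of a tissue's mean expression against the gene's cross-tissue mean,
using the sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .embed import GeneEmbedding


@dataclass
class MapCoordinates:
    gene_ids: list[str]
    xy: np.ndarray  # (g, 2)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (len(self.gene_ids), 2):
            raise ValueError("coordinate matrix must be genes x 2")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("non-finite map coordinates")


def reduce_and_map(
    emb: GeneEmbedding,
    *,
    pca_dim: int = 50,
    perplexity: float = 30.0,
    learning_rate: float = 200.0,
    iterations: int = 1000,
    seed: int = 0,
) -> MapCoordinates:
    """PCA (centered, top components) then seeded Barnes-Hut t-SNE to 2-D.

    iterations defaults to a test-scale 1000; production maps of a full
    genome-scale embedding use far more (1e5) for stability.
    """
    n = len(emb.vocab)
    if n <= 3 * perplexity:
        raise ValueError(
            f"{n} genes <= 3 x perplexity ({perplexity}); t-SNE needs more "
            f"points than 3 x perplexity — lower perplexity or embed more genes"
        )
    X = emb.W
    n_comp = min(pca_dim, X.shape[1], n)
    X50 = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate=learning_rate,
        max_iter=max(250, iterations),
        method="barnes_hut",
        angle=0.5,
        init="pca",
        random_state=seed,
        n_jobs=1,
    )
    xy = tsne.fit_transform(X50)
    return MapCoordinates(gene_ids=list(emb.vocab.gene_ids), xy=xy)


@dataclass
class TissueSpecificity:
    tissues: list[str]
    gene_ids: list[str]
    z: np.ndarray  # (g, t)
    flat_genes: list[str] = field(default_factory=list)  # zero-sd rows, z == 0


def tissue_zscores(
    mean_expr: np.ndarray,
    gene_ids: list[str],
    tissues: list[str],
    *,
    log_transform: bool = True,
) -> TissueSpecificity:
    """Per-gene z-score of tissue means against the gene's cross-tissue mean.

    z[g, t] = (x[g, t] - mean_t x[g, .]) / sd_t x[g, .]  with sample sd
    (ddof=1).  Genes flat across tissues get an all-zero row and are listed
    in flat_genes.  With log_transform, log2(x + 1) is applied first.
    """
    x = np.asarray(mean_expr, dtype=float)
    if x.ndim != 2 or x.shape != (len(gene_ids), len(tissues)):
        raise ValueError("mean_expr must be genes x tissues")
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues for a z-score")
    if log_transform:
        x = np.log2(x + 1.0)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd
    z[flat] = 0.0
    return TissueSpecificity(
        tissues=list(tissues),
        gene_ids=list(gene_ids),
        z=z,
        flat_genes=[g for g, f in zip(gene_ids, flat) if f],
    )
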