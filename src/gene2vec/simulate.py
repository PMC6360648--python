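"""Synthetic expression compendia with planted co-expression modules.

The generator emulates the statistical structure the rest of the pipeline
assumes about a microarray compendium: several studies (datasets) measured
over the same gene universe, where groups of genes ("modules") share a
per-sample latent activity and the rest is independent noise.  Under this
single-factor Gaussian model the expected Pearson correlation between two
genes of the same module has the closed form

    E[PCC] = latent_strength**2 / (latent_strength**2 + noise_sd**2)

which makes threshold-based pair selection analytically checkable.  Module
memberships double as pathway files (GMT) and as a miniature functional
annotation table, so the tuning statistic and the pair classifier can be
exercised end to end without any external database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coexpr import ExpressionDataset
from .ggipnn import AnnotationRecord, AnnotationTable
from .tune import PathwayCollection

# noise_sd giving expected within-module PCC = 24/25 = 0.96 at unit latent strength
_DEFAULT_NOISE_SD = math.sqrt(1.0 / 24.0)


@dataclass
class ModulePlan:
    """Blueprint for one synthetic compendium.

    Genes not covered by ``module_sizes`` are background genes: pure noise,
    uncorrelated with everything.
    """

    n_genes: int = 200
    module_sizes: tuple[int, ...] = (40, 40, 40, 40)
    n_datasets: int = 3
    samples_per_dataset: int = 100
    latent_strength: float = 1.0
    noise_sd: float = _DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if self.latent_strength <= 0:
            raise ValueError("latent_strength must be > 0")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def module_members(self) -> dict[str, list[str]]:
        """Module name -> member gene ids; background genes belong to none."""
        genes = self.gene_ids
        out: dict[str, list[str]] = {}
        start = 0
        for m, size in enumerate(self.module_sizes):
            out[f"module_{m}"] = genes[start : start + size]
            start += size
        return out

    def expected_within_module_pcc(self) -> float:
        s2 = self.latent_strength**2
        return s2 / (s2 + self.noise_sd**2)


def _dataset_rngs(plan: ModulePlan) -> list[np.random.Generator]:
    # one independent, reproducible stream per dataset
    seqs = np.random.SeedSequence(plan.seed).spawn(plan.n_datasets)
    return [np.random.default_rng(s) for s in seqs]


def simulate_compendium(plan: ModulePlan) -> list[ExpressionDataset]:
    """Draw one expression matrix per dataset under the planted-module model.

    For each dataset and module m, a latent factor f_m ~ N(0, 1) is drawn per
    sample; a member gene's expression is latent_strength * f_m plus
    N(0, noise_sd**2) noise. Background genes are N(0, 1) noise. Values are on
    log scale already (the model is additive), so downstream preprocessing
    should be run with linear_scale=False.
    """
    datasets: list[ExpressionDataset] = []
    members = plan.module_members()
    gene_index = {g: i for i, g in enumerate(plan.gene_ids)}
    for d, rng in enumerate(_dataset_rngs(plan)):
        values = rng.normal(0.0, 1.0, size=(plan.n_genes, plan.samples_per_dataset))
        # module genes: shared latent + scaled-down private noise
        for m, genes in enumerate(members.values()):
            factor = rng.normal(0.0, 1.0, size=plan.samples_per_dataset)
            rows = [gene_index[g] for g in genes]
            noise = rng.normal(0.0, plan.noise_sd, size=(len(rows), plan.samples_per_dataset))
            values[rows, :] = plan.latent_strength * factor[None, :] + noise
        datasets.append(
            ExpressionDataset(
                dataset_id=f"sim{d:02d}",
                gene_ids=list(plan.gene_ids),
                values=values,
            )
        )
    return datasets


def modules_to_pathways(plan: ModulePlan) -> PathwayCollection:
    """Module memberships as a pathway collection (one set per module)."""
    if plan.n_modules < 2:
        raise ValueError("need >= 2 modules to build a pathway collection")
    max_size = max(plan.module_sizes)
    return PathwayCollection.from_dict(plan.module_members(), max_size=max_size)


def modules_to_annotations(plan: ModulePlan) -> AnnotationTable:
    """Module memberships as a toy functional annotation table.

    Each module becomes one term at level 5 (under a chain of four synthetic
    ancestors from the root), annotated with experimental evidence IDA, so the
    level-<=3 exclusion filter never removes it and positive pairs reduce to
    within-module pairs. Background genes get a private leaf term each, also at
    level 5, under a separate branch: their descendant-closed term sets are
    pairwise disjoint and disjoint from every module's, so they only ever
    appear in negative pairs.
    """
    if plan.n_modules < 2:
        raise ValueError("need >= 2 modules to build an annotation table")
    edges: list[tuple[str, str]] = []
    records: list[AnnotationRecord] = []
    root = "T:ROOT"
    # chain root -> c1 -> c2 -> c3 -> c4, module terms hang off c4 (level 5)
    chain = [root] + [f"T:CHAIN{i}" for i in range(1, 5)]
    edges += [(chain[i], chain[i + 1]) for i in range(4)]
    for m, genes in enumerate(plan.module_members().items()):
        name, gene_list = genes
        term = f"T:MOD{m}"
        edges.append((chain[4], term))
        records += [AnnotationRecord(g, term, "IDA") for g in gene_list]
    covered = sum(plan.module_sizes)
    bg_chain = [root] + [f"T:BGCHAIN{i}" for i in range(1, 5)]
    edges += [(bg_chain[i], bg_chain[i + 1]) for i in range(4)]
    for g in plan.gene_ids[covered:]:
        term = f"T:BG_{g}"
        edges.append((bg_chain[4], term))
        records.append(AnnotationRecord(g, term, "IDA"))
    return AnnotationTable(records=records, edges=edges, root=root)
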