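"""Shared fixtures: the standard planted-module compendium and its products.

Everything is generated at session start from seeds, so the suite has no
on-disk data dependencies.  The "standard" scale is 200 genes in 4 modules
of 40 (40 background genes), 3 datasets of 100 samples, with module noise
set so the expected within-module Pearson correlation is 0.96.
"""

import pytest

import gene2vec as g2v


@pytest.fixture(scope="session")
def plan() -> g2v.ModulePlan:
    return g2v.ModulePlan(seed=1)


@pytest.fixture(scope="session")
def compendium(plan):
    return g2v.simulate_compendium(plan)


@pytest.fixture(scope="session")
def corpus(plan, compendium):
    return g2v.build_corpus(compendium)


@pytest.fixture(scope="session")
def pathways(plan):
    return g2v.modules_to_pathways(plan)


@pytest.fixture(scope="session")
def annotations(plan):
    return g2v.modules_to_annotations(plan)


@pytest.fixture(scope="session")
def trained_embedding(corpus):
    """The standard fixture embedding: k=50, 9 epochs, seeded."""
    return g2v.train(corpus, g2v.TrainConfig(k=50, iterations=9, seed=1))


@pytest.fixture(scope="session")
def background(trained_embedding):
    return g2v.background_pairs(trained_embedding.vocab, 100, seed=7)


@pytest.fixture(scope="session")
def module_of(plan):
    """gene -> module name map (background genes absent)."""
    return {
        gene: name
        for name, genes in plan.module_members().items()
        for gene in genes
    }
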