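"""Annotation-derived pair sets, gene-disjoint splitting, and the classifier."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import gene2vec as g2v
from gene2vec.ggipnn import (
    GGIPNN,
    AnnotationRecord,
    AnnotationTable,
    GGIPNNConfig,
    PositiveFilters,
    auc_score,
    build_pair_dataset,
    gene_disjoint_split,
    negative_pairs,
    positive_pairs,
    train_ggipnn,
)


@pytest.fixture()
def toy_ontology():
    """6 terms, 5 genes: root(0) -> A(1) -> B(2) -> C(3) -> D(4) -> E(5),
    plus a sibling branch root -> X(1)."""
    edges = [
        ("root", "A"),
        ("A", "B"),
        ("B", "C"),
        ("C", "D"),
        ("D", "E"),
        ("root", "X"),
    ]
    records = [
        AnnotationRecord("g1", "D", "IDA"),   # level 4, retained
        AnnotationRecord("g2", "D", "IMP"),   # shares D with g1
        AnnotationRecord("g3", "B", "IDA"),   # level 2, excluded for positives
        AnnotationRecord("g4", "E", "IEA"),   # non-experimental evidence
        AnnotationRecord("g5", "X", "IDA"),   # level 1, separate branch
    ]
    return AnnotationTable(records=records, edges=edges, root="root")


class TestAnnotationTable:
    def test_levels_are_min_depth_from_root(self, toy_ontology):
        assert toy_ontology.term_levels == {
            "root": 0, "A": 1, "B": 2, "C": 3, "D": 4, "E": 5, "X": 1,
        }

    def test_multi_parent_term_gets_minimum_level(self):
        edges = [("root", "A"), ("A", "B"), ("B", "C"), ("root", "C")]
        t = AnnotationTable(records=[], edges=edges, root="root")
        assert t.term_levels["C"] == 1

    def test_cycle_detected(self):
        edges = [("root", "A"), ("A", "B"), ("B", "A")]
        with pytest.raises(ValueError, match="cycle"):
            AnnotationTable(records=[], edges=edges, root="root")

    def test_descendant_closure_includes_self(self, toy_ontology):
        assert toy_ontology.descendants("C") == frozenset({"C", "D", "E"})
        assert toy_ontology.descendants("X") == frozenset({"X"})


class TestPositivePairs:
    def test_shared_deep_experimental_term_included(self, toy_ontology):
        assert ("g1", "g2") in positive_pairs(toy_ontology)

    def test_shallow_term_excluded(self):
        edges = [("root", "A"), ("A", "B")]
        records = [
            AnnotationRecord("g1", "B", "IDA"),
            AnnotationRecord("g2", "B", "IDA"),
        ]
        t = AnnotationTable(records=records, edges=edges, root="root")
        assert positive_pairs(t) == set()  # level 2 <= 3 -> filtered

    def test_excluded_term_id_filtered(self):
        edges = [("root", "A"), ("A", "B"), ("B", "C"), ("C", "D"), ("D", "GO:0007165")]
        records = [
            AnnotationRecord("g1", "GO:0007165", "IDA"),
            AnnotationRecord("g2", "GO:0007165", "IDA"),
        ]
        t = AnnotationTable(records=records, edges=edges, root="root")
        assert positive_pairs(t) == set()

    def test_orphan_term_raises(self):
        t = AnnotationTable(
            records=[AnnotationRecord("g1", "NOWHERE", "IDA")],
            edges=[("root", "A")],
            root="root",
        )
        with pytest.raises(ValueError, match="NOWHERE"):
            positive_pairs(t)

    def test_matches_exhaustive_enumeration(self, toy_ontology):
        filters = PositiveFilters()
        retained = {
            (r.gene, r.term)
            for r in toy_ontology.records
            if r.evidence in filters.evidence_codes
            and r.term not in filters.excluded_terms
            and toy_ontology.term_levels[r.term] > filters.excluded_max_level
        }
        genes = toy_ontology.genes()
        expected = set()
        for a, b in itertools.combinations(genes, 2):
            terms_a = {t for g, t in retained if g == a}
            terms_b = {t for g, t in retained if g == b}
            if terms_a & terms_b:
                expected.add((a, b))
        assert positive_pairs(toy_ontology) == expected


class TestNegativePairs:
    def test_disjoint_branches_included(self, toy_ontology):
        assert ("g1", "g5") in negative_pairs(toy_ontology)

    def test_shared_descendant_excluded(self, toy_ontology):
        # g3 is annotated at B whose descendants include D (g1's term)
        assert ("g1", "g3") not in negative_pairs(toy_ontology)

    def test_matches_transitive_closure_oracle(self, toy_ontology):
        closures = {}
        for gene in toy_ontology.genes():
            terms = {r.term for r in toy_ontology.records if r.gene == gene}
            closure = set()
            for t in terms:
                stack = [t]
                while stack:
                    cur = stack.pop()
                    if cur not in closure:
                        closure.add(cur)
                        stack.extend(toy_ontology.children.get(cur, ()))
            closures[gene] = closure
        expected = {
            (a, b)
            for a, b in itertools.combinations(sorted(closures), 2)
            if not (closures[a] & closures[b])
        }
        assert negative_pairs(toy_ontology) == expected

    def test_positive_and_negative_sets_disjoint(self, annotations):
        pos = positive_pairs(annotations)
        neg = negative_pairs(annotations)
        assert pos and neg
        assert not pos & neg

    def test_fixture_positives_are_within_module_pairs(self, plan, annotations):
        pos = positive_pairs(annotations)
        expected = set()
        for genes in plan.module_members().values():
            expected |= set(itertools.combinations(sorted(genes), 2))
        assert pos == expected


class TestGeneDisjointSplit:
    def test_ten_genes_split_7_1_2(self):
        pairs = [(f"g{i}", f"g{j}", 1) for i in range(10) for j in range(i + 1, 10)]
        ds = gene_disjoint_split(pairs, (7, 1, 2), seed=0)
        sizes = {name: len(ds.genes_in(name)) for name in ("train", "val", "test")}
        assert sizes == {"train": 7, "val": 1, "test": 2}

    def test_no_pair_spans_two_splits(self, annotations):
        pos = positive_pairs(annotations)
        neg = negative_pairs(annotations)
        ds = build_pair_dataset(pos, neg, seed=3)
        for name in ("train", "val", "test"):
            genes = ds.genes_in(name)
            for a, b, _ in ds.pairs_in(name):
                assert a in genes and b in genes
        # retained pair lists are pairwise disjoint
        all_retained = [tuple(p) for n in ("train", "val", "test") for p in ds.pairs_in(n)]
        assert len(all_retained) == len(set(all_retained))

    def test_retained_counts_match_endpoint_lookup_oracle(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(100)]
        pairs = set()
        while len(pairs) < 500:
            a, b = rng.choice(100, 2, replace=False)
            pairs.add((genes[min(a, b)], genes[max(a, b)]))
        labeled = [(a, b, int(rng.random() < 0.5)) for a, b in sorted(pairs)]
        ds = gene_disjoint_split(labeled, seed=1)
        for name in ("train", "val", "test"):
            expected = sum(
                1 for a, b, _ in labeled
                if ds.split[a] == name and ds.split[b] == name
            )
            assert len(ds.pairs_in(name)) == expected

    def test_balanced_labels_after_downsampling(self, annotations):
        pos = positive_pairs(annotations)
        neg = negative_pairs(annotations)
        ds = build_pair_dataset(pos, neg, seed=0)
        labels = [y for _, _, y in ds.pairs]
        assert labels.count(1) == labels.count(0) == len(pos)

    def test_bad_proportions_raise(self):
        with pytest.raises(ValueError, match="positive"):
            gene_disjoint_split([("a", "b", 1)], (1, 0, 1), seed=0)


class TestAucScore:
    def test_perfect_and_reversed_separation(self):
        labels = [0, 0, 1, 1]
        assert auc_score(labels, [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert auc_score(labels, [0.9, 0.8, 0.2, 0.1]) == 0.0

    def test_matches_pairwise_comparison_oracle(self):
        rng = np.random.default_rng(8)
        labels = (rng.random(50) < 0.4).astype(int)
        scores = rng.random(50)
        scores[::7] = 0.5  # force ties
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos for n in neg
        )
        expected = wins / (len(pos) * len(neg))
        assert auc_score(labels, scores) == pytest.approx(expected, abs=1e-12)
        assert auc_score(labels, scores) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_score([1, 1], [0.2, 0.3])


@pytest.fixture(scope="module")
def fixture_dataset(annotations, trained_embedding):
    pos = positive_pairs(annotations)
    neg = negative_pairs(annotations)
    vocab = set(trained_embedding.vocab.gene_ids)
    pos = {p for p in pos if p[0] in vocab and p[1] in vocab}
    neg = {p for p in neg if p[0] in vocab and p[1] in vocab}
    return build_pair_dataset(pos, neg, seed=0)


class TestGGIPNNTraining:
    def test_frozen_embedding_is_bitwise_unchanged(self, fixture_dataset, trained_embedding):
        cfg = GGIPNNConfig(embedding_trainable=False, epochs=3, seed=0)
        model = train_ggipnn(fixture_dataset, trained_embedding, cfg)
        ref = GGIPNN(sorted(fixture_dataset.split), trained_embedding.k, cfg)
        ref.set_pretrained(trained_embedding)
        assert np.array_equal(model.E, ref.E)

    def test_trainable_embedding_changes(self, fixture_dataset, trained_embedding):
        cfg = GGIPNNConfig(embedding_trainable=True, epochs=3, seed=0)
        model = train_ggipnn(fixture_dataset, trained_embedding, cfg)
        ref = GGIPNN(sorted(fixture_dataset.split), trained_embedding.k, cfg)
        ref.set_pretrained(trained_embedding)
        assert not np.array_equal(model.E, ref.E)

    def test_training_loss_decreases(self, fixture_dataset, trained_embedding):
        cfg = GGIPNNConfig(epochs=6, seed=1)
        genes = sorted(fixture_dataset.split)
        model = GGIPNN(genes, trained_embedding.k, cfg)
        model.set_pretrained(trained_embedding)
        losses = model.fit(fixture_dataset)
        smoothed = np.convolve(losses, [0.5, 0.5], mode="valid")
        assert smoothed[-1] < smoothed[0]

    def test_same_seed_identical_weights(self, fixture_dataset, trained_embedding):
        cfg = GGIPNNConfig(epochs=2, seed=4)
        m1 = train_ggipnn(fixture_dataset, trained_embedding, cfg)
        m2 = train_ggipnn(fixture_dataset, trained_embedding, cfg)
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)

    def test_unknown_gene_raises_by_name(self, fixture_dataset, trained_embedding):
        model = train_ggipnn(
            fixture_dataset, trained_embedding, GGIPNNConfig(epochs=1, seed=0)
        )
        with pytest.raises(ValueError, match="GHOST"):
            model.predict_scores([("GHOST", "G0001", 1)])
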