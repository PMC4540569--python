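import io
import itertools
import random

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import ctrlpaths as cp
from ctrlpaths.semantic_similarity import (
    DEFAULT_RELATION_WEIGHTS,
    AnnotationMap,
    OntologyDAG,
    SimilarityScorer,
)


def recursive_svalue(term, ancestor, dag, weights):
    """Independent recursive S-value oracle (memo-free, follows definitions)."""
    if ancestor == term:
        return 1.0
    closure = dag.ancestor_closure(term)
    best = 0.0
    for child in closure:
        for parent, rel in dag.parents.get(child, ()):
            if parent == ancestor:
                best = max(best, weights[rel] * recursive_svalue(term, child, dag, weights))
    return best


def oracle_term_sim(t1, t2, dag, weights=DEFAULT_RELATION_WEIGHTS):
    c1, c2 = dag.ancestor_closure(t1), dag.ancestor_closure(t2)
    s1 = {t: recursive_svalue(t1, t, dag, weights) for t in c1}
    s2 = {t: recursive_svalue(t2, t, dag, weights) for t in c2}
    common = c1 & c2
    if not common:
        return 0.0
    return sum(s1[t] + s2[t] for t in common) / (sum(s1.values()) + sum(s2.values()))


class TestTermSimilarity:
    def test_identity(self, toy_dag):
        assert cp.term_similarity("t1", "t1", toy_dag) == pytest.approx(1.0)

    def test_sibling_value_hand_computed(self, toy_dag):
        # siblings under a: common ancestors {a, root} with S-values
        # (0.8, 0.64) each; totals 1 + 0.8 + 0.64 per term
        expected = (0.8 + 0.8 + 0.64 + 0.64) / (2 * (1 + 0.8 + 0.64))
        assert cp.term_similarity("t1", "t2", toy_dag) == pytest.approx(expected)

    def test_root_only_sharing_is_weaker_than_siblings(self):
        dag = OntologyDAG(
            frozenset(["root", "a", "b", "t1", "t2", "u"]),
            {"a": (("root", "is_a"),), "b": (("root", "is_a"),),
             "t1": (("a", "is_a"),), "t2": (("a", "is_a"),), "u": (("b", "is_a"),)})
        distant = cp.term_similarity("t1", "u", dag)
        close = cp.term_similarity("t1", "t2", dag)
        assert 0 < distant < close

    def test_part_of_weight_used(self, toy_dag):
        dag = OntologyDAG(toy_dag.terms,
                          {"a": (("root", "is_a"),), "t1": (("a", "part_of"),),
                           "t2": (("a", "is_a"),)})
        assert cp.term_similarity("t1", "t2", dag) == pytest.approx(
            oracle_term_sim("t1", "t2", dag))

    def test_cross_namespace_zero(self):
        dag = OntologyDAG(frozenset(["x", "y"]), {}, {"x": "bp", "y": "mf"})
        assert cp.term_similarity("x", "y", dag) == 0.0

    def test_unknown_term_raises(self, toy_dag):
        with pytest.raises(KeyError):
            cp.term_similarity("t1", "nope", toy_dag)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_recursive_oracle_on_random_dags(self, seed):
        dag = cp.generate_ontology(4, 2, seed=seed)
        rng = random.Random(seed)
        terms = sorted(dag.terms)
        for _ in range(5):
            t1, t2 = rng.choice(terms), rng.choice(terms)
            assert cp.term_similarity(t1, t2, dag) == pytest.approx(
                oracle_term_sim(t1, t2, dag))
            assert cp.term_similarity(t1, t2, dag) == pytest.approx(
                cp.term_similarity(t2, t1, dag))


class TestGeneSimilarity:
    def test_identical_annotations_score_one(self, toy_dag):
        ann = AnnotationMap({"g1": frozenset({"t1", "t2"}), "g2": frozenset({"t1", "t2"})})
        assert cp.gene_similarity("g1", "g2", ann, toy_dag) == pytest.approx(1.0)

    def test_single_term_pair_equals_term_similarity(self, toy_dag):
        ann = AnnotationMap({"g1": frozenset({"t1"}), "g2": frozenset({"t2"})})
        assert cp.gene_similarity("g1", "g2", ann, toy_dag) == pytest.approx(
            cp.term_similarity("t1", "t2", toy_dag))

    def test_bma_matches_exhaustive_pair_oracle(self):
        dag = cp.generate_ontology(4, 2, seed=3)
        terms = sorted(dag.terms)
        ann = AnnotationMap({"g1": frozenset(terms[3:5]), "g2": frozenset(terms[6:9])})
        t1s, t2s = sorted(ann.terms("g1")), sorted(ann.terms("g2"))
        grid = {(a, b): cp.term_similarity(a, b, dag) for a in t1s for b in t2s}
        expected = (sum(max(grid[(a, b)] for b in t2s) for a in t1s)
                    + sum(max(grid[(a, b)] for a in t1s) for b in t2s)) / (len(t1s) + len(t2s))
        assert cp.gene_similarity("g1", "g2", ann, dag) == pytest.approx(expected)

    def test_unannotated_gene_scores_zero(self, toy_dag):
        ann = AnnotationMap({"g1": frozenset({"t1"})})
        assert cp.gene_similarity("g1", "ghost", ann, toy_dag) == 0.0


class TestSetSimilarity:
    def test_self_set_scores_cardinality(self, toy_dag):
        ann = AnnotationMap({"g": frozenset({"t1"})})
        assert cp.set_similarity({"g"}, {"g"}, ann, toy_dag) == pytest.approx(1.0)

    def test_empty_set_scores_zero(self, toy_dag):
        ann = AnnotationMap({"g": frozenset({"t1"})})
        assert cp.set_similarity(set(), {"g"}, ann, toy_dag) == 0.0

    def test_symmetric_and_monotone(self, bundle, bundle_scorer):
        genes = sorted(bundle.annotations.genes)[:6]
        a, b = genes[:3], genes[3:5]
        ab = bundle_scorer.set_similarity(a, b)
        assert ab == pytest.approx(bundle_scorer.set_similarity(b, a))
        assert bundle_scorer.set_similarity(a, b + [genes[5]]) >= ab

    @pytest.mark.parametrize("seed", range(30))
    def test_hungarian_matches_assignment_brute_force(self, seed):
        """scipy assignment equals direct enumeration over injective
        assignments on random grids up to 6x6."""
        rng = np.random.default_rng(seed)
        rows, cols = (int(v) for v in rng.integers(1, 7, size=2))
        grid = rng.uniform(0, 1, size=(rows, cols))
        if rows > cols:
            grid, rows, cols = grid.T, cols, rows
        r, c = linear_sum_assignment(grid, maximize=True)
        best = max(sum(grid[i, cc[i]] for i in range(rows))
                   for cc in itertools.permutations(range(cols), rows))
        assert grid[r, c].sum() == pytest.approx(best)

    def test_normalized_variant_bounded_by_one(self, bundle, bundle_scorer):
        genes = sorted(bundle.annotations.genes)[:5]
        v = bundle_scorer.set_similarity(genes[:3], genes[3:], normalized=True)
        assert 0 <= v <= 1


class TestOboRoundtrip:
    def test_write_then_read_preserves_structure(self):
        dag = cp.generate_ontology(3, 2, seed=5)
        buf = io.StringIO()
        cp.write_obo(dag, buf)
        buf.seek(0)
        again = cp.read_obo(buf)
        assert again.terms == dag.terms
        assert {t: frozenset(ps) for t, ps in again.parents.items()} \
            == {t: frozenset(ps) for t, ps in dag.parents.items()}

    def test_annotation_reader_drops_unknown_terms(self, toy_dag):
        stream = io.StringIO("g1\tt1\ng1\tmissing\n")
        ann = cp.read_annotations(stream, toy_dag)
        assert ann.terms("g1") == frozenset({"t1"})
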