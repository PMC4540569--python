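"""Ontology-based functional similarity between genes and gene sets.

Term–term similarity follows Wang's semantic-contribution scheme: a term's
ancestor closure is scored by S-values (1 for the term itself; for an
ancestor, the maximum over its children on paths toward the term of the
child's S-value damped by the relation's contribution factor), and two terms
are compared by the summed S-values of their shared ancestors relative to
their total semantic values. Gene–gene similarity is the best-match average
(BMA) over the genes' annotation sets. Set–set similarity solves the
maximum-weight bipartite matching over pairwise gene similarities and
returns the *sum* of the matched weights — intentionally unnormalized, so
larger coherent sets score higher.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

#: Wang et al.'s published semantic-contribution factors per relation type.
DEFAULT_RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass(frozen=True)
class OntologyDAG:
    """Acyclic term graph with typed child→parent edges (is_a, part_of)."""

    terms: frozenset[str]
    parents: Mapping[str, tuple[tuple[str, str], ...]]  # child → ((parent, relation), ...)
    namespaces: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, rels in self.parents.items():
            if child not in self.terms:
                raise ValueError(f"edge from unknown term {child!r}")
            for parent, _ in rels:
                if parent not in self.terms:
                    raise ValueError(f"edge to unknown term {parent!r}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str) -> None:
            state[t] = 1
            for p, _ in self.parents.get(t, ()):
                s = state.get(p)
                if s == 1:
                    raise ValueError("ontology contains a cycle")
                if s is None:
                    visit(p)
            state[t] = 2

        for t in self.terms:
            if t not in state:
                visit(t)

    def namespace(self, term: str) -> str | None:
        return self.namespaces.get(term)

    def ancestor_closure(self, term: str) -> set[str]:
        """The term plus all its ancestors."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        out = {term}
        stack = [term]
        while stack:
            for p, _ in self.parents.get(stack.pop(), ()):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out


def read_obo(stream_or_path) -> OntologyDAG:
    """Load an OBO flat file (is_a and relationship: part_of edges)."""
    import obonet

    graph = obonet.read_obo(stream_or_path)
    terms = frozenset(graph.nodes)
    parents: dict[str, list[tuple[str, str]]] = {}
    namespaces: dict[str, str] = {}
    for child, data in graph.nodes(data=True):
        if "namespace" in data:
            namespaces[child] = data["namespace"]
    for child, parent, rel in graph.edges(keys=True):
        if rel in ("is_a", "part_of"):
            parents.setdefault(child, []).append((parent, rel))
    return OntologyDAG(terms, {c: tuple(sorted(ps)) for c, ps in parents.items()}, namespaces)


@dataclass
class AnnotationMap:
    """gene → annotated ontology terms; unknown terms are dropped with a warning."""

    annotations: dict[str, frozenset[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], dag: OntologyDAG) -> "AnnotationMap":
        ann: dict[str, set[str]] = {}
        dropped = 0
        for gene, term in pairs:
            if term in dag.terms:
                ann.setdefault(gene, set()).add(term)
            else:
                dropped += 1
        if dropped:
            logger.warning("dropped %d annotations to terms absent from the ontology", dropped)
        return cls({g: frozenset(ts) for g, ts in ann.items()})

    def terms(self, gene: str) -> frozenset[str]:
        return self.annotations.get(gene, frozenset())

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.annotations)


def read_annotations(stream: IO[str], dag: OntologyDAG) -> AnnotationMap:
    """Two-column TSV (gene<TAB>term) or GAF 2.x (gene in col 3, term in col 5)."""
    pairs = []
    for raw in stream:
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!") or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) >= 15:  # GAF row
            pairs.append((fields[2], fields[4]))
        elif len(fields) >= 2:
            pairs.append((fields[0], fields[1]))
        else:
            raise ValueError(f"malformed annotation row: {line!r}")
    return AnnotationMap.from_pairs(pairs, dag)


def _svalues(term: str, dag: OntologyDAG,
             weights: Mapping[str, float]) -> dict[str, float]:
    """Wang S-values over the term's ancestor closure (S(term) = 1)."""
    closure = dag.ancestor_closure(term)
    s: dict[str, float] = {term: 1.0}
    # process children before parents: iterate until fixed point over the
    # closure's partial order (closures are small; simple relaxation is fine)
    order = _upward_order(term, dag, closure)
    for t in order:
        if t == term:
            continue
        best = 0.0
        for child in closure:
            for parent, rel in dag.parents.get(child, ()):
                if parent == t and child in s:
                    w = weights.get(rel, 0.0)
                    best = max(best, w * s[child])
        s[t] = best
    return s


def _upward_order(term: str, dag: OntologyDAG, closure: set[str]) -> list[str]:
    """Topological order of the closure from the term toward the roots."""
    children_in: dict[str, set[str]] = {t: set() for t in closure}
    for child in closure:
        for parent, _ in dag.parents.get(child, ()):
            if parent in closure:
                children_in[parent].add(child)
    order: list[str] = []
    done: set[str] = set()
    # DFS emitting a node after all its in-closure children
    for start in [term] + sorted(closure):
        if start in done:
            continue
        stack = [(start, False)]
        while stack:
            node, expanded = stack.pop()
            if node in done:
                continue
            if expanded:
                done.add(node)
                order.append(node)
                continue
            stack.append((node, True))
            for ch in sorted(children_in[node]):
                if ch not in done:
                    stack.append((ch, False))
    return order


def term_similarity(t1: str, t2: str, dag: OntologyDAG,
                    weights: Mapping[str, float] | None = None) -> float:
    """Wang semantic similarity of two terms in [0, 1].

    Cross-namespace pairs score 0 (with a warning); unknown terms raise.
    """
    if weights is None:
        weights = DEFAULT_RELATION_WEIGHTS
    for t in (t1, t2):
        if t not in dag.terms:
            raise KeyError(f"unknown term {t!r}")
    ns1, ns2 = dag.namespace(t1), dag.namespace(t2)
    if ns1 is not None and ns2 is not None and ns1 != ns2:
        logger.warning("cross-namespace pair (%s, %s): similarity 0", t1, t2)
        return 0.0
    s1 = _svalues(t1, dag, weights)
    s2 = _svalues(t2, dag, weights)
    common = set(s1) & set(s2)
    if not common:
        return 0.0
    num = sum(s1[t] + s2[t] for t in common)
    den = sum(s1.values()) + sum(s2.values())
    return num / den


class SimilarityScorer:
    """Memoizing similarity engine over one ontology and annotation map.

    The prioritization loop evaluates the same gene pairs many times; term-
    and gene-level results are cached across calls.
    """

    def __init__(self, ann: AnnotationMap, dag: OntologyDAG,
                 weights: Mapping[str, float] | None = None):
        self.ann = ann
        self.dag = dag
        self.weights = dict(weights or DEFAULT_RELATION_WEIGHTS)
        self._term_cache: dict[tuple[str, str], float] = {}
        self._gene_cache: dict[tuple[str, str], float] = {}

    def term_similarity(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        if key not in self._term_cache:
            self._term_cache[key] = term_similarity(t1, t2, self.dag, self.weights)
        return self._term_cache[key]

    def gene_similarity(self, g1: str, g2: str) -> float:
        """Best-match-average similarity GOSim_BMA(g1, g2) in [0, 1]."""
        key = (g1, g2) if g1 <= g2 else (g2, g1)
        if key in self._gene_cache:
            return self._gene_cache[key]
        t1s, t2s = self.ann.terms(g1), self.ann.terms(g2)
        if not t1s or not t2s:
            logger.warning("unannotated gene in pair (%s, %s): similarity 0", g1, g2)
            val = 0.0
        else:
            grid = {(a, b): self.term_similarity(a, b) for a in t1s for b in t2s}
            fwd = sum(max(grid[(a, b)] for b in t2s) for a in t1s)
            rev = sum(max(grid[(a, b)] for a in t1s) for b in t2s)
            val = (fwd + rev) / (len(t1s) + len(t2s))
        self._gene_cache[key] = val
        return val

    def set_similarity(self, pi_a: Iterable[str], pi_b: Iterable[str],
                       normalized: bool = False) -> float:
        """Maximum-weight bipartite matching between two gene sets.

        Builds the grid E(u, l) = gene_similarity(u, l), solves the
        assignment problem, and returns the sum of matched weights (or the
        sum divided by the larger set size when ``normalized``). Either set
        empty gives 0.
        """
        a, b = sorted(set(pi_a)), sorted(set(pi_b))
        if not a or not b:
            return 0.0
        grid = np.array([[self.gene_similarity(u, l) for l in b] for u in a])
        rows, cols = linear_sum_assignment(grid, maximize=True)
        total = float(grid[rows, cols].sum())
        return total / max(len(a), len(b)) if normalized else total


def gene_similarity(g1: str, g2: str, ann: AnnotationMap, dag: OntologyDAG,
                    weights: Mapping[str, float] | None = None) -> float:
    return SimilarityScorer(ann, dag, weights).gene_similarity(g1, g2)


def set_similarity(pi_a: Iterable[str], pi_b: Iterable[str], ann: AnnotationMap,
                   dag: OntologyDAG, weights: Mapping[str, float] | None = None,
                   normalized: bool = False) -> float:
    return SimilarityScorer(ann, dag, weights).set_similarity(pi_a, pi_b, normalized)
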