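"""Synthetic networks, ontologies, annotations and planted disease modules.

Everything the analysis pipeline consumes can be generated here, seeded and
in-memory, at any scale. The disease benchmark plants a ground truth the
scoring model assumes: genes cause the same disease by driving the same
perturbation influence. Each disease gets a fresh downstream module (a
directed chain) and a set of disease genes wired so that every gene reaches
the module head; because the module head has one matched in-link at a time,
different maximum matchings assign it to different disease genes, and the
union over diversified MMSets gives every planted gene the full module as
its perturbation influence. Module and disease genes are annotated from one
ontology branch (with a noise fraction of off-branch terms) so their
influence sets score as functionally coherent.

The construction is verified post hoc with the actual sampling machinery —
never by assuming a particular matching.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping

from .mmset_sampling import MMSetCollection, sample_mmsets_multistart
from .network_io import DirectedNetwork, DiseaseGeneMap, network_from_links
from .perturbation import PerturbationProfile, perturbation_profile
from .semantic_similarity import AnnotationMap, OntologyDAG


def generate_network(n: int, mean_out_degree: float, model: str = "erdos",
                     seed: int = 0) -> DirectedNetwork:
    """Random simple digraph (no self-loops, no parallel links).

    ``erdos`` draws links uniformly among ordered pairs; ``scale_free`` picks
    tails by preferential attachment on current out-degree (heads uniform),
    producing hub regulators like those of curated regulatory maps.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = random.Random(seed)
    width = len(str(n - 1))
    names = [f"g{str(i).zfill(width)}" for i in range(n)]
    target = min(round(n * mean_out_degree), n * (n - 1))
    links: set[tuple[str, str]] = set()
    if model == "erdos":
        while len(links) < target:
            t, h = rng.randrange(n), rng.randrange(n)
            if t != h:
                links.add((names[t], names[h]))
    elif model == "scale_free":
        tail_pool = list(range(n))  # every node once, plus one entry per out-link
        while len(links) < target:
            t = rng.choice(tail_pool)
            h = rng.randrange(n)
            if t != h and (names[t], names[h]) not in links:
                links.add((names[t], names[h]))
                tail_pool.append(t)
    else:
        raise ValueError(f"unknown model {model!r}")
    return network_from_links(links, nodes=names)


def generate_ontology(depth: int, branching: int, seed: int = 0,
                      namespace: str = "biological_process") -> OntologyDAG:
    """Rooted is_a tree of the given depth and branching factor, plus random
    part_of cross-links on 10% of terms (always toward shallower levels, so
    the graph stays acyclic). ``depth=1`` is the bare root."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = random.Random(seed)
    levels: list[list[str]] = [["T:0000001"]]
    parents: dict[str, list[tuple[str, str]]] = {}
    counter = 2
    for d in range(1, depth):
        level = []
        for parent in levels[d - 1]:
            for _ in range(branching):
                term = f"T:{counter:07d}"
                counter += 1
                parents[term] = [(parent, "is_a")]
                level.append(term)
        levels.append(level)
    all_terms = [t for lvl in levels for t in lvl]
    depth_of = {t: d for d, lvl in enumerate(levels) for t in lvl}
    n_cross = len(all_terms) // 10
    for term in rng.sample(all_terms, n_cross):
        if depth_of[term] == 0:
            continue
        shallower = [t for t in all_terms if depth_of[t] < depth_of[term]
                     and (t, "is_a") not in parents.get(term, [])]
        if not shallower:
            continue
        target = rng.choice(shallower)
        rels = parents.setdefault(term, [])
        if (target, "part_of") not in rels:
            rels.append((target, "part_of"))
    return OntologyDAG(frozenset(all_terms),
                       {t: tuple(ps) for t, ps in parents.items()},
                       {t: namespace for t in all_terms})


def write_obo(dag: OntologyDAG, stream: IO[str]) -> None:
    """Minimal OBO flat file (term stanzas with is_a / relationship lines)."""
    stream.write("format-version: 1.2\nontology: synthetic\n")
    for term in sorted(dag.terms):
        stream.write(f"\n[Term]\nid: {term}\nname: {term}\n")
        ns = dag.namespace(term)
        if ns:
            stream.write(f"namespace: {ns}\n")
        for parent, rel in dag.parents.get(term, ()):
            if rel == "is_a":
                stream.write(f"is_a: {parent} ! {parent}\n")
            else:
                stream.write(f"relationship: {rel} {parent} ! {parent}\n")


def _subtree(dag: OntologyDAG, root: str) -> list[str]:
    children: dict[str, list[str]] = {}
    for child, rels in dag.parents.items():
        for parent, rel in rels:
            if rel == "is_a":
                children.setdefault(parent, []).append(child)
    out = [root]
    stack = [root]
    while stack:
        for c in sorted(children.get(stack.pop(), [])):
            out.append(c)
            stack.append(c)
    return out


@dataclass(frozen=True)
class SyntheticBundle:
    """A complete, internally consistent input set with planted ground truth."""

    network: DirectedNetwork
    ontology: OntologyDAG
    annotations: AnnotationMap
    associations: DiseaseGeneMap
    modules: Mapping[str, frozenset[str]]  # disease → planted shared module
    collection: MMSetCollection | None = None  # sampling used for verification
    profile: PerturbationProfile | None = None

    def write(self, outdir: str | Path) -> None:
        from .network_io import write_associations, write_edge_list

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "edges.tsv", "w") as fh:
            write_edge_list(self.network, fh)
        with open(outdir / "ontology.obo", "w") as fh:
            write_obo(self.ontology, fh)
        with open(outdir / "annotations.tsv", "w") as fh:
            for gene in sorted(self.annotations.annotations):
                for term in sorted(self.annotations.terms(gene)):
                    fh.write(f"{gene}\t{term}\n")
        with open(outdir / "associations.tsv", "w") as fh:
            write_associations(self.associations, fh)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump({d: sorted(m) for d, m in self.modules.items()}, fh, indent=1)


def generate_disease_benchmark(n_background: int = 160, mean_out_degree: float = 2.5,
                               n_diseases: int = 6, genes_per_disease: int = 3,
                               module_size: int = 4, seed: int = 0,
                               ontology_depth: int = 4, ontology_branching: int = 3,
                               terms_per_gene: int = 3, annotation_noise: float = 0.2,
                               verify_samples: int = 150, verify_restarts: int = 20,
                               model: str = "erdos") -> SyntheticBundle:
    """Build and verify a planted disease benchmark.

    Per disease: ``module_size`` fresh nodes form a directed chain (the shared
    module; chain links sit in *every* maximum matching because each has a
    unique tail and head) and ``genes_per_disease`` fresh disease genes each
    point at the chain head, competing for the single matched in-link — the
    diversified MMSets then hand the module to every gene in turn. Disease
    and module genes are annotated from one is_a subtree per disease with a
    fraction ``annotation_noise`` of random off-branch terms; background
    genes get uniform random terms.

    The bundle is verified post hoc: every planted gene's sampled
    perturbation influence must contain its module (raises otherwise). The
    sampling collection and profile used for verification ride along on the
    bundle for reuse.
    """
    rng = random.Random(seed)
    base = generate_network(n_background, mean_out_degree, model=model, seed=seed)
    dag = generate_ontology(ontology_depth, ontology_branching, seed=seed)

    root = "T:0000001"
    # candidate branches: subtrees rooted two levels below the root
    level1 = sorted(t for t, rels in dag.parents.items()
                    if any(p == root and r == "is_a" for p, r in rels))
    level2 = sorted(t for t, rels in dag.parents.items()
                    if any(p in level1 and r == "is_a" for p, r in rels))
    branches = level2 if len(level2) >= n_diseases else level1
    if len(branches) < n_diseases:
        raise ValueError("ontology too small to give each disease its own branch")
    all_terms = sorted(dag.terms)

    links = set(base.links)
    nodes = set(base.nodes)
    base_nodes = sorted(base.nodes)
    associations: dict[str, frozenset[str]] = {}
    modules: dict[str, frozenset[str]] = {}
    ann_pairs: list[tuple[str, str]] = []

    def branch_terms_for(i: int) -> list[str]:
        return _subtree(dag, branches[i % len(branches)])

    def annotate(gene: str, pool: list[str]) -> None:
        for _ in range(terms_per_gene):
            if rng.random() < annotation_noise:
                ann_pairs.append((gene, rng.choice(all_terms)))
            else:
                ann_pairs.append((gene, rng.choice(pool)))

    for i in range(n_diseases):
        disease = f"MIM:{600000 + i}"
        module = [f"d{i}_m{j}" for j in range(module_size)]
        genes = [f"d{i}_g{j}" for j in range(genes_per_disease)]
        nodes.update(module + genes)
        for a, b in zip(module, module[1:]):
            links.add((a, b))
        # disease genes are perturbation sources: a single out-link into the
        # module head and no in-links, so no background gene's influence can
        # swallow the module wholesale
        for g in genes:
            links.add((g, module[0]))
        branch = branch_terms_for(i)
        for g in module + genes:
            annotate(g, branch)
        associations[disease] = frozenset(genes)
        modules[disease] = frozenset(module)

    for g in base_nodes:
        annotate(g, all_terms)

    net = DirectedNetwork(frozenset(nodes), frozenset(links))
    annotations = AnnotationMap.from_pairs(ann_pairs, dag)
    bundle = SyntheticBundle(net, dag, annotations, DiseaseGeneMap(associations), modules)

    # verify with the actual sampling machinery, escalating the budget once:
    # many short restarted walks cover the competing module-head links far
    # better than one long walk
    coll = profile = None
    for factor in (1, 4):
        coll = sample_mmsets_multistart(net, verify_samples * factor, seed=seed,
                                        restarts=verify_restarts * factor)
        profile = perturbation_profile(coll)
        if all(modules[d] <= profile[g]
               for d, genes in associations.items() for g in genes):
            return SyntheticBundle(net, dag, annotations, DiseaseGeneMap(associations),
                                   modules, collection=coll, profile=profile)
    raise RuntimeError(
        "a planted gene does not reach its module under the sampled MMSets; "
        "increase verify_samples/verify_restarts")
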