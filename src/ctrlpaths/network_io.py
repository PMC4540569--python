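"""Reading, writing and normalizing directed networks and disease-gene maps.

Networks are simple digraphs: node identifiers are case-sensitive opaque
strings, parallel links collapse under set semantics, self-loops are allowed.
Edge-list files are tab-separated ``tail<TAB>head[<TAB>direction]`` with
``direction`` in ``{directed, undirected}``; lines starting with ``#`` are
comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping


class ParseError(ValueError):
    """A malformed row in a tabular input file."""


@dataclass(frozen=True)
class DirectedNetwork:
    """A directed network G(A) with node set V and link set L.

    ``undirected_flags`` records links that the source file marked as
    undirected; :func:`bidirectionalize` resolves them into link pairs.
    """

    nodes: frozenset[str]
    links: frozenset[tuple[str, str]]
    undirected_flags: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for tail, head in self.links:
            if tail not in self.nodes or head not in self.nodes:
                raise ValueError(f"link ({tail!r}, {head!r}) has an endpoint outside the node set")
        if not self.undirected_flags <= self.links:
            raise ValueError("undirected_flags must be a subset of links")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def successors(self, node: str) -> set[str]:
        return {h for t, h in self.links if t == node}

    def subnetwork_without_links(self, removed: Iterable[tuple[str, str]]) -> "DirectedNetwork":
        """Same node set with the given links deleted (nodes are never removed)."""
        gone = set(removed)
        kept = frozenset(l for l in self.links if l not in gone)
        return DirectedNetwork(self.nodes, kept, frozenset(f for f in self.undirected_flags if f in kept))


def network_from_links(links: Iterable[tuple[str, str]],
                       nodes: Iterable[str] = (),
                       undirected: Iterable[tuple[str, str]] = ()) -> DirectedNetwork:
    """Convenience constructor: node set = explicit nodes ∪ link endpoints."""
    links = frozenset(links)
    node_set = set(nodes)
    for t, h in links:
        node_set.add(t)
        node_set.add(h)
    return DirectedNetwork(frozenset(node_set), links, frozenset(undirected))


@dataclass(frozen=True)
class DiseaseGeneMap:
    """Disease identifier (e.g. an OMIM MIM string) → known disease genes X_d."""

    associations: Mapping[str, frozenset[str]]

    def with_min_genes(self, min_genes: int) -> "DiseaseGeneMap":
        """Drop diseases with fewer than ``min_genes`` genes (cross-validation
        requires at least two known genes per disease)."""
        return DiseaseGeneMap({d: gs for d, gs in self.associations.items() if len(gs) >= min_genes})

    @property
    def n_associations(self) -> int:
        return sum(len(gs) for gs in self.associations.values())

    def pairs(self) -> list[tuple[str, str]]:
        """All (disease, gene) association pairs, deterministically ordered."""
        return [(d, g) for d in sorted(self.associations) for g in sorted(self.associations[d])]


def _rows(stream: IO[str]) -> Iterable[tuple[int, list[str]]]:
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line.split("\t")


def read_edge_list(stream: IO[str], undirected_column: bool = False) -> DirectedNetwork:
    """Parse a tab-separated edge list into a :class:`DirectedNetwork`.

    With ``undirected_column`` a third column flags each row as ``directed``
    or ``undirected``; flagged links go into ``undirected_flags`` untouched
    (call :func:`bidirectionalize` to resolve them). Duplicate rows collapse.
    Raises :class:`ParseError` naming the offending line, and on empty input.
    """
    links: set[tuple[str, str]] = set()
    undirected: set[tuple[str, str]] = set()
    for lineno, fields in _rows(stream):
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(f"line {lineno}: expected 'tail<TAB>head', got {fields!r}")
        tail, head = fields[0], fields[1]
        links.add((tail, head))
        if undirected_column:
            if len(fields) < 3 or fields[2] not in ("directed", "undirected"):
                raise ParseError(
                    f"line {lineno}: expected a third column 'directed' or 'undirected', got {fields!r}")
            if fields[2] == "undirected":
                undirected.add((tail, head))
    if not links:
        raise ParseError("empty edge list")
    return network_from_links(links, undirected=undirected)


def write_edge_list(net: DirectedNetwork, stream: IO[str]) -> None:
    for tail, head in sorted(net.links):
        flag = "\tundirected" if (tail, head) in net.undirected_flags else (
            "\tdirected" if net.undirected_flags else "")
        stream.write(f"{tail}\t{head}{flag}\n")


def bidirectionalize(net: DirectedNetwork) -> DirectedNetwork:
    """Replace each undirected link {u, v} by the directed pair (u, v), (v, u).

    Directed links are unchanged; an undirected link whose reverse already
    exists contributes only the missing direction (set semantics also make an
    undirected self-loop yield a single link). Idempotent on its own output.
    """
    links = set(net.links)
    for tail, head in net.undirected_flags:
        links.add((head, tail))
    return DirectedNetwork(net.nodes, frozenset(links), frozenset())


def read_associations(stream: IO[str], min_genes: int = 0) -> DiseaseGeneMap:
    """Parse ``disease_id<TAB>gene_id`` rows; optionally drop diseases with
    fewer than ``min_genes`` genes. An empty stream gives an empty map."""
    assoc: dict[str, set[str]] = {}
    for lineno, fields in _rows(stream):
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(f"line {lineno}: expected 'disease<TAB>gene', got {fields!r}")
        assoc.setdefault(fields[0], set()).add(fields[1])
    dgm = DiseaseGeneMap({d: frozenset(gs) for d, gs in assoc.items()})
    return dgm.with_min_genes(min_genes) if min_genes else dgm


def write_associations(dgm: DiseaseGeneMap, stream: IO[str]) -> None:
    for disease, gene in dgm.pairs():
        stream.write(f"{disease}\t{gene}\n")
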