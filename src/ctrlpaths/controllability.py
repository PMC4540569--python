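"""Structural controllability: maximum matching, driver nodes, control paths.

A directed network G(A) is structurally controllable from a minimum driver
set whose size is N_D = max{n − |M|, 1}, where M is a maximum matching of the
network — a largest link set in which no two links share a tail or share a
head. The matched links decompose the network into *control paths*: stems
(chains starting at unmatched-in driver nodes) and cycles, together a
stem–cycle cover along which control signals propagate.

For small systems the Kalman rank condition itself is checked numerically on
random weight draws over the nonzero structure (generic rank): the system
x' = A x + B u is controllable iff Q_C = [B, AB, …, A^{n−1}B] has rank n.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .network_io import DirectedNetwork

#: Maximum state dimension accepted by the numeric Kalman oracle.
KALMAN_MAX_N = 12


@dataclass(frozen=True)
class Matching:
    """A set of links with pairwise distinct tails and distinct heads."""

    links: frozenset[tuple[str, str]]
    network: DirectedNetwork

    def __post_init__(self) -> None:
        tails = [t for t, _ in self.links]
        heads = [h for _, h in self.links]
        if len(set(tails)) != len(tails) or len(set(heads)) != len(heads):
            raise ValueError("matching links must have pairwise distinct tails and heads")
        if not self.links <= self.network.links:
            raise ValueError("matching contains links outside the parent network")

    def __len__(self) -> int:
        return len(self.links)

    def canonical(self) -> tuple[tuple[str, str], ...]:
        """Canonical form for deduplication: links sorted by (tail, head)."""
        return tuple(sorted(self.links))

    def successor_map(self) -> dict[str, str]:
        """tail → head over matched links; each node has at most one entry."""
        return {t: h for t, h in self.links}

    def matched_heads(self) -> set[str]:
        return {h for _, h in self.links}


@dataclass(frozen=True)
class ControlPathSet:
    """The stems and cycles induced by one maximum matching (a CPSet).

    Stems are node sequences starting at a driver (unmatched-in) node and
    following matched links; singleton stems are isolated unmatched nodes.
    Cycles are the remaining matched links. Stems and cycles are node-disjoint
    and jointly cover every node exactly once.
    """

    stems: tuple[tuple[str, ...], ...]
    cycles: tuple[tuple[str, ...], ...]
    matching: Matching

    @property
    def n_paths(self) -> int:
        return len(self.stems) + len(self.cycles)


@dataclass(frozen=True)
class LinearSystem:
    """x' = A x + B u on an ordered node list; one input per driver column."""

    nodes: tuple[str, ...]
    structure: frozenset[tuple[str, str]]  # nonzero pattern of A as (tail, head)
    drivers: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.drivers)) != len(self.drivers):
            raise ValueError("duplicate driver")
        missing = {d for d in self.drivers if d not in self.nodes}
        if missing:
            raise ValueError(f"drivers outside node list: {missing}")


def maximum_matching(net: DirectedNetwork, seed: int = 0) -> Matching:
    """A maximum matching of the directed network via its bipartite split.

    Each node v is split into an out-copy v⁺ and an in-copy v⁻ and every link
    (u, w) becomes the bipartite edge (u⁺, w⁻); Hopcroft–Karp on the split
    graph then yields a maximum matching of the digraph (self-loops are
    matchable). The seed permutes node and edge insertion order, steering
    tie-breaks among equally large matchings while keeping the run
    deterministic.
    """
    rng = random.Random(seed)
    nodes = sorted(net.nodes)
    rng.shuffle(nodes)
    links = sorted(net.links)
    rng.shuffle(links)

    bp = nx.Graph()
    out_of = {v: ("out", v) for v in nodes}
    in_of = {v: ("in", v) for v in nodes}
    bp.add_nodes_from(out_of[v] for v in nodes)
    bp.add_nodes_from(in_of[v] for v in nodes)
    bp.add_edges_from((out_of[t], in_of[h]) for t, h in links)
    pairing = nx.bipartite.hopcroft_karp_matching(bp, top_nodes=set(out_of.values()))
    matched = frozenset(
        (u[1], w[1]) for u, w in pairing.items() if u[0] == "out")
    return Matching(matched, net)


def count_drivers(net: DirectedNetwork, m: Matching) -> int:
    """Minimum number of driver nodes N_D = max{n − |M|, 1}."""
    return max(net.n - len(m), 1)


def driver_nodes(net: DirectedNetwork, m: Matching) -> frozenset[str]:
    """Nodes whose in-copy is unmatched (the minimum driver set).

    A perfect matching leaves none, yet one external input is still needed;
    by convention the lexicographically smallest node is then the driver.
    """
    unmatched_in = net.nodes - m.matched_heads()
    if unmatched_in:
        return frozenset(unmatched_in)
    return frozenset({min(net.nodes)})


def control_paths(net: DirectedNetwork, m: Matching) -> ControlPathSet:
    """Decompose the network into the stem–cycle cover induced by ``m``."""
    succ = m.successor_map()
    unmatched_in = sorted(net.nodes - m.matched_heads())
    on_stem: set[str] = set()
    stems: list[tuple[str, ...]] = []
    for start in unmatched_in:
        path = [start]
        cur = start
        while cur in succ:
            cur = succ[cur]
            path.append(cur)
        stems.append(tuple(path))
        on_stem.update(path)

    # every matched link not on a stem lies on a cycle (each node has at most
    # one matched in- and out-link, so leftovers close on themselves)
    cycles: list[tuple[str, ...]] = []
    seen: set[str] = set(on_stem)
    for start in sorted(succ):
        if start in seen:
            continue
        cyc = [start]
        seen.add(start)
        cur = succ[start]
        while cur != start:
            cyc.append(cur)
            seen.add(cur)
            cur = succ[cur]
        # rotate so the smallest node leads: canonical orientation
        k = cyc.index(min(cyc))
        cycles.append(tuple(cyc[k:] + cyc[:k]))
    cycles.sort()
    return ControlPathSet(tuple(stems), tuple(cycles), m)


def cactus_system(net: DirectedNetwork, m: Matching,
                  extra_cycle_inputs: bool = True) -> LinearSystem:
    """The linear system whose structure is the matched-link cactus.

    A has the matching's links as its nonzero pattern; inputs sit at the
    driver nodes. A cycle in the cover has no in-link from any stem, so with
    ``extra_cycle_inputs`` each cycle additionally receives an input at its
    smallest node, making the full cover controllable (each cycle becomes a
    bud fed by its own input).
    """
    cps = control_paths(net, m)
    drivers = [s[0] for s in cps.stems]
    if extra_cycle_inputs:
        drivers += [min(c) for c in cps.cycles]
    elif not drivers:
        drivers = [min(net.nodes)]
    return LinearSystem(tuple(sorted(net.nodes)), m.links, tuple(sorted(set(drivers))))


def kalman_rank_oracle(sys: LinearSystem, trials: int = 5, seed: int = 0) -> bool:
    """Numeric generic-rank check of the Kalman controllability condition.

    Draws independent uniform weights on [0.5, 1.5] for every nonzero entry
    of A and B, builds Q_C = [B, AB, …, A^{n−1}B] and tests rank n via a
    singular-value threshold of 1e-9 relative to the largest singular value.
    The structure is deemed controllable if any trial reaches full rank
    (generic rank is attained almost surely; several trials guard against a
    degenerate draw). Refuses systems larger than ``KALMAN_MAX_N`` nodes.
    """
    n = len(sys.nodes)
    if n > KALMAN_MAX_N:
        raise ValueError(f"Kalman oracle limited to {KALMAN_MAX_N} nodes, got {n}")
    if n == 0:
        return True
    idx = {v: i for i, v in enumerate(sys.nodes)}
    rng = np.random.default_rng(seed)
    m = max(len(sys.drivers), 1)
    for _ in range(max(trials, 1)):
        A = np.zeros((n, n))
        for tail, head in sys.structure:
            A[idx[head], idx[tail]] = rng.uniform(0.5, 1.5)
        B = np.zeros((n, m))
        for j, d in enumerate(sys.drivers):
            B[idx[d], j] = rng.uniform(0.5, 1.5)
        blocks = [B]
        for _ in range(n - 1):
            blocks.append(A @ blocks[-1])
        qc = np.hstack(blocks)
        sv = np.linalg.svd(qc, compute_uv=False)
        if sv.size and sv[0] > 0 and np.sum(sv > 1e-9 * sv[0]) == n:
            return True
    return False
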