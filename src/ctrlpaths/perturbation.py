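"""Perturbation ranges and influence over diversified control paths.

A node's perturbation range under one control-path cover C_k is the set of
nodes reachable from it along that cover's matched links (each node has at
most one matched successor, so the range is the successor chain, wrapping
around a cycle if the node sits on one). The perturbation influence Pi_i is
the union of ranges over every MMSet in a collection — the node's downstream
control footprint over the diversified control paths.

A node is never a member of its own influence set, even when a cycle leads
back to it: influence lists are strictly downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .controllability import ControlPathSet, control_paths
from .mmset_sampling import MMSetCollection
from .network_io import DirectedNetwork


@dataclass(frozen=True)
class PerturbationProfile:
    """Per-node perturbation influence Pi_i for a fixed MMSet collection."""

    per_node_influence: Mapping[str, frozenset[str]]
    collection: MMSetCollection

    def __getitem__(self, node: str) -> frozenset[str]:
        return self.per_node_influence[node]


def _chain_ranges(net: DirectedNetwork, succ: Mapping[str, str]) -> dict[str, set[str]]:
    """Reachable-set per node in a functional (≤1 successor) link graph."""
    ranges: dict[str, set[str]] = {}
    for node in net.nodes:
        reach: set[str] = set()
        cur = node
        while cur in succ:
            cur = succ[cur]
            if cur == node or cur in reach:
                break
            reach.add(cur)
        ranges[node] = reach
    return ranges


def perturbation_range(node: str, cpset: ControlPathSet) -> frozenset[str]:
    """Nodes reachable from ``node`` along one cover's matched links (Pr_i(C_k))."""
    net = cpset.matching.network
    if node not in net.nodes:
        raise KeyError(f"unknown node {node!r}")
    succ = cpset.matching.successor_map()
    reach: set[str] = set()
    cur = node
    while cur in succ:
        cur = succ[cur]
        if cur == node or cur in reach:
            break
        reach.add(cur)
    return frozenset(reach)


def perturbation_profile(coll: MMSetCollection) -> PerturbationProfile:
    """Pi_i for every node, batched with one successor-map pass per MMSet."""
    net = coll.network
    influence: dict[str, set[str]] = {v: set() for v in net.nodes}
    for m in coll.mmsets:
        for node, reach in _chain_ranges(net, m.successor_map()).items():
            influence[node] |= reach
    return PerturbationProfile(
        {v: frozenset(s) for v, s in influence.items()}, coll)


def perturbation_influence(node: str, coll: MMSetCollection) -> frozenset[str]:
    """Pi_i: union of perturbation ranges over every MMSet in the collection."""
    if node not in coll.network.nodes:
        raise KeyError(f"unknown node {node!r}")
    if not coll.mmsets:
        raise ValueError("empty MMSet collection")
    out: set[str] = set()
    for m in coll.mmsets:
        out |= perturbation_range(node, control_paths(coll.network, m))
    return frozenset(out)


def common_influence(genes: Iterable[str], coll: MMSetCollection) -> frozenset[str]:
    """Intersection of perturbation influences over a gene set — the shared
    downstream module a group of disease genes jointly perturbs."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    profile = perturbation_profile(coll)
    common = set(profile[genes[0]])
    for g in genes[1:]:
        common &= profile[g]
    return frozenset(common)
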