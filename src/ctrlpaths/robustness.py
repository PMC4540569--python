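"""Stability of perturbation influence under random edge removal (SPi).

SPi measures how much of each node's perturbation influence survives when a
fraction of links is deleted uniformly at random: it is the mean over nodes
of the Jaccard coefficient between the influence sets before (Pi_i) and
after (Pi_i') removal,

    SPi = (1/n) Σ_i |Pi_i ∩ Pi_i'| / |Pi_i ∪ Pi_i'|

with the 0/0 case (a node influencing nothing in either network) defined as
1: a node with no influence is perfectly "stable". That convention inflates
SPi on sparse networks and is stated here prominently for that reason.
Nodes are never removed — only links — so isolated nodes keep Pi' = ∅.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np

from .mmset_sampling import sample_mmsets
from .network_io import DirectedNetwork
from .perturbation import perturbation_profile


@dataclass(frozen=True)
class StabilityReport:
    fraction: float
    reps: int
    spi_values: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.spi_values))

    @property
    def std(self) -> float:
        return float(np.std(self.spi_values))


def _mean_jaccard(before: dict, after: dict, nodes) -> float:
    total = 0.0
    for v in nodes:
        a, b = before[v], after[v]
        union = a | b
        total += 1.0 if not union else len(a & b) / len(union)
    return total / len(nodes)


def spi(net: DirectedNetwork, fraction: float, reps: int = 20,
        samples: int = 200, seed: int = 0) -> StabilityReport:
    """Stability of perturbation influence at one edge-removal fraction.

    Per repetition: delete ⌊fraction·|links|⌋ links uniformly at random
    without replacement (removal seeds derive from the master seed by an
    explicit counter), re-sample MMSets on the reduced network with the same
    budget and the same walk seed as the intact baseline — a paired design,
    so sampling noise cancels and SPi(0) = 1 exactly — then average the
    per-node Jaccard overlap with the intact network's Pi.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must satisfy 0 <= fraction < 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base_profile = perturbation_profile(sample_mmsets(net, samples, seed))
    before = dict(base_profile.per_node_influence)
    n_remove = int(fraction * len(net.links))
    values = []
    links = sorted(net.links)
    for rep in range(reps):
        rng = random.Random(seed + 1 + rep)
        removed = rng.sample(links, n_remove)
        reduced = net.subnetwork_without_links(removed)
        after_profile = perturbation_profile(sample_mmsets(reduced, samples, seed))
        values.append(_mean_jaccard(before, dict(after_profile.per_node_influence), sorted(net.nodes)))
    return StabilityReport(fraction, reps, tuple(values))
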