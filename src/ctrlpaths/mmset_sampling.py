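"""Enumerating diversified maximum-matching sets (MMSets).

A network usually admits many maximum matchings, each inducing its own
control-path cover; their union is the network's diversified control paths.
Sampling follows a link-swap random walk: from the current MMSet pick a
matched link uniformly at random, enumerate every MMSet that keeps all other
links (the picked link's *alternative completions*), and hop to one of them
uniformly. Every visited state is recorded, repeats included.

For small networks an exhaustive backtracking enumerator serves as the ground
truth the sampler is validated against.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .controllability import Matching, maximum_matching
from .network_io import DirectedNetwork

#: Largest link count the exhaustive enumerator accepts.
ENUMERATION_MAX_LINKS = 20


@dataclass(frozen=True)
class MMSetCollection:
    """Distinct MMSets found, keyed by canonical (sorted-link) form."""

    network: DirectedNetwork
    mmsets: tuple[Matching, ...]
    samples_taken: int
    seed: int | None = None

    def __post_init__(self) -> None:
        sizes = {len(m) for m in self.mmsets}
        if len(sizes) > 1:
            raise ValueError("collection mixes matchings of different cardinality")

    def __len__(self) -> int:
        return len(self.mmsets)

    def canonical_forms(self) -> tuple[tuple[tuple[str, str], ...], ...]:
        return tuple(m.canonical() for m in self.mmsets)


def _collect(network: DirectedNetwork, seen: dict, samples: int, seed: int | None) -> MMSetCollection:
    ordered = tuple(seen[k] for k in sorted(seen))
    return MMSetCollection(network, ordered, samples, seed)


def alternative_completions(net: DirectedNetwork, m: Matching,
                            link: tuple[str, str]) -> list[Matching]:
    """All maximum matchings that keep every link of ``m`` except ``link``.

    These are m∖{link} plus any network link from a tail unmatched in
    m∖{link} to a head unmatched in m∖{link}; the result always contains
    ``m`` itself. Returned sorted by canonical form (deterministic).
    """
    if link not in m.links:
        raise ValueError(f"link {link!r} is not in the matching")
    rest = m.links - {link}
    used_tails = {t for t, _ in rest}
    used_heads = {h for _, h in rest}
    out = []
    for cand in net.links:
        t, h = cand
        if t not in used_tails and h not in used_heads:
            out.append(Matching(rest | {cand}, net))
    out.sort(key=lambda mm: mm.canonical())
    return out


def sample_mmsets(net: DirectedNetwork, n_samples: int, seed: int = 0) -> MMSetCollection:
    """Random-walk sampling of diversified MMSets.

    Starts from ``maximum_matching(net, seed)`` and performs ``n_samples``
    recorded steps of the link-swap walk. Reproducible for a fixed seed. A
    network with no links yields the collection holding the empty matching.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = random.Random(seed)
    current = maximum_matching(net, seed)
    seen = {current.canonical(): current}
    if not current.links:  # no links anywhere: the walk cannot move
        return _collect(net, seen, 1, seed)
    for _ in range(n_samples - 1):
        link = rng.choice(sorted(current.links))
        options = alternative_completions(net, current, link)
        current = options[rng.randrange(len(options))]
        seen.setdefault(current.canonical(), current)
    return _collect(net, seen, n_samples, seed)


def sample_mmsets_multistart(net: DirectedNetwork, n_samples: int, seed: int = 0,
                             restarts: int = 10) -> MMSetCollection:
    """Union of ``restarts`` independent walks from differently seeded initial
    matchings — a guard against walk components the single-link swap cannot
    bridge on adversarial graphs. ``n_samples`` is the per-walk budget."""
    seen: dict = {}
    total = 0
    for r in range(restarts):
        coll = sample_mmsets(net, n_samples, seed=seed * restarts + r)
        total += coll.samples_taken
        for m in coll.mmsets:
            seen.setdefault(m.canonical(), m)
    return _collect(net, seen, total, seed)


def enumerate_all_mmsets(net: DirectedNetwork) -> MMSetCollection:
    """Exhaustive enumeration of every maximum matching (small networks only).

    Backtracks over links in canonical order with endpoint-disjointness
    pruning; refuses networks with more than ``ENUMERATION_MAX_LINKS`` links.
    The empty network has exactly one MMSet: the empty matching.
    """
    links = sorted(net.links)
    if len(links) > ENUMERATION_MAX_LINKS:
        raise ValueError(
            f"exhaustive enumeration limited to {ENUMERATION_MAX_LINKS} links, got {len(links)}")
    best_size = len(maximum_matching(net))
    found: list[Matching] = []

    def backtrack(i: int, chosen: list, tails: set, heads: set) -> None:
        if len(chosen) == best_size:
            found.append(Matching(frozenset(chosen), net))
            return
        if i == len(links) or len(chosen) + (len(links) - i) < best_size:
            return
        t, h = links[i]
        if t not in tails and h not in heads:
            chosen.append(links[i])
            backtrack(i + 1, chosen, tails | {t}, heads | {h})
            chosen.pop()
        backtrack(i + 1, chosen, tails, heads)

    backtrack(0, [], set(), set())
    seen = {m.canonical(): m for m in found}
    return _collect(net, seen, len(found), None)
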