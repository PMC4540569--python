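# ctrlpaths

Diversified control paths for directed biological networks: structural
controllability, perturbation influence, and disease-gene prioritization.

## The problem

Complex diseases are increasingly read as perturbations of molecular
networks. Control theory gives this a sharp form: a linear dynamic system
x′(t) = A·x(t) + B·u(t) over a directed network G(A) is controllable when the
Kalman matrix Q_C = [B, AB, …, A^{n−1}B] has full rank. Checking that rank is
infeasible for large networks, but *structural* controllability reduces it to
combinatorics: a maximum matching M of the digraph (a largest link set in
which no two links share a tail or share a head) determines the minimum
number of externally driven nodes, N_D = max{n − |M|, 1}, and the matched
links decompose the network into **control paths** — stems rooted at the
driver nodes plus cycles — along which control signals propagate.

A network rarely has a unique maximum matching. Each matching M_k induces its
own control-path cover C_k; pooling covers over many matchings gives the
**diversified control paths**, and a gene's **perturbation influence** Pi_i
is everything it reaches along the matched links of any sampled matching —
its downstream control footprint. The package's working hypothesis is that
genes causing the same disease drive the same perturbation influence, so a
candidate gene i is scored against a disease's known gene set X_d by

    score(i) = max over x in X_d of sim(Pi_i, Pi_x)

where sim is the maximum-weight bipartite matching over pairwise gene
similarities (Wang-style ontology term similarity aggregated by best-match
average), and candidates are ranked by descending score.

The package is for computational biologists who have a directed regulatory
or signaling network, ontology annotations, and disease-gene associations,
and want to decompose the network's control structure, quantify per-gene
perturbation influence, and prioritize candidate disease genes — plus
synthetic generators so the whole pipeline runs and is testable without any
external data.

## Worked example

The five-node network with links 1→3, 1→4, 2→3, 3→5 has the unique maximum
matching {1→4, 2→3, 3→5}:

```python
import ctrlpaths as cp

net = cp.network_from_links([("1", "3"), ("1", "4"), ("2", "3"), ("3", "5")])
m = cp.maximum_matching(net, seed=0)
cps = cp.control_paths(net, m)
print(cp.count_drivers(net, m), sorted(cp.driver_nodes(net, m)))
print([" -> ".join(s) for s in cps.stems])
```

prints

```
2 ['1', '2']
['1 -> 4', '2 -> 3 -> 5']
```

Two driver nodes (1 and 2) suffice, and the network splits into the two
stems `1→4` and `2→3→5`: steering nodes 1 and 2 from outside controls all
five nodes, which `cp.kalman_rank_oracle` confirms numerically on random
weight draws. The `examples/` directory walks through every capability the
same way — MMSet sampling and perturbation influence (`02`), prioritization
on a planted benchmark (`03`, where the withheld disease gene ranks 1st of
200 candidates with score 4.000, the size of its influence set),
cross-validation (`04`: median LOO rank 0.50% of the pool, 5-fold AUC 1.000)
and edge-removal stability (`05`). There is also a thin CLI:
`ctrlpaths control --edges edges.tsv --seed 0`.

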