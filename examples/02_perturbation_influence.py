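"""Diversified maximum matchings and perturbation influence.

A network usually has many maximum matchings; each induces its own control
paths. A node's perturbation influence Pi is everything it can reach along
the matched links of *any* sampled matching — its downstream control
footprint. Here node `a` feeds both `b` and `c`, but each single matching
lets it control only one of them; the diversified view recovers both.
"""

import ctrlpaths as cp

net = cp.network_from_links([("a", "b"), ("a", "c"), ("b", "d")])

coll = cp.sample_mmsets(net, n_samples=100, seed=0)
print("distinct MMSets found:", len(coll))
for m in coll.mmsets:
    print("  matching:", sorted(m.links))

profile = cp.perturbation_profile(coll)
for node in sorted(net.nodes):
    print(f"Pi_{node} = {sorted(profile[node])}")

# Two genes jointly perturb the intersection of their influences — the
# candidate disease-related pathway they share:
print("common influence of {a, b}:", sorted(cp.common_influence(["a", "b"], coll)))
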