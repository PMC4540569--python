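"""Prioritize candidate disease genes on a synthetic planted benchmark.

The generator plants, per disease, a downstream module and a set of disease
genes wired so all of them perturb that module; module genes are annotated
from one ontology branch. A candidate scores the best functional similarity
(maximum-weight matching of pairwise gene similarities) between its
perturbation influence and any known disease gene's — planted genes should
top the list.
"""

import ctrlpaths as cp
from ctrlpaths.semantic_similarity import SimilarityScorer

bundle = cp.generate_disease_benchmark(seed=1)
scorer = SimilarityScorer(bundle.annotations, bundle.ontology)

disease = sorted(bundle.associations.associations)[0]
known = sorted(bundle.associations.associations[disease])
held_out, training = known[0], known[1:]
print(f"disease {disease}: known genes {known}, withholding {held_out}")

pool = (bundle.annotations.genes & bundle.network.nodes) - set(training)
ranked = cp.rank_candidates(disease, pool, training, bundle.profile, scorer)

print(f"top 5 of {len(pool)} candidates:")
for gene, score, rank in ranked.entries[:5]:
    marker = " <- withheld disease gene" if gene == held_out else ""
    print(f"  rank {rank:4g}  score {score:.3f}  {gene}{marker}")

# The withheld gene scores the size of its influence set (every gene of the
# shared module matches itself with similarity 1) and lands at the top.
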