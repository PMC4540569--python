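"""Evaluate prioritization by leave-one-out and k-fold cross-validation.

LOO-CV withholds each disease-gene association in turn and asks where the
withheld gene ranks among all annotated network genes; recall-at-k% is the
fraction of trials landing in the top k% of the pool. k-fold CV summarizes
the same ranks as an ROC AUC (withheld genes = positives).
"""

import ctrlpaths as cp
from ctrlpaths.semantic_similarity import SimilarityScorer

bundle = cp.generate_disease_benchmark(seed=1)
scorer = SimilarityScorer(bundle.annotations, bundle.ontology)
genes = bundle.annotations.genes & bundle.network.nodes

loo = cp.loo_cv(bundle.associations, genes, bundle.profile, scorer)
curve = dict(loo.recall_curve())
print(f"LOO-CV: {len(loo.trials)} trials, pool ~{loo.trials[0].pool_size} genes")
print(f"  median rank: {100 * loo.median_rank_fraction():.2f}% of the pool")
for k in (1, 5, 10, 25):
    print(f"  recall at top {k:>2}%: {curve[k]:.2f}")

kfold = cp.kfold_cv(bundle.associations, folds=5, seed=2, candidate_genes=genes,
                    profile=bundle.profile, scorer=scorer)
print(f"5-fold CV AUC: {kfold.auc:.3f}")
# AUC near 1 means withheld genes almost always outrank the background pool.
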