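"""Candidate-gene scoring, ranking and cross-validated evaluation.

A candidate i is scored against a disease's known gene set X_d by

    score(i) = max over x in X_d of sim(Pi_i, Pi_x)

— the best set-similarity between the candidate's perturbation influence and
any known disease gene's. Genes ranked by descending score form the priority
list. Leave-one-out cross-validation withholds each association in turn and
records where the withheld gene ranks among the candidate pool; k-fold CV
partitions associations at random and summarizes ranks as an ROC AUC.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network_io import DiseaseGeneMap
from .perturbation import PerturbationProfile
from .semantic_similarity import SimilarityScorer


@dataclass(frozen=True)
class RankedList:
    """Priority list for one disease: (gene, score, rank), scores descending.

    Tied scores receive the mean of the tied rank positions.
    """

    disease: str
    entries: tuple[tuple[str, float, float], ...]
    tie_policy: str = "mean"

    def rank_of(self, gene: str) -> float:
        for g, _, r in self.entries:
            if g == gene:
                return r
        raise KeyError(f"{gene!r} not in ranked list")


@dataclass(frozen=True)
class CVTrial:
    disease: str
    held_out_gene: str
    rank: float
    pool_size: int


@dataclass(frozen=True)
class CVReport:
    """Cross-validation outcome: per-trial ranks plus a recall-at-k% curve."""

    trials: tuple[CVTrial, ...]
    k_grid: tuple[int, ...] = tuple(range(1, 101))
    auc: float | None = None

    def recall_curve(self) -> list[tuple[int, float]]:
        """Fraction of trials whose held-out gene ranked within the top k%."""
        out = []
        for k in self.k_grid:
            hits = sum(1 for t in self.trials if t.rank <= k / 100.0 * t.pool_size)
            out.append((k, hits / len(self.trials) if self.trials else 0.0))
        return out

    def median_rank_fraction(self) -> float:
        """Median of rank/pool-size over trials (0 = always first)."""
        return float(np.median([t.rank / t.pool_size for t in self.trials]))


def score_candidate(candidate: str, disease_genes: Iterable[str],
                    profile: PerturbationProfile, scorer: SimilarityScorer,
                    normalized: bool = False) -> float:
    """max over known disease genes x of sim(Pi_candidate, Pi_x)."""
    xs = list(disease_genes)
    if not xs:
        raise ValueError("empty disease gene set")
    pi_i = profile[candidate]
    return max(scorer.set_similarity(pi_i, profile[x], normalized=normalized) for x in xs)


def _mean_ranks(scores: Mapping[str, float]) -> list[tuple[str, float, float]]:
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    entries: list[tuple[str, float, float]] = []
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and ordered[j][1] == ordered[i][1]:
            j += 1
        mean_rank = (i + 1 + j) / 2.0  # mean of positions i+1 .. j
        for gene, s in ordered[i:j]:
            entries.append((gene, s, mean_rank))
        i = j
    return entries


def rank_candidates(disease: str, candidates: Iterable[str], disease_genes: Iterable[str],
                    profile: PerturbationProfile, scorer: SimilarityScorer,
                    normalized: bool = False) -> RankedList:
    """Score every candidate and return the descending priority list."""
    scores = {c: score_candidate(c, disease_genes, profile, scorer, normalized)
              for c in candidates}
    return RankedList(disease, tuple(_mean_ranks(scores)))


def _pool(all_genes: frozenset[str], training_genes: set[str], held_out: str,
          pool_mode: str) -> set[str]:
    if pool_mode == "all":
        return set(all_genes) | {held_out}
    return (set(all_genes) - training_genes) | {held_out}


def loo_cv(assoc: DiseaseGeneMap, candidate_genes: Iterable[str],
           profile: PerturbationProfile, scorer: SimilarityScorer,
           pool_mode: str = "exclude_training",
           k_grid: Sequence[int] = tuple(range(1, 101))) -> CVReport:
    """Leave-one-out cross-validation over every disease-gene association.

    For each association (d, g): g is withheld, the remaining genes of d are
    the training set, and g's rank is recorded among the candidate pool (all
    annotated network genes minus the training genes; ``pool_mode='all'``
    keeps them in). Diseases with fewer than two genes are skipped.
    """
    all_genes = frozenset(candidate_genes)
    trials: list[CVTrial] = []
    for disease, genes in sorted(assoc.associations.items()):
        if len(genes) < 2:
            continue
        for g in sorted(genes):
            training = set(genes) - {g}
            pool = _pool(all_genes, training, g, pool_mode)
            ranked = rank_candidates(disease, pool, training, profile, scorer)
            trials.append(CVTrial(disease, g, ranked.rank_of(g), len(pool)))
    return CVReport(tuple(trials), tuple(k_grid))


def auc_from_ranks(trials: Iterable[CVTrial]) -> float:
    """Rank-sum (Mann–Whitney) AUC: each trial contributes the fraction of
    its pool's negatives ranked below the held-out positive; mean over trials
    (a mid-rank handles ties because ranks are mean ranks)."""
    vals = []
    for t in trials:
        negatives = t.pool_size - 1
        if negatives <= 0:
            continue
        vals.append((t.pool_size - t.rank) / negatives)
    if not vals:
        raise ValueError("no informative trials")
    return float(np.mean(vals))


def kfold_cv(assoc: DiseaseGeneMap, folds: int, seed: int,
             candidate_genes: Iterable[str], profile: PerturbationProfile,
             scorer: SimilarityScorer, pool_mode: str = "exclude_training",
             k_grid: Sequence[int] = tuple(range(1, 101))) -> CVReport:
    """k-fold cross-validation with an ROC AUC summary.

    Associations are partitioned into ``folds`` random (seeded) folds; each
    fold is withheld in turn and its genes are ranked against the remaining
    associations. Held-out genes are positives and the rest of the pool
    negatives; AUC comes from the rank-sum formula.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    pairs = assoc.pairs()
    if len(pairs) < folds:
        raise ValueError(f"{len(pairs)} associations cannot fill {folds} folds")
    rng = random.Random(seed)
    order = pairs[:]
    rng.shuffle(order)
    fold_of = {pair: i % folds for i, pair in enumerate(order)}

    all_genes = frozenset(candidate_genes)
    trials: list[CVTrial] = []
    for f in range(folds):
        held = [p for p in pairs if fold_of[p] == f]
        for disease, g in held:
            training = {x for x in assoc.associations[disease]
                        if fold_of[(disease, x)] != f}
            if not training:
                continue
            pool = _pool(all_genes, training, g, pool_mode)
            ranked = rank_candidates(disease, pool, training, profile, scorer)
            trials.append(CVTrial(disease, g, ranked.rank_of(g), len(pool)))
    report = CVReport(tuple(trials), tuple(k_grid))
    return CVReport(report.trials, report.k_grid, auc=auc_from_ranks(trials))
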