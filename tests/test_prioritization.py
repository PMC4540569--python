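import random

import numpy as np
import pytest

import ctrlpaths as cp
from ctrlpaths.network_io import DiseaseGeneMap
from ctrlpaths.perturbation import PerturbationProfile
from ctrlpaths.prioritization import CVReport, CVTrial, _mean_ranks, auc_from_ranks


class FixedScorer:
    """Stub similarity engine driven by a literal set-similarity table."""

    def __init__(self, table):
        self.table = table

    def set_similarity(self, a, b, normalized=False):
        return self.table.get((frozenset(a), frozenset(b)), 0.0)


def profile_of(influences):
    return PerturbationProfile({k: frozenset(v) for k, v in influences.items()}, None)


class TestScoreCandidate:
    def test_maximum_over_disease_genes(self):
        profile = profile_of({"i": {"p"}, "x1": {"q"}, "x2": {"r"}, "x3": {"s"}})
        table = {(frozenset({"p"}), frozenset({"q"})): 2.1,
                 (frozenset({"p"}), frozenset({"r"})): 0.7,
                 (frozenset({"p"}), frozenset({"s"})): 1.3}
        score = cp.score_candidate("i", ["x1", "x2", "x3"], profile, FixedScorer(table))
        assert score == pytest.approx(2.1)

    def test_identical_influence_scores_set_size(self, bundle, bundle_scorer):
        # a planted gene scored against its own disease's genes: Pi sets
        # coincide on the module and every self-similarity is 1
        disease = sorted(bundle.associations.associations)[0]
        genes = sorted(bundle.associations.associations[disease])
        score = cp.score_candidate(genes[0], genes[1:], bundle.profile, bundle_scorer)
        assert score == pytest.approx(len(bundle.profile[genes[0]]))

    def test_empty_influence_scores_zero(self, bundle, bundle_scorer):
        sink = next(v for v in sorted(bundle.network.nodes) if not bundle.profile[v])
        disease = sorted(bundle.associations.associations)[0]
        genes = sorted(bundle.associations.associations[disease])
        assert cp.score_candidate(sink, genes, bundle.profile, bundle_scorer) == 0.0

    def test_empty_disease_genes_rejected(self, bundle, bundle_scorer):
        with pytest.raises(ValueError):
            cp.score_candidate("d0_g0", [], bundle.profile, bundle_scorer)


class TestRanking:
    def test_descending_order(self):
        entries = _mean_ranks({"g1": 3.0, "g2": 1.0, "g3": 2.0})
        assert [(g, r) for g, _, r in entries] == [("g1", 1.0), ("g3", 2.0), ("g2", 3.0)]

    def test_ties_get_mean_rank(self):
        entries = _mean_ranks({"a": 5.0, "b": 5.0, "c": 1.0})
        assert {g: r for g, _, r in entries} == {"a": 1.5, "b": 1.5, "c": 3.0}

    def test_planted_genes_top_ranked(self, bundle, bundle_scorer):
        disease = sorted(bundle.associations.associations)[0]
        genes = sorted(bundle.associations.associations[disease])
        pool = (bundle.annotations.genes & bundle.network.nodes) - frozenset(genes[1:])
        ranked = cp.rank_candidates(disease, pool, genes[1:], bundle.profile, bundle_scorer)
        assert ranked.rank_of(genes[0]) <= 3


class TestLooCV:
    def test_recall_reaches_one_at_full_threshold(self, bundle, bundle_scorer):
        genes = bundle.annotations.genes & bundle.network.nodes
        report = cp.loo_cv(bundle.associations, genes, bundle.profile, bundle_scorer)
        curve = dict(report.recall_curve())
        assert curve[100] == 1.0
        vals = [v for _, v in sorted(curve.items())]
        assert all(b >= a for a, b in zip(vals, vals[1:]))  # non-decreasing

    def test_small_diseases_skipped(self, bundle, bundle_scorer):
        assoc = DiseaseGeneMap({"solo": frozenset({"d0_g0"})})
        report = cp.loo_cv(assoc, bundle.annotations.genes & bundle.network.nodes,
                           bundle.profile, bundle_scorer)
        assert report.trials == ()

    def test_identical_influence_pair_always_first(self, bundle, bundle_scorer):
        """Two genes with equal Pi force each other to the top under the
        max-similarity score."""
        assoc = DiseaseGeneMap({"MIM:600000": bundle.associations.associations["MIM:600000"]})
        genes = bundle.annotations.genes & bundle.network.nodes
        report = cp.loo_cv(assoc, genes, bundle.profile, bundle_scorer)
        assert all(t.rank <= 3 for t in report.trials)

    def test_pool_modes(self, bundle, bundle_scorer):
        genes = bundle.annotations.genes & bundle.network.nodes
        excl = cp.loo_cv(bundle.associations, genes, bundle.profile, bundle_scorer)
        full = cp.loo_cv(bundle.associations, genes, bundle.profile, bundle_scorer,
                         pool_mode="all")
        assert all(f.pool_size >= e.pool_size for e, f in zip(excl.trials, full.trials))


class TestAUC:
    def test_perfect_separation(self):
        trials = [CVTrial("d", "g", 1.0, 50) for _ in range(5)]
        assert auc_from_ranks(trials) == pytest.approx(1.0)

    def test_random_ranks_near_half(self):
        rng = random.Random(0)
        trials = [CVTrial("d", "g", rng.randint(1, 100), 100) for _ in range(1000)]
        assert auc_from_ranks(trials) == pytest.approx(0.5, abs=0.03)

    def test_matches_pairwise_comparison_oracle(self):
        """Rank-sum AUC equals explicit positive-vs-negative comparison
        counting on a 10-positive / 50-negative pool."""
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, 1, 10)
        neg = rng.uniform(0, 1, 50)
        # each trial ranks one positive within itself + the 50 negatives
        trials = [CVTrial("d", "g", float(1 + np.sum(neg > p) + 0.5 * np.sum(neg == p)), 51)
                  for p in pos]
        oracle = np.mean([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / 50 for p in pos])
        assert auc_from_ranks(trials) == pytest.approx(float(oracle))


class TestKfoldCV:
    def test_auc_high_on_planted_benchmark(self, bundle, bundle_scorer):
        genes = bundle.annotations.genes & bundle.network.nodes
        report = cp.kfold_cv(bundle.associations, 5, 7, genes, bundle.profile, bundle_scorer)
        assert report.auc is not None and report.auc > 0.9

    def test_fold_partition_reproducible(self, bundle, bundle_scorer):
        genes = bundle.annotations.genes & bundle.network.nodes
        a = cp.kfold_cv(bundle.associations, 2, 3, genes, bundle.profile, bundle_scorer)
        b = cp.kfold_cv(bundle.associations, 2, 3, genes, bundle.profile, bundle_scorer)
        assert a.trials == b.trials and a.auc == b.auc

    def test_too_many_folds_rejected(self, bundle, bundle_scorer):
        assoc = DiseaseGeneMap({"d": frozenset({"d0_g0", "d0_g1"})})
        with pytest.raises(ValueError):
            cp.kfold_cv(assoc, 5, 0, {"d0_g0"}, bundle.profile, bundle_scorer)

    def test_folds_must_be_at_least_two(self, bundle, bundle_scorer):
        with pytest.raises(ValueError):
            cp.kfold_cv(bundle.associations, 1, 0, set(), bundle.profile, bundle_scorer)
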