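"""Split scores, ranking estimators, quartet decisions, and greedy tree
assembly."""

import warnings

import numpy as np
import pytest
from sklearn.base import clone

import splitrank as sr
from splitrank.models import PatternCounts
from splitrank.scoring import SplitScoreResult, greedy_tree, tree_from_splits
from splitrank.tree import Split

from conftest import generic_markov_tree


def full_svd_score(matrix, k):
    sv = np.linalg.svd(np.asarray(matrix, dtype=float), compute_uv=False)
    fro2 = (sv**2).sum()
    return np.sqrt(max(0.0, 1.0 - (sv[:k] ** 2).sum() / fro2))


class TestSplitScore:
    def test_low_rank_matrix_scores_zero(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(10, 4)) @ rng.normal(size=(4, 10))  # rank 4
        # the score is a square root of a cancellation-prone difference,
        # so its numerical floor is ~sqrt(machine epsilon)
        assert sr.split_score(m, 4).score == pytest.approx(0.0, abs=1e-7)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(8, 8))
        assert sr.split_score(3.7 * m, 4).score == pytest.approx(
            sr.split_score(m, 4).score, abs=1e-12
        )

    def test_matches_full_svd_oracle(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(10, 8)) @ rng.normal(size=(8, 10))  # rank 8
        res = sr.split_score(m, 4)
        assert res.score == pytest.approx(full_svd_score(m, 4), abs=1e-10)

    def test_score_identity(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(12, 7))
        res = sr.split_score(m, 4)
        lhs = res.score**2 + (res.top_singular_values**2).sum() / res.frobenius_norm**2
        assert lhs == pytest.approx(1.0, abs=1e-10)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            sr.split_score(np.zeros((4, 4)), 4)

    def test_sparse_large_flattening(self):
        # huge nominal shape, tiny nonzero block: compaction must handle it
        taxa = tuple(f"t{i:02d}" for i in range(16))
        counts = PatternCounts(
            {(0,) * 16: 5, (1,) * 16: 4, tuple(range(4)) * 4: 2}, taxa
        )
        flat = sr.flattening(counts, Split(taxa[:8], taxa[8:]))
        res = sr.split_score(flat.matrix, 4)
        assert 0.0 <= res.score <= 1.0


class TestSplitScorer:
    def test_displayed_splits_rank_best(self, six_taxon_dist, six_taxon_tree):
        displayed = six_taxon_tree.displayed_splits()
        for method in ("flattening", "subflattening"):
            scorer = sr.SplitScorer(method=method).fit(six_taxon_dist)
            top = {r.split for r in scorer.results_[: len(displayed)]}
            assert top == displayed

    def test_counts_vs_frequencies_identical_ranking(self, six_taxon_dist):
        counts = sr.simulate_pattern_counts(six_taxon_dist, 2000, seed=5)
        freqs = counts.normalise()
        a = {str(r.split): r.score for r in sr.SplitScorer().fit(counts).results_}
        b = {str(r.split): r.score for r in sr.SplitScorer().fit(freqs).results_}
        for text, score in a.items():
            assert b[text] == pytest.approx(score, abs=1e-6)

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        tree = generic_markov_tree(5, rng)
        counts = sr.simulate_pattern_counts(
            sr.site_pattern_distribution(tree), 800, rng
        )
        perm = dict(zip(counts.taxon_order, ("3", "0", "4", "2", "1")))
        permuted = PatternCounts(
            {
                tuple(
                    pat[counts.taxon_order.index(x)]
                    for x in sorted(counts.taxon_order, key=lambda y: perm[y])
                ): c
                for pat, c in counts.data.items()
            },
            tuple(sorted(perm.values())),
        )
        s1 = {str(r.split): r.score for r in sr.SplitScorer().fit(counts).results_}
        s2 = {str(r.split): r.score for r in sr.SplitScorer().fit(permuted).results_}
        for text, score in s1.items():
            mapped = Split.from_string(text, counts.taxon_order).apply_permutation(perm)
            assert s2[str(mapped)] == pytest.approx(score, abs=1e-6)

    def test_memory_guard_for_all_flattenings(self):
        taxa = tuple(f"t{i:02d}" for i in range(17))
        counts = PatternCounts({(0,) * 17: 1}, taxa)
        with pytest.raises(ValueError, match="splits"):
            sr.SplitScorer(method="flattening").fit(counts)
        # an explicit split list is still allowed
        res = sr.SplitScorer(
            method="flattening", splits=[Split(taxa[:2], taxa[2:])]
        ).fit(counts)
        assert len(res.results_) == 1

    def test_sklearn_protocol(self, six_taxon_dist):
        est = sr.SplitScorer(method="flattening", k=4)
        assert est.get_params()["method"] == "flattening"
        cloned = clone(est).set_params(method="subflattening")
        cloned.fit(six_taxon_dist)
        assert hasattr(cloned, "results_") and not hasattr(est, "results_")


class TestQuartetDecision:
    def test_exact_distribution_recovers_true_split(self):
        from splitrank.experiments import quartet_tree

        tree = quartet_tree({x: 0.1 for x in "abcd"}, 0.1)
        dist = sr.site_pattern_distribution(tree)
        for method in ("flattening", "subflattening"):
            assert sr.best_quartet_split(dist, method=method) == Split("ab", "cd")

    def test_easy_simulated_quartets(self):
        from splitrank.experiments import quartet_tree

        tree = quartet_tree({x: 0.1 for x in "abcd"}, 0.1)
        dist = sr.site_pattern_distribution(tree)
        truth = Split("ab", "cd")
        for method in ("flattening", "subflattening"):
            wins = sum(
                sr.best_quartet_split(
                    sr.simulate_pattern_counts(dist, 1000, seed=[41, i]),
                    method=method,
                )
                == truth
                for i in range(100)
            )
            assert wins >= 99

    def test_star_tree_tie_flagged(self):
        from splitrank.experiments import star_quartet_tree

        dist = sr.site_pattern_distribution(star_quartet_tree(0.1, 0.1))
        split, tied, results = sr.best_quartet_split(
            dist, method="flattening", return_details=True
        )
        assert tied
        scores = [r.score for r in results]
        assert max(scores) - min(scores) < 1e-6

    def test_requires_four_taxa(self, six_taxon_dist):
        with pytest.raises(ValueError):
            sr.best_quartet_split(six_taxon_dist)


class TestGreedyTree:
    def test_recovers_six_taxon_tree(self, six_taxon_dist, six_taxon_tree):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            est = sr.GreedySplitTree(method="subflattening").fit(six_taxon_dist)
        assert est.complete_
        assert set(est.splits_) == {
            s for s in six_taxon_tree.displayed_splits() if not s.is_trivial
        }
        assert est.tree_.displayed_splits() == six_taxon_tree.displayed_splits()

    def test_quartet_reduces_to_best_split(self):
        from splitrank.experiments import quartet_tree

        dist = sr.site_pattern_distribution(quartet_tree({x: 0.1 for x in "abcd"}, 0.1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            est = sr.GreedySplitTree().fit(dist)
        assert est.splits_ == [sr.best_quartet_split(dist)]

    def test_incompatible_runner_up_skipped(self):
        taxa = tuple("012345")

        def res(text, score):
            return SplitScoreResult(
                Split.from_string(text, taxa), "subflattening", score,
                np.ones(4), 1.0,
            )

        ranked = [
            res("01|2345", 0.01),
            res("02|1345", 0.02),  # incompatible with the first
            res("012|345", 0.03),
            res("0123|45", 0.04),
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            kept, complete = greedy_tree(ranked)
        assert complete
        texts = [str(s) for s in kept]
        assert "02|1345" not in texts
        assert texts == ["01|2345", "012|345", "0123|45"]
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert sr.is_compatible(a, b)

    def test_partial_result_warns(self):
        taxa = tuple("012345")
        ranked = [
            SplitScoreResult(
                Split.from_string("01|2345", taxa), "subflattening", 0.1,
                np.ones(4), 1.0,
            )
        ]
        with pytest.warns(UserWarning, match="partial"):
            kept, complete = greedy_tree(ranked, n_taxa=6, _warn=False)
        assert not complete and len(kept) == 1

    def test_bias_warning_emitted(self, six_taxon_dist):
        scorer = sr.SplitScorer().fit(six_taxon_dist)
        with pytest.warns(UserWarning, match="biased"):
            greedy_tree(scorer.results_)

    def test_tree_from_splits_roundtrip(self):
        rng = np.random.default_rng(31)
        for t in (4, 6, 9):
            tree = sr.random_binary_tree([str(i) for i in range(t)], rng, 0.1)
            rebuilt = tree_from_splits(
                [s for s in tree.displayed_splits() if not s.is_trivial],
                tree.taxa,
            )
            assert rebuilt.displayed_splits() == tree.displayed_splits()
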