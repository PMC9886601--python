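"""Simulation-study plumbing at reduced problem sizes.

These tests exercise determinism, table annotation, and the qualitative
behaviour of each experiment; the full-size study conditions are run by
the acceptance suite.
"""

import numpy as np
import pandas as pd
import pytest

import splitrank as sr
from splitrank import experiments as ex


class TestPresetTrees:
    def test_six_taxon_topology(self):
        tree = ex.balanced_six_taxon_tree(0.1)
        nontrivial = {str(s) for s in tree.displayed_splits() if not s.is_trivial}
        assert nontrivial == {"01|2345", "012|345", "0123|45"}
        assert all(
            d["length"] == pytest.approx(0.1)
            for _, _, d in tree.graph.edges(data=True)
        )

    def test_twenty_taxon_tree(self):
        tree = ex.balanced_twenty_taxon_tree(0.05)
        assert tree.n_taxa == 20
        assert all(tree.graph.degree(n) == 3 for n in tree.internal_nodes())

    def test_lba_presets_cover_symmetric_cases(self):
        assert set(ex.LBA_PRESETS) == {
            "all-short", "opposite-long", "cherry-long", "all-long"
        }
        tree = ex._lba_tree("opposite-long", 0.05, 0.5)
        lengths = {
            x: tree.graph.edges[next(iter(tree.graph.neighbors(x))), x]["length"]
            for x in "abcd"
        }
        assert lengths["a"] == lengths["c"] == 0.5
        assert lengths["b"] == lengths["d"] == 0.05


class TestSixTaxonExperiment:
    def test_determinism_and_annotations(self, six_taxon_tree):
        kwargs = dict(
            branch_length=0.1, sequence_lengths=(1000,), replicates=3, seed=5
        )
        t1 = ex.six_taxon_experiment(**kwargs)
        t2 = ex.six_taxon_experiment(**kwargs)
        pd.testing.assert_frame_equal(t1, t2)
        assert len(t1) == 3 * 9 * 2  # replicates x orbit reps x methods
        for _, row in t1.iterrows():
            split = sr.Split.from_string(row["split"], six_taxon_tree.taxa)
            assert row["shared_edges"] == sr.shared_edges(six_taxon_tree, split)
            assert row["parsimony"] == sr.parsimony_score(six_taxon_tree, split)

    def test_scores_group_by_shared_edges(self):
        table = ex.six_taxon_experiment(
            branch_length=0.1, sequence_lengths=(1000,), replicates=10, seed=1
        )
        for method in ("flattening", "subflattening"):
            sub = table[table["method"] == method]
            means = sub.groupby("shared_edges")["score"].mean()
            assert list(means.index) == sorted(means.index)
            assert means.is_monotonic_increasing

    def test_exact_probability_limit(self, six_taxon_dist, six_taxon_tree):
        # displayed splits score ~0 at exact probabilities
        displayed = six_taxon_tree.displayed_splits()
        for res in sr.score_all_splits(six_taxon_dist):
            if res.split in displayed:
                assert res.score < 1e-6
            else:
                assert res.score > 1e-3


class TestSharedEdgesRegression:
    def test_all_subsets_fitted(self):
        summary = ex.shared_edges_regression(replicates=2, seed=3)
        assert len(summary.adj_r2) == 7  # all non-empty subsets of 3 predictors
        assert summary.best_subset in summary.adj_r2
        assert len(summary.rows) == 2 * 25  # non-trivial splits only

    def test_degenerate_equal_lengths(self):
        # zero-width length interval: regression must still run
        summary = ex.shared_edges_regression(
            length_low=0.4, length_high=0.4, replicates=2, seed=1
        )
        assert summary.rows["shared_edges"].nunique() <= 4
        assert np.isfinite(summary.best_adj_r2)

    def test_trivial_splits_optional(self):
        summary = ex.shared_edges_regression(
            replicates=1, seed=2, include_trivial=True
        )
        assert len(summary.rows) == 31


class TestSplitBalance:
    def test_small_tree_rows_and_capping(self):
        rng = np.random.default_rng(0)
        tree = sr.random_binary_tree([f"x{i}" for i in range(8)], rng, 0.05)
        with pytest.warns(UserWarning, match="sampling all"):
            rows, summary, increase = ex.split_balance_experiment(
                tree=tree, sequence_length=300, n_per_size=100, seed=4
            )
        # sizes 2..4 on 8 taxa; size-2 has C(8,2)=28 < 100 candidates
        assert set(rows["size"]) == {2, 3, 4}
        assert len(rows[rows["size"] == 2]) == 2 * 28
        assert set(increase) == {"flattening", "subflattening"}

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(1)
        tree = sr.random_binary_tree([f"x{i}" for i in range(8)], rng, 0.05)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1, _, _ = ex.split_balance_experiment(
                tree=tree, sequence_length=200, n_per_size=10, seed=9
            )
            r2, _, _ = ex.split_balance_experiment(
                tree=tree, sequence_length=200, n_per_size=10, seed=9
            )
        pd.testing.assert_frame_equal(r1, r2)


class TestLBAQuartets:
    def test_easy_regime_high_accuracy(self):
        df = ex.lba_quartet_experiment(
            sequence_lengths=(1000,), replicates=20, seed=2, presets=("all-short",)
        )
        assert (df["percent_correct"] >= 90).all()

    def test_output_shape_and_bounds(self):
        df = ex.lba_quartet_experiment(
            sequence_lengths=(100, 200), replicates=5, seed=7
        )
        assert len(df) == 4 * 2 * 2
        assert df["percent_correct"].between(0, 100).all()
        again = ex.lba_quartet_experiment(
            sequence_lengths=(100, 200), replicates=5, seed=7
        )
        pd.testing.assert_frame_equal(df, again)


class TestStarTree:
    def test_symmetric_star_is_unbiased(self):
        df = ex.star_tree_experiment(
            long_length=0.1, short_length=0.1, replicates=100, seed=3
        )
        assert np.allclose(df["long_pair_fraction"], 1.0 / 3.0, atol=0.15)

    def test_reference_line(self):
        df = ex.star_tree_experiment(replicates=5, seed=1)
        assert np.allclose(df["unbiased_reference"], 1 / 3)


class TestSlidingWindow:
    def _write_two_regime_alignment(self, tmp_path, rng, L_seg=3000):
        # segment 1 evolves on ab|cd, segment 2 on ac|bd: the scan must
        # switch its best split near the boundary
        from splitrank.models import STATE_ORDERS

        def columns(tree, L):
            dist = sr.site_pattern_distribution(tree)
            pats, w = dist.as_arrays()
            idx = rng.choice(len(w), size=L, p=w / w.sum())
            return pats[idx], dist.taxon_order

        t1 = ex.quartet_tree({x: 0.1 for x in "abcd"}, 0.2)
        t2 = ex.quartet_tree({x: 0.1 for x in "abcd"}, 0.2, labels=("a", "c", "b", "d"))
        cols1, order = columns(t1, L_seg)
        cols2, _ = columns(t2, L_seg)
        cols = np.vstack([cols1, cols2])
        alphabet = STATE_ORDERS[4]
        path = tmp_path / "two_regime.fasta"
        with open(path, "w") as fh:
            for i, name in enumerate(order):
                seq = "".join(alphabet[s] for s in cols[:, i])
                fh.write(f">{name}\n{seq}\n")
        return path

    def test_detects_regime_switch(self, tmp_path):
        rng = np.random.default_rng(13)
        path = self._write_two_regime_alignment(tmp_path, rng)
        df = ex.sliding_window(path, window=1000, step=1000)
        assert len(df) == 6
        assert df.iloc[0]["best_subflattening"] == "ab|cd"
        assert df.iloc[-1]["best_subflattening"] == "ac|bd"
        assert df.iloc[0]["best_flattening"] == "ab|cd"
        assert df.iloc[-1]["best_flattening"] == "ac|bd"

    def test_single_window_and_count_formula(self, tmp_path):
        rng = np.random.default_rng(14)
        path = self._write_two_regime_alignment(tmp_path, rng, L_seg=500)
        df = ex.sliding_window(path, window=1000, step=1000)
        assert len(df) == 1
        df2 = ex.sliding_window(path, window=400, step=150)
        assert len(df2) == (1000 - 400) // 150 + 1

    def test_short_alignment_rejected(self, tmp_path):
        rng = np.random.default_rng(15)
        path = self._write_two_regime_alignment(tmp_path, rng, L_seg=100)
        with pytest.raises(ValueError, match="shorter"):
            ex.sliding_window(path, window=5000)


class TestConfig:
    def test_config_file_roundtrip(self, tmp_path):
        path = tmp_path / "cfg.txt"
        path.write_text(
            "branch_length = 0.8\nsequence_lengths = 1000, 10000\n"
            "replicates = 50\nseed = 3\nmethods = flattening\n# comment\n"
        )
        cfg = ex.ExperimentConfig.from_file(path)
        assert cfg.branch_length == 0.8
        assert cfg.sequence_lengths == (1000, 10000)
        assert cfg.replicates == 50 and cfg.seed == 3
        assert cfg.methods == ("flattening",)
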