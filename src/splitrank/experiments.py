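"""Simulation studies comparing flattening and subflattening split scores.

All experiments simulate under the Jukes-Cantor model, draw site-pattern
counts either multinomially from an exact distribution (small trees) or
site-by-site down the tree (large trees), and score splits with both
constructions.  Each experiment is a pure function of its configuration
and seed: per-replicate random streams are derived from the master seed
by a counter scheme (``default_rng([seed, stream, replicate])``), so any
replicate is reproducible in isolation.

Study designs
-------------
* :func:`six_taxon_experiment` -- score distributions for the nine
  symmetry classes (automorphism orbits) of non-trivial splits on the
  balanced six-taxon caterpillar.
* :func:`shared_edges_regression` -- how well shared edges, split
  parsimony and split size predict the split score when branch lengths
  are randomised.
* :func:`split_balance_experiment` -- the bias of scores towards
  unbalanced splits on a 20-taxon tree.
* :func:`lba_quartet_experiment` / :func:`star_tree_experiment` -- long
  branch attraction: quartets with long pendant edges, and the zero
  internal-edge star tree where any preference for pairing the two long
  edges is pure bias (an unbiased method picks each split 1/3 of the
  time).
* :func:`sliding_window` -- windowed best-quartet-split scan along an
  alignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .models import (
    PatternCounts,
    simulate_alignment_counts,
    simulate_pattern_counts,
    site_pattern_distribution,
)
from .scoring import METHODS, best_quartet_split, score_all_splits
from .tree import (
    PhyloTree,
    Split,
    parse_newick,
    parsimony_score,
    shared_edges,
    split_orbits,
    splits_of_size,
)

__all__ = [
    "ExperimentConfig",
    "balanced_six_taxon_tree",
    "balanced_twenty_taxon_tree",
    "quartet_tree",
    "star_quartet_tree",
    "LBA_PRESETS",
    "six_taxon_experiment",
    "shared_edges_regression",
    "RegressionSummary",
    "split_balance_experiment",
    "lba_quartet_experiment",
    "star_tree_experiment",
    "sliding_window",
]


@dataclass
class ExperimentConfig:
    """Key-value experiment configuration (CLI/file front end).

    Unused fields are ignored by experiments that do not need them.
    """

    tree: str | None = None
    model: str = "JC"
    branch_length: float = 0.1
    short_length: float = 0.05
    long_length: float = 0.5
    length_low: float = 0.1
    length_high: float = 1.0
    sequence_lengths: tuple = (1000,)
    replicates: int = 100
    seed: int = 0
    methods: tuple = METHODS

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        values: dict = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                val = val.strip()
                if key in ("sequence_lengths", "methods"):
                    parts = [p.strip() for p in val.split(",") if p.strip()]
                    values[key] = tuple(
                        int(p) for p in parts
                    ) if key == "sequence_lengths" else tuple(parts)
                elif key in ("replicates", "seed"):
                    values[key] = int(val)
                elif key in ("tree", "model"):
                    values[key] = val
                else:
                    values[key] = float(val)
        return cls(**values)


# ---------------------------------------------------------------------------
# Preset trees


def balanced_six_taxon_tree(branch_length: float = 0.1, k: int = 4) -> PhyloTree:
    """The balanced six-taxon caterpillar with cherries (0,1) and (4,5).

    Non-trivial displayed splits: 01|2345, 012|345, 0123|45.  All branch
    lengths equal; uniform root distribution.
    """
    b = float(branch_length)
    text = f"((0:{b},1:{b}):{b},2:{b},(3:{b},(4:{b},5:{b}):{b}):{b});"
    return parse_newick(text, k=k)


def balanced_twenty_taxon_tree(branch_length: float = 0.05, k: int = 4) -> PhyloTree:
    """A balanced 20-leaf tree (recursive halving of the leaf set).

    Used as the default topology for the split-balance experiment; any
    other 20-taxon tree may be passed to that experiment instead.
    """
    labels = [chr(ord("a") + i) for i in range(20)]
    b = float(branch_length)

    def nest(ls):
        if len(ls) == 1:
            return f"{ls[0]}:{b}"
        mid = (len(ls) + 1) // 2
        return f"({nest(ls[:mid])},{nest(ls[mid:])}):{b}"

    text = f"({nest(labels[:10])},{nest(labels[10:])});"
    return parse_newick(text, k=k)


def quartet_tree(
    pendants: dict, internal: float, labels=("a", "b", "c", "d"), k: int = 4
) -> PhyloTree:
    """Quartet ((a,b),(c,d)) with per-leaf pendant lengths."""
    a, b, c, d = labels
    text = (
        f"(({a}:{pendants[a]},{b}:{pendants[b]}):{internal},"
        f"{c}:{pendants[c]},{d}:{pendants[d]});"
    )
    return parse_newick(text, k=k)


def star_quartet_tree(
    long_length: float, short_length: float, labels=("a", "b", "c", "d"), k: int = 4
) -> PhyloTree:
    """Star quartet (zero internal edge): leaves a and c long, b and d
    short."""
    a, b, c, d = labels
    pend = {a: long_length, b: short_length, c: long_length, d: short_length}
    return quartet_tree(pend, 0.0, labels=labels, k=k)


#: LBA quartet presets: which pendant edges are long on ((a,b),(c,d)).
#: The internal edge is always short.  "opposite-long" puts the two long
#: edges on opposite sides of the internal edge (the classic attraction
#: setting); "cherry-long" puts them on the same cherry.
LBA_PRESETS = {
    "all-short": (),
    "opposite-long": ("a", "c"),
    "cherry-long": ("a", "b"),
    "all-long": ("a", "b", "c", "d"),
}


def _lba_tree(preset: str, short: float, long: float) -> PhyloTree:
    longs = LBA_PRESETS[preset]
    pend = {x: (long if x in longs else short) for x in "abcd"}
    return quartet_tree(pend, short)


def _rng(seed, stream, replicate) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream), int(replicate)])


# ---------------------------------------------------------------------------
# Six-taxon score distributions


def six_taxon_experiment(
    branch_length: float = 0.1,
    sequence_lengths=(1000, 10000),
    replicates: int = 1000,
    seed: int = 0,
    methods=METHODS,
) -> pd.DataFrame:
    """Split-score distributions on the balanced six-taxon tree.

    For each sequence length, draws *replicates* multinomial samples from
    the exact site-pattern distribution and scores one representative of
    each of the 9 non-trivial split orbits with each method.  Rows carry
    the orbit id, split size, shared-edges count and parsimony score so
    histograms can be grouped by any of them.
    """
    tree = balanced_six_taxon_tree(branch_length)
    dist = site_pattern_distribution(tree)
    orbits = [orb for orb in split_orbits(tree) if not orb[0].is_trivial]
    reps = [orb[0] for orb in orbits]
    annot = {
        s: (i, s.size, shared_edges(tree, s), parsimony_score(tree, s))
        for i, s in enumerate(reps)
    }
    rows = []
    for li, L in enumerate(sequence_lengths):
        for r in range(replicates):
            counts = simulate_pattern_counts(dist, L, _rng(seed, li, r))
            for method in methods:
                for res in score_all_splits(counts, method=method, splits=reps):
                    orbit, size, sh, pars = annot[res.split]
                    rows.append(
                        (r, L, method, str(res.split), orbit, size, sh, pars,
                         res.score, seed)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "replicate", "sequence_length", "method", "split", "orbit", "size",
            "shared_edges", "parsimony", "score", "seed",
        ],
    )


# ---------------------------------------------------------------------------
# Shared-edges regression


@dataclass
class RegressionSummary:
    """Adjusted R-squared for every predictor subset, plus the raw rows."""

    rows: pd.DataFrame
    adj_r2: dict
    best_subset: tuple
    best_adj_r2: float

    def adj_r2_for(self, *predictors) -> float:
        return self.adj_r2[tuple(sorted(predictors))]


PREDICTORS = ("shared_edges", "parsimony", "size")


def shared_edges_regression(
    length_low: float = 0.1,
    length_high: float = 1.0,
    replicates: int = 20,
    seed: int = 0,
    method: str = "subflattening",
    include_trivial: bool = False,
) -> RegressionSummary:
    """Predict split scores from tree statistics on randomised trees.

    Each replicate draws every edge length of the balanced six-taxon
    topology uniformly from ``[length_low, length_high]``, computes the
    exact site-pattern distribution and scores every split.  Linear
    models on every non-empty subset of {shared edges, parsimony score,
    split size} are fitted to the pooled rows and ranked by adjusted
    R-squared.

    Trivial splits are displayed by every tree and score ~0 regardless of
    the branch lengths, so by default only the 25 non-trivial splits
    enter the pool; ``include_trivial=True`` adds the other six.
    """
    rows = []
    for r in range(replicates):
        rng = _rng(seed, 0, r)
        tree = balanced_six_taxon_tree(0.1)
        tree.set_lengths(lambda: rng.uniform(length_low, length_high))
        dist = site_pattern_distribution(tree)
        for res in score_all_splits(dist, method=method):
            s = res.split
            if s.is_trivial and not include_trivial:
                continue
            rows.append(
                (r, str(s), s.size, shared_edges(tree, s),
                 parsimony_score(tree, s), res.score)
            )
    df = pd.DataFrame(
        rows,
        columns=["replicate", "split", "size", "shared_edges", "parsimony", "score"],
    )
    adj = {}
    for n in range(1, len(PREDICTORS) + 1):
        for subset in itertools.combinations(PREDICTORS, n):
            X = sm.add_constant(df[list(subset)].astype(float))
            fit = sm.OLS(df["score"], X).fit()
            adj[tuple(sorted(subset))] = float(fit.rsquared_adj)
    best = max(adj, key=adj.get)
    return RegressionSummary(df, adj, best, adj[best])


# ---------------------------------------------------------------------------
# Split balance bias


def split_balance_experiment(
    tree: PhyloTree | None = None,
    sequence_length: int = 500,
    branch_length: float = 0.05,
    n_per_size: int = 190,
    seed: int = 0,
    methods=METHODS,
):
    """Mean split score as a function of split size on a 20-taxon tree.

    Simulates one alignment of *sequence_length* sites, samples
    ``n_per_size`` splits uniformly without replacement for each size
    (all of them when fewer exist), and scores each with each method.
    Returns ``(rows, summary)`` where *summary* has the per-size mean and
    standard deviation and the relative increase of the mean from the
    smallest non-trivial size to the largest.
    """
    if tree is None:
        tree = balanced_twenty_taxon_tree(branch_length)
    taxa = tree.taxa
    t = len(taxa)
    counts = simulate_alignment_counts(tree, sequence_length, _rng(seed, 0, 0))
    rng = _rng(seed, 1, 0)
    rows = []
    for m in range(2, t // 2 + 1):
        candidates = list(splits_of_size(taxa, m))
        n = min(n_per_size, len(candidates))
        if n < n_per_size:
            import warnings

            warnings.warn(
                f"only {len(candidates)} splits of size {m}; sampling all of them",
                UserWarning,
            )
        chosen = [candidates[i] for i in rng.choice(len(candidates), n, replace=False)]
        for method in methods:
            for res in score_all_splits(counts, method=method, splits=chosen):
                rows.append((method, m, str(res.split), res.score))
    df = pd.DataFrame(rows, columns=["method", "size", "split", "score"])
    summary = (
        df.groupby(["method", "size"])["score"].agg(["mean", "std"]).reset_index()
    )
    increase = {}
    for method in methods:
        sub = summary[summary["method"] == method].set_index("size")["mean"]
        increase[method] = float(
            (sub.loc[sub.index.max()] - sub.loc[sub.index.min()])
            / sub.loc[sub.index.min()]
        )
    return df, summary, increase


# ---------------------------------------------------------------------------
# Long branch attraction


def lba_quartet_experiment(
    short_length: float = 0.05,
    long_length: float = 0.5,
    sequence_lengths=tuple(range(100, 1001, 100)),
    replicates: int = 100,
    seed: int = 0,
    presets=tuple(LBA_PRESETS),
    methods=METHODS,
) -> pd.DataFrame:
    """Percent of replicates recovering the true quartet split ab|cd.

    Four pendant-length presets around the quartet ((a,b),(c,d)); the
    internal edge always takes the short length.
    """
    truth = Split("ab", "cd")
    rows = []
    for pi, preset in enumerate(presets):
        tree = _lba_tree(preset, short_length, long_length)
        dist = site_pattern_distribution(tree)
        for li, L in enumerate(sequence_lengths):
            correct = {m: 0 for m in methods}
            for r in range(replicates):
                counts = simulate_pattern_counts(
                    dist, L, _rng(seed, 100 * pi + li, r)
                )
                for method in methods:
                    if best_quartet_split(counts, method=method) == truth:
                        correct[method] += 1
            for method in methods:
                rows.append(
                    (preset, L, method, 100.0 * correct[method] / replicates)
                )
    return pd.DataFrame(
        rows, columns=["preset", "sequence_length", "method", "percent_correct"]
    )


def star_tree_experiment(
    long_length: float = 0.5,
    short_length: float = 0.1,
    sequence_length: int = 1000,
    replicates: int = 100,
    seed: int = 0,
    methods=METHODS,
) -> pd.DataFrame:
    """Fraction of replicates pairing the two long edges on a star tree.

    The generating tree has a zero-length internal edge, long pendants on
    a and c, short on b and d, so no split is true; an unbiased method
    picks the long-pair split ac|bd one third of the time.
    """
    tree = star_quartet_tree(long_length, short_length)
    dist = site_pattern_distribution(tree)
    long_pair = Split("ac", "bd")
    chose = {m: 0 for m in methods}
    for r in range(replicates):
        counts = simulate_pattern_counts(dist, sequence_length, _rng(seed, 0, r))
        for method in methods:
            if best_quartet_split(counts, method=method) == long_pair:
                chose[method] += 1
    return pd.DataFrame(
        {
            "method": list(methods),
            "long_pair_fraction": [chose[m] / replicates for m in methods],
            "unbiased_reference": 1.0 / 3.0,
        }
    )


# ---------------------------------------------------------------------------
# Sliding window


def sliding_window(
    alignment_path,
    window: int = 10000,
    step: int = 1000,
    methods=METHODS,
    k: int = 4,
) -> pd.DataFrame:
    """Best quartet split per window along a four-taxon alignment.

    Windows are *window* columns long and advance by *step*; columns with
    non-ACGT symbols are dropped within each window.  The output has one
    row per window with the winning split per method and a flag for
    whether all methods agree.
    """
    from .models import STATE_ORDERS
    from Bio import SeqIO

    records = list(SeqIO.parse(str(alignment_path), "fasta"))
    if len(records) != 4:
        raise ValueError("sliding window scan requires a 4-taxon alignment")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError("sequences have unequal lengths")
    L = lengths.pop()
    if L < window:
        raise ValueError(f"alignment ({L} bp) is shorter than one window")
    taxon_order = tuple(sorted(r.id for r in records))
    seqs = {r.id: str(r.seq).upper() for r in records}
    alphabet = STATE_ORDERS[k]
    lookup = np.full(256, -1, dtype=np.int64)
    for i, c in enumerate(alphabet):
        lookup[ord(c)] = i
    mat = np.stack(
        [lookup[np.frombuffer(seqs[x].encode(), dtype=np.uint8)] for x in taxon_order]
    )
    rows = []
    for start in range(0, L - window + 1, step):
        block = mat[:, start : start + window]
        good = np.all(block >= 0, axis=0)
        cols = block[:, good].T
        pats, cnts = np.unique(cols, axis=0, return_counts=True)
        counts = PatternCounts(
            {tuple(p): int(c) for p, c in zip(pats, cnts)}, taxon_order, k
        )
        winners = {
            m: str(best_quartet_split(counts, method=m)) for m in methods
        }
        rows.append(
            {
                "start": start,
                "end": start + window,
                **{f"best_{m}": winners[m] for m in methods},
                "all_agree": len(set(winners.values())) == 1,
            }
        )
    return pd.DataFrame(rows)
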