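"""Split scores, ranking, quartet decisions, and greedy tree assembly.

The split score of a flattening or subflattening ``F`` with ``k`` states
is

    ``SplitScore(F) = (1 - sum_{i<=k} sigma_i^2 / ||F||^2)^(1/2)``,

the normalised Frobenius distance from ``F`` to the nearest rank-``k``
matrix (Eckart-Young), computed from the ``k`` largest singular values
only.  A split displayed by the generating tree gives a matrix of rank
``k`` at exact probabilities, hence score 0; false splits score higher.
The score is invariant to positive rescaling of the input, so raw counts
and relative frequencies give identical scores.

The estimators follow the scikit-learn protocol: construct with
hyper-parameters, call :meth:`fit` on a pattern table, read trailing-
underscore attributes afterwards.  :class:`SplitScorer` ranks candidate
splits by score; :class:`GreedySplitTree` additionally assembles a tree
by scanning the ranking and keeping each split compatible with those
already kept.  The module-level functions are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .flattening import flattening as _build_flattening
from .flattening import singular_values as _singular_values
from .subflattening import subflattening as _build_subflattening
from .tree import PhyloTree, Split, enumerate_splits, is_compatible

__all__ = [
    "SplitScoreResult",
    "split_score",
    "SplitScorer",
    "GreedySplitTree",
    "score_all_splits",
    "best_quartet_split",
    "greedy_tree",
    "tree_from_splits",
]

METHODS = ("flattening", "subflattening")

#: absolute score difference below which two splits are reported as tied;
#: the score is a square root of a cancellation-prone difference, so its
#: numerical noise floor is ~sqrt(machine epsilon) ~ 1e-8
TIE_TOLERANCE = 1e-6

#: taxon count above which scoring every flattening is refused outright
#: (a single 17-taxon flattening already has more than 4^17 entries; the
#: sparse representation survives, but 2^(t-1)-1 of them will not)
MAX_TAXA_ALL_FLATTENINGS = 16


@dataclass
class SplitScoreResult:
    """Score and supporting quantities for one split."""

    split: Split
    method: str
    score: float
    top_singular_values: np.ndarray
    frobenius_norm: float
    tied: bool = False

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0 + 1e-12:
            raise ValueError(f"split score {self.score} outside [0, 1]")


def split_score(matrix, k: int) -> SplitScoreResult:
    """Score an arbitrary matrix against rank ``k``.

    Returns a result fragment with ``split=None``; the ``k`` largest
    singular values are computed with a truncated method when the input
    is large and sparse.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    import scipy.sparse as sp

    if sp.issparse(matrix):
        fro = np.sqrt(float((matrix.data**2).sum()))
    else:
        matrix = np.asarray(matrix, dtype=float)
        fro = float(np.linalg.norm(matrix))
    if fro == 0.0:
        raise ValueError("split score is undefined for an all-zero matrix")
    sv = _singular_values(matrix, top=k)
    score = float(np.sqrt(max(0.0, 1.0 - float((sv**2).sum()) / fro**2)))
    return SplitScoreResult(None, "matrix", score, sv, fro)


def _score_one(data, split: Split, method: str, k: int) -> SplitScoreResult:
    if method == "flattening":
        mat = _build_flattening(data, split).matrix
    elif method == "subflattening":
        mat = _build_subflattening(data, split).matrix
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    frag = split_score(mat, k)
    return SplitScoreResult(
        split, method, frag.score, frag.top_singular_values, frag.frobenius_norm
    )


class SplitScorer(BaseEstimator):
    """Rank candidate splits of a pattern table by split score.

    Parameters
    ----------
    method:
        ``"subflattening"`` (default) or ``"flattening"``.
    k:
        State-space size used for the rank-``k`` score; defaults to the
        data's own ``k`` when None.
    splits:
        Candidate splits; all ``2^(t-1) - 1`` splits when None.  Scoring
        every flattening is refused for more than
        ``MAX_TAXA_ALL_FLATTENINGS`` taxa unless an explicit list is
        given.
    transform:
        Optional similarity-transform matrix for subflattenings
        (defaults to the Hadamard-type transform for the data's ``k``).

    Attributes
    ----------
    results_ : list of :class:`SplitScoreResult`, ascending by score
        (ties broken by canonical split order and flagged).
    table_ : ``pandas.DataFrame`` with one row per split.
    taxa_ : the taxon order of the fitted data.
    """

    def __init__(self, method="subflattening", k=None, splits=None, transform=None):
        self.method = method
        self.k = k
        self.splits = splits
        self.transform = transform

    def fit(self, X, y=None):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        k = X.k if self.k is None else self.k
        splits = self.splits
        if splits is None:
            if self.method == "flattening" and X.t > MAX_TAXA_ALL_FLATTENINGS:
                raise ValueError(
                    f"scoring all {2 ** (X.t - 1) - 1} flattenings of {X.t} taxa "
                    "would exhaust memory; pass an explicit `splits` list or use "
                    "method='subflattening'"
                )
            splits = enumerate_splits(X.taxon_order)
        results = []
        for s in splits:
            if self.method == "subflattening":
                mat = _build_subflattening(X, s, H=self.transform).matrix
            else:
                mat = _build_flattening(X, s).matrix
            frag = split_score(mat, k)
            results.append(
                SplitScoreResult(
                    s, self.method, frag.score, frag.top_singular_values,
                    frag.frobenius_norm,
                )
            )
        results.sort(key=lambda r: (r.score, r.split.sort_key()))
        for a, b in zip(results, results[1:]):
            if abs(a.score - b.score) <= TIE_TOLERANCE:
                a.tied = b.tied = True
        self.results_ = results
        self.taxa_ = X.taxon_order
        self.k_ = k
        self.table_ = pd.DataFrame(
            {
                "split": [str(r.split) for r in results],
                "size": [r.split.size for r in results],
                "score": [r.score for r in results],
                "tied": [r.tied for r in results],
                **{
                    f"sv{i + 1}": [
                        r.top_singular_values[i]
                        if i < len(r.top_singular_values)
                        else np.nan
                        for r in results
                    ]
                    for i in range(k)
                },
            }
        )
        return self


class GreedySplitTree(BaseEstimator):
    """Naive greedy tree assembly from ranked split scores.

    Scores all non-trivial splits, scans the ranking from best (smallest)
    score, and keeps each split compatible with all splits kept so far,
    stopping once ``t - 3`` non-trivial splits are collected.  The kept
    split set defines an unrooted binary tree.

    Note that the scan compares scores across splits of different sizes,
    which the split-score bias towards unbalanced splits makes
    statistically dubious; a warning is emitted.  This mirrors the naive
    algorithm the scores were designed to study, flaw included.

    Attributes
    ----------
    splits_ : kept non-trivial splits, in the order selected.
    complete_ : True when ``t - 3`` compatible splits were found.
    tree_ : :class:`PhyloTree` built from the kept splits.
    ranking_ : the underlying :class:`SplitScorer` results.
    """

    def __init__(self, method="subflattening", k=None):
        self.method = method
        self.k = k

    def fit(self, X, y=None):
        candidates = [s for s in enumerate_splits(X.taxon_order) if not s.is_trivial]
        scorer = SplitScorer(method=self.method, k=self.k, splits=candidates).fit(X)
        self.ranking_ = scorer.results_
        self.splits_, self.complete_ = greedy_tree(
            self.ranking_, n_taxa=X.t, _warn=False
        )
        self.tree_ = tree_from_splits(self.splits_, X.taxon_order)
        return self


def score_all_splits(data, method="subflattening", splits=None, k=None):
    """Score (a list of) splits and return results in ascending order."""
    return SplitScorer(method=method, k=k, splits=splits).fit(data).results_


def best_quartet_split(data, method="subflattening", k=None, return_details=False):
    """Best of the three non-trivial quartet splits by split score.

    Ties (scores equal within tolerance) are resolved by canonical split
    order and flagged on the winning result.
    """
    if data.t != 4:
        raise ValueError("quartet decision requires exactly 4 taxa")
    results = score_all_splits(
        data,
        method=method,
        k=k,
        splits=[s for s in enumerate_splits(data.taxon_order) if not s.is_trivial],
    )
    best = results[0]
    if return_details:
        return best.split, best.tied, results
    return best.split


def greedy_tree(ranked, n_taxa=None, _warn=True):
    """Scan a ranked result list, keeping mutually compatible splits.

    Returns ``(splits, complete)`` where *complete* is False when fewer
    than ``t - 3`` mutually compatible non-trivial splits were found (a
    partial result, reported with a warning).
    """
    nontrivial = [r for r in ranked if not r.split.is_trivial]
    if not nontrivial:
        raise ValueError("no non-trivial splits in the ranking")
    if _warn:
        warnings.warn(
            "greedy selection compares split scores across split sizes, which "
            "are biased towards unbalanced splits; interpret with care",
            UserWarning,
            stacklevel=2,
        )
    t = n_taxa if n_taxa is not None else len(nontrivial[0].split.taxa)
    needed = t - 3
    kept: list = []
    for r in nontrivial:
        if all(is_compatible(r.split, s) for s in kept):
            kept.append(r.split)
        if len(kept) == needed:
            break
    complete = len(kept) == needed
    if not complete:
        warnings.warn(
            f"only {len(kept)} of {needed} compatible splits found; "
            "returning a partial (unresolved) tree",
            UserWarning,
            stacklevel=2,
        )
    return kept, complete


def tree_from_splits(splits, taxa, k: int = 4) -> PhyloTree:
    """Build the tree displaying a pairwise-compatible set of non-trivial
    splits (plus all trivial ones) by successive star refinement."""
    taxa = tuple(sorted(taxa))
    g = nx.Graph()
    centre = 0
    for x in taxa:
        g.add_edge(centre, x, length=0.0)
    leaf_set = set(taxa)

    def neighbor_leafsets(v):
        """For each neighbor of v, the taxa in its component of T - v."""
        h = g.copy()
        h.remove_node(v)
        out = {}
        for n in g.neighbors(v):
            out[n] = frozenset(nx.node_connected_component(h, n) & leaf_set)
        return out

    tree = PhyloTree(g, k=k)
    for split in sorted(set(splits), key=lambda s: s.sort_key()):
        if split.is_trivial:
            continue
        if split in tree.displayed_splits():
            continue
        placed = False
        for v in [n for n in g.nodes if n not in leaf_set]:
            sides = neighbor_leafsets(v)
            if not all(
                ls <= split.side_a or ls <= split.side_b for ls in sides.values()
            ):
                continue
            a_neighbors = [n for n, ls in sides.items() if ls <= split.side_a]
            w = max((n for n in g.nodes if not isinstance(n, str)), default=0) + 1
            for n in a_neighbors:
                length = g.edges[v, n]["length"]
                g.remove_edge(v, n)
                g.add_edge(w, n, length=length)
            g.add_edge(v, w, length=0.0)
            placed = True
            break
        if not placed:
            raise ValueError(f"split {split} is incompatible with the tree so far")
        tree = PhyloTree(g, k=k)
    return tree
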