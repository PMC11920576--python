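"""Key-gene prioritisation: random-forest Gini importance and Friends-style
mean semantic similarity, intersected at the top-k.

The forest is a bagging ensemble of scikit-learn decision trees grown one at
a time so that (a) the out-of-bag (OOB) error can be recorded for every
forest size from 1 to max_trees — the curve used to pick the tree count —
and (b) importance is the unnormalised mean decrease in Gini impurity (MDG)
averaged over trees, matching the classical randomForest measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .semsim import DEFAULT_EDGE_WEIGHTS, OntologyDAG, similarity_matrix

logger = logging.getLogger(__name__)


@dataclass
class NtreeSelection:
    """OOB error as a function of forest size and the chosen tree count.

    ``chosen_ntree`` is the smallest forest size attaining the minimum of
    the error curve.
    """

    error_by_ntree: np.ndarray
    chosen_ntree: int


@dataclass
class ImportanceRanking:
    """Genes ranked by mean decrease in Gini (descending, ties lexicographic)."""

    mdg: "pd.Series"          # index = gene, descending
    ntree: int
    seed: int

    @property
    def order(self) -> list[str]:
        return list(self.mdg.index)

    def top(self, k: int) -> list[str]:
        return self.order[:k]


@dataclass
class FriendsRanking:
    """Genes ranked by mean pairwise semantic similarity to the others."""

    genes: list[str]
    matrix: np.ndarray
    mean_similarity: "pd.Series"   # descending

    @property
    def order(self) -> list[str]:
        return list(self.mean_similarity.index)

    def top(self, k: int) -> list[str]:
        return self.order[:k]


def _validate_xy(expr: pd.DataFrame, labels: Sequence[str]
                 ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Expression matrix is genes × samples; features are genes."""
    X = expr.to_numpy(dtype=float).T          # samples × genes
    y = np.asarray(labels)
    if X.shape[0] != len(y):
        raise ValueError(
            f"{X.shape[0]} samples in matrix but {len(y)} labels")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        small = classes[counts < 2].tolist()
        raise ValueError(f"class(es) {small} have fewer than 2 samples")
    return X, y, list(expr.index)


def _grow_forest(X: np.ndarray, y: np.ndarray, ntree: int, seed: int):
    """Grow ``ntree`` bagged trees; yield (tree, oob_mask) per tree.

    Each tree sees a bootstrap sample of the rows and sqrt(p) features per
    split; all randomness flows from ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    for _ in range(ntree):
        boot = rng.integers(0, n, size=n)
        oob = np.ones(n, dtype=bool)
        oob[boot] = False
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        yield tree, oob


def select_ntree(expr: pd.DataFrame, labels: Sequence[str],
                 max_trees: int = 500, seed: int = 0) -> NtreeSelection:
    """Record the OOB error for every forest size 1..max_trees.

    The error at size t is the misclassification rate of the majority OOB
    vote over trees 1..t, over samples that have at least one OOB vote so
    far.  The chosen size is the smallest one attaining the minimum error.
    """
    X, y, _ = _validate_xy(expr, labels)
    classes = np.unique(y)
    class_idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_idx[c] for c in y])
    n = X.shape[0]
    votes = np.zeros((n, len(classes)), dtype=int)
    errors = np.empty(max_trees)
    for t, (tree, oob) in enumerate(_grow_forest(X, y, max_trees, seed)):
        if oob.any():
            pred = tree.predict(X[oob])
            for i, p in zip(np.flatnonzero(oob), pred):
                votes[i, class_idx[p]] += 1
        voted = votes.sum(axis=1) > 0
        if voted.any():
            maj = votes[voted].argmax(axis=1)
            errors[t] = float(np.mean(maj != y_idx[voted]))
        else:
            errors[t] = np.nan
        # propagate last defined error if nothing voted yet
        if np.isnan(errors[t]):
            errors[t] = 1.0
    chosen = int(np.argmin(errors)) + 1
    return NtreeSelection(errors, chosen)


def rank_genes_gini(expr: pd.DataFrame, labels: Sequence[str],
                    ntree: int, seed: int = 0) -> ImportanceRanking:
    """Rank genes by mean decrease in Gini impurity over a bagged forest.

    MDG per gene is the unnormalised total impurity decrease attributed to
    splits on that gene, averaged over trees.  Constant features get MDG 0
    and are retained.  Ties are broken lexicographically by gene id.
    """
    X, y, genes = _validate_xy(expr, labels)
    if ntree < 1:
        raise ValueError("ntree must be >= 1")
    total = np.zeros(X.shape[1])
    for tree, _oob in _grow_forest(X, y, ntree, seed):
        total += tree.tree_.compute_feature_importances(normalize=False)
    mdg = total / ntree
    ser = pd.Series(mdg, index=genes, name="mdg")
    ser = ser.iloc[np.lexsort((ser.index, -ser.values))]
    return ImportanceRanking(ser, ntree, seed)


def friends_rank(annotations: Mapping[str, Iterable[str]],
                 dag: OntologyDAG,
                 weights: Mapping[str, float] = DEFAULT_EDGE_WEIGHTS
                 ) -> FriendsRanking:
    """Rank genes by mean Wang/BMA similarity to the other candidates.

    Genes without annotations are excluded with a warning; the pairwise
    matrix is symmetric with unit diagonal and the mean excludes self.
    """
    usable = {g: list(ts) for g, ts in annotations.items() if list(ts)}
    dropped = sorted(set(annotations) - set(usable))
    if dropped:
        logger.warning("excluding unannotated gene(s): %s", dropped)
    if len(usable) < 2:
        raise ValueError("need at least 2 annotated genes")
    genes, mat = similarity_matrix(dag, usable, weights)
    n = len(genes)
    means = (mat.sum(axis=1) - np.diag(mat)) / (n - 1)
    ser = pd.Series(means, index=genes, name="mean_similarity")
    ser = ser.iloc[np.lexsort((ser.index, -ser.values))]
    return FriendsRanking(genes, mat, ser)


def core_gene_intersection(rf_ranking: ImportanceRanking,
                           friends_ranking: FriendsRanking,
                           k: int = 3) -> frozenset[str]:
    """Intersect the top-k genes of the two rankings.

    Mirrors the step that names the core SE-driven gene; an empty
    intersection is reported (with a warning), not raised.
    """
    if k > len(rf_ranking.order) or k > len(friends_ranking.order):
        raise ValueError(f"k={k} exceeds the ranked gene count")
    core = frozenset(rf_ranking.top(k)) & frozenset(friends_ranking.top(k))
    if not core:
        logger.warning("top-%d lists are disjoint; no core gene", k)
    return core
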