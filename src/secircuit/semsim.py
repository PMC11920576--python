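"""Ontology-graph semantic similarity (Wang method, best-match average).

A small, self-contained implementation of the Wang graph-based term
similarity with the conventional edge weights (is_a 0.8, part_of 0.6) and
the best-match-average (BMA) combination over gene term sets — the measure
behind "Friends"-style mean-similarity gene ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class OntologyDAG:
    """Directed acyclic term graph: child -> [(parent, edge_type), ...]."""

    parents: dict[str, tuple[tuple[str, str], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, plist in self.parents.items():
            for parent, _etype in plist:
                if parent not in self.parents:
                    raise ValueError(f"term {term!r} has unknown parent {parent!r}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str) -> None:
            state[t] = 1
            for p, _ in self.parents[t]:
                s = state.get(p, 0)
                if s == 1:
                    raise ValueError(f"ontology cycle through {t!r} -> {p!r}")
                if s == 0:
                    visit(p)
            state[t] = 2

        for t in self.parents:
            if state.get(t, 0) == 0:
                visit(t)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    def s_values(self, term: str,
                 weights: Mapping[str, float] = DEFAULT_EDGE_WEIGHTS
                 ) -> dict[str, float]:
        """Wang S-values: the semantic contribution of each ancestor of
        ``term`` (including itself, with S = 1).

        S(t) = max over child edges on paths from ``term``:
        S(child) * w(edge); computed by relaxation, exact on a DAG.
        """
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        s: dict[str, float] = {term: 1.0}
        frontier = [term]
        while frontier:
            nxt: list[str] = []
            for child in frontier:
                for parent, etype in self.parents[child]:
                    w = weights.get(etype)
                    if w is None:
                        raise ValueError(f"unknown edge type {etype!r}")
                    cand = s[child] * w
                    if cand > s.get(parent, 0.0):
                        s[parent] = cand
                        nxt.append(parent)
            frontier = nxt
        return s


def term_similarity(dag: OntologyDAG, a: str, b: str,
                    weights: Mapping[str, float] = DEFAULT_EDGE_WEIGHTS) -> float:
    """Wang similarity of two terms in [0, 1].

    sim(A, B) = sum over shared ancestors of (S_A(t) + S_B(t)) divided by
    (SV(A) + SV(B)), where SV is the sum of a term's own S-values.
    """
    sa = dag.s_values(a, weights)
    sb = dag.s_values(b, weights)
    shared = set(sa) & set(sb)
    if not shared:
        return 0.0
    num = sum(sa[t] + sb[t] for t in shared)
    return num / (sum(sa.values()) + sum(sb.values()))


def gene_similarity_bma(dag: OntologyDAG, terms_a: Iterable[str],
                        terms_b: Iterable[str],
                        weights: Mapping[str, float] = DEFAULT_EDGE_WEIGHTS
                        ) -> float:
    """Best-match-average similarity of two term sets.

    BMA = (sum_i max_j sim(a_i, b_j) + sum_j max_i sim(a_i, b_j)) / (m + n).
    """
    ta = sorted(set(terms_a))
    tb = sorted(set(terms_b))
    if not ta or not tb:
        raise ValueError("empty term set")
    m = np.array([[term_similarity(dag, a, b, weights) for b in tb] for a in ta])
    return float((m.max(axis=1).sum() + m.max(axis=0).sum()) / (len(ta) + len(tb)))


def similarity_matrix(dag: OntologyDAG,
                      annotations: Mapping[str, Iterable[str]],
                      weights: Mapping[str, float] = DEFAULT_EDGE_WEIGHTS
                      ) -> tuple[list[str], np.ndarray]:
    """Symmetric gene-gene BMA similarity matrix with unit diagonal.

    Genes are sorted so the result is independent of input order.
    """
    genes = sorted(annotations)
    term_sets = {g: sorted(set(annotations[g])) for g in genes}
    for g, ts in term_sets.items():
        if not ts:
            raise ValueError(f"gene {g!r} has no annotations")
        for t in ts:
            if t not in dag:
                raise ValueError(f"gene {g!r} annotated to unknown term {t!r}")
    n = len(genes)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = gene_similarity_bma(dag, term_sets[genes[i]],
                                    term_sets[genes[j]], weights)
            mat[i, j] = mat[j, i] = s
    return genes, mat
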