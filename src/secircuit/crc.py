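"""Core transcriptional regulatory circuitry (CRC) inference.

Five steps over super-enhancer (SE) assignments: (1) take the genes owning
SEs as the active set; (2) keep the transcription factors among them;
(3-4) scan each SE's constituent sequences with every TF's position weight
matrix at an exact p-value threshold (default 1e-4), computed by dynamic
programming over the integer-discretised log-odds score distribution;
(5) keep TFs with >= 3 own-motif hits in their own SE (self-regulating),
draw the TF -> SE binding digraph with the same rule, and enumerate all
maximal fully interconnected circuits by recursive (Bron-Kerbosch with
pivoting) search.  Circuits are scored by mean member frequency and the top
circuit is the representative CRC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BASES, GeneModel, PWM

logger = logging.getLogger(__name__)

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
SCORE_SCALE = 1000  # log-odds discretisation: integer units of 1/1000 bit
DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_MIN_INSTANCES = 3

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class MotifHit:
    tf_name: str
    se_id: str
    constituent: int
    offset: int
    strand: str           # '+' or '-'
    score: float          # log2 odds
    p_value: float


@dataclass(frozen=True)
class SelfRegulatingTF:
    tf_name: str
    se_ids: tuple[str, ...]
    own_motif_count: int


@dataclass
class CircuitGraph:
    """Digraph on self-regulating TFs; edge A->B: A's motif passes the
    instance rule in B's SE constituents.  Every node carries its implied
    self-loop; reported degree tables exclude self-loops."""

    nodes: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def out_degree(self, t: str, include_self: bool = False) -> int:
        return sum(1 for a, b in self.edges
                   if a == t and (include_self or a != b))

    def in_degree(self, t: str, include_self: bool = False) -> int:
        return sum(1 for a, b in self.edges
                   if b == t and (include_self or a != b))

    def degree_table(self) -> pd.DataFrame:
        rows = [(t, self.in_degree(t), self.out_degree(t))
                for t in sorted(self.nodes)]
        return pd.DataFrame(rows, columns=["tf", "in_degree", "out_degree"])


@dataclass(frozen=True)
class Circuit:
    members: tuple[str, ...]      # sorted
    score: float = float("nan")


# ---------------------------------------------------------------------------
# Exact PWM p-values
# ---------------------------------------------------------------------------

def _int_logodds_matrix(pwm: PWM, background: Sequence[float]) -> np.ndarray:
    """(length, 5) integer log2-odds matrix in 1/SCORE_SCALE units.

    Column 4 is the 'N' code and scores 0 (background expectation).
    """
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
        raise ValueError("background must be 4 positive frequencies summing to 1")
    p = pwm.as_array()
    if (p <= 0).any():
        raise ValueError(
            f"PWM {pwm.tf_name} has zero probabilities; apply a pseudocount")
    lo = np.log2(p / bg)
    m = np.rint(lo * SCORE_SCALE).astype(np.int64)
    return np.hstack([m, np.zeros((m.shape[0], 1), dtype=np.int64)])


def score_distribution(pwm: PWM,
                       background: Sequence[float] = UNIFORM_BACKGROUND
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the discretised score of a random background
    k-mer, by position-wise convolution.

    Returns (scores, probabilities) with scores ascending; probabilities
    sum to 1.
    """
    m = _int_logodds_matrix(pwm, background)[:, :4]
    bg = np.asarray(background, dtype=float)
    lo_min = int(m.min(axis=1).sum())
    lo_max = int(m.max(axis=1).sum())
    width = lo_max - lo_min + 1
    dist = np.zeros(width)
    # running offset: minimum attainable partial score so far
    dist[0] = 1.0
    cur_min = 0
    cur_len = 1
    for j in range(m.shape[0]):
        row = m[j]
        new_min = cur_min + int(row.min())
        new_len = cur_len + int(row.max() - row.min())
        new = np.zeros(new_len)
        for b in range(4):
            shift = int(row[b]) + cur_min - new_min
            new[shift:shift + cur_len] += bg[b] * dist[:cur_len]
        dist = new
        cur_min, cur_len = new_min, new_len
    scores = np.arange(cur_min, cur_min + cur_len)
    mask = dist > 0
    return scores[mask], dist[mask]


def pwm_threshold_score(pwm: PWM, p_threshold: float = DEFAULT_P_THRESHOLD,
                        background: Sequence[float] = UNIFORM_BACKGROUND
                        ) -> tuple[int | None, dict[int, float]]:
    """Smallest discretised score whose background tail probability is at
    most ``p_threshold``, plus the exact tail map score -> P(S >= score).

    Returns (None, tails) when even the maximum attainable score is too
    probable, in which case no window can pass.
    """
    if not 0.0 < p_threshold < 1.0 and p_threshold != 1.0:
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    scores, probs = score_distribution(pwm, background)
    tail = np.cumsum(probs[::-1])[::-1]
    tails = {int(s): float(t) for s, t in zip(scores, tail)}
    passing = scores[tail <= p_threshold]
    if len(passing) == 0:
        return None, tails
    return int(passing[0]), tails


def _window_scores(codes: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Integer score of every length-k window of an encoded sequence."""
    k = m.shape[0]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out += m[j, codes[j:j + n]]
    return out


def scan_motifs(se_sequences: Mapping[str, Sequence[str]],
                pwms: Sequence[PWM],
                p_threshold: float = DEFAULT_P_THRESHOLD,
                background: Sequence[float] = UNIFORM_BACKGROUND
                ) -> list[MotifHit]:
    """Scan both strands of every SE constituent sequence with every PWM.

    A hit is any window whose discretised log-odds score reaches the exact
    p-value threshold.  Sequences shorter than a motif yield no hits.
    'N' bases contribute zero log-odds.  Hits are returned in deterministic
    (tf, se, constituent, offset, strand) order.
    """
    hits: list[MotifHit] = []
    for pwm in sorted(pwms, key=lambda p: p.tf_name):
        thr, tails = pwm_threshold_score(pwm, p_threshold, background)
        if thr is None:
            logger.warning("PWM %s: threshold unattainable at p=%g",
                           pwm.tf_name, p_threshold)
            continue
        m = _int_logodds_matrix(pwm, background)
        # reverse-complement matrix scans the forward sequence for - strand
        mrc = m[::-1, [3, 2, 1, 0, 4]]
        tail_scores = np.array(sorted(tails))
        tail_vals = np.array([tails[int(s)] for s in tail_scores])

        def pval(score: int) -> float:
            i = np.searchsorted(tail_scores, score)
            return float(tail_vals[min(i, len(tail_vals) - 1)])

        for se_id in sorted(se_sequences):
            for ci, seq in enumerate(se_sequences[se_id]):
                codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
                for strand, mat in (("+", m), ("-", mrc)):
                    ws = _window_scores(codes, mat)
                    for off in np.flatnonzero(ws >= thr):
                        s = int(ws[off])
                        hits.append(MotifHit(
                            pwm.tf_name, se_id, ci, int(off), strand,
                            s / SCORE_SCALE, pval(s)))
    return hits


# ---------------------------------------------------------------------------
# Circuit construction
# ---------------------------------------------------------------------------

def identify_se_tfs(se_assignment: Mapping[str, str],
                    gene_models: Sequence[GeneModel],
                    pwms: Sequence[PWM]) -> dict[str, list[str]]:
    """TFs among SE-assigned genes that have a PWM, with their SE ids.

    ``se_assignment`` maps SE id -> assigned gene id.  TFs lacking a PWM
    are excluded with a warning.  A TF assigned several SEs keeps all of
    them (hits are pooled downstream).
    """
    is_tf = {g.gene_id for g in gene_models if g.is_tf}
    has_pwm = {p.tf_name for p in pwms}
    out: dict[str, list[str]] = {}
    skipped: set[str] = set()
    for se_id in sorted(se_assignment):
        gene = se_assignment[se_id]
        if gene not in is_tf:
            continue
        if gene not in has_pwm:
            skipped.add(gene)
            continue
        out.setdefault(gene, []).append(se_id)
    if skipped:
        logger.warning("TF(s) without a PWM excluded: %s", sorted(skipped))
    return out


def _own_hit_counts(tf_ses: Mapping[str, Sequence[str]],
                    hits: Sequence[MotifHit]) -> dict[tuple[str, str], int]:
    """Count hits of each TF's motif within each candidate TF's SE set."""
    se_owner = {se: tf for tf, ses in tf_ses.items() for se in ses}
    counts: dict[tuple[str, str], int] = {}
    for h in hits:
        owner = se_owner.get(h.se_id)
        if owner is None:
            continue
        key = (h.tf_name, owner)
        counts[key] = counts.get(key, 0) + 1
    return counts


def detect_self_regulating(tf_ses: Mapping[str, Sequence[str]],
                           hits: Sequence[MotifHit],
                           min_instances: int = DEFAULT_MIN_INSTANCES
                           ) -> list[SelfRegulatingTF]:
    """TFs whose own SE constituents carry >= min_instances own-motif hits."""
    counts = _own_hit_counts(tf_ses, hits)
    out = []
    for tf in sorted(tf_ses):
        c = counts.get((tf, tf), 0)
        if c >= min_instances:
            out.append(SelfRegulatingTF(tf, tuple(tf_ses[tf]), c))
    return out


def build_tf_graph(selfreg: Sequence[SelfRegulatingTF],
                   hits: Sequence[MotifHit],
                   min_instances: int = DEFAULT_MIN_INSTANCES) -> CircuitGraph:
    """Edge A->B iff A's motif has >= min_instances hits in B's SE set."""
    tf_ses = {t.tf_name: t.se_ids for t in selfreg}
    counts = _own_hit_counts(tf_ses, hits)
    nodes = sorted(tf_ses)
    edges = {(a, b) for (a, b), c in counts.items()
             if c >= min_instances and a in tf_ses and b in tf_ses}
    return CircuitGraph(nodes, edges)


def _bron_kerbosch(adj: Mapping[str, set[str]]) -> list[tuple[str, ...]]:
    """Maximal cliques of an undirected graph, Bron-Kerbosch with pivoting."""
    cliques: list[tuple[str, ...]] = []

    def expand(r: set[str], p: set[str], x: set[str]) -> None:
        if not p and not x:
            cliques.append(tuple(sorted(r)))
            return
        pivot = max(p | x, key=lambda u: (len(adj[u] & p), u))
        for v in sorted(p - adj[pivot]):
            expand(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    expand(set(), set(adj), set())
    return cliques


def enumerate_circuits(graph: CircuitGraph) -> list[Circuit]:
    """All maximal fully interconnected circuits (size >= 2).

    A circuit is a maximal set in which every ordered member pair has an
    edge — a maximal clique of the underlying graph restricted to
    bidirectional edges.  Output order is deterministic (sorted member
    tuples).
    """
    adj: dict[str, set[str]] = {t: set() for t in graph.nodes}
    for a, b in graph.edges:
        if a != b and (b, a) in graph.edges:
            adj[a].add(b)
            adj[b].add(a)
    cliques = [c for c in _bron_kerbosch(adj) if len(c) >= 2]
    return [Circuit(c) for c in sorted(cliques)]


def score_circuits(circuits: Sequence[Circuit]
                   ) -> tuple[list[Circuit], Circuit | None]:
    """Score circuits by mean member frequency and pick the representative.

    A TF's frequency f(t) is the fraction of circuits containing it; a
    circuit's score is the mean of f over its members.  Circuits are ranked
    by descending score, ties to the larger circuit then lexicographic
    members; the top circuit is the representative CRC.
    """
    if not circuits:
        logger.warning("no circuits to score")
        return [], None
    n = len(circuits)
    freq: dict[str, float] = {}
    for c in circuits:
        for t in c.members:
            freq[t] = freq.get(t, 0.0) + 1.0 / n
    scored = [Circuit(c.members, sum(freq[t] for t in c.members) / len(c.members))
              for c in circuits]
    scored.sort(key=lambda c: (-c.score, -len(c.members), c.members))
    return scored, scored[0]


def hits_table(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.tf_name, h.se_id, h.constituent, h.offset, h.strand,
          h.score, h.p_value) for h in hits],
        columns=["tf", "se_id", "constituent", "offset", "strand",
                 "score", "p_value"],
    )
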