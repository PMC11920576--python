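"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (transitive closure by repeated
passes, exhaustive enumeration, closed forms) and shares no code with the
package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_stitch(peaks, tss_list, stitch, excl):
    """Transitive-closure merge of peaks honouring the gap and TSS rules.

    ``peaks`` are (chrom, start, end) tuples; ``tss_list`` is (chrom, tss)
    tuples.  Returns (merged regions, excluded single-peak regions), each a
    sorted list of (chrom, start, end, sorted constituent tuple).
    """
    def is_excluded(p):
        c, s, e = p
        return any(tc == c and s <= t + excl and e - 1 >= t - excl
                   for tc, t in tss_list)

    excluded = sorted(p for p in peaks if is_excluded(p))
    rest = [p for p in peaks if not is_excluded(p)]
    groups = [{p} for p in rest]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(a[0] == b[0]
                       and max(a[1] - b[2], b[1] - a[2]) <= stitch
                       for a in groups[i] for b in groups[j]):
                    groups[i] |= groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    merged = sorted(
        (min(p[1] for p in g), max(p[2] for p in g), next(iter(g))[0],
         tuple(sorted(g)))
        for g in groups)
    merged = [(c, s, e, cons) for s, e, c, cons in merged]
    merged.sort()
    return merged, [(c, s, e, ((c, s, e),)) for c, s, e in excluded]


def brute_cutoff(scores):
    """Exhaustive argmin(y_i - x_i) with ties to the largest index.

    Returns (cutoff_index, cutoff_score, n_super) on the ascending order,
    or None when degenerate (n < 3 or constant).
    """
    s = sorted(scores)
    n = len(s)
    if n < 3 or s[0] == s[-1]:
        return None
    best_i, best_d = 0, math.inf
    for i in range(n):
        x = i / (n - 1)
        y = (s[i] - s[0]) / (s[-1] - s[0])
        d = y - x
        if d <= best_d:  # ties -> largest index
            best_i, best_d = i, d
    cutoff = s[best_i]
    return best_i, cutoff, sum(1 for v in s if v > cutoff)


def brute_nearest_gene(midpoint, genes):
    """Exhaustive nearest-TSS search; genes are (gene_id, tss) on one
    chromosome.  Ties -> smaller TSS, then lexicographic id."""
    return min(genes, key=lambda g: (abs(g[1] - midpoint), g[1], g[0]))[0]


def brute_circuits(nodes, edges):
    """All maximal S (|S| >= 2) with every ordered pair an edge, by
    checking every subset."""
    nodes = sorted(nodes)
    edge_set = set(edges)
    full = []
    for r in range(2, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all((a, b) in edge_set for a in sub for b in sub if a != b):
                full.append(frozenset(sub))
    maximal = [s for s in full if not any(s < t for t in full)]
    return sorted(tuple(sorted(s)) for s in maximal)


def brute_pwm_tail(matrix_int, bg):
    """Exact tail P(S >= s) of the discretised PWM score of a random
    background k-mer, by enumerating all 4^k words.

    ``matrix_int`` is the (k, 4) integer log-odds matrix.  Returns a dict
    score -> tail probability.
    """
    k = matrix_int.shape[0]
    scores = {}
    for word in itertools.product(range(4), repeat=k):
        s = int(sum(matrix_int[i, b] for i, b in enumerate(word)))
        p = float(np.prod([bg[b] for b in word]))
        scores[s] = scores.get(s, 0.0) + p
    out = {}
    acc = 0.0
    for s in sorted(scores, reverse=True):
        acc += scores[s]
        out[s] = acc
    return out


def brute_hypergeom_upper(N, K, n, k):
    """P[X >= k] for X ~ Hypergeom(N, K, n), by summing the exact mass."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom
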