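"""ROSE-style super-enhancer calling.

Constituent enhancer peaks are stitched whenever the gap between consecutive
peaks is at most the stitching distance (default 12,500 bp), except that
peaks within ±2,500 bp of an annotated TSS are excluded from stitching and
kept as standalone regions.  Stitched regions are ranked by input-subtracted
H3K27ac signal and the super-enhancer cutoff is the discrete slope-1 tangent
point (inflection point) of the 0-1 scaled rank-vs-signal curve: regions
scoring above it are super-enhancers.  Each region is then assigned the gene
whose TSS is nearest its midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, Peak

DEFAULT_STITCH_DISTANCE = 12_500
DEFAULT_TSS_EXCLUSION = 2_500


@dataclass(frozen=True)
class StitchedEnhancer:
    """A gap-merged run of constituent peaks (or one TSS-excluded peak)."""

    chrom: str
    start: int
    end: int
    constituents: tuple[Peak, ...]
    excluded_from_stitching: bool = False

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def score(self) -> float:
        """Input-subtracted signal, clamped at zero on the constituent sum."""
        total = sum(p.sample_signal - p.input_signal for p in self.constituents)
        return max(0.0, total)


@dataclass
class RankedEnhancerTable:
    """Stitched enhancers with scores, sorted so rank 1 is the highest score."""

    entries: list[StitchedEnhancer]
    scores: np.ndarray           # aligned with entries, non-increasing
    stitch_distance: int = DEFAULT_STITCH_DISTANCE
    tss_exclusion: int = DEFAULT_TSS_EXCLUSION

    def __len__(self) -> int:
        return len(self.entries)

    def region_id(self, i: int) -> str:
        e = self.entries[i]
        return f"{e.chrom}:{e.start}-{e.end}"


@dataclass(frozen=True)
class SECutoff:
    """Inflection-point cutoff separating super from typical enhancers."""

    cutoff_score: float
    cutoff_index: int        # ascending-order index of the tangent point
    n_super: int
    degenerate: bool = False


@dataclass(frozen=True)
class GeneAssignment:
    gene_id: str | None
    distance: int | None     # signed TSS - midpoint; None if unassigned


def tss_excluded(peak: Peak, tss_by_chrom: dict[str, np.ndarray],
                 tss_exclusion: int) -> bool:
    """True if the peak overlaps [tss - excl, tss + excl] (both ends inclusive)
    of any TSS on its chromosome."""
    tss = tss_by_chrom.get(peak.chrom)
    if tss is None or len(tss) == 0:
        return False
    # peak [start, end) overlaps closed window iff start <= tss+excl and
    # end-1 >= tss-excl
    lo = np.searchsorted(tss, peak.start - tss_exclusion)
    hi = np.searchsorted(tss, (peak.end - 1) + tss_exclusion, side="right")
    return hi > lo


def _tss_index(genes: Sequence[GeneModel]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g.tss)
    return {c: np.array(sorted(v)) for c, v in by_chrom.items()}


def stitch_enhancers(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion: int = DEFAULT_TSS_EXCLUSION,
) -> list[StitchedEnhancer]:
    """Merge peaks into stitched enhancer regions with TSS exclusion.

    A peak overlapping any TSS ± ``tss_exclusion`` window is emitted as its
    own single-constituent region flagged ``excluded_from_stitching``.  The
    remaining peaks are merged transitively whenever the gap between
    consecutive peaks (next.start - current.end) is at most
    ``stitch_distance``.  Output is sorted by (chrom, start, end).
    """
    if stitch_distance < 0:
        raise ValueError(f"stitch_distance must be >= 0, got {stitch_distance}")
    if tss_exclusion < 0:
        raise ValueError(f"tss_exclusion must be >= 0, got {tss_exclusion}")
    tss_by_chrom = _tss_index(genes)
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end, p.name))
    regions: list[StitchedEnhancer] = []
    run: list[Peak] = []
    run_end = 0

    def flush() -> None:
        if run:
            regions.append(StitchedEnhancer(
                run[0].chrom, run[0].start, max(p.end for p in run),
                tuple(run), excluded_from_stitching=False))

    for p in ordered:
        if tss_excluded(p, tss_by_chrom, tss_exclusion):
            regions.append(StitchedEnhancer(
                p.chrom, p.start, p.end, (p,), excluded_from_stitching=True))
            continue
        if run and p.chrom == run[0].chrom and p.start - run_end <= stitch_distance:
            run.append(p)
            run_end = max(run_end, p.end)
        else:
            flush()
            run = [p]
            run_end = p.end
    flush()
    regions.sort(key=lambda r: (r.chrom, r.start, r.end, r.excluded_from_stitching))
    return regions


def rank_enhancers(
    stitched: Sequence[StitchedEnhancer],
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion: int = DEFAULT_TSS_EXCLUSION,
) -> RankedEnhancerTable:
    """Score regions by clamped input-subtracted signal and sort descending.

    The sort is stable with ties broken by (chrom, start), so rank 1 is the
    highest-scoring region.
    """
    order = sorted(
        range(len(stitched)),
        key=lambda i: (-stitched[i].score(), stitched[i].chrom,
                       stitched[i].start, stitched[i].end),
    )
    entries = [stitched[i] for i in order]
    scores = np.array([e.score() for e in entries], dtype=float)
    return RankedEnhancerTable(entries, scores, stitch_distance, tss_exclusion)


def find_se_cutoff(ranked: RankedEnhancerTable | np.ndarray) -> SECutoff:
    """Locate the discrete slope-1 tangent point of the rank-signal curve.

    With scores sorted ascending s_1 <= ... <= s_n, both axes are scaled to
    [0, 1]: x_i = (i-1)/(n-1), y_i = (s_i - s_1)/(s_n - s_1).  The cutoff
    index is argmin_i (y_i - x_i), ties resolved to the largest i (fewest
    super-enhancers); regions scoring strictly above the cutoff score are
    super-enhancers.  Degenerate inputs (n < 3 or constant scores) yield
    n_super = 0 with the degenerate flag set.
    """
    scores = ranked if isinstance(ranked, np.ndarray) else ranked.scores
    s = np.sort(np.asarray(scores, dtype=float))
    n = len(s)
    if n < 3 or s[-1] == s[0]:
        cutoff = float(s[-1]) if n else 0.0
        return SECutoff(cutoff, max(n - 1, 0), 0, degenerate=True)
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    diff = y - x
    # argmin with ties to the largest index
    idx = int(n - 1 - np.argmin(diff[::-1]))
    cutoff_score = float(s[idx])
    n_super = int(np.sum(s > cutoff_score))
    return SECutoff(cutoff_score, idx, n_super)


def classify_super_enhancers(
    ranked: RankedEnhancerTable, cutoff: SECutoff
) -> pd.DataFrame:
    """Flag each ranked region as super (score > cutoff) or typical.

    Returns the hockey-stick table: rank, region coordinates, score,
    is_super.  The flag count must equal ``cutoff.n_super``; a mismatch
    means the cutoff came from a different table.
    """
    flags = ranked.scores > cutoff.cutoff_score
    if int(flags.sum()) != cutoff.n_super:
        raise ValueError(
            "cutoff/table mismatch: flag count "
            f"{int(flags.sum())} != cutoff.n_super {cutoff.n_super}"
        )
    return pd.DataFrame({
        "rank": np.arange(1, len(ranked) + 1),
        "chrom": [e.chrom for e in ranked.entries],
        "start": [e.start for e in ranked.entries],
        "end": [e.end for e in ranked.entries],
        "n_constituents": [len(e.constituents) for e in ranked.entries],
        "tss_excluded": [e.excluded_from_stitching for e in ranked.entries],
        "score": ranked.scores,
        "is_super": flags,
    })


def assign_nearest_gene(
    regions: Sequence[StitchedEnhancer], genes: Sequence[GeneModel]
) -> dict[str, GeneAssignment]:
    """Assign each region the gene minimising |TSS - region midpoint|.

    Ties go to the smaller TSS coordinate, then lexicographic gene_id.
    Regions on chromosomes with no annotated gene are reported unassigned.
    Keys are region ids "chrom:start-end".
    """
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for lst in genes_by_chrom.values():
        lst.sort(key=lambda g: (g.tss, g.gene_id))
    out: dict[str, GeneAssignment] = {}
    for r in regions:
        rid = f"{r.chrom}:{r.start}-{r.end}"
        cands = genes_by_chrom.get(r.chrom)
        if not cands:
            out[rid] = GeneAssignment(None, None)
            continue
        mid = r.midpoint
        best = min(cands, key=lambda g: (abs(g.tss - mid), g.tss, g.gene_id))
        out[rid] = GeneAssignment(best.gene_id, best.tss - mid)
    return out


def call_super_enhancers(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion: int = DEFAULT_TSS_EXCLUSION,
) -> tuple[pd.DataFrame, SECutoff, RankedEnhancerTable, dict[str, GeneAssignment]]:
    """Full caller: stitch, rank, cut, classify and assign nearest genes.

    Returns the classification table (with an added gene_id column), the
    cutoff, the ranked table, and the per-region gene assignment.
    """
    stitched = stitch_enhancers(peaks, genes, stitch_distance, tss_exclusion)
    ranked = rank_enhancers(stitched, stitch_distance, tss_exclusion)
    cutoff = find_se_cutoff(ranked)
    table = classify_super_enhancers(ranked, cutoff)
    assignment = assign_nearest_gene(ranked.entries, genes)
    table["gene_id"] = [
        assignment[ranked.region_id(i)].gene_id or "" for i in range(len(ranked))
    ]
    return table, cutoff, ranked, assignment


def se_gene_set(table: pd.DataFrame) -> frozenset[str]:
    """Genes assigned to regions classified as super-enhancers."""
    return frozenset(
        g for g in table.loc[table["is_super"], "gene_id"] if g
    )
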