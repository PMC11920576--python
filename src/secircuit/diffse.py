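"""Differential super-enhancer gene sets and their DEG intersections.

Set logic between two conditions: genes whose SE assignment exists only in
the post-treatment condition ("gained"), only in the pre-treatment condition
("lost"), or in both ("shared"), intersected with direction-resolved DEG
sets to give candidate target genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import DEGRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiffSESets:
    """Gained / lost / shared SE gene sets between two conditions.

    ``lost_after_ea`` ∪ ``shared`` is the model-condition SE gene set and
    ``gained_after_ea`` ∪ ``shared`` the treated-condition set; the three
    sets are pairwise disjoint.
    """

    gained_after_ea: frozenset[str]
    lost_after_ea: frozenset[str]
    shared: frozenset[str]


@dataclass(frozen=True)
class CandidateGeneSet:
    genes: frozenset[str]
    provenance: str


@dataclass(frozen=True)
class DEGSets:
    up: frozenset[str]
    down: frozenset[str]
    q_max: float
    lfc_min: float


def diff_se_genes(
    model_genes: Iterable[str], ea_genes: Iterable[str]
) -> DiffSESets:
    """Venn decomposition of the two conditions' SE gene sets."""
    model = frozenset(model_genes)
    ea = frozenset(ea_genes)
    out = DiffSESets(
        gained_after_ea=ea - model,
        lost_after_ea=model - ea,
        shared=model & ea,
    )
    logger.info(
        "diff SE genes: lost=%d gained=%d shared=%d",
        len(out.lost_after_ea), len(out.gained_after_ea), len(out.shared),
    )
    return out


def filter_degs(
    records: Sequence[DEGRecord], q_max: float = 0.05, lfc_min: float = 0.0
) -> DEGSets:
    """Split a DEG table into up / down gene sets.

    Up-regulated: qvalue <= q_max and log2fc > lfc_min (strict); down is
    symmetric with log2fc < -lfc_min.  Records with non-finite log2fc are
    skipped with a warning.
    """
    up: set[str] = set()
    down: set[str] = set()
    for r in records:
        if not math.isfinite(r.log2fc):
            logger.warning("skipping %s: non-finite log2fc", r.gene_id)
            continue
        if r.qvalue <= q_max:
            if r.log2fc > lfc_min:
                up.add(r.gene_id)
            elif r.log2fc < -lfc_min:
                down.add(r.gene_id)
    return DEGSets(frozenset(up), frozenset(down), q_max, lfc_min)


INTERSECTION_RULES = ("lost_up_model", "gained_up_ea")


def intersect_candidates(
    diff: DiffSESets, deg_sets: DEGSets, rule: str = "lost_up_model"
) -> CandidateGeneSet:
    """Intersect an SE change set with a DEG direction set.

    ``lost_up_model``: SE genes lost after treatment × genes up-regulated in
    the untreated (model) side of the contrast.  ``gained_up_ea``: SE genes
    gained after treatment × genes up-regulated after treatment — with a
    model-vs-treatment log2FC convention those are the DEG table's down
    genes.  An empty result is a valid outcome, not an error.
    """
    if rule == "lost_up_model":
        genes = diff.lost_after_ea & deg_sets.up
    elif rule == "gained_up_ea":
        genes = diff.gained_after_ea & deg_sets.down
    else:
        raise ValueError(f"unknown intersection rule {rule!r}; "
                         f"expected one of {INTERSECTION_RULES}")
    return CandidateGeneSet(frozenset(genes), provenance=rule)
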