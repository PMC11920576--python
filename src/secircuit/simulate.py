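"""Two-condition synthetic data with planted ground truth.

The generator emulates the statistical structure of an H3K27ac ChIP-seq /
RNA-seq treated-vs-model comparison so that every downstream
stage can be exercised with no external data:

* a random genome with genes on a >= 30 kb grid;
* per-condition enhancer peaks: a log-normal "typical" background plus
  planted super-enhancer clusters (constituents within the stitching
  distance, far above the typical signal) near owner-gene TSSs, producing
  the hockey-stick rank curve;
* partially overlapping SE-gene sets between conditions;
* a DEG table whose up-in-model genes overlap the lost-SE genes by a
  planted count (the candidate set);
* an expression matrix with a group-mean shift planted in one key gene,
  plus two weaker decoy shifts (distinct secondary importance signals,
  mirroring the shape of a real importance ranking);
* an ontology in which the key gene's annotation is a superset of every
  other candidate's (making it the mean-similarity maximiser) and two
  designated runner-up genes carry intermediate overlap;
* SE sequences of a planted, fully interconnected self-regulating TF
  clique, with exact consensus motif insertions.

Every claim recorded in the manifest is re-verified against the generated
objects by a self-audit pass before the bundle is returned; a single
integer seed fixes every emitted byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (BASES, DEGRecord, GeneModel, GeneSetCollection, PWM, Peak,
                 write_deg_table, write_expression_matrix, write_fasta,
                 write_gene_annotation, write_gene_sets,
                 write_motif_library_jaspar, write_peaks)
from .semsim import OntologyDAG

GENE_GRID = 30_000          # minimum TSS spacing, bp
GENE_LENGTH = 2_000
SE_OFFSET_FROM_TSS = 5_000  # first constituent starts here, clear of ±2.5 kb
SE_PEAK_LEN = 1_000
SE_GAP = 2_000              # within-SE constituent gap, well under 12,500
STITCH = 12_500
TSS_EXCL = 2_500
MOTIF_LEN = 10
CONDITIONS = ("model", "ea")


class SimulationError(RuntimeError):
    pass


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic named RNG stream derived from one integer seed."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic bundle.

    The default mirrors the recovery-test design (12 planted SEs per
    condition at 10x the typical median over 500 typical peaks); the
    ``study_scale`` preset carries the full study-scale set sizes (403/77
    SE genes with overlap 36, 18 candidate genes).
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 5_000_000
    n_genes: int = 80
    tf_fraction: float = 0.2
    n_typical_peaks: int = 500
    n_se_model: int = 12
    n_se_ea: int = 12
    typical_signal_mu: float = 1.0
    typical_signal_sigma: float = 0.1
    se_signal_multiplier: float = 10.0
    se_constituents: int = 4
    shared_se_gene_overlap: int = 2
    n_up_model: int = 40
    n_up_ea: int = 10
    candidate_overlap: int = 6
    clique_tfs: tuple[str, ...] = ("TF1", "TF2", "TF3", "TF4")
    own_motif_copies: int = 3
    expression_effect_sd: float = 3.0
    decoy_effect_sd: float = 1.5
    n_samples_per_group: int = 20
    gc: float = 0.5

    def __post_init__(self) -> None:
        counts = {
            "n_chroms": self.n_chroms, "chrom_length": self.chrom_length,
            "n_genes": self.n_genes, "n_typical_peaks": self.n_typical_peaks,
            "n_se_model": self.n_se_model, "n_se_ea": self.n_se_ea,
            "shared_se_gene_overlap": self.shared_se_gene_overlap,
            "n_up_model": self.n_up_model, "n_up_ea": self.n_up_ea,
            "candidate_overlap": self.candidate_overlap,
            "own_motif_copies": self.own_motif_copies,
            "n_samples_per_group": self.n_samples_per_group,
        }
        for name, v in counts.items():
            if v < 0:
                raise SimulationError(f"{name} must be >= 0, got {v}")
        if not 2 <= self.se_constituents <= 6:
            raise SimulationError("se_constituents must be in 2..6")
        if self.se_signal_multiplier < 5:
            raise SimulationError("se_signal_multiplier must be >= 5")
        if not 0.0 < self.gc < 1.0:
            raise SimulationError("gc must be in (0, 1)")
        if self.shared_se_gene_overlap > min(self.n_se_model, self.n_se_ea):
            raise SimulationError("shared overlap exceeds a condition's SE count")
        lost = self.n_se_model - self.shared_se_gene_overlap
        if self.candidate_overlap > min(self.n_up_model, lost):
            raise SimulationError(
                f"candidate_overlap {self.candidate_overlap} exceeds "
                f"min(n_up_model={self.n_up_model}, lost SE genes={lost})")
        if lost < len(self.clique_tfs) + self.candidate_overlap:
            raise SimulationError(
                "model-only SE genes cannot host both the clique and the "
                "candidate set; increase n_se_model or reduce overlap")
        n_tf = int(self.n_genes * self.tf_fraction)
        if len(self.clique_tfs) > n_tf:
            raise SimulationError("clique larger than the TF gene count")

    @classmethod
    def study_scale(cls, seed: int = 0) -> "SimulationConfig":
        """Preset at the full study-scale SE-gene set sizes (403/77,
        overlap 36, 18 candidates)."""
        return cls(
            seed=seed, n_chroms=8, chrom_length=5_000_000, n_genes=560,
            n_se_model=403, n_se_ea=77, shared_se_gene_overlap=36,
            n_up_model=100, n_up_ea=10, candidate_overlap=18,
        )


@dataclass
class RoleTruth:
    """Gene-level planted roles (no coordinates)."""

    gene_ids: list[str]
    tf_genes: frozenset[str]
    model_se_genes: frozenset[str]
    ea_se_genes: frozenset[str]
    candidates: tuple[str, ...]       # lost-SE ∩ up-in-model, ordered
    key_gene: str | None
    rf_decoys: tuple[str, ...]
    friends_runners: tuple[str, ...]
    up_model: frozenset[str]
    up_ea: frozenset[str]
    clique: tuple[str, ...]

    @property
    def lost(self) -> frozenset[str]:
        return self.model_se_genes - self.ea_se_genes

    @property
    def gained(self) -> frozenset[str]:
        return self.ea_se_genes - self.model_se_genes

    @property
    def shared(self) -> frozenset[str]:
        return self.model_se_genes & self.ea_se_genes


@dataclass
class GroundTruthManifest:
    """Everything the generator planted, for acceptance checks."""

    config: SimulationConfig
    roles: RoleTruth
    se_regions: dict[str, dict[str, list[tuple[str, int, int]]]]
    motif_placements: list[tuple[str, str, int]]   # (tf, chrom, pos)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "roles": {
                "gene_ids": self.roles.gene_ids,
                "tf_genes": sorted(self.roles.tf_genes),
                "model_se_genes": sorted(self.roles.model_se_genes),
                "ea_se_genes": sorted(self.roles.ea_se_genes),
                "candidates": list(self.roles.candidates),
                "key_gene": self.roles.key_gene,
                "rf_decoys": list(self.roles.rf_decoys),
                "friends_runners": list(self.roles.friends_runners),
                "up_model": sorted(self.roles.up_model),
                "up_ea": sorted(self.roles.up_ea),
                "clique": list(self.roles.clique),
            },
            "se_regions": self.se_regions,
            "motif_placements": self.motif_placements,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class Bundle:
    """In-memory synthetic dataset; see write_bundle for the file layout."""

    config: SimulationConfig
    genome: dict[str, np.ndarray]        # chrom -> base codes 0..3
    genes: list[GeneModel]
    gene_spans: dict[str, tuple[int, int]]
    peaks: dict[str, list[Peak]]         # condition -> peaks
    pwms: list[PWM]
    deg: list[DEGRecord]
    expression: pd.DataFrame             # genes × samples
    sample_groups: dict[str, str]
    dag: OntologyDAG
    annotations: dict[str, list[str]]
    gene_sets: GeneSetCollection
    manifest: GroundTruthManifest

    def sequence(self, chrom: str, start: int, end: int) -> str:
        codes = self.genome[chrom][start:end]
        return "".join(BASES[c] for c in codes)

    def se_sequences(self, condition: str) -> dict[str, list[str]]:
        """Planted SE constituent sequences keyed by owner gene."""
        out: dict[str, list[str]] = {}
        for gene, regions in self.manifest.se_regions[condition].items():
            out[gene] = [self.sequence(c, s, e) for c, s, e in regions]
        return out


# ---------------------------------------------------------------------------
# Role assignment (pure set logic, cheap; no genome required)
# ---------------------------------------------------------------------------

def plant_roles(config: SimulationConfig) -> RoleTruth:
    """Assign planted roles to gene ids, deterministically from the seed."""
    rng = _substream(config.seed, "roles")
    ids = [f"G{i:04d}" for i in range(config.n_genes)]
    n_owned = config.n_se_model + config.n_se_ea - config.shared_se_gene_overlap
    spare = config.n_genes - n_owned - (
        config.n_up_model - config.candidate_overlap) - config.n_up_ea
    if spare < 0:
        raise SimulationError(
            f"n_genes={config.n_genes} too small for the planted sets "
            f"(need {config.n_genes - spare})")
    perm = rng.permutation(config.n_genes)
    owners = [ids[i] for i in perm[:n_owned]]
    rest = [ids[i] for i in perm[n_owned:]]
    n_model_only = config.n_se_model - config.shared_se_gene_overlap
    model_only = owners[:n_model_only]
    shared = owners[n_model_only:config.n_se_model]
    ea_only = owners[config.n_se_model:]

    clique_k = len(config.clique_tfs)
    # clique genes live among model-only owners and get the configured names
    for j, name in enumerate(config.clique_tfs):
        old = model_only[j]
        model_only[j] = name
        ids[ids.index(old)] = name
    candidates = tuple(model_only[clique_k:clique_k + config.candidate_overlap])
    key_gene = candidates[0] if candidates else None
    rf_decoys = candidates[1:3]
    friends_runners = candidates[3:5]

    up_model = set(candidates)
    extra_up = config.n_up_model - config.candidate_overlap
    up_model |= set(rest[:extra_up])
    up_ea = set(rest[extra_up:extra_up + config.n_up_ea])

    n_tf = int(config.n_genes * config.tf_fraction)
    tf_genes = set(config.clique_tfs)
    pool = [g for g in ids if g not in tf_genes]
    extra_tf = rng.choice(len(pool), size=max(0, n_tf - len(tf_genes)),
                          replace=False)
    tf_genes |= {pool[i] for i in sorted(extra_tf)}

    return RoleTruth(
        gene_ids=ids,
        tf_genes=frozenset(tf_genes),
        model_se_genes=frozenset(model_only) | frozenset(shared),
        ea_se_genes=frozenset(ea_only) | frozenset(shared),
        candidates=candidates,
        key_gene=key_gene,
        rf_decoys=rf_decoys,
        friends_runners=friends_runners,
        up_model=frozenset(up_model),
        up_ea=frozenset(up_ea),
        clique=tuple(config.clique_tfs),
    )


# ---------------------------------------------------------------------------
# Genome and peaks
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig, roles: RoleTruth | None = None
                    ) -> tuple[dict[str, np.ndarray], list[GeneModel],
                               dict[str, tuple[int, int]]]:
    """Random genome with genes on a >= 30 kb grid.

    Background bases are i.i.d. with the configured GC content; genes are
    placed on randomly chosen grid slots, strand at random.  Returns
    (genome arrays, gene models, gene txStart/txEnd spans).
    """
    if roles is None:
        roles = plant_roles(config)
    rng = _substream(config.seed, "genome")
    p = np.array([(1 - config.gc) / 2, config.gc / 2,
                  config.gc / 2, (1 - config.gc) / 2])
    genome = {
        f"chr{i + 1}": rng.choice(4, size=config.chrom_length, p=p).astype(np.int8)
        for i in range(config.n_chroms)
    }
    usable = config.chrom_length - 52_000
    per_chrom = usable // GENE_GRID + 1 if usable >= 0 else 0
    slots = [(f"chr{i + 1}", 20_000 + j * GENE_GRID)
             for i in range(config.n_chroms) for j in range(per_chrom)]
    if len(slots) < config.n_genes:
        raise SimulationError(
            f"{config.n_genes} genes do not fit: only {len(slots)} grid "
            f"slots on {config.n_chroms} x {config.chrom_length} bp")
    chosen = sorted(rng.choice(len(slots), size=config.n_genes, replace=False))
    strands = rng.choice(["+", "-"], size=config.n_genes)
    genes: list[GeneModel] = []
    spans: dict[str, tuple[int, int]] = {}
    for gid, si, strand in zip(roles.gene_ids, chosen, strands):
        chrom, tx_start = slots[si]
        tx_end = tx_start + GENE_LENGTH
        tss = tx_start if strand == "+" else tx_end - 1
        genes.append(GeneModel(gid, chrom, str(strand), tss,
                               gid in roles.tf_genes))
        spans[gid] = (tx_start, tx_end)
    return genome, genes, spans


def _se_layout(gene: GeneModel, k: int) -> list[tuple[str, int, int]]:
    """Constituent intervals of a planted SE near the owner TSS."""
    start = gene.tss + SE_OFFSET_FROM_TSS
    out = []
    for i in range(k):
        s = start + i * (SE_PEAK_LEN + SE_GAP)
        out.append((gene.chrom, s, s + SE_PEAK_LEN))
    return out


def simulate_chipseq_peaks(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    roles: RoleTruth,
    condition: str,
) -> tuple[list[Peak], dict[str, list[tuple[str, int, int]]]]:
    """Peaks for one condition: shared typical background + planted SEs.

    Typical peaks (identical across conditions for one seed) carry
    log-normal signal; each planted constituent carries the typical median
    times the SE multiplier.  Input signal is ~10% of sample signal.
    Returns (peaks, planted SE regions keyed by owner gene).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    by_id = {g.gene_id: g for g in genes}
    owners = sorted(roles.model_se_genes if condition == "model"
                    else roles.ea_se_genes)
    k = config.se_constituents
    regions: dict[str, list[tuple[str, int, int]]] = {}
    tss_sorted: dict[str, np.ndarray] = {}
    for g in genes:
        tss_sorted.setdefault(g.chrom, [])
    for g in genes:
        tss_sorted[g.chrom].append(g.tss)  # type: ignore[arg-type]
    tss_sorted = {c: np.sort(np.array(v)) for c, v in tss_sorted.items()}

    peaks: list[Peak] = []
    median = float(np.exp(config.typical_signal_mu))
    for gene_id in owners:
        g = by_id[gene_id]
        layout = _se_layout(g, k)
        # planted constituents must stay clear of every TSS-exclusion window
        for chrom, s, e in layout:
            tss = tss_sorted[chrom]
            lo = np.searchsorted(tss, s - TSS_EXCL)
            hi = np.searchsorted(tss, (e - 1) + TSS_EXCL, side="right")
            if hi > lo:
                raise SimulationError(
                    f"planted SE of {gene_id} collides with a TSS window")
        srng = _substream(config.seed, f"se:{gene_id}")
        for i, (chrom, s, e) in enumerate(layout):
            sample = median * config.se_signal_multiplier * srng.uniform(0.95, 1.05)
            peaks.append(Peak(chrom, s, e, f"se_{gene_id}_{i}",
                              round(sample, 4), round(sample * 0.1, 4)))
        regions[gene_id] = layout

    peaks.extend(_typical_peaks(config, genes, roles))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end, p.name))
    return peaks, regions


def _blocked_zones(config: SimulationConfig, genes: Sequence[GeneModel],
                   roles: RoleTruth) -> dict[str, list[tuple[int, int]]]:
    """Regions no typical peak may approach: any planted SE hull (either
    condition) padded by the stitching distance plus the max peak length."""
    by_id = {g.gene_id: g for g in genes}
    pad = STITCH + 1_500
    zones: dict[str, list[tuple[int, int]]] = {}
    for gene_id in sorted(roles.model_se_genes | roles.ea_se_genes):
        layout = _se_layout(by_id[gene_id], config.se_constituents)
        chrom = layout[0][0]
        hull = (layout[0][1] - pad, layout[-1][2] + pad)
        zones.setdefault(chrom, []).append(hull)
    for chrom in zones:
        merged: list[tuple[int, int]] = []
        for s, e in sorted(zones[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        zones[chrom] = merged
    return zones


def _typical_peaks(config: SimulationConfig, genes: Sequence[GeneModel],
                   roles: RoleTruth) -> list[Peak]:
    """Typical background peaks in disjoint slots.

    Each slot reserves a stitching-distance margin, so typical peaks never
    stitch with each other or with a planted SE: the planted clusters are
    the only multi-constituent regions and the typical rank curve is the
    single-peak signal law.
    """
    rng = _substream(config.seed, "typical")
    zones = _blocked_zones(config, genes, roles)
    allowed: list[tuple[str, int, int]] = []
    for i in range(config.n_chroms):
        chrom = f"chr{i + 1}"
        pos = 0
        for s, e in zones.get(chrom, []):
            if s - pos > 2_000:
                allowed.append((chrom, pos, s))
            pos = max(pos, e)
        if config.chrom_length - pos > 2_000:
            allowed.append((chrom, pos, config.chrom_length))
    room = 2_000                      # random jitter of the peak start
    slot = room + 1_500 + STITCH + 1  # margin keeps gaps > stitch distance
    slots = [(chrom, s + k * slot)
             for chrom, s, e in allowed for k in range((e - s) // slot)]
    if len(slots) < config.n_typical_peaks:
        raise SimulationError(
            f"only {len(slots)} typical-peak slots for "
            f"{config.n_typical_peaks} peaks; enlarge the genome")
    chosen = sorted(rng.choice(len(slots), size=config.n_typical_peaks,
                               replace=False))
    peaks = []
    for j, si in enumerate(chosen):
        chrom, base = slots[si]
        start = base + int(rng.integers(0, room))
        length = int(rng.integers(500, 1_500))
        sample = float(np.exp(rng.normal(config.typical_signal_mu,
                                         config.typical_signal_sigma)))
        inp = sample * 0.1 * rng.uniform(0.5, 1.5)
        peaks.append(Peak(chrom, start, start + length, f"typ_{j:05d}",
                          round(sample, 4), round(inp, 4)))
    return peaks


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

def simulate_motif_library(config: SimulationConfig, roles: RoleTruth
                           ) -> list[PWM]:
    """One informative PWM per TF gene (consensus probability ~0.97)."""
    pwms = []
    for tf in sorted(roles.tf_genes):
        rng = _substream(config.seed, f"pwm:{tf}")
        consensus = rng.integers(0, 4, size=MOTIF_LEN)
        counts = np.ones((MOTIF_LEN, 4))
        counts[np.arange(MOTIF_LEN), consensus] = 97.0
        pwms.append(PWM.from_counts(tf, counts))
    return pwms


def plant_clique_motifs(config: SimulationConfig,
                        genome: dict[str, np.ndarray],
                        genes: Sequence[GeneModel],
                        roles: RoleTruth,
                        pwms: Sequence[PWM]) -> list[tuple[str, str, int]]:
    """Overwrite genome bases so each clique member's model-condition SE
    carries ``own_motif_copies`` exact consensus sites of every member's
    motif.  Returns the placement list (tf, chrom, position)."""
    by_id = {g.gene_id: g for g in genes}
    pwm_by_tf = {p.tf_name: p for p in pwms}
    placements: list[tuple[str, str, int]] = []
    members = list(roles.clique)
    if not members:
        return placements
    stride = MOTIF_LEN + 15
    per_constituent = (SE_PEAK_LEN - 100) // stride
    need = len(members) * config.own_motif_copies
    if need > per_constituent * config.se_constituents:
        raise SimulationError("SE constituents too small for motif planting")
    for owner in members:
        layout = _se_layout(by_id[owner], config.se_constituents)
        sites = [(chrom, s + 50 + t * stride)
                 for chrom, s, _e in layout for t in range(per_constituent)]
        i = 0
        for tf in members:
            consensus = pwm_by_tf[tf].consensus
            codes = np.array([BASES.index(b) for b in consensus], dtype=np.int8)
            for _copy in range(config.own_motif_copies):
                chrom, pos = sites[i]
                genome[chrom][pos:pos + MOTIF_LEN] = codes
                placements.append((tf, chrom, pos))
                i += 1
    return placements


# ---------------------------------------------------------------------------
# DEG table, expression, ontology
# ---------------------------------------------------------------------------

def simulate_deg_table(config: SimulationConfig, roles: RoleTruth
                       ) -> list[DEGRecord]:
    """DEG records for the model-vs-EA contrast.

    Planted up-in-model genes: log2fc ~ N(+2, 0.25^2), q ~ U(0, 0.01);
    up-after-EA genes the mirror image; all other genes are null
    (log2fc ~ N(0, 0.25^2), q ~ U(0.2, 1)).
    """
    rng = _substream(config.seed, "deg")
    records = []
    for gid in roles.gene_ids:
        if gid in roles.up_model:
            lfc = rng.normal(2.0, 0.25)
            q = rng.uniform(0.0, 0.01)
        elif gid in roles.up_ea:
            lfc = -rng.normal(2.0, 0.25)
            q = rng.uniform(0.0, 0.01)
        else:
            lfc = rng.normal(0.0, 0.25)
            q = rng.uniform(0.2, 1.0)
        records.append(DEGRecord(gid, float(lfc), float(q) * 0.5, float(q)))
    return records


def simulate_expression(config: SimulationConfig, roles: RoleTruth
                        ) -> tuple[pd.DataFrame, dict[str, str]]:
    """FPKM matrix over the candidate genes, two groups.

    The key gene's group means differ by expression_effect_sd within-group
    SDs; the two decoy genes differ by decoy_effect_sd; the rest are
    exchangeable between groups.
    """
    rng = _substream(config.seed, "expr")
    n = config.n_samples_per_group
    genes = list(roles.candidates)
    if not genes:
        raise SimulationError("no candidate genes to express")
    samples = [f"model_{i + 1}" for i in range(n)] + [f"ea_{i + 1}" for i in range(n)]
    groups = dict(zip(samples, ["model"] * n + ["ea"] * n))
    rows = []
    for g in genes:
        mu = rng.uniform(10.0, 50.0)
        sd = 0.15 * mu
        if g == roles.key_gene:
            shift = config.expression_effect_sd * sd
        elif g in roles.rf_decoys:
            shift = config.decoy_effect_sd * sd
        else:
            shift = 0.0
        vals = np.concatenate([
            rng.normal(mu + shift, sd, size=n),
            rng.normal(mu, sd, size=n),
        ])
        rows.append(np.clip(vals, 0.0, None))
    df = pd.DataFrame(rows, index=genes, columns=samples)
    return df, groups


def simulate_ontology(config: SimulationConfig, roles: RoleTruth
                      ) -> tuple[OntologyDAG, dict[str, list[str]],
                                 GeneSetCollection]:
    """Term DAG (>= 30 terms) and candidate annotations.

    Each non-key candidate gets two private leaf terms under rotating
    branches; the key gene is annotated with every candidate leaf (a strict
    superset, making it the mean-similarity maximiser); the two designated
    runner-up genes additionally borrow leaves from several other genes, so
    the similarity ranking below the key gene is deterministic.  Also
    returns branch-level gene sets (GMT semantics) for enrichment.
    """
    candidates = list(roles.candidates)
    others = [g for g in candidates if g != roles.key_gene]
    n_branch = 6
    parents: dict[str, tuple[tuple[str, str], ...]] = {"root": ()}
    for b in range(n_branch):
        parents[f"branch{b}"] = (("root", "is_a"),)
    annotations: dict[str, list[str]] = {g: [] for g in candidates}
    leaves_of: dict[str, list[str]] = {}
    for i, g in enumerate(others):
        leaves = []
        for j in range(2):
            term = f"leaf_{g}_{j}"
            etype = "is_a" if (i + j) % 3 else "part_of"
            parents[term] = ((f"branch{(2 * i + j) % n_branch}", etype),)
            leaves.append(term)
        leaves_of[g] = leaves
        annotations[g] = list(leaves)
    if roles.key_gene is not None:
        annotations[roles.key_gene] = sorted(
            t for ls in leaves_of.values() for t in ls)
    # runner-up genes borrow leaves from other candidates (but never enough
    # to reach the key gene's full coverage)
    donors = [g for g in others if g not in roles.friends_runners]
    for r, runner in enumerate(roles.friends_runners):
        extra = donors[:4 - r] if len(donors) >= 4 - r else donors
        for d in extra:
            annotations[runner].append(leaves_of[d][0])
    pad = 0
    while len(parents) < 30:
        parents[f"filler_{pad}"] = ((f"branch{pad % n_branch}", "is_a"),)
        pad += 1
    dag = OntologyDAG(parents)

    sets = GeneSetCollection()
    for b in range(n_branch):
        members = {g for g, ts in annotations.items()
                   if any(parents[t][0][0] == f"branch{b}" for t in ts
                          if t.startswith("leaf_"))}
        if members:
            sets.add(f"branch{b}_geneset", members, f"genes under branch{b}")
    return dag, annotations, sets


# ---------------------------------------------------------------------------
# Bundle assembly, audit, output
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig) -> Bundle:
    """Generate the full two-condition dataset and self-audit it."""
    roles = plant_roles(config)
    genome, genes, spans = simulate_genome(config, roles)
    model_peaks, model_regions = simulate_chipseq_peaks(config, genes, roles, "model")
    ea_peaks, ea_regions = simulate_chipseq_peaks(config, genes, roles, "ea")
    pwms = simulate_motif_library(config, roles)
    placements = plant_clique_motifs(config, genome, genes, roles, pwms)
    deg = simulate_deg_table(config, roles)
    expr, groups = simulate_expression(config, roles)
    dag, annotations, gene_sets = simulate_ontology(config, roles)
    manifest = GroundTruthManifest(
        config=config, roles=roles,
        se_regions={"model": {g: [list(r) for r in v]  # type: ignore[misc]
                              for g, v in model_regions.items()},
                    "ea": {g: [list(r) for r in v]  # type: ignore[misc]
                           for g, v in ea_regions.items()}},
        motif_placements=placements,
    )
    bundle = Bundle(config, genome, genes, spans,
                    {"model": model_peaks, "ea": ea_peaks},
                    pwms, deg, expr, groups, dag, annotations, gene_sets,
                    manifest)
    audit_bundle(bundle)
    return bundle


def audit_bundle(bundle: Bundle) -> None:
    """Re-verify every manifest claim against the generated objects."""
    cfg = bundle.config
    roles = bundle.manifest.roles
    # Venn counts
    if len(roles.shared) != cfg.shared_se_gene_overlap:
        raise SimulationError("audit: shared SE gene count mismatch")
    if len(roles.model_se_genes) != cfg.n_se_model:
        raise SimulationError("audit: model SE gene count mismatch")
    if len(roles.ea_se_genes) != cfg.n_se_ea:
        raise SimulationError("audit: EA SE gene count mismatch")
    # candidate set: exactly the planted lost ∩ up-in-model genes
    cand = set(roles.candidates)
    if cand != (roles.lost & roles.up_model):
        raise SimulationError("audit: candidates != lost ∩ up_model")
    if len(cand) != cfg.candidate_overlap:
        raise SimulationError("audit: candidate count mismatch")
    if roles.gained & roles.up_ea:
        raise SimulationError("audit: gained ∩ up_ea should be empty")
    # DEG construction
    by_id = {r.gene_id: r for r in bundle.deg}
    for g in roles.up_model:
        r = by_id[g]
        if not (r.qvalue <= 0.05 and r.log2fc > 0):
            raise SimulationError(f"audit: planted up gene {g} not up")
    # planted SE geometry
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in bundle.genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    for cond in CONDITIONS:
        for gene, regions in bundle.manifest.se_regions[cond].items():
            for (c1, s1, e1), (_c2, s2, _e2) in zip(regions, regions[1:]):
                if s2 - e1 > STITCH:
                    raise SimulationError(
                        f"audit: SE of {gene} has gap > {STITCH}")
            for c, s, e in regions:
                tss = tss_by_chrom[c]
                lo = np.searchsorted(tss, s - TSS_EXCL)
                hi = np.searchsorted(tss, (e - 1) + TSS_EXCL, side="right")
                if hi > lo:
                    raise SimulationError(
                        f"audit: SE constituent of {gene} in a TSS window")
    # typical peaks clear of planted hulls
    hulls: dict[str, list[tuple[int, int]]] = {}
    for cond in CONDITIONS:
        for gene, regions in bundle.manifest.se_regions[cond].items():
            hulls.setdefault(regions[0][0], []).append(
                (regions[0][1], regions[-1][2]))
    for cond in CONDITIONS:
        for p in bundle.peaks[cond]:
            if not p.name.startswith("typ_"):
                continue
            for s, e in hulls.get(p.chrom, []):
                if p.start <= e + STITCH and p.end >= s - STITCH:
                    raise SimulationError(
                        f"audit: typical peak {p.name} within stitching "
                        "range of a planted SE")
    # motif copies present as exact substrings
    pwm_by_tf = {p.tf_name: p for p in bundle.pwms}
    for owner in roles.clique:
        seqs = bundle.se_sequences("model").get(owner, [])
        joined = "|".join(seqs)
        for tf in roles.clique:
            n = joined.count(pwm_by_tf[tf].consensus)
            if n < cfg.own_motif_copies:
                raise SimulationError(
                    f"audit: {tf} consensus x{n} < {cfg.own_motif_copies} "
                    f"in SE of {owner}")


def write_bundle(bundle: Bundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle component as plain-text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.tsv",
        "model_peaks": outdir / "peaks_model.bed",
        "ea_peaks": outdir / "peaks_ea.bed",
        "motifs": outdir / "motifs.jaspar",
        "deg": outdir / "deg.tsv",
        "expression": outdir / "expression.tsv",
        "groups": outdir / "sample_groups.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "ontology": outdir / "ontology.tsv",
        "annotations": outdir / "annotations.tsv",
        "manifest": outdir / "manifest.json",
    }
    fasta = {c: "".join(BASES[b] for b in arr)
             for c, arr in bundle.genome.items()}
    write_fasta(fasta, paths["genome"])
    write_gene_annotation(bundle.genes, paths["genes"], bundle.gene_spans)
    write_peaks(bundle.peaks["model"], paths["model_peaks"])
    write_peaks(bundle.peaks["ea"], paths["ea_peaks"])
    write_motif_library_jaspar(bundle.pwms, paths["motifs"])
    write_deg_table(bundle.deg, paths["deg"])
    write_expression_matrix(bundle.expression, paths["expression"])
    pd.DataFrame(sorted(bundle.sample_groups.items()),
                 columns=["sample", "group"]).to_csv(
        paths["groups"], sep="\t", index=False)
    write_gene_sets(bundle.gene_sets, paths["gene_sets"])
    rows = [(t, p, e) for t, ps in bundle.dag.parents.items()
            for p, e in ps]
    pd.DataFrame(sorted(rows), columns=["term", "parent", "edge_type"]
                 ).to_csv(paths["ontology"], sep="\t", index=False)
    arows = [(g, t) for g, ts in bundle.annotations.items() for t in ts]
    pd.DataFrame(sorted(arows), columns=["gene_id", "term"]).to_csv(
        paths["annotations"], sep="\t", index=False)
    bundle.manifest.to_json(paths["manifest"])
    return paths


def read_ontology_table(path: str | Path) -> OntologyDAG:
    """Read the term/parent/edge_type TSV written by write_bundle."""
    df = pd.read_csv(path, sep="\t")
    parents: dict[str, list[tuple[str, str]]] = {}
    for r in df.itertuples(index=False):
        parents.setdefault(str(r.term), []).append((str(r.parent), str(r.edge_type)))
        parents.setdefault(str(r.parent), [])
    return OntologyDAG({t: tuple(v) for t, v in parents.items()})


def read_annotation_table(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.gene_id), []).append(str(r.term))
    return out
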